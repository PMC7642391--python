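"""Robust rank aggregation of independent evidence sources into pair scores.

Each evidence source contributes a ranked list of entities with normalized
ranks in (0, 1]. Receptor-level lists (activity, modulator analysis) are
lifted to the pair level by rank inheritance; unranked entities get the
worst rank 1.0. Under the null that an entity's k normalized ranks are
independent Uniform(0, 1), the j-th smallest rank follows Beta(j, k-j+1);
the aggregation statistic is

    rho = min_j BetaCDF(r_(j); j, k-j+1)

and the final score is the Bonferroni-corrected min(1, k * rho). Small
scores flag entities ranked consistently high across sources; rank-based
aggregation sidesteps the non-comparability of p-values computed under the
different sources' null models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedEvidence",
    "AggregatedPair",
    "expand_to_pairs",
    "rra_rho",
    "aggregate_pairs",
    "count_significant",
]

Pair = tuple[str, str]


@dataclass
class RankedEvidence:
    """One evidence source's entities with normalized ranks in (0, 1].

    ``entries`` maps an entity id (a receptor id, or a (ligand, receptor)
    tuple for pair-level evidence) to its normalized rank position/n.
    """

    evidence_id: str
    entity_level: str  # "pair" or "receptor"
    entries: dict

    def __post_init__(self) -> None:
        if self.entity_level not in ("pair", "receptor"):
            raise ValueError(f"unknown entity level {self.entity_level!r}")
        for ent, r in self.entries.items():
            if not (0.0 < r <= 1.0):
                raise ValueError(
                    f"normalized rank {r} for {ent} outside (0, 1]")

    @classmethod
    def from_ordered(cls, evidence_id: str, entity_level: str,
                     ordered_entities: list) -> "RankedEvidence":
        """Build from a best-to-worst ordered entity list (rank = pos/n)."""
        n = len(ordered_entities)
        return cls(evidence_id, entity_level,
                   {e: (i + 1) / n for i, e in enumerate(ordered_entities)})


@dataclass
class AggregatedPair:
    ligand_id: str
    receptor_id: str
    ranks: list[float] = field(default_factory=list)
    rho: float = 1.0
    score: float = 1.0


def expand_to_pairs(evidence: RankedEvidence,
                    pair_space: list[Pair]) -> RankedEvidence:
    """Lift receptor-level evidence to pair level by rank inheritance.

    Every pair inherits its receptor's normalized rank (ligand identity is
    irrelevant for receptor-level evidence); pairs whose receptor is absent
    from the list get the worst rank 1.0. Pair-level input passes through
    unchanged.
    """
    if evidence.entity_level == "pair":
        return evidence
    entries = {(l, r): evidence.entries.get(r, 1.0) for l, r in pair_space}
    return RankedEvidence(evidence.evidence_id, "pair", entries)


def rra_rho(ranks) -> float:
    """Beta order-statistic minimum over a vector of normalized ranks."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("empty rank vector")
    if np.any((ranks <= 0.0) | (ranks > 1.0)):
        raise ValueError(f"ranks outside (0, 1]: {ranks}")
    k = ranks.size
    r = np.sort(ranks)
    j = np.arange(1, k + 1)
    return float(np.min(stats.beta.cdf(r, j, k - j + 1)))


def aggregate_pairs(evidences: list[RankedEvidence],
                    pair_space: list[Pair],
                    bonferroni: bool = True) -> pd.DataFrame:
    """Aggregate evidence lists over the candidate pair space.

    All receptor-level lists are expanded first. Per pair, score =
    min(1, k * rho) with k the number of evidence lists (``bonferroni=False``
    reports the raw rho as the score). Output is sorted by ascending score,
    ties by ascending rho then lexicographic pair id, with one normalized
    rank column per evidence source.
    """
    if not pair_space:
        raise ValueError("empty pair space")
    if not evidences:
        raise ValueError("no evidence lists")
    expanded = [expand_to_pairs(e, pair_space) for e in evidences]
    k = len(expanded)
    rows = []
    for pair in pair_space:
        ranks = [e.entries.get(pair, 1.0) for e in expanded]
        rho = rra_rho(ranks)
        score = min(1.0, k * rho) if bonferroni else rho
        rows.append((*pair, *ranks, rho, score))
    cols = ["ligand", "receptor",
            *[f"rank_{e.evidence_id}" for e in expanded], "rho", "score"]
    table = pd.DataFrame(rows, columns=cols)
    table = table.sort_values(["score", "rho", "ligand", "receptor"],
                              kind="mergesort").reset_index(drop=True)
    return table


def count_significant(table: pd.DataFrame, alpha: float = 0.01) -> int:
    """Number of aggregated pairs with final score <= alpha."""
    return int((table["score"] <= alpha).sum())
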