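"""Empirical p-values for candidate pairs against per-protein PPI score nulls.

Each protein carries a precomputed interaction-probability score in [0, 1]
against every annotated partner (a structural/contextual PPI prior exported
as a flat table). A candidate ligand-receptor pair is judged against two
empirical nulls: the distribution of the ligand's scores with all of its
*other* partners, and likewise for the receptor. The pair-level p-value is
the maximum of the two one-sided empirical p-values, i.e. the interaction
must look exceptional from both proteins' perspectives; a Fisher combination
of the two sides is available as an alternative rule.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evidence_integration import RankedEvidence

__all__ = [
    "PPIScoreSet",
    "PairPrior",
    "empirical_pvalue",
    "pair_pvalue",
    "candidate_pair_space",
    "rank_pairs_by_ppi",
]

HIGH_CONFIDENCE_SCORE = 0.5  # conventional high-confidence cut on the prior


@dataclass
class PPIScoreSet:
    """All PPI prior scores of one protein against its putative partners."""

    protein_id: str
    partner_scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.protein_id in self.partner_scores:
            raise ValueError(f"self-pair in score set for {self.protein_id}")
        for partner, s in self.partner_scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"score {s} for {self.protein_id}-{partner} outside [0, 1]")

    def null_scores(self, exclude: str) -> np.ndarray:
        """Scores against all partners except ``exclude`` (the tested pair)."""
        return np.asarray(
            [s for p, s in self.partner_scores.items() if p != exclude],
            dtype=float)


@dataclass
class PairPrior:
    ligand_id: str
    receptor_id: str
    score: float
    p_ligand_side: float
    p_receptor_side: float
    p_pair: float
    q_value: float = float("nan")
    high_confidence: bool = False


def empirical_pvalue(s: float, null_scores: np.ndarray) -> float:
    """Add-one empirical p-value of ``s`` against a null score collection.

    p = (1 + #{x in null : x >= s}) / (1 + |null|), guaranteed in (0, 1].
    An empty null carries no evidence and yields p = 1 with a warning.
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"score {s} outside [0, 1]")
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        warnings.warn("empty null model; returning p = 1", stacklevel=2)
        return 1.0
    return (1 + int(np.sum(null_scores >= s))) / (1 + null_scores.size)


def pair_pvalue(ligand_set: PPIScoreSet, receptor_set: PPIScoreSet,
                pair_score: float | None = None,
                combination: str = "max") -> PairPrior:
    """Score one candidate pair against both proteins' empirical nulls.

    ``pair_score`` may be omitted when both score sets contain the pair; if
    present in both it must agree to float precision.
    """
    lig, rec = ligand_set.protein_id, receptor_set.protein_id
    s_l = ligand_set.partner_scores.get(rec)
    s_r = receptor_set.partner_scores.get(lig)
    known = [s for s in (s_l, s_r, pair_score) if s is not None]
    if not known:
        raise ValueError(f"no score available for pair {lig}-{rec}")
    if max(known) - min(known) > 1e-9:
        raise ValueError(
            f"inconsistent pair score for {lig}-{rec}: {sorted(set(known))}")
    s = known[0]

    p_l = empirical_pvalue(s, ligand_set.null_scores(exclude=rec))
    p_r = empirical_pvalue(s, receptor_set.null_scores(exclude=lig))
    if combination == "max":
        p_pair = max(p_l, p_r)
    elif combination == "fisher":
        stat = -2.0 * (math.log(p_l) + math.log(p_r))
        p_pair = float(stats.chi2.sf(stat, df=4))
        p_pair = min(max(p_pair, np.nextafter(0.0, 1.0)), 1.0)
    else:
        raise ValueError(f"unknown combination rule {combination!r}")
    return PairPrior(lig, rec, float(s), p_l, p_r, p_pair,
                     high_confidence=s > HIGH_CONFIDENCE_SCORE)


def candidate_pair_space(ligands: list[str],
                         receptors: list[str]) -> list[tuple[str, str]]:
    """Full ligand x receptor cross product, excluding self-pairs.

    The count is ``|L|*|R| - |L & R|`` since an id present on both sides
    contributes exactly one excluded self-pair.
    """
    if not ligands or not receptors:
        raise ValueError("ligand and receptor lists must be non-empty")
    for name, ids in (("ligand", ligands), ("receptor", receptors)):
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated {name} ids: {dupes}")
    return [(l, r) for l, r in itertools.product(ligands, receptors) if l != r]


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float),
                                         method="bh")


def rank_pairs_by_ppi(pairs: list[PairPrior],
                      high_confidence_only: bool = False
                      ) -> tuple[pd.DataFrame, RankedEvidence]:
    """Order pairs by ascending p_pair and attach BH q-values and ranks.

    Ties on p_pair are broken by descending raw score, then by the
    lexicographic pair id. Normalized rank is position/n over the sorted
    list. Returns the sorted table and the pair-level ranked evidence.
    """
    if high_confidence_only:
        pairs = [p for p in pairs if p.high_confidence]
    if not pairs:
        raise ValueError("no pairs to rank")
    pairs = sorted(pairs, key=lambda p: (p.p_pair, -p.score,
                                         p.ligand_id, p.receptor_id))
    q = bh_qvalues([p.p_pair for p in pairs])
    n = len(pairs)
    rows = []
    entries: dict[tuple[str, str], float] = {}
    for i, p in enumerate(pairs, start=1):
        p.q_value = float(q[i - 1])
        norm_rank = i / n
        entries[(p.ligand_id, p.receptor_id)] = norm_rank
        rows.append((p.ligand_id, p.receptor_id, p.score, p.p_ligand_side,
                     p.p_receptor_side, p.p_pair, p.q_value, norm_rank))
    table = pd.DataFrame(rows, columns=["ligand", "receptor", "score",
                                        "p_ligand", "p_receptor", "p_pair",
                                        "q", "norm_rank"])
    evidence = RankedEvidence(evidence_id="ppi", entity_level="pair",
                              entries=entries)
    return table, evidence
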