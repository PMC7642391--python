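"""Conditional-mutual-information screen for upstream modulators of a TF.

A candidate receptor modulates a transcription factor's activity when the
dependence between the TF and its targets varies with the receptor's
expression. For every (modulator, TF, target) triplet the conditional
mutual information I(TF; target | modulator) is estimated by binning the
modulator's expression into equal-frequency strata and averaging the
within-stratum MI. Triplets at or above the dataset-mean CMI are retained;
a modulator whose triplets are retained more often than the global
retention rate (binomial tail) ranks as a likely modulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evidence_integration import RankedEvidence
from .regulon_net import ExpressionMatrix, Regulon, mutual_information

__all__ = [
    "TripletRecord",
    "ModulatorResult",
    "conditional_mi",
    "cindy_triplets",
    "rank_modulators",
]


@dataclass
class TripletRecord:
    modulator_id: str
    tf_id: str
    target_id: str
    cmi: float
    retained: bool = False


@dataclass
class ModulatorResult:
    modulator_id: str
    n_triplets: int
    n_retained: int
    p_modulation: float


def conditional_mi(x, y, z, n_bins_z: int = 3, **mi_kwargs) -> float:
    """I(X; Y | Z) in nats via equal-frequency conditioning bins on Z.

    CMI = sum_b (n_b / n) * MI(x, y | samples in bin b). A constant Z
    cannot be stratified and falls back to a single bin (CMI = MI) with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be 1-D vectors of equal length")
    if n_bins_z < 1:
        raise ValueError("n_bins_z must be >= 1")
    n = x.size
    if n < 10 * n_bins_z:
        raise ValueError(
            f"need at least {10 * n_bins_z} samples for {n_bins_z} bins")
    if np.ptp(z) == 0 and n_bins_z > 1:
        warnings.warn("constant conditioning vector; using a single bin",
                      stacklevel=2)
        n_bins_z = 1
    order = np.argsort(z, kind="mergesort")
    total = 0.0
    for bin_idx in np.array_split(order, n_bins_z):
        total += (bin_idx.size / n) * mutual_information(
            x[bin_idx], y[bin_idx], **mi_kwargs)
    return float(total)


def cindy_triplets(expr: ExpressionMatrix, modulators: list[str], tf: str,
                   tf_regulon: Regulon, n_bins_z: int = 3,
                   **mi_kwargs) -> list[TripletRecord]:
    """Score every (modulator, TF, regulon-target) triplet and flag retention.

    x is the TF profile, y a regulon target's profile, z the modulator's
    profile. The retention cut is the mean CMI over all computed triplets.
    Modulators or targets absent from the expression matrix are dropped
    with a warning; an absent TF is an error.
    """
    genes = set(expr.gene_ids)
    if tf not in genes:
        raise ValueError(f"TF {tf!r} absent from expression matrix")
    usable_mods = [m for m in modulators if m in genes and m != tf]
    skipped = sorted(set(modulators) - set(usable_mods) - {tf})
    if skipped:
        warnings.warn(f"modulators absent from expression matrix, dropped: "
                      f"{skipped}", stacklevel=2)
    if not usable_mods:
        raise ValueError("no usable modulators")
    targets = [t for t in tf_regulon.targets if t in genes]
    if not targets:
        raise ValueError(f"no regulon target of {tf!r} in expression matrix")

    x = expr.values.loc[tf].to_numpy(dtype=float)
    records: list[TripletRecord] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mod in usable_mods:
            z = expr.values.loc[mod].to_numpy(dtype=float)
            for t in targets:
                if t == mod:
                    continue
                y = expr.values.loc[t].to_numpy(dtype=float)
                cmi = conditional_mi(x, y, z, n_bins_z=n_bins_z, **mi_kwargs)
                records.append(TripletRecord(mod, tf, t, cmi))
    mean_cmi = float(np.mean([r.cmi for r in records]))
    for r in records:
        r.retained = r.cmi >= mean_cmi
    return records


def rank_modulators(triplets: list[TripletRecord]
                    ) -> tuple[pd.DataFrame, RankedEvidence]:
    """Binomial-tail enrichment of retained triplets per modulator.

    With global retention rate p0, a modulator with n triplets of which k
    are retained gets p = P(Binomial(n, p0) >= k). Ranking is ascending p,
    ties broken by descending retained fraction then modulator id.
    """
    if not triplets:
        raise ValueError("no triplets")
    p0 = sum(t.retained for t in triplets) / len(triplets)
    per_mod: dict[str, list[TripletRecord]] = {}
    for t in triplets:
        per_mod.setdefault(t.modulator_id, []).append(t)
    results: list[ModulatorResult] = []
    for mod, recs in per_mod.items():
        n = len(recs)
        k = sum(r.retained for r in recs)
        # P(X >= k) with the k = 0 boundary exactly 1
        p = 1.0 if k == 0 else float(stats.binom.sf(k - 1, n, p0))
        results.append(ModulatorResult(mod, n, k, min(p, 1.0)))
    results.sort(key=lambda r: (r.p_modulation,
                                -(r.n_retained / r.n_triplets),
                                r.modulator_id))
    n_mod = len(results)
    rows = [(r.modulator_id, r.n_triplets, r.n_retained, r.p_modulation,
             (i + 1) / n_mod) for i, r in enumerate(results)]
    table = pd.DataFrame(rows, columns=["modulator", "n_triplets",
                                        "n_retained", "p", "norm_rank"])
    evidence = RankedEvidence(
        evidence_id="cindy", entity_level="receptor",
        entries={r.modulator_id: (i + 1) / n_mod
                 for i, r in enumerate(results)})
    return table, evidence


def triplets_to_frame(triplets: list[TripletRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.modulator_id, t.tf_id, t.target_id, t.cmi, t.retained)
         for t in triplets],
        columns=["modulator", "tf", "target", "cmi", "retained"])
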