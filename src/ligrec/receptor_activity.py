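"""Regulon-enrichment inference of differential receptor activity.

A receptor's activity change between two conditions is read out from the
coordinated differential expression of its transcriptional targets, the way
a multiplexed reporter assay would: targets are weighted by regulation mode
(sign) and edge confidence, and their rank positions in the differential
signature are combined into a normalized enrichment score (NES) that is
N(0, 1) under the null of a random signature.

The enrichment has two components: a *directed* part that rewards activated
targets at the top (and repressed targets at the bottom) of the signed
signature, and a *magnitude* part, engaged when the regulation mode is
uncertain (|mode| < 1), that rewards targets extreme in |stat| regardless
of direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evidence_integration import RankedEvidence
from .regulon_net import ExpressionMatrix, Regulon

__all__ = [
    "Signature",
    "ActivityResult",
    "signature_from_expression",
    "area_nes",
    "rank_receptors_by_activity",
]


@dataclass
class Signature:
    """Per-gene differential statistic (z-scale) between two conditions."""

    stat: pd.Series  # index: gene ids
    derivation: str = ""

    def __post_init__(self) -> None:
        if self.stat.index.duplicated().any():
            raise ValueError("duplicate gene ids in signature")
        if not np.isfinite(self.stat.to_numpy(dtype=float)).all():
            raise ValueError("signature statistics must be finite")


@dataclass
class ActivityResult:
    regulator_id: str
    nes: float
    p_activation: float  # one-sided, activation tail: 1 - Phi(NES)
    n_targets_used: int


def signature_from_expression(case: ExpressionMatrix,
                              ctrl: ExpressionMatrix) -> Signature:
    """Two-sample differential signature on the shared gene universe.

    Per gene, a Welch t statistic (case vs control) is mapped to a z-score
    through its two-sided p-value, signed by the direction of the change.
    Genes with zero variance on both sides get stat 0 with a warning.
    """
    shared = [g for g in case.gene_ids if g in set(ctrl.gene_ids)]
    if not shared:
        raise ValueError("case and control share no genes")
    a = case.values.loc[shared].to_numpy(dtype=float)
    b = ctrl.values.loc[shared].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per condition")

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} genes with zero variance in "
                      "both groups; stat set to 0", stacklevel=2)
    # two-sided p -> z magnitude, signed by the direction of change;
    # clip away from 0/1 to keep the quantile finite
    p = np.clip(p, 1e-300, 1.0)
    z = stats.norm.isf(p / 2.0) * np.sign(diff)
    z[degenerate] = 0.0
    return Signature(pd.Series(z, index=pd.Index(shared), name="stat"),
                     derivation="case_vs_control")


def _signature_quantile_z(sig: Signature) -> tuple[pd.Series, pd.Series]:
    """Signed and magnitude rank-quantile z-scores over the signature.

    Directed component: z_i = Phi^{-1}((rank_i - 0.5) / n) over the signed
    stats. Magnitude component: ranks of |stat| mapped into the upper half,
    z*_i = Phi^{-1}(0.5 + (rank|stat|_i - 0.5) / (2n)). Tied stats receive
    average (mid) ranks.
    """
    s = sig.stat
    n = s.size
    r_signed = stats.rankdata(s.to_numpy(), method="average")
    z_signed = stats.norm.ppf((r_signed - 0.5) / n)
    r_abs = stats.rankdata(np.abs(s.to_numpy()), method="average")
    z_abs = stats.norm.ppf(0.5 + (r_abs - 0.5) / (2 * n))
    return (pd.Series(z_signed, index=s.index),
            pd.Series(z_abs, index=s.index))


def area_nes(sig: Signature, reg: Regulon) -> ActivityResult:
    """Weighted two-component regulon enrichment of a signature.

    With target mode m_t and weight w_t, the directed part is
    D = sum_t w_t m_t z_t and the magnitude part is
    T = sum_t w_t (1 - |m_t|) z*_t;
    NES = (D + T) / sqrt(sum (w m)^2 + sum (w (1-|m|))^2), standard normal
    under a random signature. p_activation = 1 - Phi(NES).
    """
    z_signed, z_abs = _signature_quantile_z(sig)
    targets = [t for t in reg.targets if t in z_signed.index]
    dropped = len(reg.targets) - len(targets)
    if not targets:
        raise ValueError(
            f"regulon {reg.regulator_id} has no targets in the signature")
    if dropped:
        warnings.warn(f"regulon {reg.regulator_id}: {dropped} targets absent "
                      "from the signature, dropped", stacklevel=2)
    m = np.array([reg.targets[t][0] for t in targets])
    w = np.array([reg.targets[t][1] for t in targets])
    zs = z_signed.loc[targets].to_numpy()
    za = z_abs.loc[targets].to_numpy()
    directed = float(np.sum(w * m * zs))
    magnitude = float(np.sum(w * (1.0 - np.abs(m)) * za))
    denom = float(np.sqrt(np.sum((w * m) ** 2)
                          + np.sum((w * (1.0 - np.abs(m))) ** 2)))
    if denom == 0.0:
        raise ValueError(f"regulon {reg.regulator_id} has zero total weight")
    nes = (directed + magnitude) / denom
    return ActivityResult(reg.regulator_id, nes, float(stats.norm.sf(nes)),
                          len(targets))


def rank_receptors_by_activity(sig: Signature,
                               regulons: dict[str, Regulon],
                               two_sided: bool = False
                               ) -> tuple[pd.DataFrame, RankedEvidence]:
    """Rank regulators by activation p-value; attach normalized ranks.

    Regulators whose regulon has no overlap with the signature are skipped
    with a warning; an error is raised if every regulon fails. Ordering is
    ascending p (ties by descending NES, then regulator id). With
    ``two_sided=True`` the ranking p is 2 * (1 - Phi(|NES|)) instead of the
    activation tail.
    """
    if not regulons:
        raise ValueError("no regulons supplied")
    results: list[ActivityResult] = []
    for rid, reg in regulons.items():
        try:
            results.append(area_nes(sig, reg))
        except ValueError as exc:
            warnings.warn(f"skipping regulator {rid}: {exc}", stacklevel=2)
    if not results:
        raise ValueError("no regulon overlaps the signature")

    def rank_p(res: ActivityResult) -> float:
        if two_sided:
            return float(2.0 * stats.norm.sf(abs(res.nes)))
        return res.p_activation

    results.sort(key=lambda r: (rank_p(r), -r.nes, r.regulator_id))
    n = len(results)
    rows = [(r.regulator_id, r.nes, r.p_activation, r.n_targets_used,
             (i + 1) / n) for i, r in enumerate(results)]
    table = pd.DataFrame(rows, columns=["regulator", "nes", "p_activation",
                                        "n_targets", "norm_rank"])
    evidence = RankedEvidence(
        evidence_id="viper", entity_level="receptor",
        entries={r.regulator_id: (i + 1) / n for i, r in enumerate(results)})
    return table, evidence
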