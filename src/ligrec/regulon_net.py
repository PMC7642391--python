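"""Regulon inference from expression data: MI, permutation threshold, DPI.

A receptor-centered transcriptional network is reverse-engineered from a
gene-expression compendium in three steps:

1. Pairwise mutual information between each candidate regulator and every
   gene, estimated on copula-transformed data by recursive adaptive
   partitioning.
2. An edge-significance threshold taken as a quantile of MI over randomly
   permuted gene pairs.
3. Data-processing-inequality pruning: in every fully connected triple the
   weakest edge is removed, suppressing indirect interactions.

Regulators retaining at least ``min_targets`` targets form the interactome;
each target carries a regulation mode (signed Spearman correlation) and a
confidence weight (MI normalized within the regulon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "Regulon",
    "mutual_information",
    "mi_significance_threshold",
    "dpi_prune",
    "build_regulons",
]

MIN_SAMPLES_WARN = 30


@dataclass
class ExpressionMatrix:
    """Continuous expression values, genes x samples, no missing entries."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {sorted(set(dups))}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.shape[1] < MIN_SAMPLES_WARN:
            warnings.warn(
                f"only {self.values.shape[1]} samples; network inference "
                f"is unreliable below {MIN_SAMPLES_WARN}", stacklevel=2)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Regulon:
    """A regulator with its transcriptional targets.

    ``targets`` maps target id -> (mode, weight) with mode in [-1, 1]
    (sign and strength of regulation) and weight in (0, 1] (relative edge
    confidence, 1 for the regulon's strongest target).
    """

    regulator_id: str
    targets: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.regulator_id in self.targets:
            raise ValueError(
                f"regulator {self.regulator_id} cannot target itself")
        for t, (m, w) in self.targets.items():
            if not (-1.0 <= m <= 1.0):
                raise ValueError(f"mode {m} for target {t} outside [-1, 1]")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"weight {w} for target {t} outside (0, 1]")

    def __len__(self) -> int:
        return len(self.targets)


def _copula(x: np.ndarray) -> np.ndarray:
    """Rank/n transform onto (0, 1] (average ranks for ties)."""
    return stats.rankdata(x, method="average") / x.size


def mutual_information(x, y, alpha_split: float = 1.0,
                       min_subcell_points: int = 4) -> float:
    """Adaptive-partitioning MI estimate (nats) on copula-transformed data.

    Starting from the unit square, a cell is recursively split at the
    marginal medians of its points into four subcells while it holds at
    least ``4 * min_subcell_points`` points (so each subcell expects
    ``min_subcell_points`` or more). With ``alpha_split < 1`` the split is
    additionally gated on a chi-squared uniformity test over the four
    quadrant counts (df = 3) rejecting at that level; the gate is off by
    default because it cuts the recursion short in small cells and badly
    underestimates strong dependence, while the positive bias of the
    ungated estimator on independent data is absorbed by the permutation
    threshold computed with the same estimator. The estimate is the sum
    over leaf cells of (n_c/n) * ln[(n_c/n) / area_c], non-negative by the
    log-sum inequality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector; MI = 0", stacklevel=2)
        return 0.0

    u = _copula(x)
    v = _copula(y)
    gated = alpha_split < 1.0
    chi2_crit = stats.chi2.isf(alpha_split, df=3) if gated else 0.0

    total = 0.0
    # stack of (point index array, cell bounds u_lo, u_hi, v_lo, v_hi)
    stack = [(np.arange(n), 0.0, 1.0, 0.0, 1.0)]
    while stack:
        idx, ulo, uhi, vlo, vhi = stack.pop()
        nc = idx.size
        if nc == 0:
            continue
        split = False
        if nc >= 4 * min_subcell_points:
            cu, cv = u[idx], v[idx]
            mu = float(np.median(cu))
            mv = float(np.median(cv))
            # degenerate medians (heavy ties) cannot partition the cell
            if ulo < mu < uhi and vlo < mv < vhi:
                left = cu <= mu
                bottom = cv <= mv
                quads = [idx[left & bottom], idx[left & ~bottom],
                         idx[~left & bottom], idx[~left & ~bottom]]
                if gated:
                    counts = np.array([q.size for q in quads], dtype=float)
                    chi2 = float(np.sum((counts - nc / 4) ** 2) / (nc / 4))
                    split = chi2 > chi2_crit
                else:
                    split = True
                if split:
                    bounds = [(ulo, mu, vlo, mv), (ulo, mu, mv, vhi),
                              (mu, uhi, vlo, mv), (mu, uhi, mv, vhi)]
                    for q, b in zip(quads, bounds):
                        stack.append((q, *b))
        if not split:
            p = nc / n
            area = (uhi - ulo) * (vhi - vlo)
            total += p * np.log(p / area)
    return float(total)


def mi_significance_threshold(expr: ExpressionMatrix, n_perm: int = 1000,
                              alpha: float = 0.05,
                              rng: np.random.Generator | None = None,
                              **mi_kwargs) -> float:
    """(1 - alpha) quantile of MI over randomly permuted gene pairs.

    Each draw picks a random pair of distinct genes and shuffles one of the
    two expression vectors, destroying any dependence while preserving the
    marginals. Seeded and reproducible through ``rng``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable quantile")
    if rng is None:
        rng = np.random.default_rng()
    vals = expr.values.to_numpy(dtype=float)
    n_genes = vals.shape[0]
    if n_genes < 2:
        raise ValueError("need at least two genes")
    null = np.empty(n_perm)
    for i in range(n_perm):
        gi, gj = rng.choice(n_genes, size=2, replace=False)
        shuffled = rng.permutation(vals[gj])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null[i] = mutual_information(vals[gi], shuffled, **mi_kwargs)
    return float(np.quantile(null, 1.0 - alpha))


def dpi_prune(edges: list[tuple[str, str, float]],
              tolerance: float = 0.0) -> list[tuple[str, str, float]]:
    """Data-processing-inequality pruning of an undirected weighted graph.

    For every fully connected triple the minimum-MI edge is removed when its
    weight is strictly below ``min(other two) * (1 - tolerance)``; exact
    ties keep all three edges. Removal decisions are computed on the input
    graph and applied simultaneously, so the result does not depend on
    triangle visiting order.
    """
    if not (0.0 <= tolerance < 1.0):
        raise ValueError("tolerance must be in [0, 1)")
    weight: dict[frozenset, float] = {}
    adj: dict[str, set[str]] = {}
    for a, b, w in edges:
        if a == b:
            raise ValueError(f"self-edge on {a}")
        if w <= 0:
            raise ValueError(f"non-positive MI weight on {a}-{b}")
        key = frozenset((a, b))
        if key in weight:
            raise ValueError(f"duplicate edge {a}-{b}")
        weight[key] = w
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    to_remove: set[frozenset] = set()
    for a, b in list(weight):
        for c in adj[a] & adj[b]:
            w_ab = weight[frozenset((a, b))]
            w_ac = weight[frozenset((a, c))]
            w_bc = weight[frozenset((b, c))]
            if w_ab < min(w_ac, w_bc) * (1.0 - tolerance):
                to_remove.add(frozenset((a, b)))
    return [(a, b, w) for a, b, w in edges
            if frozenset((a, b)) not in to_remove]


def build_regulons(expr: ExpressionMatrix, regulators: list[str],
                   min_targets: int = 25, alpha: float = 0.05,
                   n_perm: int = 1000, tolerance: float = 0.0,
                   rng: np.random.Generator | None = None,
                   mi_threshold: float | None = None,
                   **mi_kwargs) -> dict[str, Regulon]:
    """Infer one regulon per regulator from an expression compendium.

    Edges regulator-gene with MI at or above the permutation threshold are
    kept, DPI-pruned, and grouped per regulator; the mode is the Spearman
    correlation between regulator and target profiles and the weight is the
    edge MI normalized by the regulon's strongest edge. Regulators with
    fewer than ``min_targets`` surviving targets are excluded (small
    regulons degrade downstream activity inference).
    """
    if not regulators:
        raise ValueError("empty regulator list")
    genes = set(expr.gene_ids)
    missing = [r for r in regulators if r not in genes]
    if missing:
        warnings.warn(f"regulators absent from expression matrix, dropped: "
                      f"{sorted(missing)}", stacklevel=2)
    regulators = [r for r in regulators if r in genes]
    if not regulators:
        raise ValueError("no regulator is present in the expression matrix")

    if mi_threshold is None:
        mi_threshold = mi_significance_threshold(expr, n_perm=n_perm,
                                                 alpha=alpha, rng=rng,
                                                 **mi_kwargs)

    vals = expr.values
    reg_set = set(regulators)
    edges: list[tuple[str, str, float]] = []
    seen: set[frozenset] = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in regulators:
            xr = vals.loc[r].to_numpy(dtype=float)
            for g in expr.gene_ids:
                if g == r:
                    continue
                key = frozenset((r, g))
                if g in reg_set and key in seen:
                    continue
                seen.add(key)
                mi = mutual_information(xr, vals.loc[g].to_numpy(dtype=float),
                                        **mi_kwargs)
                if mi >= mi_threshold and mi > 0:
                    edges.append((r, g, mi))

    edges = dpi_prune(edges, tolerance=tolerance)

    neighbors: dict[str, list[tuple[str, float]]] = {r: [] for r in regulators}
    for a, b, w in edges:
        if a in reg_set:
            neighbors[a].append((b, w))
        if b in reg_set:
            neighbors[b].append((a, w))

    regulons: dict[str, Regulon] = {}
    for r in regulators:
        targs = neighbors[r]
        if len(targs) < min_targets:
            continue
        max_mi = max(w for _, w in targs)
        xr = vals.loc[r].to_numpy(dtype=float)
        tmap: dict[str, tuple[float, float]] = {}
        for t, w in sorted(targs):
            rho = stats.spearmanr(xr, vals.loc[t].to_numpy(dtype=float)).statistic
            tmap[t] = (float(rho), w / max_mi)
        regulons[r] = Regulon(r, tmap)
    return regulons


def regulons_to_frame(regulons: dict[str, Regulon]) -> pd.DataFrame:
    """Flatten a regulon set to a 4-column table (adjacency-like layout)."""
    rows = [(r, t, m, w)
            for r, reg in sorted(regulons.items())
            for t, (m, w) in sorted(reg.targets.items())]
    return pd.DataFrame(rows, columns=["regulator", "target", "mode", "weight"])


def regulons_from_frame(frame: pd.DataFrame) -> dict[str, Regulon]:
    out: dict[str, Regulon] = {}
    for r, grp in frame.groupby("regulator", sort=True):
        targets = {str(row.target): (float(row.mode), float(row.weight))
                   for row in grp.itertuples()}
        if len(targets) != len(grp):
            raise ValueError(f"duplicate targets in regulon {r}")
        out[str(r)] = Regulon(str(r), targets)
    return out
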