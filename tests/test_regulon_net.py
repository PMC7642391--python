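import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ligrec.regulon_net import (ExpressionMatrix, Regulon, build_regulons,
                                dpi_prune, mi_significance_threshold,
                                mutual_information, regulons_from_frame,
                                regulons_to_frame)


# -- mutual information -------------------------------------------------------

def test_mi_input_validation():
    x = np.arange(20, dtype=float)
    with pytest.raises(ValueError, match="equal length"):
        mutual_information(x, x[:10])
    with pytest.raises(ValueError, match="at least 10"):
        mutual_information(x[:5], x[:5])
    with pytest.raises(ValueError, match="finite"):
        mutual_information(np.r_[x[:-1], np.nan], x)


def test_mi_constant_vector_warns_and_returns_zero(rng):
    with pytest.warns(UserWarning, match="constant"):
        assert mutual_information(np.ones(50), rng.normal(size=50)) == 0.0


def test_mi_nonnegative_and_symmetric(rng):
    x = rng.normal(size=200)
    y = rng.normal(size=200)
    mi_xy = mutual_information(x, y)
    assert mi_xy >= 0.0
    assert mi_xy == pytest.approx(mutual_information(y, x), abs=1e-12)


def test_mi_invariant_under_monotone_transforms(rng):
    x = rng.normal(size=300)
    y = x + rng.normal(scale=0.5, size=300)
    base = mutual_information(x, y)
    assert mutual_information(np.exp(x), y) == pytest.approx(base, abs=1e-12)
    assert mutual_information(x, y ** 3) == pytest.approx(base, abs=1e-12)


def test_mi_orders_dependence_strength(rng):
    x = rng.normal(size=500)
    strong = x + rng.normal(scale=0.2, size=500)
    weak = x + rng.normal(scale=2.0, size=500)
    indep = rng.normal(size=500)
    assert mutual_information(x, strong) > mutual_information(x, weak) \
        > mutual_information(x, indep)


def test_mi_detects_nonmonotone_dependence(rng):
    x = rng.normal(size=500)
    y = x ** 2 + rng.normal(scale=0.1, size=500)  # zero linear correlation
    indep = rng.normal(size=500)
    assert mutual_information(x, y) > mutual_information(x, indep) + 0.2


# -- permutation threshold ----------------------------------------------------

def small_expr(rng, n_genes=30, n_samples=80):
    vals = rng.normal(size=(n_genes, n_samples))
    frame = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"s{i}" for i in range(n_samples)])
    return ExpressionMatrix(frame)


def test_mi_threshold_reproducible_and_positive(rng):
    expr = small_expr(rng)
    t1 = mi_significance_threshold(expr, n_perm=200, alpha=0.05,
                                   rng=np.random.default_rng(7))
    t2 = mi_significance_threshold(expr, n_perm=200, alpha=0.05,
                                   rng=np.random.default_rng(7))
    assert t1 == t2 > 0.0


def test_mi_threshold_monotone_in_alpha(rng):
    expr = small_expr(rng)
    strict = mi_significance_threshold(expr, n_perm=300, alpha=0.01,
                                       rng=np.random.default_rng(7))
    loose = mi_significance_threshold(expr, n_perm=300, alpha=0.2,
                                      rng=np.random.default_rng(7))
    assert strict > loose


def test_mi_threshold_controls_false_positive_rate(rng):
    # fraction of fresh independent pairs above the alpha=0.05 threshold
    # should sit near 5%
    expr = small_expr(rng, n_genes=40)
    thr = mi_significance_threshold(expr, n_perm=1000, alpha=0.05,
                                    rng=np.random.default_rng(11))
    hits = sum(mutual_information(rng.normal(size=80), rng.normal(size=80))
               >= thr for _ in range(400))
    assert 0.005 < hits / 400 < 0.15


def test_mi_threshold_validation(rng):
    expr = small_expr(rng)
    with pytest.raises(ValueError, match="n_perm"):
        mi_significance_threshold(expr, n_perm=10)


# -- DPI ----------------------------------------------------------------------

def test_dpi_removes_weakest_edge_of_triangle():
    edges = [("a", "b", 1.0), ("b", "c", 0.8), ("a", "c", 0.3)]
    kept = dpi_prune(edges)
    assert ("a", "c", 0.3) not in kept and len(kept) == 2


def test_dpi_exact_tie_keeps_all():
    edges = [("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)]
    assert dpi_prune(edges) == edges


def test_dpi_no_triangle_no_pruning():
    edges = [("a", "b", 0.1), ("b", "c", 0.9), ("c", "d", 0.2)]
    assert dpi_prune(edges) == edges


def test_dpi_tolerance_protects_close_edges():
    edges = [("a", "b", 1.0), ("b", "c", 0.95), ("a", "c", 0.90)]
    assert len(dpi_prune(edges, tolerance=0.0)) == 2
    assert len(dpi_prune(edges, tolerance=0.2)) == 3


def test_dpi_validation():
    with pytest.raises(ValueError, match="self-edge"):
        dpi_prune([("a", "a", 0.5)])
    with pytest.raises(ValueError, match="duplicate edge"):
        dpi_prune([("a", "b", 0.5), ("b", "a", 0.4)])
    with pytest.raises(ValueError, match="non-positive"):
        dpi_prune([("a", "b", 0.0)])
    with pytest.raises(ValueError, match="tolerance"):
        dpi_prune([("a", "b", 0.5)], tolerance=1.0)


def test_dpi_order_independent(rng):
    nodes = [f"n{i}" for i in range(8)]
    edges = []
    for i in range(8):
        for j in range(i + 1, 8):
            if rng.random() < 0.6:
                edges.append((nodes[i], nodes[j], float(rng.random()) + 0.01))
    ref = {frozenset((a, b)) for a, b, _ in dpi_prune(edges)}
    perm = [edges[i] for i in rng.permutation(len(edges))]
    assert {frozenset((a, b)) for a, b, _ in dpi_prune(perm)} == ref


# -- regulon construction -----------------------------------------------------

def planted_expr(rng, n_targets=30, n_other=20, n_samples=120):
    reg = rng.normal(size=n_samples)
    rows = {"REG": reg}
    modes = {}
    for i in range(n_targets):
        sign = 1.0 if i % 2 == 0 else -1.0
        rows[f"t{i}"] = sign * reg + rng.normal(scale=0.4, size=n_samples)
        modes[f"t{i}"] = sign
    for i in range(n_other):
        rows[f"o{i}"] = rng.normal(size=n_samples)
    frame = pd.DataFrame(rows).T
    frame.columns = [f"s{i}" for i in range(n_samples)]
    return ExpressionMatrix(frame), modes


def test_build_regulons_recovers_planted_targets(rng):
    expr, modes = planted_expr(rng)
    regs = build_regulons(expr, ["REG"], min_targets=20, n_perm=300,
                          rng=np.random.default_rng(3))
    assert "REG" in regs
    reg = regs["REG"]
    recovered = set(reg.targets) & set(modes)
    assert len(recovered) >= 28          # nearly all planted targets
    false_pos = set(reg.targets) - set(modes)
    assert len(false_pos) <= 3
    for t in recovered:
        mode, weight = reg.targets[t]
        assert np.sign(mode) == modes[t]  # Spearman sign matches plant
        assert 0.0 < weight <= 1.0
    assert max(w for _, w in reg.targets.values()) == 1.0


def test_build_regulons_min_targets_filter(rng):
    expr, _ = planted_expr(rng, n_targets=5)
    regs = build_regulons(expr, ["REG"], min_targets=25, n_perm=300,
                          rng=np.random.default_rng(3))
    assert regs == {}


def test_build_regulons_missing_regulator(rng):
    expr, _ = planted_expr(rng, n_targets=5, n_other=5)
    with pytest.warns(UserWarning, match="absent"):
        regs = build_regulons(expr, ["REG", "GHOST"], min_targets=3,
                              n_perm=300, rng=np.random.default_rng(3))
    assert "GHOST" not in regs
    with pytest.raises(ValueError, match="no regulator"):
        build_regulons(expr, ["GHOST"], min_targets=3, mi_threshold=0.1)


def test_regulon_validation():
    with pytest.raises(ValueError, match="cannot target itself"):
        Regulon("r", {"r": (1.0, 1.0)})
    with pytest.raises(ValueError, match="mode"):
        Regulon("r", {"t": (2.0, 1.0)})
    with pytest.raises(ValueError, match="weight"):
        Regulon("r", {"t": (1.0, 0.0)})


def test_regulons_frame_round_trip():
    regs = {"r1": Regulon("r1", {"a": (1.0, 1.0), "b": (-0.5, 0.3)}),
            "r2": Regulon("r2", {"c": (0.0, 0.7)})}
    back = regulons_from_frame(regulons_to_frame(regs))
    assert back.keys() == regs.keys()
    for r in regs:
        assert back[r].targets == pytest.approx(regs[r].targets)


def test_expression_matrix_validation():
    frame = pd.DataFrame(np.ones((2, 40)), index=["a", "a"])
    with pytest.raises(ValueError, match="duplicate gene"):
        ExpressionMatrix(frame)
    frame = pd.DataFrame(np.full((2, 40), np.nan), index=["a", "b"])
    with pytest.raises(ValueError, match="missing"):
        ExpressionMatrix(frame)
    with pytest.warns(UserWarning, match="samples"):
        ExpressionMatrix(pd.DataFrame(np.ones((2, 5)), index=["a", "b"]))
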