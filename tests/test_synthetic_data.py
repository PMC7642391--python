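import numpy as np
import pytest

from ligrec.synthetic_data import (GroundTruth, end_to_end_fixture,
                                   simulate_ppi_scores, simulate_proteome,
                                   simulate_regulatory_expression)


def test_proteome_structure_and_plants():
    table, truth = simulate_proteome(n_other=5, n_enriched=3, n_case_only=2,
                                     log2_effect=1.0, seed=4)
    assert len(table.protein_ids) == 10
    assert truth.enriched_ligands == {"L_ENR1", "L_ENR2", "L_ENR3"}
    assert truth.case_only_ligands == {"L_ONLY1", "L_ONLY2"}
    case_cols = table.columns_for("case")
    ctrl_cols = table.columns_for("control")
    # case-only proteins are undetected in all control replicates
    for p in truth.case_only_ligands:
        assert table.log2_intensity.loc[p, ctrl_cols].isna().all()
        assert table.log2_intensity.loc[p, case_cols].notna().all()
    # planted enrichment is close to the nominal effect
    for p in truth.enriched_ligands:
        diff = (table.log2_intensity.loc[p, case_cols].mean()
                - table.log2_intensity.loc[p, ctrl_cols].mean())
        assert diff == pytest.approx(1.0, abs=0.6)


def test_proteome_deterministic():
    t1, _ = simulate_proteome(seed=9)
    t2, _ = simulate_proteome(seed=9)
    t3, _ = simulate_proteome(seed=10)
    assert t1.log2_intensity.equals(t2.log2_intensity)
    assert not t1.log2_intensity.equals(t3.log2_intensity)


def test_expression_structure():
    expr, truth = simulate_regulatory_expression(
        n_samples_per_cond=40, n_decoy_receptors=3, regulon_size=10,
        n_noise_genes=5, seed=2)
    genes = set(expr.gene_ids)
    assert truth.active_receptor == "REC00" == truth.modulating_receptor
    assert truth.tf_id == "TF1"
    assert {"REC00", "REC01", "REC02", "REC03", "TF1"} <= genes
    assert sum(g.startswith("T_TF1_") for g in genes) == 10
    assert sum(g.startswith("G_NOISE") for g in genes) == 5
    assert sum(c.startswith("case_") for c in expr.sample_ids) == 40
    assert set(truth.regulon_spec) == {"REC00", "REC01", "REC02", "REC03",
                                       "TF1"}
    assert set(truth.regulon_spec["TF1"]) == \
        {g for g in genes if g.startswith("T_TF1_")}


def test_expression_condition_shift_and_severing():
    planted, _ = simulate_regulatory_expression(
        n_samples_per_cond=150, n_decoy_receptors=2, regulon_size=10,
        n_noise_genes=2, condition_shift=1.0, modulation=1.0, seed=5)
    null, _ = simulate_regulatory_expression(
        n_samples_per_cond=150, n_decoy_receptors=2, regulon_size=10,
        n_noise_genes=2, condition_shift=0.0, modulation=0.0, seed=5)

    def receptor_case_shift(expr):
        vals = expr.values.loc["REC00"]
        case = vals[[c for c in expr.sample_ids if c.startswith("case")]]
        ctrl = vals[[c for c in expr.sample_ids if c.startswith("control")]]
        return case.mean() - ctrl.mean()

    assert receptor_case_shift(planted) > 0.6
    assert abs(receptor_case_shift(null)) < 0.4

    def receptor_target_corr(expr):
        rec = expr.values.loc["REC00"].to_numpy()
        tgt = expr.values.loc["T_TF1_001"].to_numpy()
        return abs(np.corrcoef(rec, tgt)[0, 1])

    # with modulation the receptor couples to TF targets; severed it does not
    assert receptor_target_corr(planted) > 0.25
    assert receptor_target_corr(null) < 0.15


def test_expression_validation():
    with pytest.raises(ValueError, match="regulon_size"):
        simulate_regulatory_expression(regulon_size=0)
    with pytest.raises(ValueError, match="samples per condition"):
        simulate_regulatory_expression(n_samples_per_cond=1)


def test_ppi_scores_symmetric_and_planted():
    sets = simulate_ppi_scores(["A", "B", "C"], planted_pair=("A", "B"),
                               planted_score=0.95, n_background_proteins=10,
                               seed=3)
    assert len(sets) == 13
    assert sets["A"].partner_scores["B"] == 0.95
    assert sets["B"].partner_scores["A"] == 0.95
    for p, s in sets.items():
        for q, v in s.partner_scores.items():
            assert sets[q].partner_scores[p] == v
    with pytest.raises(ValueError, match="duplicate"):
        simulate_ppi_scores(["A", "A"])
    with pytest.raises(ValueError, match="not in the universe"):
        simulate_ppi_scores(["A"], planted_pair=("A", "ZZZ"),
                            n_background_proteins=2)


def test_ground_truth_manifest_round_trip():
    truth = GroundTruth(seed=11, enriched_ligands={"L_ENR1"},
                        case_only_ligands={"L_ONLY1", "L_ONLY2"},
                        planted_pair=("L_ENR1", "REC00"),
                        active_receptor="REC00",
                        modulating_receptor="REC00", tf_id="TF1")
    back = GroundTruth.from_manifest(truth.to_manifest())
    assert back.seed == 11
    assert back.enriched_ligands == truth.enriched_ligands
    assert back.case_only_ligands == truth.case_only_ligands
    assert back.planted_pair == truth.planted_pair
    assert back.tf_id == "TF1"


def test_end_to_end_fixture_writes_inputs(tmp_path):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        proteome, expr, ppi, receptors, truth = end_to_end_fixture(
            seed=6, outdir=tmp_path, n_samples_per_cond=30,
            n_decoy_receptors=2, regulon_size=5, n_background_proteins=5,
            n_noise_genes=2)
    for name in ("proteome.tsv", "expression.tsv", "ppi_scores.tsv",
                 "receptors.tsv", "manifest.tsv"):
        assert (tmp_path / name).exists()
    assert truth.planted_pair == ("L_ENR1", "REC00")
    assert set(receptors) == {"REC00", "REC01", "REC02"}
    # planted pair has a score in both PPI sets
    l, r = truth.planted_pair
    assert ppi[l].partner_scores[r] == 0.95
    # refuses to clobber an existing fixture
    with pytest.raises(FileExistsError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            end_to_end_fixture(seed=6, outdir=tmp_path,
                               n_samples_per_cond=30, n_decoy_receptors=2,
                               regulon_size=5, n_background_proteins=5,
                               n_noise_genes=2)


def test_end_to_end_fixture_deterministic():
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kwargs = dict(n_samples_per_cond=30, n_decoy_receptors=2,
                      regulon_size=5, n_background_proteins=5,
                      n_noise_genes=2)
        _, e1, _, _, _ = end_to_end_fixture(seed=8, **kwargs)
        _, e2, _, _, _ = end_to_end_fixture(seed=8, **kwargs)
    assert e1.values.equals(e2.values)
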