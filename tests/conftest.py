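"""Shared fixtures: deterministic RNGs and a reduced end-to-end input set."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ligrec.pipeline import PipelineConfig, run_pipeline
from ligrec.synthetic_data import end_to_end_fixture

# Scaled-down generator parameters: same structure as the default fixture,
# small enough that a full pipeline run takes ~2 s (used where many runs are
# needed, e.g. the null-uniformity sweep).
REDUCED_FIXTURE = dict(n_samples_per_cond=60, n_decoy_receptors=8,
                       regulon_size=25, n_background_proteins=60,
                       n_noise_genes=20)
REDUCED_N_PERM = 500


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def run_fixture_pipeline(tmpdir, seed, plant_signals=True, reduced=True,
                         **config_overrides):
    """Generate a synthetic input set and run the full pipeline on it."""
    kwargs = REDUCED_FIXTURE if reduced else {}
    end_to_end_fixture(seed=seed, outdir=tmpdir, plant_signals=plant_signals,
                       **kwargs)
    cfg = PipelineConfig(
        proteome_path=f"{tmpdir}/proteome.tsv",
        expression_path=f"{tmpdir}/expression.tsv",
        ppi_scores_path=f"{tmpdir}/ppi_scores.tsv",
        receptors_path=f"{tmpdir}/receptors.tsv",
        tf="TF1", seed=seed,
        n_perm=REDUCED_N_PERM if reduced else PipelineConfig.n_perm,
        **config_overrides)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


def planted_pair_rank(final_table, ligand="L_ENR1", receptor="REC00"):
    """1-based position of the planted pair in the final ranking + its score."""
    f = final_table.reset_index(drop=True)
    row = f[(f.ligand == ligand) & (f.receptor == receptor)]
    assert len(row) == 1, "planted pair absent from the final ranking"
    return int(row.index[0]) + 1, float(row.score.iloc[0]), len(f)
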