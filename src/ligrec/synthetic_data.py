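"""Synthetic pipeline inputs with planted ground truth.

Generates desk-scale versions of the four pipeline inputs — a differential
secretome abundance table, an expression compendium with case/control
samples, per-protein PPI prior score sets, and a receptor annotation list —
in which one ligand-receptor pair is planted to be recoverable by every
evidence source:

* the ligand is over-abundant in the case secretome,
* the pair's PPI prior score stands out from both proteins' score nulls,
* the receptor's activity (through its inferred regulon) rises in the case
  condition, and
* the receptor modulates the coupling between a downstream TF and the TF's
  targets, so it tops the conditional-mutual-information screen.

The expression model is Gaussian with one nonlinearity: receptor activity
A_R ~ N(shift * 1{case}, 1) post-translationally gates the TF, scaling the
transfer from TF transcript level (which is independent of the receptor)
to each TF target by c(A_R) = 2 * sigmoid(3 * gamma * A_R). The gate is
what makes the TF-target dependence conditional on the receptor — the
modulator-analysis premise — and, through the TF's positive baseline
expression, also shifts target means between conditions, so the receptor's
inferred regulon responds to the contrast. With gamma = 0 the gate is
constant and every planted signal in the expression compartment vanishes.
Decoy receptors drive regulons of their own through independent latents.
All generators are pure functions of parameters + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ligand_screen import ProteinAbundanceTable
from .regulon_net import ExpressionMatrix
from .ppi_prior import PPIScoreSet

__all__ = [
    "GroundTruth",
    "simulate_proteome",
    "simulate_regulatory_expression",
    "simulate_ppi_scores",
    "end_to_end_fixture",
]


@dataclass
class GroundTruth:
    """Planted entities of a synthetic run; fully determined by the seed."""

    seed: int
    enriched_ligands: set[str] = field(default_factory=set)
    case_only_ligands: set[str] = field(default_factory=set)
    planted_pair: tuple[str, str] | None = None
    active_receptor: str | None = None
    modulating_receptor: str | None = None
    tf_id: str | None = None
    regulon_spec: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_manifest(self) -> dict[str, str]:
        kv = {"seed": str(self.seed)}
        if self.enriched_ligands:
            kv["enriched_ligands"] = ",".join(sorted(self.enriched_ligands))
        if self.case_only_ligands:
            kv["case_only_ligands"] = ",".join(sorted(self.case_only_ligands))
        if self.planted_pair:
            kv["planted_pair"] = "-".join(self.planted_pair)
        for key in ("active_receptor", "modulating_receptor", "tf_id"):
            val = getattr(self, key)
            if val is not None:
                kv[key] = val
        return kv

    @classmethod
    def from_manifest(cls, kv: dict[str, str]) -> "GroundTruth":
        gt = cls(seed=int(kv["seed"]))
        if "enriched_ligands" in kv:
            gt.enriched_ligands = set(kv["enriched_ligands"].split(","))
        if "case_only_ligands" in kv:
            gt.case_only_ligands = set(kv["case_only_ligands"].split(","))
        if "planted_pair" in kv:
            l, r = kv["planted_pair"].split("-")
            gt.planted_pair = (l, r)
        for key in ("active_receptor", "modulating_receptor", "tf_id"):
            if key in kv:
                setattr(gt, key, kv[key])
        return gt


def simulate_proteome(n_other: int = 13, n_enriched: int = 4,
                      n_case_only: int = 3, log2_effect: float = 1.0,
                      n_reps: int = 3, noise_sd: float = 0.2,
                      seed: int = 0) -> tuple[ProteinAbundanceTable,
                                              GroundTruth]:
    """Two-condition log2 abundance table with planted over-abundance.

    Baseline protein log2 intensities are Normal(20, 2); replicate noise is
    Normal(0, noise_sd). Enriched proteins gain ``log2_effect`` in every
    case replicate; case-only proteins are undetected (missing) in all
    control replicates.
    """
    if min(n_other, n_enriched, n_case_only) < 0 or noise_sd <= 0:
        raise ValueError("counts must be >= 0 and noise_sd > 0")
    n_prot = n_other + n_enriched + n_case_only
    if n_prot == 0:
        raise ValueError("at least one protein required")
    rng = np.random.default_rng(seed)
    enriched = [f"L_ENR{i+1}" for i in range(n_enriched)]
    case_only = [f"L_ONLY{i+1}" for i in range(n_case_only)]
    null = [f"L_NULL{i+1}" for i in range(n_other)]
    ids = enriched + case_only + null

    base = rng.normal(20.0, 2.0, size=n_prot)
    cols = [f"case_{j+1}" for j in range(n_reps)] + \
           [f"control_{j+1}" for j in range(n_reps)]
    vals = base[:, None] + rng.normal(0.0, noise_sd, size=(n_prot, 2 * n_reps))
    vals[:n_enriched, :n_reps] += log2_effect
    frame = pd.DataFrame(vals, index=pd.Index(ids, name="protein_id"),
                         columns=cols)
    frame.iloc[n_enriched:n_enriched + n_case_only, n_reps:] = np.nan
    labels = {c: ("case" if c.startswith("case") else "control")
              for c in cols}
    truth = GroundTruth(seed=seed, enriched_ligands=set(enriched),
                        case_only_ligands=set(case_only))
    return ProteinAbundanceTable(frame, labels), truth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_regulatory_expression(n_samples_per_cond: int = 100,
                                   n_decoy_receptors: int = 20,
                                   regulon_size: int = 40,
                                   coupling: float = 1.0,
                                   modulation: float = 1.0,
                                   noise_sd: float = 0.5,
                                   condition_shift: float = 1.0,
                                   n_noise_genes: int = 50,
                                   seed: int = 0
                                   ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Case/control expression compendium with a receptor -> TF causal chain.

    The planted receptor REC00 has activity A_R ~ N(condition_shift * case,
    1) and mRNA correlated with it. The TF transcript is Normal(2, 1),
    independent of the receptor; each of the TF's ``regulon_size`` targets
    follows m_t * coupling * c(A_R) * x_TF + eps with the sigmoidal
    activation gate c(A_R) = 2 * sigmoid(3 * modulation * A_R). Decoy
    receptors each drive a same-sized regulon from an independent latent.
    Sample ids carry the condition prefix (case_*/control_*).
    """
    if regulon_size < 1:
        raise ValueError("regulon_size must be >= 1")
    if n_samples_per_cond < 2:
        raise ValueError("need >= 2 samples per condition")
    rng = np.random.default_rng(seed)
    n = 2 * n_samples_per_cond
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_samples_per_cond] = True
    samples = [f"case_{i+1}" for i in range(n_samples_per_cond)] + \
              [f"control_{i+1}" for i in range(n_samples_per_cond)]

    receptor = "REC00"
    decoys = [f"REC{i+1:02d}" for i in range(n_decoy_receptors)]
    tf = "TF1"

    a_r = rng.normal(0.0, 1.0, size=n) + condition_shift * is_case
    x_tf = 2.0 + rng.normal(0.0, 1.0, size=n)  # TF transcript, receptor-free
    gate = 2.0 * _sigmoid(3.0 * modulation * a_r)

    rows: dict[str, np.ndarray] = {}
    spec: dict[str, dict[str, float]] = {receptor: {}, tf: {}}
    rows[receptor] = a_r + rng.normal(0.0, noise_sd, size=n)
    rows[tf] = x_tf

    modes_tf = rng.choice([-1.0, 1.0], size=regulon_size)
    for t in range(regulon_size):
        gid = f"T_TF1_{t+1:03d}"
        rows[gid] = (modes_tf[t] * coupling * gate * x_tf
                     + rng.normal(0.0, noise_sd, size=n))
        spec[tf][gid] = float(modes_tf[t])

    for d in decoys:
        latent = rng.normal(0.0, 1.0, size=n)
        rows[d] = latent + rng.normal(0.0, noise_sd, size=n)
        spec[d] = {}
        modes = rng.choice([-1.0, 1.0], size=regulon_size)
        for t in range(regulon_size):
            gid = f"T_{d}_{t+1:03d}"
            rows[gid] = (modes[t] * coupling * latent
                         + rng.normal(0.0, noise_sd, size=n))
            spec[d][gid] = float(modes[t])

    for g in range(n_noise_genes):
        rows[f"G_NOISE{g+1:03d}"] = rng.normal(0.0, 1.0, size=n)

    frame = pd.DataFrame(rows).T
    frame.columns = samples
    frame.index.name = "gene_id"
    truth = GroundTruth(seed=seed, active_receptor=receptor,
                        modulating_receptor=receptor, tf_id=tf,
                        regulon_spec=spec)
    return ExpressionMatrix(frame), truth


def simulate_ppi_scores(protein_ids: list[str],
                        planted_pair: tuple[str, str] | None = None,
                        background_beta_params: tuple[float, float] = (1.0, 9.0),
                        planted_score: float | None = 0.95,
                        n_background_proteins: int = 100,
                        seed: int = 0) -> dict[str, PPIScoreSet]:
    """Symmetric PPI prior score sets over a toy protein universe.

    Background scores are i.i.d. Beta(a, b) (defaults put most mass below
    0.5, mimicking a prior where high-confidence interactions are rare).
    The planted pair's score is overwritten with ``planted_score`` on both
    proteins' score sets; score(A, B) == score(B, A) throughout.
    """
    if len(set(protein_ids)) != len(protein_ids):
        raise ValueError("duplicate protein ids")
    if planted_pair is not None and planted_score is not None:
        if not (0.0 < planted_score <= 1.0):
            raise ValueError("planted_score must be in (0, 1]")
    rng = np.random.default_rng(seed)
    universe = list(protein_ids) + \
        [f"BG{i+1:04d}" for i in range(n_background_proteins)]
    a, b = background_beta_params
    n = len(universe)
    scores: dict[str, dict[str, float]] = {p: {} for p in universe}
    for i in range(n):
        draws = rng.beta(a, b, size=n - i - 1)
        for k, j in enumerate(range(i + 1, n)):
            s = float(np.clip(draws[k], 1e-9, 1.0))
            scores[universe[i]][universe[j]] = s
            scores[universe[j]][universe[i]] = s
    if planted_pair is not None and planted_score is not None:
        l, r = planted_pair
        if l not in scores or r not in scores:
            raise ValueError(f"planted pair {l}-{r} not in the universe")
        scores[l][r] = planted_score
        scores[r][l] = planted_score
    return {p: PPIScoreSet(p, s) for p, s in scores.items()}


def end_to_end_fixture(seed: int = 0, outdir: str | Path | None = None,
                       plant_signals: bool = True,
                       n_samples_per_cond: int = 100,
                       n_decoy_receptors: int = 20,
                       regulon_size: int = 40,
                       n_background_proteins: int = 100,
                       n_noise_genes: int = 50):
    """Generate coherent inputs for a full pipeline run.

    The planted pair (L_ENR1, REC00) is simultaneously over-abundant,
    high-scoring in the PPI prior, activity-top, and modulation-top. With
    ``plant_signals=False`` the pair still exists in every input (so it is
    rankable) but carries no signal: no abundance effect beyond selection,
    a background PPI score, no condition shift, and a severed receptor ->
    TF chain. When ``outdir`` is given the four input files plus a manifest
    are written there (the directory must not already contain a manifest).

    Returns (proteome_table, expression, ppi_sets, receptor_ids, truth).
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
    proteome, p_truth = simulate_proteome(seed=sub[0])
    expr, e_truth = simulate_regulatory_expression(
        n_samples_per_cond=n_samples_per_cond,
        n_decoy_receptors=n_decoy_receptors,
        regulon_size=regulon_size,
        n_noise_genes=n_noise_genes,
        condition_shift=1.0 if plant_signals else 0.0,
        modulation=1.0 if plant_signals else 0.0,
        seed=sub[1])
    receptor_ids = [g for g in expr.gene_ids if g.startswith("REC")]
    planted_pair = ("L_ENR1", e_truth.active_receptor)
    ppi_sets = simulate_ppi_scores(
        list(proteome.protein_ids) + receptor_ids + [e_truth.tf_id],
        planted_pair=planted_pair,
        planted_score=0.95 if plant_signals else None,
        n_background_proteins=n_background_proteins,
        seed=sub[2])

    truth = GroundTruth(
        seed=seed,
        enriched_ligands=p_truth.enriched_ligands,
        case_only_ligands=p_truth.case_only_ligands,
        planted_pair=planted_pair,
        active_receptor=e_truth.active_receptor,
        modulating_receptor=e_truth.modulating_receptor,
        tf_id=e_truth.tf_id,
        regulon_spec=e_truth.regulon_spec)

    if outdir is not None:
        from . import io as _io
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest_path = outdir / "manifest.tsv"
        if manifest_path.exists():
            raise FileExistsError(f"{manifest_path} already exists")
        _io.write_abundance_table(proteome, outdir / "proteome.tsv")
        _io.write_expression(expr, outdir / "expression.tsv")
        _io.write_ppi_scores(ppi_sets, outdir / "ppi_scores.tsv")
        _io.write_id_list(receptor_ids, outdir / "receptors.tsv",
                          header="receptor_id")
        _io.write_manifest(truth.to_manifest(), manifest_path)

    return proteome, expr, ppi_sets, receptor_ids, truth
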