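"""End-to-end orchestration: from the four inputs to the final pair ranking.

Stages: ligand screen -> candidate pair space -> PPI empirical priors;
regulon inference -> receptor activity; TF modulator screen; rank
aggregation. Any stage failure aborts the run with the stage name attached.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .evidence_integration import aggregate_pairs, count_significant
from .ligand_screen import compute_fold_changes, select_ligand_candidates, \
    selected_ids, candidates_to_frame
from .modulator_cmi import cindy_triplets, rank_modulators, triplets_to_frame
from .ppi_prior import candidate_pair_space, pair_pvalue, rank_pairs_by_ppi
from .receptor_activity import rank_receptors_by_activity, \
    signature_from_expression
from .regulon_net import build_regulons, mi_significance_threshold

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("ligrec")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run."""

    proteome_path: str = ""
    expression_path: str = ""
    ppi_scores_path: str = ""
    receptors_path: str = ""
    id_map_path: str = ""          # optional ligand-id translation table
    tf: str = "TF1"                # master regulator for the modulator screen
    fc_min: float = 1.5
    min_detect: int = 2
    min_targets: int = 25
    alpha_mi: float = 0.001        # per-edge significance (genome-scale)
    alpha_split: float = 1.0       # chi-squared split gate (1 = off)
    alpha: float = 0.01            # final significance level
    n_perm: int = 2000
    n_bins_z: int = 3
    pair_combination: str = "max"  # or "fisher"
    high_confidence_only: bool = False
    seed: int = 0
    outdir: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1) or not (0 < self.alpha_mi <= 1):
            raise ValueError("significance levels must lie in (0, 1]")
        if self.fc_min <= 0 or self.min_detect < 1 or self.min_targets < 1:
            raise ValueError("fc_min, min_detect, min_targets out of range")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key-value config (key<TAB>value or key=value per line)."""
        kv: dict[str, str] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                k, v = line.split("\t", 1)
            elif "=" in line:
                k, v = line.split("=", 1)
            else:
                raise ValueError(f"{path}:{i}: expected key=value")
            kv[k.strip()] = v.strip()
        kv.update({k: v for k, v in overrides.items() if v is not None})
        types = {f.name: f.type for f in fields(cls)}
        cast: dict = {}
        for k, v in kv.items():
            if k not in types:
                raise ValueError(f"unknown config key {k!r}")
            t = types[k]
            if t == "int":
                cast[k] = int(v)
            elif t == "float":
                cast[k] = float(v)
            elif t == "bool":
                cast[k] = str(v).lower() in ("1", "true", "yes") \
                    if isinstance(v, str) else bool(v)
            else:
                cast[k] = v
        return cls(**cast)

    def header_comments(self) -> list[str]:
        return [f"ligrec seed={self.seed} fc_min={self.fc_min} "
                f"min_detect={self.min_detect} min_targets={self.min_targets} "
                f"alpha={self.alpha} pair_combination={self.pair_combination}"]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of stage outputs.

    Keys: candidates, pair_space, ppi_table, regulons, signature,
    activity_table, triplets, modulator_table, final (the aggregated pair
    table), n_significant. When ``config.outdir`` is set, stage tables and
    the final ranking are written there.
    """
    rng = np.random.default_rng(config.seed)
    out: dict = {}

    @_stage("ligand_screen")
    def s1():
        table = io.read_abundance_table(config.proteome_path)
        fcs = compute_fold_changes(table, min_detect=config.min_detect)
        cands = select_ligand_candidates(fcs, fc_min=config.fc_min)
        if config.id_map_path:
            idmap = io.read_id_map(config.id_map_path)
            for c in cands:
                c.protein_id = idmap.get(c.protein_id, c.protein_id)
        return cands

    out["candidates"] = s1()
    ligands = selected_ids(out["candidates"])
    log.info("ligand_screen: %d candidates selected of %d proteins",
             len(ligands), len(out["candidates"]))

    @_stage("pair_space")
    def s2():
        receptors = io.read_id_list(config.receptors_path)
        return receptors, candidate_pair_space(ligands, receptors)

    receptors, pair_space = s2()
    out["pair_space"] = pair_space
    log.info("pair_space: %d candidate pairs (%d ligands x %d receptors)",
             len(pair_space), len(ligands), len(receptors))

    @_stage("ppi_prior")
    def s3():
        sets = io.read_ppi_scores(config.ppi_scores_path)
        priors = []
        for l, r in pair_space:
            if l not in sets or r not in sets:
                warnings.warn(f"no PPI score set for pair {l}-{r}; skipped")
                continue
            priors.append(pair_pvalue(sets[l], sets[r],
                                      combination=config.pair_combination))
        return rank_pairs_by_ppi(
            priors, high_confidence_only=config.high_confidence_only)

    out["ppi_table"], ppi_evidence = s3()
    log.info("ppi_prior: %d pairs ranked", len(out["ppi_table"]))

    @_stage("regulon_net")
    def s4():
        expr = io.read_expression(config.expression_path)
        threshold = mi_significance_threshold(
            expr, n_perm=config.n_perm, alpha=config.alpha_mi, rng=rng,
            alpha_split=config.alpha_split)
        log.info("regulon_net: MI threshold %.4f", threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            regulons = build_regulons(
                expr, [r for r in receptors if r in set(expr.gene_ids)],
                min_targets=config.min_targets, mi_threshold=threshold,
                alpha_split=config.alpha_split)
            tf_regulons = build_regulons(
                expr, [config.tf], min_targets=config.min_targets,
                mi_threshold=threshold, alpha_split=config.alpha_split)
        return expr, regulons, tf_regulons.get(config.tf)

    expr, regulons, tf_regulon = s4()
    out["regulons"] = regulons
    log.info("regulon_net: %d receptor regulons of >= %d targets",
             len(regulons), config.min_targets)

    @_stage("receptor_activity")
    def s5():
        if not regulons:
            raise ValueError(
                f"no receptor regulon passed the min_targets={config.min_targets} "
                "size filter")
        case, ctrl = io.split_by_condition(expr)
        sig = signature_from_expression(case, ctrl)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, evidence = rank_receptors_by_activity(sig, regulons)
        return sig, table, evidence

    out["signature"], out["activity_table"], viper_evidence = s5()
    log.info("receptor_activity: %d receptors ranked",
             len(out["activity_table"]))

    @_stage("modulator_cmi")
    def s6():
        if tf_regulon is None:
            raise ValueError(
                f"TF {config.tf!r} has no regulon of >= {config.min_targets} "
                "targets")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            triplets = cindy_triplets(expr, receptors, config.tf, tf_regulon,
                                      n_bins_z=config.n_bins_z,
                                      alpha_split=config.alpha_split)
            return triplets, *rank_modulators(triplets)

    triplets, out["modulator_table"], cindy_evidence = s6()
    out["triplets"] = triplets
    log.info("modulator_cmi: %d triplets over %d modulators", len(triplets),
             len(out["modulator_table"]))

    @_stage("evidence_integration")
    def s7():
        final = aggregate_pairs(
            [ppi_evidence, viper_evidence, cindy_evidence], pair_space)
        return final, count_significant(final, alpha=config.alpha)

    out["final"], out["n_significant"] = s7()
    log.info("evidence_integration: %d pairs, %d significant at alpha=%g "
             "(seed=%d)", len(out["final"]), out["n_significant"],
             config.alpha, config.seed)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        comments = config.header_comments()
        io.write_table(candidates_to_frame(out["candidates"]),
                       outdir / "ligand_candidates.tsv", comments)
        io.write_table(out["ppi_table"], outdir / "ppi_prior.tsv", comments)
        io.write_regulons(regulons, outdir / "regulons.tsv", comments)
        io.write_signature(out["signature"], outdir / "signature.tsv",
                           comments)
        io.write_table(out["activity_table"],
                       outdir / "receptor_activity.tsv", comments)
        io.write_table(triplets_to_frame(triplets),
                       outdir / "cmi_triplets.tsv", comments)
        io.write_table(out["modulator_table"], outdir / "modulators.tsv",
                       comments)
        io.write_table(out["final"], outdir / "final_ranking.tsv", comments)
    return out
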