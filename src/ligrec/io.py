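"""Tab-separated file formats for every pipeline artifact.

All files are UTF-8 TSV. Writers may prepend ``#``-prefixed comment lines
(version, seed, parameters); readers skip them. Round-trips are lossless up
to float formatting; column order is normalized on write.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .evidence_integration import RankedEvidence
from .ligand_screen import ProteinAbundanceTable
from .ppi_prior import PPIScoreSet
from .regulon_net import ExpressionMatrix, Regulon, regulons_from_frame, \
    regulons_to_frame
from .receptor_activity import Signature

__all__ = [
    "read_abundance_table", "write_abundance_table",
    "read_expression", "write_expression",
    "read_ppi_scores", "write_ppi_scores",
    "read_id_list", "write_id_list",
    "read_id_map",
    "read_regulons", "write_regulons",
    "read_signature", "write_signature",
    "read_ranked_evidence", "write_ranked_evidence",
    "read_pair_ranking", "load_published_ranking",
    "read_manifest", "write_manifest",
    "write_table",
]

_FLOAT_FMT = "%.6g"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def _write_tsv(frame: pd.DataFrame, path: str | Path,
               header_comments: list[str] | None = None,
               index: bool = False) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FMT,
                     lineterminator="\n")


def write_table(frame: pd.DataFrame, path: str | Path,
                comments: list[str] | None = None) -> None:
    """Write a generic result table with optional header comments."""
    _write_tsv(frame, path, header_comments=comments)


# -- abundance ---------------------------------------------------------------

def read_abundance_table(path: str | Path) -> ProteinAbundanceTable:
    """Columns: protein_id, then <condition>_<rep>; empty cell = missing."""
    frame = _read_tsv(path, index_col="protein_id")
    labels = {}
    for col in frame.columns:
        cond = col.rsplit("_", 1)[0]
        if cond not in ("case", "control"):
            raise ValueError(f"replicate column {col!r} must be named "
                             "<condition>_<rep> with condition case/control")
        labels[col] = cond
    return ProteinAbundanceTable(frame.astype(float), labels)


def write_abundance_table(table: ProteinAbundanceTable, path: str | Path,
                          comments: list[str] | None = None) -> None:
    _write_tsv(table.log2_intensity, path, header_comments=comments,
               index=True)


# -- expression --------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Columns: gene_id, then one column per sample."""
    frame = _read_tsv(path, index_col="gene_id")
    return ExpressionMatrix(frame.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     comments: list[str] | None = None) -> None:
    _write_tsv(expr.values, path, header_comments=comments, index=True)


def split_by_condition(expr: ExpressionMatrix
                       ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split samples into case/control by the sample-name prefix."""
    case_cols = [c for c in expr.sample_ids if c.startswith("case")]
    ctrl_cols = [c for c in expr.sample_ids if c.startswith("control")]
    if not case_cols or not ctrl_cols:
        raise ValueError("sample names must carry case_*/control_* prefixes")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return (ExpressionMatrix(expr.values[case_cols]),
                ExpressionMatrix(expr.values[ctrl_cols]))


# -- PPI score sets ----------------------------------------------------------

def read_ppi_scores(path: str | Path) -> dict[str, PPIScoreSet]:
    """Columns: protein_id, partner_id, score. Symmetry is enforced."""
    frame = _read_tsv(path, dtype={"protein_id": str, "partner_id": str})
    required = {"protein_id", "partner_id", "score"}
    if not required <= set(frame.columns):
        raise ValueError(f"PPI score file needs columns {sorted(required)}")
    scores: dict[str, dict[str, float]] = {}
    for row in frame.itertuples():
        a, b, s = row.protein_id, row.partner_id, float(row.score)
        prev = scores.get(a, {}).get(b)
        if prev is not None and abs(prev - s) > 1e-9:
            raise ValueError(f"conflicting scores for pair {a}-{b}")
        scores.setdefault(a, {})[b] = s
        scores.setdefault(b, {})[a] = s
    return {p: PPIScoreSet(p, s) for p, s in scores.items()}


def write_ppi_scores(sets: dict[str, PPIScoreSet], path: str | Path,
                     comments: list[str] | None = None) -> None:
    rows = []
    seen: set[frozenset] = set()
    for p, sset in sorted(sets.items()):
        for partner, s in sorted(sset.partner_scores.items()):
            key = frozenset((p, partner))
            if key in seen:
                continue
            seen.add(key)
            rows.append((p, partner, s))
    frame = pd.DataFrame(rows, columns=["protein_id", "partner_id", "score"])
    _write_tsv(frame, path, header_comments=comments)


# -- simple lists and maps ---------------------------------------------------

def read_id_list(path: str | Path) -> list[str]:
    frame = _read_tsv(path, dtype=str)
    ids = frame.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate ids in {path}")
    return ids


def write_id_list(ids: list[str], path: str | Path,
                  header: str = "id",
                  comments: list[str] | None = None) -> None:
    _write_tsv(pd.DataFrame({header: ids}), path, header_comments=comments)


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column source_id -> target_id mapping (orthology/idconversion)."""
    frame = _read_tsv(path, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("id map needs two columns: source_id, target_id")
    src, tgt = frame.columns[:2]
    if frame[src].duplicated().any():
        raise ValueError("duplicate source ids in id map")
    return dict(zip(frame[src], frame[tgt]))


# -- regulons ----------------------------------------------------------------

def read_regulons(path: str | Path) -> dict[str, Regulon]:
    frame = _read_tsv(path, dtype={"regulator": str, "target": str})
    required = {"regulator", "target", "mode", "weight"}
    if not required <= set(frame.columns):
        raise ValueError(f"regulon file needs columns {sorted(required)}")
    return regulons_from_frame(frame)


def write_regulons(regulons: dict[str, Regulon], path: str | Path,
                   comments: list[str] | None = None) -> None:
    _write_tsv(regulons_to_frame(regulons), path, header_comments=comments)


# -- signatures and ranked evidence ------------------------------------------

def read_signature(path: str | Path) -> Signature:
    frame = _read_tsv(path, index_col="gene_id")
    return Signature(frame["stat"].astype(float))


def write_signature(sig: Signature, path: str | Path,
                    comments: list[str] | None = None) -> None:
    frame = sig.stat.rename("stat").to_frame()
    frame.index.name = "gene_id"
    _write_tsv(frame, path, header_comments=comments, index=True)


def read_ranked_evidence(path: str | Path, evidence_id: str,
                         entity_level: str = "receptor") -> RankedEvidence:
    frame = _read_tsv(path, dtype={"entity": str})
    if not {"entity", "norm_rank"} <= set(frame.columns):
        raise ValueError("ranked evidence needs columns entity, norm_rank")
    entries = {}
    for row in frame.itertuples():
        entity = (tuple(row.entity.split("-", 1)) if entity_level == "pair"
                  else row.entity)
        entries[entity] = float(row.norm_rank)
    return RankedEvidence(evidence_id, entity_level, entries)


def write_ranked_evidence(evidence: RankedEvidence, path: str | Path,
                          comments: list[str] | None = None) -> None:
    rows = []
    for ent, r in sorted(evidence.entries.items(), key=lambda kv: kv[1]):
        name = "-".join(ent) if isinstance(ent, tuple) else ent
        rows.append((name, r))
    _write_tsv(pd.DataFrame(rows, columns=["entity", "norm_rank"]), path,
               header_comments=comments)


# -- final pair ranking ------------------------------------------------------

def read_pair_ranking(path) -> pd.DataFrame:
    """Parse a published-style ranking: rank, hyphenated pair, score.

    Returns a DataFrame with columns rank, ligand, receptor, score sorted
    by rank.
    """
    frame = _read_tsv(path, dtype={"pair": str})
    required = {"rank", "pair", "score"}
    if not required <= set(frame.columns):
        raise ValueError(f"pair ranking needs columns {sorted(required)}")
    lig, rec = zip(*(p.split("-", 1) for p in frame["pair"]))
    out = pd.DataFrame({
        "rank": frame["rank"].astype(int),
        "ligand": lig,
        "receptor": rec,
        "score": frame["score"].astype(float),
    })
    if (out["score"] <= 0).any() or (out["score"] > 1).any():
        raise ValueError("pair scores must lie in (0, 1]")
    return out.sort_values("rank").reset_index(drop=True)


def load_published_ranking() -> pd.DataFrame:
    """Bundled ligand-receptor ranking published for the motor-neuron study."""
    ref = importlib.resources.files("ligrec.data") / \
        "published_pair_ranking.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_pair_ranking(path)


# -- manifest ----------------------------------------------------------------

def read_manifest(path: str | Path) -> dict[str, str]:
    kv = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected key<TAB>value")
        kv[parts[0]] = parts[1]
    return kv


def write_manifest(kv: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for k, v in kv.items():
            fh.write(f"{k}\t{v}\n")
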