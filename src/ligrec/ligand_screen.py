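"""Selection of over-abundant secreted-ligand candidates from differential proteomics.

The input is a label-free MS abundance table (log2 intensities, proteins x
replicates) contrasting a *case* secretome with a *control* secretome.
Missing values encode non-detection and are treated categorically: a protein
is either quantified in both conditions (and screened by fold change) or
present only in the case condition (and selected outright).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProteinAbundanceTable",
    "LigandCandidate",
    "compute_fold_changes",
    "select_ligand_candidates",
]

STATUS_ENRICHED = "enriched"
STATUS_CASE_ONLY = "case_only"
STATUS_OTHER = "other"


@dataclass
class ProteinAbundanceTable:
    """Log2 MS intensities per protein and replicate, with a detection mask.

    Parameters
    ----------
    log2_intensity
        DataFrame indexed by protein id, one column per replicate. NaN where
        the protein was not detected in that replicate.
    condition_labels
        Mapping replicate (column) name -> "case" or "control".
    """

    log2_intensity: pd.DataFrame
    condition_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.log2_intensity.shape[0] == 0:
            raise ValueError("abundance table has no proteins")
        if self.log2_intensity.index.duplicated().any():
            dups = self.log2_intensity.index[self.log2_intensity.index.duplicated()]
            raise ValueError(f"duplicate protein ids: {sorted(set(dups))}")
        labels = set(self.condition_labels.values())
        if not labels <= {"case", "control"}:
            raise ValueError(f"condition labels must be case/control, got {labels}")
        for cond in ("case", "control"):
            if not self.columns_for(cond):
                raise ValueError(f"condition {cond!r} has zero replicates")
        missing = set(self.log2_intensity.columns) - set(self.condition_labels)
        if missing:
            raise ValueError(f"replicates without condition label: {sorted(missing)}")
        vals = self.log2_intensity.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("detected intensities must be finite")

    def columns_for(self, condition: str) -> list[str]:
        return [c for c in self.log2_intensity.columns
                if self.condition_labels.get(c) == condition]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.log2_intensity.index)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (protein x replicate)."""
        return self.log2_intensity.notna()


@dataclass
class LigandCandidate:
    protein_id: str
    log2_fc: float  # NaN for case-only proteins (ratio undefined)
    status: str
    selected: bool = field(default=False)


def compute_fold_changes(table: ProteinAbundanceTable,
                         min_detect: int = 2) -> pd.DataFrame:
    """Per-protein log2 fold change (case minus control) and presence category.

    A protein detected in >= ``min_detect`` replicates of both conditions gets
    ``log2_fc = mean(case) - mean(control)``. A protein detected in >=
    ``min_detect`` case replicates and in zero control replicates is flagged
    ``case_only`` (fold change undefined). Everything else is ``other``.

    Returns a DataFrame indexed by protein id with columns ``log2_fc`` and
    ``category`` in {"both", "case_only", "other"}.
    """
    if min_detect < 1:
        raise ValueError("min_detect must be >= 1")
    case_cols = table.columns_for("case")
    ctrl_cols = table.columns_for("control")
    case = table.log2_intensity[case_cols]
    ctrl = table.log2_intensity[ctrl_cols]
    n_case = case.notna().sum(axis=1)
    n_ctrl = ctrl.notna().sum(axis=1)

    both = (n_case >= min_detect) & (n_ctrl >= min_detect)
    case_only = (n_case >= min_detect) & (n_ctrl == 0)

    log2_fc = pd.Series(np.nan, index=table.log2_intensity.index, name="log2_fc")
    log2_fc[both] = case[both].mean(axis=1) - ctrl[both].mean(axis=1)

    category = pd.Series(STATUS_OTHER, index=table.log2_intensity.index,
                         name="category")
    category[both] = "both"
    category[case_only] = STATUS_CASE_ONLY
    return pd.DataFrame({"log2_fc": log2_fc, "category": category})


def select_ligand_candidates(fcs: pd.DataFrame,
                             fc_min: float = 1.5) -> list[LigandCandidate]:
    """Apply the over-abundance rule and return candidates in report order.

    Selected = proteins quantified in both conditions with fold change
    ``2**log2_fc >= fc_min``, plus case-only proteins. Ordering: case-only
    first, then descending log2 fold change; ties broken by protein id.
    """
    if fc_min <= 0:
        raise ValueError("fc_min must be positive")
    log2_fc_min = np.log2(fc_min)
    out: list[LigandCandidate] = []
    for pid, row in fcs.iterrows():
        cat = row["category"]
        if cat == STATUS_CASE_ONLY:
            out.append(LigandCandidate(str(pid), float("nan"),
                                       STATUS_CASE_ONLY, True))
        elif cat == "both":
            lfc = float(row["log2_fc"])
            if lfc >= log2_fc_min:
                out.append(LigandCandidate(str(pid), lfc, STATUS_ENRICHED, True))
            else:
                out.append(LigandCandidate(str(pid), lfc, STATUS_OTHER, False))
        else:
            out.append(LigandCandidate(str(pid), float("nan"),
                                       STATUS_OTHER, False))

    def key(c: LigandCandidate):
        case_only_first = 0 if c.status == STATUS_CASE_ONLY else 1
        lfc = c.log2_fc if np.isfinite(c.log2_fc) else -np.inf
        return (case_only_first, -lfc, c.protein_id)

    out.sort(key=key)
    return out


def selected_ids(candidates: list[LigandCandidate]) -> list[str]:
    return [c.protein_id for c in candidates if c.selected]


def candidates_to_frame(candidates: list[LigandCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in candidates],
            "log2_fc": [c.log2_fc for c in candidates],
            "status": [c.status for c in candidates],
            "selected": [c.selected for c in candidates],
        }
    )
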