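"""Invasion, proliferation and apoptosis scoring for organotypic assays.

Scored counts arrive per 500 x 500 um region of interest (ROI): the number
of cells remaining on the matrix surface, the number of invaded cells in
each depth bin (0-100, 100-200, 200-300, > 300 um; half-open at the upper
edge) and marker-positive counts (Ki67 for proliferation, cleaved
caspase-3 for apoptosis) out of the total cells in the ROI.

* invasive index  = 100 * invaded / (invaded + surface)
* marker index    = 100 * marker-positive / total cells
* depth profile   = per-bin invaded / surface, optionally normalised to the
  vehicle control per bin for drug-screen comparisons.

Aggregation averages ROI-level values per replicate first and reports the
condition mean +/- SEM across replicate means, treating the biological
replicate as the unit of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyGroupError, InvalidInputError, UndefinedStatisticError
from .simulate import DEPTH_BIN_COLUMNS

__all__ = [
    "CellCountRecord",
    "invasive_index",
    "marker_index",
    "depth_profile",
    "records_from_frame",
    "aggregate_indices",
    "mean_depth_profiles",
    "normalize_profile_table",
    "normalize_to_control",
    "DEPTH_BIN_COLUMNS",
]


@dataclass(frozen=True)
class CellCountRecord:
    """Manually scored counts for one ROI."""

    condition: str
    replicate: int
    roi: int
    surface_count: int
    invaded_counts: tuple  # 4 ints, depth bins 0-100/100-200/200-300/>300 um
    marker_positive: int = 0
    marker_total: int = 0

    def __post_init__(self) -> None:
        if len(self.invaded_counts) != 4:
            raise InvalidInputError("need 4 depth-bin counts")
        counts = (self.surface_count, *self.invaded_counts,
                  self.marker_positive, self.marker_total)
        if any(c < 0 for c in counts):
            raise InvalidInputError("counts must be non-negative")
        if self.marker_positive > self.marker_total:
            raise InvalidInputError("marker_positive cannot exceed marker_total")

    @property
    def total_invaded(self) -> int:
        return int(sum(self.invaded_counts))


def invasive_index(record: CellCountRecord) -> float:
    """Percent of cells that invaded: 100 * invaded / (invaded + surface)."""
    denom = record.total_invaded + record.surface_count
    if denom == 0:
        raise UndefinedStatisticError("invasive index undefined: no cells scored")
    return 100.0 * record.total_invaded / denom


def marker_index(record: CellCountRecord) -> float:
    """Percent marker-positive cells: 100 * positive / total."""
    if record.marker_total == 0:
        raise UndefinedStatisticError("marker index undefined: zero total cells")
    return 100.0 * record.marker_positive / record.marker_total


def depth_profile(record: CellCountRecord) -> np.ndarray:
    """Per-bin ratio of invaded cells to surface cells (length 4)."""
    if record.surface_count == 0:
        raise UndefinedStatisticError("depth profile undefined: zero surface cells")
    return np.asarray(record.invaded_counts, dtype=float) / record.surface_count


def records_from_frame(df: pd.DataFrame) -> list[CellCountRecord]:
    """Build ROI records from a tidy count table.

    Expected columns: condition, replicate, roi, surface, the four depth-bin
    columns, marker_pos, marker_total (marker columns optional).
    """
    required = {"condition", "replicate", "roi", "surface", *DEPTH_BIN_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"count table missing columns: {sorted(missing)}")
    has_marker = {"marker_pos", "marker_total"}.issubset(df.columns)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CellCountRecord(
                condition=str(row.condition),
                replicate=int(row.replicate),
                roi=int(row.roi),
                surface_count=int(row.surface),
                invaded_counts=tuple(int(getattr(row, c)) for c in DEPTH_BIN_COLUMNS),
                marker_positive=int(row.marker_pos) if has_marker else 0,
                marker_total=int(row.marker_total) if has_marker else 0,
            )
        )
    return records


def _per_roi_index(records: Iterable[CellCountRecord], which: str) -> pd.DataFrame:
    fn = {"invasive": invasive_index, "marker": marker_index}[which]
    rows = [
        {
            "condition": r.condition,
            "replicate": r.replicate,
            "roi": r.roi,
            "index_pct": fn(r),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def aggregate_indices(
    records: Sequence[CellCountRecord], which: str = "invasive"
) -> pd.DataFrame:
    """Condition-level mean +/- SEM of an index (ROI -> replicate -> condition).

    Returns a frame indexed by condition with columns ``mean_pct``,
    ``sem_pct`` (NaN for a single replicate) and ``n_replicates``.
    """
    if which not in ("invasive", "marker"):
        raise InvalidInputError("which must be 'invasive' or 'marker'")
    if len(records) == 0:
        raise EmptyGroupError("no records to aggregate")
    per_roi = _per_roi_index(records, which)
    per_rep = (
        per_roi.groupby(["condition", "replicate"])["index_pct"].mean().reset_index()
    )
    grouped = per_rep.groupby("condition")["index_pct"]
    out = pd.DataFrame(
        {
            "mean_pct": grouped.mean(),
            "sem_pct": grouped.sem(ddof=1),
            "n_replicates": grouped.size(),
        }
    )
    return out


def mean_depth_profiles(records: Sequence[CellCountRecord]) -> pd.DataFrame:
    """Condition x depth-bin table of mean invaded/surface ratios.

    ROI profiles are averaged per replicate and then across replicates,
    matching the aggregation hierarchy used for the indices.
    """
    if len(records) == 0:
        raise EmptyGroupError("no records to aggregate")
    rows = []
    for r in records:
        prof = depth_profile(r)
        rows.append(
            {
                "condition": r.condition,
                "replicate": r.replicate,
                **{c: prof[i] for i, c in enumerate(DEPTH_BIN_COLUMNS)},
            }
        )
    df = pd.DataFrame(rows)
    per_rep = df.groupby(["condition", "replicate"]).mean().reset_index()
    return per_rep.groupby("condition")[list(DEPTH_BIN_COLUMNS)].mean()


def normalize_profile_table(
    profiles: pd.DataFrame, vehicle_label: str
) -> pd.DataFrame:
    """Divide each condition's per-bin mean ratio by the vehicle's.

    The vehicle row maps to 1 at every bin with a nonzero control ratio;
    bins where the vehicle ratio is zero are non-comparable and returned as
    NaN (their labels are listed in ``result.attrs['non_comparable_bins']``).
    Applying the function twice is a no-op because the vehicle row of a
    normalised table is identically 1.
    """
    if vehicle_label not in profiles.index:
        raise InvalidInputError(f"vehicle label {vehicle_label!r} not in table")
    vehicle = profiles.loc[vehicle_label]
    out = profiles.divide(vehicle, axis=1)
    non_comparable = [c for c in profiles.columns if vehicle[c] == 0]
    out[non_comparable] = np.nan
    out.attrs["non_comparable_bins"] = non_comparable
    return out


def normalize_to_control(
    records: Sequence[CellCountRecord], vehicle_label: str
) -> pd.DataFrame:
    """Vehicle-normalised mean depth profiles per condition."""
    profiles = mean_depth_profiles(records)
    return normalize_profile_table(profiles, vehicle_label)
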