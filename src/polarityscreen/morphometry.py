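"""Per-cell morphometry of segmented T cells and well-level aggregation.

Five shape read-outs quantify the transition from a resting, round
lymphocyte to the polarized "hand-mirror" morphology of a migrating cell:

``inv_form_factor``
    Roundness index :math:`P^2 / (4 \\pi A)`; 1 for a perfect circle and
    increasing without bound as the outline grows more complex.
``nuclear_displacement``
    Euclidean distance between the nuclear centroid and the cell centroid;
    rises as the nucleus translocates toward the leading edge.
``area``
    Cell area.
``gyration_radius``
    Root-mean-square distance of cell pixels from the cell centroid — a
    measure of cell spread.
``elongation_factor``
    Major/minor axis ratio of the moment-equivalent ellipse (length to
    width); ≥ 1 by construction.

Inputs are paired integer label images (cell mask + nucleus mask) as
produced by any nucleus-seeded segmentation. Perimeter uses the Crofton
multi-directional estimator so that a rasterized disk scores close to the
analytic circle value; a raw pixel-edge count would systematically inflate
``inv_form_factor``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import perimeter_crofton, regionprops

#: Canonical order of the five morphology parameters.
PARAMETERS = (
    "inv_form_factor",
    "nuclear_displacement",
    "area",
    "gyration_radius",
    "elongation_factor",
)

# Minor-axis floor (px) so single-pixel-wide regions don't yield an
# infinite elongation.
_MINOR_AXIS_FLOOR = 1.0


class MaskError(ValueError):
    """Raised when a label-image pair violates its invariants."""


@dataclass
class LabeledImagePair:
    """Paired cell and nucleus label masks for one imaged field.

    Both masks share dimensions; labels are positive integers on a zero
    background. Each nucleus is expected to overlap exactly one cell.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    pixel_size: float = 1.0
    field_id: str = "F1"
    well_id: str = ""
    plate_id: str = ""
    screen_id: int = 0

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask)
        self.nucleus_mask = np.asarray(self.nucleus_mask)
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise MaskError(
                f"cell mask {self.cell_mask.shape} and nucleus mask "
                f"{self.nucleus_mask.shape} differ in shape"
            )
        if self.cell_mask.ndim != 2:
            raise MaskError("masks must be 2-D label images")
        if self.cell_mask.min() < 0 or self.nucleus_mask.min() < 0:
            raise MaskError("labels must be non-negative integers")
        if self.pixel_size <= 0:
            raise MaskError("pixel_size must be positive")


@dataclass
class CellRecord:
    """One segmented cell's five morphology parameters plus identifiers."""

    cell_id: int
    area: float
    perimeter: float
    inv_form_factor: float
    nuclear_displacement: float
    gyration_radius: float
    elongation_factor: float
    cell_centroid: tuple[float, float] = (0.0, 0.0)  # (x, y), x = column
    nucleus_centroid: tuple[float, float] = (0.0, 0.0)
    field_id: str = ""
    well_id: str = ""
    plate_id: str = ""
    screen_id: int = 0

    def as_dict(self) -> dict:
        d = {
            "plate_id": self.plate_id,
            "well_id": self.well_id,
            "screen_id": self.screen_id,
            "field_id": self.field_id,
            "cell_id": self.cell_id,
            "cell_x": self.cell_centroid[0],
            "cell_y": self.cell_centroid[1],
            "nucleus_x": self.nucleus_centroid[0],
            "nucleus_y": self.nucleus_centroid[1],
            "perimeter": self.perimeter,
        }
        for p in PARAMETERS:
            d[p] = getattr(self, p)
        return d


@dataclass
class WellProfile:
    """Per-well mean of the five parameters with treatment annotation."""

    well_id: str
    plate_id: str
    screen_id: int
    treatment: str
    n_cells: int
    values: dict = field(default_factory=dict)
    qc_pass: bool = True

    def as_dict(self) -> dict:
        d = {
            "plate_id": self.plate_id,
            "well_id": self.well_id,
            "screen_id": self.screen_id,
            "treatment": self.treatment,
            "n_cells": self.n_cells,
            "qc_pass": self.qc_pass,
        }
        d.update({p: self.values[p] for p in PARAMETERS})
        return d


def gyration_radius(mask: np.ndarray) -> float:
    """RMS distance of foreground pixels from their centroid (px).

    For a filled disk of radius R this converges to R/sqrt(2).
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise MaskError("empty mask has no gyration radius")
    rc, cc = rows.mean(), cols.mean()
    return float(np.sqrt(np.mean((rows - rc) ** 2 + (cols - cc) ** 2)))


def _touches_border(slc: tuple[slice, slice], shape: tuple[int, int]) -> bool:
    return (
        slc[0].start == 0
        or slc[1].start == 0
        or slc[0].stop == shape[0]
        or slc[1].stop == shape[1]
    )


def _match_nuclei_to_cells(pair: LabeledImagePair) -> dict[int, int]:
    """Map cell label -> nucleus label by maximal pixel overlap."""
    cell = pair.cell_mask
    nuc = pair.nucleus_mask
    out: dict[int, int] = {}
    counts: dict[tuple[int, int], int] = {}
    both = (cell > 0) & (nuc > 0)
    pairs, n = np.unique(
        np.stack([cell[both], nuc[both]]), axis=1, return_counts=True
    )
    for (c, k), cnt in zip(pairs.T, n):
        counts[(int(c), int(k))] = int(cnt)
    # assign each nucleus to the cell it overlaps most; keep the larger
    # overlap if two nuclei claim the same cell
    by_nuc: dict[int, tuple[int, int]] = {}
    for (c, k), cnt in counts.items():
        if k not in by_nuc or cnt > by_nuc[k][1]:
            by_nuc[k] = (c, cnt)
    chosen: dict[int, tuple[int, int]] = {}
    for k in sorted(by_nuc):
        c, cnt = by_nuc[k]
        if c not in chosen or cnt > chosen[c][1]:
            chosen[c] = (k, cnt)
    out = {c: k for c, (k, _) in chosen.items()}
    return out


def compute_cell_features(
    pair: LabeledImagePair,
    *,
    exclude_border: bool = True,
    normalize_displacement: bool = False,
) -> list[CellRecord]:
    """Measure the five morphology parameters for every cell in a field.

    One record is produced per cell label that has a matched nucleus and
    (by default) does not touch the image border — border-touching cells
    are truncated and their shape unreliable. Nuclei without an enclosing
    cell are skipped with a warning. Empty masks yield an empty list.

    Parameters
    ----------
    pair
        Cell/nucleus label masks plus identifiers.
    exclude_border
        Drop cells whose bounding box touches the image border.
    normalize_displacement
        If set, report nuclear displacement as a fraction of the cell's
        equivalent radius ``sqrt(area/pi)`` instead of length units.
    """
    cell = pair.cell_mask
    nuc = pair.nucleus_mask
    if cell.max() == 0:
        return []
    px = pair.pixel_size

    cell_to_nuc = _match_nuclei_to_cells(pair)
    n_orphans = len(np.setdiff1d(np.unique(nuc[nuc > 0]), list(cell_to_nuc.values())))
    if n_orphans:
        warnings.warn(
            f"{n_orphans} nucleus label(s) without an enclosing cell skipped",
            stacklevel=2,
        )

    nuc_centroids = {
        p.label: p.centroid for p in regionprops(nuc.astype(np.int32))
    }

    records: list[CellRecord] = []
    for prop in regionprops(cell.astype(np.int32)):
        if prop.label not in cell_to_nuc:
            continue
        if exclude_border and _touches_border(prop.slice, cell.shape):
            continue
        region = prop.image  # cropped boolean mask
        area = prop.area * px**2
        perim = perimeter_crofton(region, directions=4) * px
        inv_ff = perim**2 / (4.0 * np.pi * area)
        cy, cx = prop.centroid  # (row, col)
        ny, nx = nuc_centroids[cell_to_nuc[prop.label]]
        displacement = float(np.hypot(nx - cx, ny - cy)) * px
        if normalize_displacement:
            displacement /= np.sqrt(area / np.pi)
        rg = gyration_radius(region) * px
        minor = max(prop.axis_minor_length, _MINOR_AXIS_FLOOR)
        elong = max(prop.axis_major_length / minor, 1.0)
        records.append(
            CellRecord(
                cell_id=int(prop.label),
                area=float(area),
                perimeter=float(perim),
                inv_form_factor=float(inv_ff),
                nuclear_displacement=displacement,
                gyration_radius=float(rg),
                elongation_factor=float(elong),
                cell_centroid=(float(cx * px), float(cy * px)),
                nucleus_centroid=(float(nx * px), float(ny * px)),
                field_id=pair.field_id,
                well_id=pair.well_id,
                plate_id=pair.plate_id,
                screen_id=pair.screen_id,
            )
        )
    return records


def aggregate_well(
    records: list[CellRecord] | pd.DataFrame,
    *,
    min_cells: int = 20,
    treatment: str = "",
    aggregator: str = "mean",
) -> WellProfile:
    """Pool the cells of one well (across its fields) into a WellProfile.

    The aggregate is the arithmetic mean of each parameter by default
    (``aggregator="median"`` for the robust alternative). Wells with fewer
    than ``min_cells`` cells keep their values but fail QC.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.as_dict() for r in records])
    if df.empty:
        raise MaskError("cannot aggregate an empty record list")
    if aggregator not in ("mean", "median"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    agg = df[list(PARAMETERS)].agg(aggregator)
    first = df.iloc[0]
    n = len(df)
    return WellProfile(
        well_id=str(first.get("well_id", "")),
        plate_id=str(first.get("plate_id", "")),
        screen_id=int(first.get("screen_id", 0)),
        treatment=treatment or str(first.get("treatment", "")),
        n_cells=n,
        values={p: float(agg[p]) for p in PARAMETERS},
        qc_pass=n >= min_cells,
    )


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Flatten CellRecords into the `cells.csv` table layout."""
    return pd.DataFrame([r.as_dict() for r in records])


def aggregate_cells_frame(
    cells: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    *,
    min_cells: int = 20,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Aggregate a per-cell table to the `wells.csv` table, one row per
    (plate, well, screen), optionally annotating treatments from a layout.
    """
    keys = ["plate_id", "well_id", "screen_id"]
    rows = []
    for key, grp in cells.groupby(keys, sort=True):
        prof = aggregate_well(grp, min_cells=min_cells, aggregator=aggregator)
        prof.plate_id, prof.well_id, prof.screen_id = (
            str(key[0]),
            str(key[1]),
            int(key[2]),
        )
        rows.append(prof.as_dict())
    wells = pd.DataFrame(rows)
    if layout is not None:
        ann = layout[keys + ["treatment"]].astype({"screen_id": int})
        wells = wells.drop(columns=["treatment"]).merge(ann, on=keys, how="left")
        if wells["treatment"].isna().any():
            missing = wells.loc[wells["treatment"].isna(), keys]
            raise KeyError(
                f"wells absent from layout: {missing.to_records(index=False)}"
            )
    return wells
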