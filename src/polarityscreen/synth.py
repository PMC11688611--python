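"""Seed-controlled synthetic RNAi screens of T-cell polarity.

The generator emulates the study design of an arrayed siRNA screen read
out by high-content imaging: three replicate screens, multiple 96-well
plates, one SMARTpool (gene) per well, six non-targeting control wells
per plate, positive-control wells in which knockdown collapses the
polarized phenotype (talin-1-like), and round-reference wells mimicking
cells rested on poly-L-lysine. Per-gene effects are planted as
multiplicative shifts on the five morphology parameters so that every
downstream stage — morphometry, plate normalization, Z-score hit calling,
clustering — is testable without any external data, and ground-truth hit
labels are emitted alongside.

Two tiers share one effect model:

* the **feature tier** draws per-cell parameter values directly from the
  phenotype distributions (fast; used for statistical tests), and
* the **image tier** renders each cell as a labeled mask — an ellipse
  body, for polarized cells with a tapering trailing tail (the
  "hand-mirror" silhouette) and the nucleus displaced toward the leading
  edge — exercising the morphometry stage end to end.

All outputs are pure functions of (configuration, master seed): per-well
random substreams are derived as ``default_rng([master_seed, screen_id,
plate_index, well_index])``, so wells are independent and reproducible.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon
from skimage.morphology import erosion

from .morphometry import PARAMETERS

CONTROL_SIRNA = "control_siRNA"
POSITIVE_CONTROL = "TLN1"
REFERENCE = "polyL-lysine"
CONTROL_TREATMENTS = (CONTROL_SIRNA, POSITIVE_CONTROL, REFERENCE)

#: Baseline well-mean values of the five parameters for cells polarized
#: on anti-LFA-1 (px units at 10x magnification scale).
BASELINE_POLARIZED = {
    "inv_form_factor": 2.0,
    "nuclear_displacement": 2.5,
    "area": 220.0,
    "gyration_radius": 9.0,
    "elongation_factor": 1.9,
}

#: Multipliers mapping the polarized baseline to the round, non-polarized
#: phenotype of cells on poly-L-lysine.
ROUND_MULTIPLIERS = {
    "inv_form_factor": 0.575,
    "nuclear_displacement": 0.32,
    "area": 0.72,
    "gyration_radius": 0.74,
    "elongation_factor": 0.63,
}

#: Multiplier applied to all five parameters in talin-1 positive-control
#: wells: knockdown abolishes polarization, landing the wells a few plate
#: SDs below the library mean on every read-out.
TLN1_MULTIPLIER = 0.60


class ConfigurationError(ValueError):
    """Raised for invalid generator parameters or missing genes."""


class SizingError(ValueError):
    """Raised when a requested shape cannot fit in the image."""


# ---------------------------------------------------------------------------
# shape model


@dataclass(frozen=True)
class ShapeParams:
    """Geometry of one synthetic cell.

    ``elongation_target`` is the major/minor ratio of the body ellipse
    (1 = circular). ``tail_length_frac`` is the uropod-to-tail length as a
    fraction of the body length (polarized cells only).
    ``nucleus_offset_frac`` displaces the nucleus toward the leading edge
    as a fraction of the body's equivalent radius. ``jitter_sd`` is the
    relative (lognormal) scale of boundary/axis jitter.
    """

    phenotype_class: str = "round"
    body_radius: float = 9.0
    elongation_target: float = 1.0
    tail_length_frac: float = 0.0
    nucleus_offset_frac: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.phenotype_class not in ("round", "polarized", "elongated"):
            raise ConfigurationError(
                f"unknown phenotype_class {self.phenotype_class!r}"
            )
        if self.body_radius <= 0:
            raise ConfigurationError("body_radius must be > 0")
        if self.elongation_target < 1:
            raise ConfigurationError("elongation_target must be >= 1")
        if not 0 <= self.tail_length_frac <= 2:
            raise ConfigurationError("tail_length_frac must be in [0, 2]")
        if not 0 <= self.nucleus_offset_frac <= 1:
            raise ConfigurationError("nucleus_offset_frac must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")


def _ellipse_poly(a: float, b: float, n: int = 256) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.stack([a * np.cos(th), b * np.sin(th)], axis=1)


def _rotate(pts: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return pts @ np.array([[c, -s], [s, c]]).T


def generate_cell_mask(
    params: ShapeParams,
    image_size: int = 96,
    seed: int = 0,
    *,
    theta: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell as paired uint16 label masks (cell, nucleus).

    The body is an ellipse of equivalent radius ``body_radius`` whose
    axes realize ``elongation_target``. Polarized cells gain a tapering
    triangular tail at the rear, and the nucleus is offset toward the
    leading edge. Deterministic for fixed (params, seed); the orientation
    is drawn from the seed unless ``theta`` is given.

    Returns (cell_mask, nucleus_mask), the single cell labeled 1.
    """
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi) if theta is None else float(theta)

    jit = (
        rng.lognormal(mean=0.0, sigma=params.jitter_sd, size=4)
        if params.jitter_sd > 0
        else np.ones(4)
    )
    e = params.elongation_target
    a = params.body_radius * np.sqrt(e) * jit[0]
    b = params.body_radius / np.sqrt(e) * jit[1]
    tail_len = params.tail_length_frac * 2 * a * jit[2]
    half_extent = a + tail_len
    if 2 * (half_extent + 2) > image_size or 2 * (b + 2) > image_size:
        raise SizingError(
            f"shape extent {2 * half_extent:.0f} px exceeds image size "
            f"{image_size} px"
        )

    body = _ellipse_poly(a, b)
    parts = [body]
    if params.phenotype_class == "polarized" and tail_len > 0:
        w0 = 0.9 * b * jit[3]
        # tail roots inside the body so the mask stays connected
        parts.append(
            np.array(
                [
                    [-0.7 * a, w0 / 2],
                    [-0.7 * a, -w0 / 2],
                    [-(a + tail_len), 0.0],
                ]
            )
        )

    c0 = image_size / 2.0
    cell = np.zeros((image_size, image_size), dtype=np.uint16)
    for pts in parts:
        pts = _rotate(pts, theta)
        rr, cc = polygon(pts[:, 1] + c0, pts[:, 0] + c0, shape=cell.shape)
        cell[rr, cc] = 1

    # nucleus: smaller ellipse displaced toward the leading edge (+x)
    rn = 0.45 * params.body_radius
    offset = params.nucleus_offset_frac * params.body_radius
    offset = min(offset, max(a - 1.3 * rn, 0.0))
    nuc_pts = _ellipse_poly(1.15 * rn, 0.9 * rn) + np.array([offset, 0.0])
    nuc_pts = _rotate(nuc_pts, theta)
    nucleus = np.zeros_like(cell)
    rr, cc = polygon(nuc_pts[:, 1] + c0, nuc_pts[:, 0] + c0, shape=cell.shape)
    nucleus[rr, cc] = 1
    # keep the nucleus strictly interior to the cell
    interior = erosion(cell > 0)
    nucleus[~interior] = 0
    if nucleus.sum() == 0:
        raise SizingError("nucleus vanished after clipping to the cell body")
    return cell, nucleus


# ---------------------------------------------------------------------------
# plate layout


@dataclass(frozen=True)
class PlateLayout:
    """One plate of one screen: well -> treatment mapping."""

    plate_id: str
    screen_id: int
    wells: dict = field(default_factory=dict)  # well_id -> treatment

    def library_wells(self) -> dict:
        return {
            w: t for w, t in self.wells.items() if t not in CONTROL_TREATMENTS
        }


def well_ids_96() -> list[str]:
    return [
        f"{row}{col:02d}" for row in string.ascii_uppercase[:8] for col in range(1, 13)
    ]


def make_layouts(
    n_plates: int = 2,
    n_screens: int = 3,
    *,
    n_control: int = 6,
    n_positive: int = 2,
    n_reference: int = 2,
    gene_prefix: str = "GENE",
) -> list[PlateLayout]:
    """Build the default screen layout: identical plate maps replicated
    across screens, control wells spread evenly across each plate.
    """
    wells = well_ids_96()
    n_ctrl = n_control + n_positive + n_reference
    ctrl_pos = np.linspace(0, len(wells) - 1, n_ctrl).round().astype(int)
    ctrl_treatments = (
        [CONTROL_SIRNA] * n_control
        + [POSITIVE_CONTROL] * n_positive
        + [REFERENCE] * n_reference
    )
    layouts = []
    gene_counter = 1
    plate_maps: list[dict] = []
    for p in range(n_plates):
        mapping: dict[str, str] = {}
        ctrl_iter = iter(sorted(zip(ctrl_pos, ctrl_treatments)))
        nxt = next(ctrl_iter, None)
        for i, w in enumerate(wells):
            if nxt is not None and i == nxt[0]:
                mapping[w] = nxt[1]
                nxt = next(ctrl_iter, None)
            else:
                mapping[w] = f"{gene_prefix}{gene_counter:04d}"
                gene_counter += 1
        plate_maps.append(mapping)
    for s in range(1, n_screens + 1):
        for p, mapping in enumerate(plate_maps, start=1):
            layouts.append(
                PlateLayout(plate_id=f"P{p:02d}", screen_id=s, wells=dict(mapping))
            )
    return layouts


def layouts_to_frame(layouts: list[PlateLayout]) -> pd.DataFrame:
    rows = [
        {
            "plate_id": lo.plate_id,
            "well_id": w,
            "screen_id": lo.screen_id,
            "treatment": t,
        }
        for lo in layouts
        for w, t in lo.wells.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# effect model


@dataclass
class EffectModel:
    """Planted per-gene effects and the generator's noise scales.

    ``gene_effects`` maps treatment -> multiplicative factor per parameter
    (1.0 everywhere for null genes). Noise model per cell:

    ``value = baseline * effect * exp(eps_screen + eps_well + eps_cell)``

    with ``eps_screen ~ N(0, between_screen_sd)`` per (gene, screen,
    parameter), ``eps_well ~ N(0, well_noise_sd)`` per well, and
    ``eps_cell ~ N(0, cell_cv)`` per cell (mean-corrected lognormal).
    """

    gene_effects: dict = field(default_factory=dict)
    fraction_hits_decrease: float = 0.08
    fraction_hits_increase: float = 0.10
    effect_magnitude: float = 0.35
    between_screen_sd: float = 0.03
    well_noise_sd: float = 0.04
    cell_cv: float = 0.30

    def __post_init__(self) -> None:
        if self.fraction_hits_decrease + self.fraction_hits_increase > 1:
            raise ConfigurationError("hit fractions must sum to <= 1")
        for frac in (self.fraction_hits_decrease, self.fraction_hits_increase):
            if not 0 <= frac <= 1:
                raise ConfigurationError("hit fractions must be in [0, 1]")
        if min(self.between_screen_sd, self.well_noise_sd, self.cell_cv) < 0:
            raise ConfigurationError("noise SDs must be >= 0")

    @classmethod
    def plant(
        cls,
        genes: list[str],
        seed: int,
        *,
        fraction_hits_decrease: float = 0.08,
        fraction_hits_increase: float = 0.10,
        effect_magnitude: float = 0.35,
        between_screen_sd: float = 0.03,
        well_noise_sd: float = 0.04,
        cell_cv: float = 0.30,
    ) -> "EffectModel":
        """Randomly assign decrease/increase effect vectors to a gene list.

        Planted hits shift all five parameters in the same direction by
        ``effect_magnitude`` (the talin-like / ROCK-like regimes); null
        genes keep unit multipliers.
        """
        model = cls(
            fraction_hits_decrease=fraction_hits_decrease,
            fraction_hits_increase=fraction_hits_increase,
            effect_magnitude=effect_magnitude,
            between_screen_sd=between_screen_sd,
            well_noise_sd=well_noise_sd,
            cell_cv=cell_cv,
        )
        rng = np.random.default_rng([seed, 0xEFFEC])
        genes = sorted(genes)
        n = len(genes)
        n_dec = int(round(fraction_hits_decrease * n))
        n_inc = int(round(fraction_hits_increase * n))
        perm = rng.permutation(n)
        dec = {genes[i] for i in perm[:n_dec]}
        inc = {genes[i] for i in perm[n_dec : n_dec + n_inc]}
        for g in genes:
            if g in dec:
                mult = 1.0 - effect_magnitude
            elif g in inc:
                mult = 1.0 + effect_magnitude
            else:
                mult = 1.0
            model.gene_effects[g] = {p: mult for p in PARAMETERS}
        model.gene_effects[CONTROL_SIRNA] = {p: 1.0 for p in PARAMETERS}
        model.gene_effects[POSITIVE_CONTROL] = {
            p: TLN1_MULTIPLIER for p in PARAMETERS
        }
        model.gene_effects[REFERENCE] = dict(ROUND_MULTIPLIERS)
        return model

    def truth_frame(self) -> pd.DataFrame:
        """Ground-truth table: planted direction per gene and parameter."""
        rows = []
        for g, eff in sorted(self.gene_effects.items()):
            if g in CONTROL_TREATMENTS:
                continue
            row = {"gene": g}
            for p in PARAMETERS:
                row[f"direction_{p}"] = int(np.sign(eff[p] - 1.0))
            row["planted_hit"] = any(eff[p] != 1.0 for p in PARAMETERS)
            row["planted_direction"] = int(
                np.sign(sum(eff[p] - 1.0 for p in PARAMETERS))
            )
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screen generation (feature tier)


def _well_rng(seed: int, screen_id: int, plate_idx: int, well_idx: int):
    return np.random.default_rng([seed, screen_id, plate_idx, well_idx])


def generate_screen_set(
    layouts: list[PlateLayout],
    effects: EffectModel,
    cells_per_well: int = 50,
    seed: int = 0,
    *,
    fields_per_well: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a full multi-screen per-cell feature table (feature tier).

    Returns ``(cells, truth)``: one row per synthetic cell with the five
    parameters, and the planted ground-truth table. Deterministic for a
    fixed (layouts, effects, seed).
    """
    if cells_per_well < 1:
        raise ConfigurationError("cells_per_well must be >= 1")
    screens = sorted({lo.screen_id for lo in layouts})
    if len(screens) < 1:
        raise ConfigurationError("no screens in layout set")

    baseline = np.array([BASELINE_POLARIZED[p] for p in PARAMETERS])
    npar = len(PARAMETERS)

    # per-(gene, screen, parameter) replicate noise, deterministic from seed
    genes_all = sorted(
        {t for lo in layouts for t in lo.wells.values()}
    )
    missing = [
        g for g in genes_all if g not in effects.gene_effects
    ]
    if missing:
        raise ConfigurationError(
            f"{len(missing)} treatment(s) missing from effect model, "
            f"e.g. {missing[:3]}"
        )
    rng_screen = np.random.default_rng([seed, 0x5C12EE])
    eps_screen = {
        (g, s): rng_screen.normal(0.0, effects.between_screen_sd, npar)
        for g in genes_all
        for s in screens
    }

    plate_ids = sorted({lo.plate_id for lo in layouts})
    plate_index = {p: i for i, p in enumerate(plate_ids)}
    well_index = {w: i for i, w in enumerate(well_ids_96())}

    chunks = []
    for lo in sorted(layouts, key=lambda x: (x.screen_id, x.plate_id)):
        for w in sorted(lo.wells):
            t = lo.wells[w]
            rng = _well_rng(seed, lo.screen_id, plate_index[lo.plate_id], well_index[w])
            eff = np.array([effects.gene_effects[t][p] for p in PARAMETERS])
            eps_w = rng.normal(0.0, effects.well_noise_sd, npar)
            target = baseline * eff * np.exp(eps_screen[(t, lo.screen_id)] + eps_w)
            s = effects.cell_cv
            draws = target * np.exp(
                rng.normal(0.0, s, size=(cells_per_well, npar)) - s**2 / 2.0
            )
            # digitization floors: elongation and roundness cannot dip
            # below their geometric minima
            draws[:, PARAMETERS.index("elongation_factor")] = np.maximum(
                draws[:, PARAMETERS.index("elongation_factor")], 1.0
            )
            draws[:, PARAMETERS.index("inv_form_factor")] = np.maximum(
                draws[:, PARAMETERS.index("inv_form_factor")], 1.0
            )
            chunk = pd.DataFrame(draws, columns=list(PARAMETERS))
            chunk.insert(0, "cell_id", np.arange(1, cells_per_well + 1))
            chunk.insert(
                0, "field_id", [f"F{1 + i % fields_per_well}" for i in range(cells_per_well)]
            )
            chunk.insert(0, "treatment", t)
            chunk.insert(0, "screen_id", lo.screen_id)
            chunk.insert(0, "well_id", w)
            chunk.insert(0, "plate_id", lo.plate_id)
            chunks.append(chunk)
    cells = pd.concat(chunks, ignore_index=True)
    return cells, effects.truth_frame()


# ---------------------------------------------------------------------------
# image tier


def _shape_from_params(values: dict) -> ShapeParams:
    """Map a drawn five-parameter vector to cell geometry (qualitative).

    Area sets the body radius, the elongation read-out sets the axis
    ratio, roundness in excess of a circle sets the tail length, and
    nuclear displacement sets the nucleus offset.
    """
    area = max(values["area"], 20.0)
    elong = float(np.clip(values["elongation_factor"], 1.0, 2.5))
    tail = float(np.clip(values["inv_form_factor"] - 1.0, 0.0, 1.2))
    body_radius = float(
        np.clip(np.sqrt(area / np.pi) / np.sqrt(1.0 + 0.3 * tail), 3.0, 10.0)
    )
    offset = float(np.clip(values["nuclear_displacement"] / body_radius, 0.0, 0.8))
    polarized = tail > 0.15
    return ShapeParams(
        phenotype_class="polarized" if polarized else "elongated",
        body_radius=body_radius,
        elongation_target=elong,
        tail_length_frac=tail if polarized else 0.0,
        nucleus_offset_frac=offset if polarized else 0.0,
        jitter_sd=0.0,
    )


def render_field(
    cell_values: pd.DataFrame,
    image_size: int = 512,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stamp one labeled field from per-cell parameter draws.

    Cells are placed on a grid with enough pitch to avoid overlap and a
    margin so they stay clear of the border.
    """
    rng = np.random.default_rng(seed)
    n = len(cell_values)
    pitch = 128
    per_side = max((image_size - 16) // pitch, 1)
    if n > per_side**2:
        raise SizingError(
            f"{n} cells do not fit a {image_size}px field at pitch {pitch}"
        )
    cell_mask = np.zeros((image_size, image_size), dtype=np.uint16)
    nuc_mask = np.zeros_like(cell_mask)
    for i, (_, row) in enumerate(cell_values.iterrows()):
        sp = _shape_from_params(row[list(PARAMETERS)].to_dict())
        sub_c, sub_n = generate_cell_mask(
            sp, image_size=pitch, seed=int(rng.integers(2**31 - 1))
        )
        gy = 8 + (i // per_side) * pitch
        gx = 8 + (i % per_side) * pitch
        label = i + 1
        sl = (slice(gy, gy + pitch), slice(gx, gx + pitch))
        cell_mask[sl][sub_c > 0] = label
        nuc_mask[sl][sub_n > 0] = label
    return cell_mask, nuc_mask


def generate_image_screen(
    layouts: list[PlateLayout],
    effects: EffectModel,
    cells_per_well: int = 8,
    seed: int = 0,
    *,
    fields_per_well: int = 2,
    image_size: int = 512,
):
    """Yield (plate_id, well_id, screen_id, field_id, cell_mask, nuc_mask)
    for every field of an image-tier screen.

    Per-cell parameter draws reuse the feature-tier model; each field
    renders its share of the well's cells.
    """
    cells, _ = generate_screen_set(
        layouts, effects, cells_per_well, seed, fields_per_well=fields_per_well
    )
    for (pid, wid, sid, fid), grp in cells.groupby(
        ["plate_id", "well_id", "screen_id", "field_id"], sort=True
    ):
        sub_seed = (seed + zlib.crc32(f"{pid}_{wid}_{sid}_{fid}".encode())) % (2**31)
        cm, nm = render_field(grp, image_size=image_size, seed=sub_seed)
        yield pid, wid, int(sid), fid, cm, nm


def write_image_screen(out_dir, layouts, effects, **kwargs) -> pd.DataFrame:
    """Write TIFF label masks named `<plate>_<well>_S<screen>_<field>_{cell,nuc}.tif`
    plus `layout.csv` and `truth.csv`; returns the layout table."""
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, wid, sid, fid, cm, nm in generate_image_screen(
        layouts, effects, **kwargs
    ):
        stem = f"{pid}_{wid}_S{sid}_{fid}"
        tifffile.imwrite(out / f"{stem}_cell.tif", cm.astype(np.uint16))
        tifffile.imwrite(out / f"{stem}_nuc.tif", nm.astype(np.uint16))
    layout_df = layouts_to_frame(layouts)
    layout_df.to_csv(out / "layout.csv", index=False)
    effects.truth_frame().to_csv(out / "truth.csv", index=False)
    return layout_df
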