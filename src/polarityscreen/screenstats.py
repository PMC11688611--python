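"""Plate normalization, Z-scoring, and replicate hit calling.

The scoring follows the standard arrayed-screen recipe: per-well raw
values are first expressed as ratios to the mean of the plate's
non-targeting control wells, then standardized per plate and parameter,

    Z = (x - mean) / SD,

with mean and SD taken over the plate's library wells (controls anchor
the normalization and are scored against the library distribution but do
not contribute to it). A gene is significant on a parameter when
|Z| >= 1.5 in at least two of the three replicate screens — with, by
default, a consistent sign across those screens — and is a hit when one
or more of the five morphology parameters is significant. Hits whose
significant parameters all decrease are classified as reduced polarity
(the talin-1-like phenotype); all-increase hits as enhanced polarity;
anything else as mixed.

A robust variant (median and 1.4826*MAD) is available for plates with
heavy-tailed well distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import PARAMETERS
from .synth import CONTROL_SIRNA, CONTROL_TREATMENTS


class PlateError(ValueError):
    """Raised when a plate cannot be normalized or scored."""


@dataclass
class ScreenConfig:
    """Scoring knobs with the screening-standard defaults."""

    z_threshold: float = 1.5
    min_screens: int = 2
    n_screens: int = 3
    sd_mode: str = "sample"  # or "population"
    z_variant: str = "classical"  # or "robust"
    normalization: str = "ratio_to_control"  # or "none"
    require_sign_consistency: bool = True
    include_controls_in_stats: bool = False
    min_cells: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.min_screens <= self.n_screens:
            raise ValueError("need 0 < min_screens <= n_screens")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")
        if self.z_variant not in ("classical", "robust"):
            raise ValueError(f"unknown z_variant {self.z_variant!r}")
        if self.normalization not in ("ratio_to_control", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def normalize_plate(wells: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Express each well's parameters as ratios to the plate's control mean.

    Operates per (plate_id, screen_id) group; the mean of the QC-passing
    non-targeting control wells defines 1.0 for each parameter. Plates
    without usable controls, or with a zero control mean, raise
    :class:`PlateError`.
    """
    wells = wells.copy()
    if config.normalization == "none":
        return wells
    params = list(PARAMETERS)
    for (pid, sid), idx in wells.groupby(["plate_id", "screen_id"]).groups.items():
        grp = wells.loc[idx]
        ctrl = grp[(grp["treatment"] == CONTROL_SIRNA) & grp["qc_pass"]]
        if ctrl.empty:
            raise PlateError(
                f"plate {pid} screen {sid}: no QC-passing control wells"
            )
        denom = ctrl[params].mean()
        if (denom == 0).any() or denom.isna().any():
            raise PlateError(
                f"plate {pid} screen {sid}: control mean is zero/NaN"
            )
        wells.loc[idx, params] = grp[params] / denom
    return wells


def _location_scale(x: np.ndarray, config: ScreenConfig) -> tuple[float, float]:
    if config.z_variant == "robust":
        loc = float(np.median(x))
        scale = float(stats.median_abs_deviation(x, scale="normal"))
    else:
        loc = float(np.mean(x))
        ddof = 1 if config.sd_mode == "sample" else 0
        scale = float(np.std(x, ddof=ddof))
    return loc, scale


def zscore_plate(
    normalized: pd.DataFrame, config: ScreenConfig
) -> pd.DataFrame:
    """Standardize well values per (plate, screen, parameter).

    Returns the long-format Z-score table with one row per (plate, well,
    screen, parameter): the normalized value ``x``, its score ``z``, the
    plate location/scale used, and control/QC annotations. Control wells
    receive a score against the library distribution but never enter the
    location/scale estimate. A zero SD (or MAD) raises :class:`PlateError`
    rather than emitting silent zeros.
    """
    params = list(PARAMETERS)
    rows = []
    for (pid, sid), grp in normalized.groupby(["plate_id", "screen_id"], sort=True):
        if config.include_controls_in_stats:
            scored = grp[grp["qc_pass"]]
        else:
            scored = grp[~grp["treatment"].isin(CONTROL_TREATMENTS) & grp["qc_pass"]]
        if len(scored) < 3:
            raise PlateError(
                f"plate {pid} screen {sid}: fewer than 3 scored wells"
            )
        for p in params:
            loc, scale = _location_scale(scored[p].to_numpy(float), config)
            if scale == 0 or not np.isfinite(scale):
                raise PlateError(
                    f"plate {pid} screen {sid} parameter {p}: zero spread, "
                    "Z-scores undefined"
                )
            for _, well in grp.iterrows():
                rows.append(
                    {
                        "plate_id": pid,
                        "well_id": well["well_id"],
                        "gene": well["treatment"],
                        "screen_id": int(sid),
                        "parameter": p,
                        "value": float(well[p]),
                        "z": (float(well[p]) - loc) / scale,
                        "plate_mean": loc,
                        "plate_sd": scale,
                        "is_control": well["treatment"] in CONTROL_TREATMENTS,
                        "qc_pass": bool(well["qc_pass"]),
                    }
                )
    return pd.DataFrame(rows)


def score_screens(wells: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Convenience: normalize then Z-score a full multi-screen well table."""
    return zscore_plate(normalize_plate(wells, config), config)


def call_hits(ztable: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Apply the replicate hit rule gene by gene.

    For each gene and parameter, count screens with |z| >= threshold;
    with sign consistency required (default) the count is the larger of
    the all-positive and all-negative exceedance counts. A parameter is
    significant when that count reaches ``min_screens``; its direction is
    the shared sign. A gene is a hit when >= 1 parameter is significant.
    Genes observed in fewer than ``min_screens`` screens are returned
    with ``evaluable = False`` (never silently "not hit") and a warning.

    Returns one row per gene: per-parameter direction (+1/-1/0) and
    significant-screen counts, the overall hit flag, the phenotype class
    and the number of perturbed parameters.
    """
    lib = ztable[~ztable["is_control"] & ztable["qc_pass"]]
    rows = []
    n_dropped = 0
    for gene, grp in lib.groupby("gene", sort=True):
        piv = grp.pivot_table(index="screen_id", columns="parameter", values="z")
        n_screens_seen = piv.shape[0]
        evaluable = n_screens_seen >= config.min_screens
        if not evaluable:
            n_dropped += 1
        row: dict = {
            "gene": gene,
            "n_screens": int(n_screens_seen),
            "evaluable": evaluable,
        }
        n_sig = 0
        signs = []
        for p in PARAMETERS:
            z = piv[p].dropna().to_numpy(float) if p in piv else np.array([])
            n_pos = int(np.sum(z >= config.z_threshold))
            n_neg = int(np.sum(z <= -config.z_threshold))
            if config.require_sign_consistency:
                count = max(n_pos, n_neg)
                direction = 0
                if count >= config.min_screens:
                    direction = 1 if n_pos >= n_neg else -1
            else:
                count = n_pos + n_neg
                direction = 0
                if count >= config.min_screens:
                    direction = int(np.sign(np.sum(np.sign(z[np.abs(z) >= config.z_threshold]))))
            significant = evaluable and count >= config.min_screens
            if not significant:
                direction = 0
            row[f"direction_{p}"] = direction
            row[f"n_sig_screens_{p}"] = count
            row[f"significant_{p}"] = significant
            if significant:
                n_sig += 1
                signs.append(direction)
        row["n_parameters_perturbed"] = n_sig
        row["hit"] = evaluable and n_sig >= 1
        if not row["hit"]:
            row["phenotype_class"] = "none" if evaluable else "not_evaluable"
        elif all(s < 0 for s in signs):
            row["phenotype_class"] = "decreased_polarity"
        elif all(s > 0 for s in signs):
            row["phenotype_class"] = "increased_polarity"
        else:
            row["phenotype_class"] = "mixed"
        rows.append(row)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} gene(s) observed in fewer than "
            f"{config.min_screens} screens: reported not evaluable",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def summarize_screen(hits: pd.DataFrame) -> dict:
    """Counts and fractions of increased/decreased/mixed hits."""
    if hits.empty:
        raise ValueError("empty hit list")
    evaluable = hits[hits["evaluable"]]
    n = len(evaluable)
    counts = evaluable["phenotype_class"].value_counts().to_dict()
    n_dec = counts.get("decreased_polarity", 0)
    n_inc = counts.get("increased_polarity", 0)
    n_mix = counts.get("mixed", 0)
    n_hits = int(evaluable["hit"].sum())
    return {
        "n_genes": int(len(hits)),
        "n_evaluable": int(n),
        "n_hits": n_hits,
        "n_decreased": int(n_dec),
        "n_increased": int(n_inc),
        "n_mixed": int(n_mix),
        "fraction_hits": n_hits / n if n else 0.0,
        "fraction_decreased": n_dec / n if n else 0.0,
        "fraction_increased": n_inc / n if n else 0.0,
    }


def confusion_vs_truth(hits: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity/specificity of the hit calls against planted truth.

    Direction agreement is evaluated on recovered true hits whose planted
    effect has a net direction.
    """
    merged = hits.merge(truth, on="gene", how="inner", validate="1:1")
    merged = merged[merged["evaluable"]]
    tp = int(((merged["hit"]) & (merged["planted_hit"])).sum())
    fn = int((~merged["hit"] & merged["planted_hit"]).sum())
    fp = int((merged["hit"] & ~merged["planted_hit"]).sum())
    tn = int((~merged["hit"] & ~merged["planted_hit"]).sum())
    recovered = merged[merged["hit"] & merged["planted_hit"]]
    dir_map = {"decreased_polarity": -1, "increased_polarity": 1, "mixed": 0}
    n_dir = int(
        (
            recovered["phenotype_class"].map(dir_map)
            == recovered["planted_direction"]
        ).sum()
    )
    return {
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "direction_match_fraction": n_dir / len(recovered)
        if len(recovered)
        else float("nan"),
    }
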