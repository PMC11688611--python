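"""Plate normalization, Z-scores, and the 2-of-3 replicate hit rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from polarityscreen.morphometry import PARAMETERS
from polarityscreen.screenstats import (
    PlateError,
    ScreenConfig,
    call_hits,
    normalize_plate,
    score_screens,
    summarize_screen,
    zscore_plate,
)
from polarityscreen.synth import CONTROL_SIRNA


def wells_frame(values, treatments, plate="P01", screen=1):
    """Build a minimal wells table; `values` sets every parameter."""
    rows = []
    for i, (v, t) in enumerate(zip(values, treatments)):
        row = {
            "plate_id": plate,
            "well_id": f"A{i + 1:02d}",
            "screen_id": screen,
            "treatment": t,
            "n_cells": 50,
            "qc_pass": True,
        }
        row.update({p: float(v) for p in PARAMETERS})
        rows.append(row)
    return pd.DataFrame(rows)


class TestNormalization:
    def test_controls_map_to_mean_one(self):
        wells = wells_frame([2.0, 4.0, 5.0, 9.0], [CONTROL_SIRNA, CONTROL_SIRNA, "G1", "G2"])
        out = normalize_plate(wells, ScreenConfig())
        ctrl = out[out["treatment"] == CONTROL_SIRNA]
        assert ctrl[list(PARAMETERS)].mean().round(12).eq(1.0).all()

    def test_library_well_at_twice_control_mean_scores_two(self):
        wells = wells_frame([3.0, 3.0, 6.0], [CONTROL_SIRNA, CONTROL_SIRNA, "G1"])
        out = normalize_plate(wells, ScreenConfig())
        assert out.loc[out["treatment"] == "G1", "area"].iloc[0] == pytest.approx(2.0)

    def test_constant_plate_normalizes_to_ones(self):
        wells = wells_frame([5.0] * 6, [CONTROL_SIRNA] * 2 + ["G1", "G2", "G3", "G4"])
        out = normalize_plate(wells, ScreenConfig())
        assert np.allclose(out[list(PARAMETERS)].to_numpy(), 1.0)

    def test_no_usable_controls_is_plate_error(self):
        wells = wells_frame([1, 2, 3], ["G1", "G2", "G3"])
        with pytest.raises(PlateError, match="control"):
            normalize_plate(wells, ScreenConfig())

    def test_zero_control_mean_is_plate_error(self):
        wells = wells_frame([0.0, 0.0, 3.0], [CONTROL_SIRNA, CONTROL_SIRNA, "G1"])
        with pytest.raises(PlateError, match="zero"):
            normalize_plate(wells, ScreenConfig())


class TestZScores:
    def test_hand_computed_example(self):
        """Library values {1,2,3} with sample SD: the well at 3 scores 1."""
        wells = wells_frame(
            [1.0, 2.0, 3.0, 2.0],
            ["G1", "G2", "G3", CONTROL_SIRNA],
        )
        cfg = ScreenConfig(normalization="none")
        zt = zscore_plate(wells, cfg)
        sub = zt[(zt["parameter"] == "area")].set_index("gene")["z"]
        assert sub["G3"] == pytest.approx(1.0)
        assert sub["G2"] == pytest.approx(0.0)
        assert sub[CONTROL_SIRNA] == pytest.approx(0.0)  # scored vs library

    def test_population_sd_mode(self):
        wells = wells_frame([1.0, 2.0, 3.0], ["G1", "G2", "G3"])
        cfg = ScreenConfig(normalization="none", sd_mode="population")
        zt = zscore_plate(wells, cfg)
        sub = zt[zt["parameter"] == "area"].set_index("gene")["z"]
        assert sub["G3"] == pytest.approx(np.sqrt(3 / 2))

    def test_standardization_invariant(self, default_screen):
        """Scored z-values have mean 0 and SD 1 within every
        (plate, parameter, screen) group, to 1e-9."""
        zt = default_screen["ztable"]
        lib = zt[~zt["is_control"]]
        g = lib.groupby(["plate_id", "screen_id", "parameter"])["z"]
        assert np.abs(g.mean().to_numpy()).max() < 1e-9
        assert np.abs(g.std(ddof=1).to_numpy() - 1).max() < 1e-9

    def test_constant_plate_raises_not_silent_zeros(self):
        wells = wells_frame([2.0] * 5, ["G1", "G2", "G3", "G4", "G5"])
        with pytest.raises(PlateError, match="zero spread"):
            zscore_plate(wells, ScreenConfig(normalization="none"))

    @given(
        shift=hst.floats(-50, 50, allow_nan=False),
        scale=hst.floats(0.01, 100, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance_of_classical_z(self, shift, scale):
        rng = np.random.default_rng(7)
        base = 5 + rng.random(12)
        wells = wells_frame(base, [f"G{i}" for i in range(12)])
        cfg = ScreenConfig(normalization="none")
        z0 = zscore_plate(wells, cfg)["z"].to_numpy()
        wells2 = wells.copy()
        wells2[list(PARAMETERS)] = wells2[list(PARAMETERS)] * scale + shift
        z1 = zscore_plate(wells2, cfg)["z"].to_numpy()
        assert np.allclose(z0, z1, atol=1e-7)

    def test_robust_variant_uses_median_and_mad(self):
        vals = [1.0, 2.0, 3.0, 4.0, 100.0]
        wells = wells_frame(vals, [f"G{i}" for i in range(5)])
        cfg = ScreenConfig(normalization="none", z_variant="robust")
        zt = zscore_plate(wells, cfg)
        sub = zt[zt["parameter"] == "area"].set_index("gene")["z"]
        from scipy.stats import median_abs_deviation

        mad = median_abs_deviation(vals, scale="normal")
        assert sub["G2"] == pytest.approx(0.0)
        assert sub["G4"] == pytest.approx((100 - 3.0) / mad)


def ztable_from_zmatrix(zmat: dict) -> pd.DataFrame:
    """zmat: gene -> {param -> (z1, z2, z3)}; builds a minimal z table."""
    rows = []
    for gene, params in zmat.items():
        for p, zs in params.items():
            for s, z in enumerate(zs, start=1):
                rows.append(
                    {
                        "plate_id": "P01",
                        "well_id": "A01",
                        "gene": gene,
                        "screen_id": s,
                        "parameter": p,
                        "value": np.nan,
                        "z": z,
                        "plate_mean": 0.0,
                        "plate_sd": 1.0,
                        "is_control": False,
                        "qc_pass": True,
                    }
                )
    return pd.DataFrame(rows)


def full_zmat(z_by_param):
    return {p: z_by_param.get(p, (0.0, 0.0, 0.0)) for p in PARAMETERS}


class TestHitRule:
    def test_two_of_three_exceedance_is_significant(self):
        zt = ztable_from_zmatrix(
            {"G1": full_zmat({"area": (1.6, 1.7, 0.3)})}
        )
        hits = call_hits(zt, ScreenConfig())
        row = hits.iloc[0]
        assert row["hit"]
        assert row["direction_area"] == 1
        assert row["n_parameters_perturbed"] == 1
        assert row["phenotype_class"] == "increased_polarity"

    def test_opposite_signs_not_significant_under_consistency(self):
        zt = ztable_from_zmatrix(
            {"G1": full_zmat({"area": (1.6, -1.7, 0.3)})}
        )
        hits = call_hits(zt, ScreenConfig())
        assert not hits.iloc[0]["hit"]
        # without the consistency requirement the same gene is a hit
        hits2 = call_hits(zt, ScreenConfig(require_sign_consistency=False))
        assert hits2.iloc[0]["hit"]

    def test_all_five_negative_is_decreased_polarity(self):
        zt = ztable_from_zmatrix(
            {"G1": {p: (-2.0, -1.8, -2.5) for p in PARAMETERS}}
        )
        row = call_hits(zt, ScreenConfig()).iloc[0]
        assert row["phenotype_class"] == "decreased_polarity"
        assert row["n_parameters_perturbed"] == 5

    def test_mixed_directions_classified_mixed(self):
        zt = ztable_from_zmatrix(
            {"G1": full_zmat({"area": (2.0, 2.0, 0.0), "elongation_factor": (-2.0, -2.0, 0.0)})}
        )
        assert call_hits(zt, ScreenConfig()).iloc[0]["phenotype_class"] == "mixed"

    def test_gene_in_one_screen_not_evaluable(self):
        zt = ztable_from_zmatrix({"G1": {p: (1.9,) for p in PARAMETERS}})
        with pytest.warns(UserWarning, match="not evaluable"):
            hits = call_hits(zt, ScreenConfig())
        row = hits.iloc[0]
        assert not row["evaluable"]
        assert row["phenotype_class"] == "not_evaluable"
        assert not row["hit"]

    def test_threshold_monotonicity_hit_set_shrinks(self, default_screen):
        zt = default_screen["ztable"]
        prev = None
        for thr in (1.0, 1.5, 2.0, 3.0):
            cfg = ScreenConfig(z_threshold=thr)
            hits = call_hits(zt, cfg)
            hitset = set(hits.loc[hits["hit"], "gene"])
            if prev is not None:
                assert hitset <= prev
            prev = hitset

    def test_robust_and_classical_agree_on_clean_screens(self, default_screen):
        wells = default_screen["wells"]
        sets = {}
        for variant in ("classical", "robust"):
            cfg = ScreenConfig(z_variant=variant)
            hits = call_hits(score_screens(wells, cfg), cfg)
            sets[variant] = set(hits.loc[hits["hit"], "gene"])
        inter = len(sets["classical"] & sets["robust"])
        union = len(sets["classical"] | sets["robust"])
        assert inter / union >= 0.8


class TestSummary:
    def test_counts_and_fractions(self):
        zt = ztable_from_zmatrix(
            {
                "G1": {p: (-2.0, -2.0, -2.0) for p in PARAMETERS},
                "G2": {p: (-2.0, -2.0, -2.0) for p in PARAMETERS},
                **{f"N{i}": full_zmat({}) for i in range(8)},
            }
        )
        summary = summarize_screen(call_hits(zt, ScreenConfig()))
        assert summary["n_genes"] == 10
        assert summary["n_decreased"] == 2
        assert summary["fraction_decreased"] == pytest.approx(0.2)

    def test_zero_hits_all_counts_zero(self):
        zt = ztable_from_zmatrix({f"N{i}": full_zmat({}) for i in range(5)})
        summary = summarize_screen(call_hits(zt, ScreenConfig()))
        assert summary["n_hits"] == 0
        assert summary["fraction_hits"] == 0.0

    def test_summary_matches_truth_confusion_rows(self, default_screen):
        """On a planted screen the summary counts equal the confusion-table
        row sums recomputed independently from truth.csv."""
        from polarityscreen.screenstats import confusion_vs_truth

        cfg = default_screen["config"]
        hits = call_hits(default_screen["ztable"], cfg)
        summary = summarize_screen(hits)
        conf = confusion_vs_truth(hits, default_screen["truth"])
        assert summary["n_hits"] == conf["tp"] + conf["fp"]
        assert summary["n_evaluable"] - summary["n_hits"] == conf["tn"] + conf["fn"]
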