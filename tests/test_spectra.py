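"""Fraction-frozen curves, T50 and the Vali spectrum inversion."""

import numpy as np
import pandas as pd
import pytest

from icenuc import (
    AssayDesign,
    FractionFrozenCurve,
    FreezingAssay,
    SubpopulationMixture,
    expected_fraction,
    fraction_frozen,
    merge_dilution_series,
    sample_assay,
    t50,
    vali_nm,
)
from icenuc.errors import EmptySpectrumError, ExcludedPointError, NoT50Error


def make_assay(temps_per_dilution, design=None):
    rows = []
    for d, temps in enumerate(temps_per_dilution):
        for j, t in enumerate(temps):
            rows.append((d, j, t))
    design = design or AssayDesign(
        n_dilutions=len(temps_per_dilution),
        droplets_per_dilution=len(temps_per_dilution[0]),
    )
    return FreezingAssay(
        design=design,
        records=pd.DataFrame(rows, columns=["dilution_index", "droplet_id", "freeze_temp_C"]),
    )


class TestFractionFrozen:
    def test_all_unfrozen(self):
        assay = make_assay([[np.nan, np.nan]])
        curve = fraction_frozen(assay, np.array([-5.0, -10.0, -20.0]))
        assert np.all(curve.f_ice == 0.0)

    def test_direct_count(self):
        assay = make_assay([[-5.0, -10.0]])
        curve = fraction_frozen(assay, np.array([-7.0]))
        assert curve.f_ice[0, 0] == 0.5

    def test_matches_analytic_fraction_at_scale(self, clean_design):
        mixture = SubpopulationMixture(
            weights=[1.0], modes=[-6.5], spreads=[0.6], n_tot=1 / 3e-3
        )
        design = AssayDesign(
            n_dilutions=1,
            droplets_per_dilution=5000,
            background_enabled=False,
            temp_noise_sd=0.0,
        )
        assay = sample_assay(mixture, design, seed=21)
        T_grid = np.array([-5.55, -6.05, -6.55, -7.05])
        curve = fraction_frozen(assay, T_grid)
        for j, T in enumerate(T_grid):
            f_exp = expected_fraction(mixture, 1.0, T)
            se = np.sqrt(f_exp * (1 - f_exp) / 5000)
            assert abs(curve.f_ice[0, j] - f_exp) <= 3 * se

    def test_grid_validation(self):
        assay = make_assay([[-5.0, -10.0]])
        with pytest.raises(ValueError):
            fraction_frozen(assay, np.array([-10.0, -5.0]))  # ascending


class TestT50:
    def test_step_curve(self):
        grid = np.arange(-6.5, -8.01, -0.1)
        f = np.where(grid <= -7.1, 1.0, 0.0)
        curve = FractionFrozenCurve(T_grid=grid, f_ice=f[None, :], n_droplets=[10])
        assert t50(curve, 0) == pytest.approx(-7.1, abs=0.051)

    def test_symmetric_sigmoid_center(self):
        grid = np.arange(-5.0, -10.01, -0.1)
        f = 1 / (1 + np.exp((grid + 7.4) / 0.4))
        curve = FractionFrozenCurve(T_grid=grid, f_ice=f[None, :], n_droplets=[100])
        assert t50(curve, 0) == pytest.approx(-7.4, abs=1e-6)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        grid = np.arange(-4.0, -12.01, -0.1)
        for _ in range(25):
            f = np.minimum(np.cumsum(rng.random(grid.size)) / (0.35 * grid.size), 1.0)
            curve = FractionFrozenCurve(T_grid=grid, f_ice=f[None, :], n_droplets=[50])
            # brute force: first grid T with f >= 0.5, refined linearly
            i = int(np.argmax(f >= 0.5))
            if f[i] == 0.5 or i == 0:
                expect = grid[i]
            else:
                expect = grid[i - 1] + (0.5 - f[i - 1]) / (f[i] - f[i - 1]) * (
                    grid[i] - grid[i - 1]
                )
            assert t50(curve, 0) == pytest.approx(expect, abs=1e-12)

    def test_never_crossing_signals(self):
        grid = np.array([-5.0, -6.0, -7.0])
        curve = FractionFrozenCurve(
            T_grid=grid, f_ice=np.array([[0.0, 0.1, 0.2]]), n_droplets=[10]
        )
        with pytest.raises(NoT50Error):
            t50(curve, 0)


class TestValiNm:
    def test_zero_fraction(self):
        assert vali_nm(0.0, 3e-3, 1.0, 96) == (0.0, 0.0)

    def test_unit_log_point(self):
        # f = 1 - e^{-1}: -ln(1-f) = 1 exactly
        nm, _ = vali_nm(1 - np.exp(-1), 3e-3, 1.0, 96)
        assert nm == pytest.approx(333.3333, rel=1e-6)

    def test_propagated_sigma_at_half(self):
        # sigma_f = sqrt(0.25/96) = 0.0510310; / (0.5 * 0.003) = 34.0207
        _, sig = vali_nm(0.5, 3e-3, 1.0, 96)
        assert sig == pytest.approx(34.0207, rel=1e-4)

    def test_saturated_point_excluded(self):
        with pytest.raises(ExcludedPointError):
            vali_nm(1.0, 3e-3, 1.0, 96)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            vali_nm(-0.2, 3e-3, 1.0, 96)
        with pytest.raises(ValueError):
            vali_nm(1.2, 3e-3, 1.0, 96)

    def test_mass_conc_scaling_is_exact(self):
        nm1, s1 = vali_nm(0.4, 3e-3, 1.0, 96)
        nm2, s2 = vali_nm(0.4, 3e-3, 5.0, 96)
        assert nm1 == pytest.approx(5 * nm2, rel=1e-12)
        assert s1 == pytest.approx(5 * s2, rel=1e-12)


class TestMergeDilutionSeries:
    def test_single_dilution_passthrough(self):
        design = AssayDesign(n_dilutions=1, droplets_per_dilution=4)
        assay = make_assay([[-5.0, -6.0, -7.0, np.nan]], design)
        grid = np.array([-5.5, -6.5])
        spectrum = merge_dilution_series(fraction_frozen(assay, grid), design)
        for _, row in spectrum.points.iterrows():
            f = [0.25, 0.5][int(row["T_C"] == -6.5)]
            nm, sig = vali_nm(f, design.droplet_volume_ml, 1.0, 4)
            assert row["Nm_per_mg"] == pytest.approx(nm)
            assert row["sigma_Nm"] == pytest.approx(sig)

    def test_saturated_dilution_contributes_nothing(self):
        design = AssayDesign(n_dilutions=2, droplets_per_dilution=2)
        assay = make_assay([[-1.0, -1.0], [-5.0, np.nan]], design)
        spectrum = merge_dilution_series(
            fraction_frozen(assay, np.array([-4.0, -6.0])), design
        )
        assert set(spectrum.points["dilution_index"]) == {1}

    def test_empty_spectrum_signalled(self):
        design = AssayDesign(n_dilutions=1, droplets_per_dilution=2)
        assay = make_assay([[np.nan, np.nan]], design)
        with pytest.raises(EmptySpectrumError):
            merge_dilution_series(fraction_frozen(assay, np.array([-5.0])), design)

    def test_droplet_relabeling_invariance(self, three_mode_mixture, clean_design):
        assay = sample_assay(three_mode_mixture, clean_design, seed=3)
        shuffled = FreezingAssay(
            design=clean_design,
            records=assay.records.sample(frac=1.0, random_state=0).reset_index(
                drop=True
            ),
        )
        grid = np.arange(-4.0, -12.01, -0.1)
        a = merge_dilution_series(fraction_frozen(assay, grid), clean_design)
        b = merge_dilution_series(fraction_frozen(shuffled, grid), clean_design)
        pd.testing.assert_frame_equal(a.points, b.points)

    def test_adjacent_dilutions_estimate_same_spectrum(
        self, three_mode_mixture, clean_design
    ):
        """Overlapping-T N_m from adjacent dilutions agree within 2 combined sigma
        for >= 95% of overlap points (both estimate N_tot F_u(T))."""
        grid = np.arange(-4.0, -12.01, -0.1)
        agree = total = 0
        for seed in range(10):
            assay = sample_assay(three_mode_mixture, clean_design, seed=seed)
            spectrum = merge_dilution_series(fraction_frozen(assay, grid), clean_design)
            pts = spectrum.points
            conc = pts["dilution_index"].map(spectrum.mass_conc).to_numpy(float)
            f = 1 - np.exp(-pts["Nm_per_mg"].to_numpy() * 3e-3 * conc)
            pts = pts[(f >= 0.05) & (f <= 0.95)]
            for T, grp in pts.groupby("T_C"):
                if len(grp) < 2:
                    continue
                grp = grp.sort_values("dilution_index")
                for i in range(len(grp) - 1):
                    a, b = grp.iloc[i], grp.iloc[i + 1]
                    sig = np.hypot(a["sigma_Nm"], b["sigma_Nm"])
                    total += 1
                    agree += abs(a["Nm_per_mg"] - b["Nm_per_mg"]) <= 2 * sig
        assert total > 50
        assert agree / total >= 0.95

    def test_spectrum_tsv_round_trip(self, tmp_path, three_mode_mixture, clean_design):
        assay = sample_assay(three_mode_mixture, clean_design, seed=6)
        grid = np.arange(-4.0, -12.01, -0.1)
        spectrum = merge_dilution_series(fraction_frozen(assay, grid), clean_design)
        path = tmp_path / "spectrum.tsv"
        spectrum.to_tsv(path)
        back = type(spectrum).from_tsv(path)
        pd.testing.assert_frame_equal(
            spectrum.points.reset_index(drop=True), back.points, check_dtype=False
        )
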