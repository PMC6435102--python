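import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hpbrain.protocol import GAMMA_13C_HZ_PER_T
from hpbrain.spatial import (
    RATIO_COLUMNS,
    TissueProbabilityVolume,
    chemical_shift_displacement,
    compare_gray_white,
    make_binary_mask,
    metabolite_probability_maps,
    project_probability,
    ratio_maps,
    roi_summary,
    summed_maps_and_normalize,
)


class TestDisplacement:
    def test_hand_value_lactate_at_3t(self):
        """12 ppm at 3 T with a 3.6 mT/m gradient displaces by 10.0 mm."""
        delta_f = 12e-6 * GAMMA_13C_HZ_PER_T * 3.0  # ~385.5 Hz
        dz = chemical_shift_displacement(delta_f, GAMMA_13C_HZ_PER_T, 3.6e-3)
        assert dz == pytest.approx(0.0100, abs=1e-6)

    def test_sign_follows_frequency(self):
        assert chemical_shift_displacement(-100.0, GAMMA_13C_HZ_PER_T, 3.6e-3) < 0

    @settings(max_examples=50, derandomize=True)
    @given(f=st.floats(-1e3, 1e3), c=st.floats(-5, 5))
    def test_linearity_in_frequency(self, f, c):
        a = chemical_shift_displacement(f, GAMMA_13C_HZ_PER_T, 3.6e-3)
        b = chemical_shift_displacement(c * f, GAMMA_13C_HZ_PER_T, 3.6e-3)
        assert b == pytest.approx(c * a, rel=1e-12, abs=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chemical_shift_displacement(100.0, -1.0, 3.6e-3)
        with pytest.raises(ValueError):
            chemical_shift_displacement(100.0, GAMMA_13C_HZ_PER_T, 0.0)


def ramp_volume(nz=20, thin=0.005):
    """Probability rises linearly with slice index: p(iz) = iz / (nz - 1)."""
    ramp = (np.arange(nz) / (nz - 1))[:, None, None] * np.ones((1, 3, 3))
    return TissueProbabilityVolume(data={"gray": ramp},
                                   thin_slice_thickness=thin)


class TestProjection:
    def test_ramp_closed_form(self):
        vol = ramp_volume()
        # slab [0.02, 0.05) covers slices with centres 0.0225..0.0475,
        # i.e. indices 4..9; mean of iz/19 over 4..9 = 6.5/19
        proj = project_probability(vol, slab_center=0.035, slab_thickness=0.03)
        assert proj["gray"] == pytest.approx(np.full((3, 3), 6.5 / 19))

    def test_displacement_shifts_window(self):
        vol = ramp_volume()
        base = project_probability(vol, 0.035, 0.03)["gray"][0, 0]
        shifted = project_probability(vol, 0.035, 0.03,
                                      displacement=0.005)["gray"][0, 0]
        assert shifted == pytest.approx(base + 1 / 19)

    def test_outside_volume_raises(self):
        vol = ramp_volume()
        with pytest.raises(ValueError, match="outside"):
            project_probability(vol, 10.0, 0.03)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            TissueProbabilityVolume(data={"gray": np.full((4, 2, 2), 1.5)},
                                    thin_slice_thickness=0.005)

    def test_gray_plus_white_cap(self):
        g = np.full((4, 2, 2), 0.6)
        with pytest.raises(ValueError):
            TissueProbabilityVolume(data={"gray": g, "white": g},
                                    thin_slice_thickness=0.005)


def constant_maps(values_per_met, tissue="gray", shape=(2, 2)):
    return {f"met{i}": {tissue: np.full(shape, v)}
            for i, v in enumerate(values_per_met)}


class TestBinaryMask:
    def test_above_threshold_for_all_metabolites_included(self):
        mask = make_binary_mask(constant_maps([0.70, 0.65, 0.61]), 0.60)
        assert mask["gray"].all()

    def test_one_metabolite_below_excludes(self):
        mask = make_binary_mask(constant_maps([0.70, 0.59, 0.80]), 0.60)
        assert not mask["gray"].any()

    def test_threshold_is_strict(self):
        mask = make_binary_mask(constant_maps([0.60, 0.60, 0.60]), 0.60)
        assert not mask["gray"].any()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        maps = {"m0": {"gray": rng.uniform(size=(8, 8))},
                "m1": {"gray": rng.uniform(size=(8, 8))}}
        low = make_binary_mask(maps, 0.3)["gray"]
        high = make_binary_mask(maps, 0.7)["gray"]
        assert np.all(high <= low)  # raising the threshold never adds voxels

    @settings(max_examples=30, derandomize=True)
    @given(thr=st.floats(0.5, 0.99))
    def test_gray_white_disjoint_above_half(self, thr):
        rng = np.random.default_rng(1)
        gray = rng.uniform(size=(6, 6))
        white = np.clip(1 - gray - rng.uniform(0, 0.2, size=(6, 6)), 0, 1)
        maps = {"m0": {"gray": gray, "white": white}}
        mask = make_binary_mask(maps, thr)
        assert not np.any(mask["gray"] & mask["white"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            make_binary_mask({}, 0.6)


class DmiStub:
    def __init__(self, data, basis):
        self.data = data
        self.basis = basis


class TestNormalization:
    def make_dmi(self, basis, scale=1.0):
        rng = np.random.default_rng(2)
        data = scale * (rng.uniform(0.1, 1, size=(len(basis), 5, 6, 6))
                        + 1j * rng.uniform(0, 0.3, size=(len(basis), 5, 6, 6)))
        return DmiStub(data, basis)

    def test_peak_pyruvate_is_one(self, basis):
        dmi = self.make_dmi(basis)
        mask = np.ones((6, 6), dtype=bool)
        maps = summed_maps_and_normalize(dmi, mask)
        assert maps["pyruvate"].max() == pytest.approx(1.0)

    def test_scale_invariance(self, basis):
        mask = np.ones((6, 6), dtype=bool)
        a = summed_maps_and_normalize(self.make_dmi(basis, 1.0), mask)
        b = summed_maps_and_normalize(self.make_dmi(basis, 77.0), mask)
        for name in a:
            assert a[name] == pytest.approx(b[name], rel=1e-12)

    def test_empty_mask_raises(self, basis):
        dmi = self.make_dmi(basis)
        with pytest.raises(ValueError, match="empty"):
            summed_maps_and_normalize(dmi, np.zeros((6, 6), dtype=bool))


class TestRatioMaps:
    def test_algebraic_identity(self):
        rng = np.random.default_rng(3)
        totals = {name: rng.uniform(0.1, 1, size=(5, 5))
                  for name in ("pyruvate", "lactate", "bicarbonate")}
        r = ratio_maps(totals)
        assert np.abs(r["bic:pyr"] - r["bic:lac"] * r["lac:pyr"]).max() < 1e-12

    def test_zero_denominator_is_nan(self):
        totals = {"pyruvate": np.zeros((2, 2)), "lactate": np.ones((2, 2)),
                  "bicarbonate": np.ones((2, 2))}
        r = ratio_maps(totals)
        assert np.all(np.isnan(r["lac:pyr"]))
        assert np.all(np.isfinite(r["bic:lac"]))


class TestRoiSummary:
    def make_values(self, seed=0, shape=(6, 6)):
        rng = np.random.default_rng(seed)
        return {col: rng.uniform(size=shape) for col in RATIO_COLUMNS}

    def test_schema(self):
        vm = self.make_values()
        masks = {"brain": np.ones((6, 6), dtype=bool)}
        out = roi_summary(vm, masks)
        assert list(out.columns) == RATIO_COLUMNS
        assert out.index.names == ["roi", "stat"]
        assert set(out.index.get_level_values("stat")) == {"mean", "sd"}

    def test_nan_excluded(self):
        vm = self.make_values()
        vm["k_pl"][0, 0] = np.nan
        masks = {"brain": np.ones((6, 6), dtype=bool)}
        out = roi_summary(vm, masks)
        clean = vm["k_pl"][np.isfinite(vm["k_pl"])]
        assert out.loc[("brain", "mean"), "k_pl"] == pytest.approx(clean.mean())

    def test_pooled_across_datasets(self):
        vms = [self.make_values(0), self.make_values(1)]
        mask = np.ones((6, 6), dtype=bool)
        out = roi_summary(vms, {"brain": [mask, mask]})
        pooled = np.concatenate([vms[0]["k_pl"].ravel(), vms[1]["k_pl"].ravel()])
        assert out.loc[("brain", "mean"), "k_pl"] == pytest.approx(pooled.mean())

    def test_empty_roi_raises(self):
        vm = self.make_values()
        with pytest.raises(ValueError, match="empty"):
            roi_summary(vm, {"brain": np.zeros((6, 6), dtype=bool)})


class TestGrayWhiteComparison:
    def test_hand_enumerated_w_zero(self):
        """All 8 differences positive: W = 0, exact two-sided p = 2/2^8."""
        gray = np.array([5.0, 6, 7, 8, 9, 10, 11, 12])
        white = gray - np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        res = compare_gray_white(gray, white)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 2 ** 8)
        assert res.significant

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(4)
        gray = rng.normal(1.0, 0.1, size=10)
        white = gray - rng.uniform(0.05, 0.2, size=10)
        res1 = compare_gray_white(gray, white, n_comparisons=1)
        res5 = compare_gray_white(gray, white, n_comparisons=5)
        assert res5.p_adjusted == pytest.approx(min(1.0, res1.p_value * 5))

    def test_adjusted_p_capped_at_one(self):
        rng = np.random.default_rng(5)
        gray = rng.normal(size=10)
        white = gray + rng.normal(scale=1.0, size=10)
        res = compare_gray_white(gray, white, n_comparisons=1000)
        assert res.p_adjusted <= 1.0

    def test_all_zero_differences_degenerate(self):
        x = np.ones(8)
        res = compare_gray_white(x, x)
        assert res.degenerate and res.p_value == 1.0 and not res.significant

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            compare_gray_white(np.ones(4), np.ones(5))


class TestMetaboliteMaps:
    def test_per_metabolite_windows_differ(self):
        vol = ramp_volume()
        maps = metabolite_probability_maps(
            vol, 0.035, 0.03, {"pyruvate": 0.0, "lactate": 0.01})
        assert maps["lactate"]["gray"][0, 0] > maps["pyruvate"]["gray"][0, 0]
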