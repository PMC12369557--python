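"""Synthetic blended-spectra generator: mixing model, designs, shifts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirtransfer import (
    BrandDesign,
    DomainShift,
    default_four_brand_study,
    default_grid,
    make_component_library,
    sample_blend_design,
    synthesize_dataset,
)
from nirtransfer.simulate import ANALYTE, COMPONENTS, default_brand_designs

GRID = default_grid(10_000, 4_000, 16)  # coarse grid keeps unit tests fast


def idx_of(grid, w):
    return int(np.argmin(np.abs(grid - w)))


class TestComponentLibrary:
    def test_same_seed_identical(self):
        a = make_component_library(GRID, 7)
        b = make_component_library(GRID, 7)
        for name in a.endmembers:
            assert np.array_equal(a.endmembers[name], b.endmembers[name])
        assert np.array_equal(a.nuisance_modes, b.nuisance_modes)

    def test_peak_exceeds_trough_for_every_endmember(self):
        lib = make_component_library(GRID, 0, silk_variants={"v": 0.1})
        for name, spec in lib.endmembers.items():
            assert spec[idx_of(GRID, 5760)] > spec[idx_of(GRID, 6055)], name

    def test_zero_amplitudes_leave_baseline(self):
        lib = make_component_library(GRID, 0, amplitude_scale=0.0)
        for name, spec in lib.endmembers.items():
            baseline, _ = lib.band_params[name]
            assert np.allclose(spec, baseline)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            make_component_library(np.array([]), 0)

    def test_silk_variants_share_grid_and_differ_in_amplitude_only(self):
        lib = make_component_library(GRID, 0, silk_variants={"vx": 0.2})
        base_b, base_bands = lib.band_params[ANALYTE]
        var_b, var_bands = lib.band_params[f"{ANALYTE}@vx"]
        assert var_b == base_b
        assert [(c, w) for c, w, _ in var_bands] == [(c, w) for c, w, _ in base_bands]
        assert any(a1 != a2 for (_, _, a1), (_, _, a2) in zip(base_bands, var_bands))


class TestBlendDesign:
    def test_brand2_table_ranges_respected(self):
        design = BrandDesign(
            "#2", 199, {"tobacco_silk": (75, 100), "fermented_cut_stem": (0, 25)}
        )
        comps = sample_blend_design(design, seed=0)
        assert len(comps) == 199
        silk = np.array([c["tobacco_silk"] for c in comps])
        assert silk.min() >= 75 and silk.max() <= 100

    def test_single_component_design_forced(self):
        design = BrandDesign("x", 5, {"tobacco_silk": (100, 100)})
        for comp in sample_blend_design(design, seed=1):
            assert comp == {"tobacco_silk": 100.0}

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**16))
    def test_compositions_on_constrained_simplex(self, seed):
        design = default_brand_designs()["#1"]
        for comp in sample_blend_design(design, seed=seed):
            assert abs(sum(comp.values()) - 100.0) < 1e-9
            for c, value in comp.items():
                lo, hi = design.component_ranges[c]
                assert lo - 1e-9 <= value <= hi + 1e-9

    def test_infeasible_ranges_rejected(self):
        with pytest.raises(ValueError, match="[Ii]nfeasible"):
            BrandDesign("bad", 5, {"tobacco_silk": (10, 20), "cut_stem": (0, 10)})

    def test_design_without_analyte_rejected(self):
        with pytest.raises(ValueError, match="analyte"):
            BrandDesign("bad", 5, {"cut_stem": (0, 100)})


class TestSynthesize:
    def test_pure_endmember_recovered_exactly(self):
        lib = make_component_library(GRID, 3, n_nuisance_modes=0)
        design = BrandDesign("x", 4, {"tobacco_silk": (100, 100)})
        ds = synthesize_dataset(lib, design, DomainShift.identity(), seed=0)
        assert np.allclose(ds.absorbance, lib.endmembers["tobacco_silk"], atol=1e-12)
        assert np.all(ds.target == 100.0)

    def test_fifty_fifty_blend_is_pointwise_mean(self):
        lib = make_component_library(GRID, 3, n_nuisance_modes=0)
        design = BrandDesign("x", 3, {"tobacco_silk": (50, 50), "cut_stem": (50, 50)})
        ds = synthesize_dataset(lib, design, DomainShift.identity(), seed=0)
        expected = 0.5 * (lib.endmembers["tobacco_silk"] + lib.endmembers["cut_stem"])
        assert np.allclose(ds.absorbance, expected, atol=1e-12)

    def test_noise_seed_changes_spectra_not_targets(self):
        lib = make_component_library(GRID, 3)
        design = default_brand_designs(distinct_silk=False)["#2"]
        shift = DomainShift(noise_sd=1e-3)
        a = synthesize_dataset(lib, design, shift, seed=1)
        b = synthesize_dataset(lib, design, shift, seed=2)
        assert not np.array_equal(a.absorbance, b.absorbance)
        assert np.array_equal(a.target, b.target)

    def test_missing_component_rejected(self):
        lib = make_component_library(GRID, 3)
        design = BrandDesign("x", 2, {"tobacco_silk": (50, 100), "mystery": (0, 50)})
        with pytest.raises(KeyError, match="mystery"):
            synthesize_dataset(lib, design, DomainShift.identity(), seed=0)

    def test_shift_applies_offset_tilt_gain(self):
        lib = make_component_library(GRID, 3, n_nuisance_modes=0)
        design = BrandDesign("x", 2, {"tobacco_silk": (100, 100)})
        shift = DomainShift(additive_offset=0.2, slope=1e-4, multiplicative_gain=1.5)
        ds = synthesize_dataset(lib, design, shift, seed=0)
        expected = 1.5 * lib.endmembers["tobacco_silk"] + 0.2 + 1e-4 * (GRID - GRID.mean())
        assert np.allclose(ds.absorbance[0], expected, atol=1e-12)

    def test_noiseless_matrix_is_low_rank(self):
        # pure Beer-Lambert mixing: rank <= #endmembers used; offset and
        # tilt add at most two more directions
        lib = make_component_library(GRID, 5, n_nuisance_modes=0)
        design = default_brand_designs(distinct_silk=False)["#1"]  # 4 components
        ds = synthesize_dataset(
            lib, design, DomainShift(additive_offset=0.1, slope=1e-4), seed=0
        )
        s = np.linalg.svd(ds.absorbance, compute_uv=False)
        assert s[6] < 1e-8 * s[0]


class TestDefaultStudy:
    def test_brand_sizes_and_ranges(self, default_study):
        sizes = {b: len(ds) for b, ds in default_study.items()}
        assert sizes == {"#1": 210, "#2": 199, "#3": 200, "#4": 183}
        designs = default_brand_designs()
        for brand, ds in default_study.items():
            lo, hi = designs[brand].component_ranges[ANALYTE]
            assert ds.target.min() >= lo and ds.target.max() <= hi
            assert set(ds.brand.tolist()) == {brand}

    def test_similar_pair_closer_than_divergent_pair(self, default_study):
        means = {b: ds.absorbance.mean(axis=0) for b, ds in default_study.items()}
        d23 = np.linalg.norm(means["#2"] - means["#3"])
        d14 = np.linalg.norm(means["#1"] - means["#4"])
        assert d23 < d14

    def test_bit_reproducible(self):
        grid = default_grid(10_000, 4_000, 40)
        a = default_four_brand_study(11, grid=grid)
        b = default_four_brand_study(11, grid=grid)
        for brand in a:
            assert np.array_equal(a[brand].absorbance, b[brand].absorbance)
            assert np.array_equal(a[brand].target, b[brand].target)
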