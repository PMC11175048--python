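"""Processing-chain exactness: screening statistic, unit conversion,
resampling, absorbance, smoothing, SNV, and the fixed stage order."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moistspec import (
    SpectraSet,
    SyntheticConfig,
    average_replicates,
    generate_dataset,
    preprocess_pipeline,
    resample,
    savitzky_golay,
    screen_replicates,
    snv,
    to_absorbance,
    wavenumber_to_wavelength,
)
from moistspec.exceptions import DegenerateInputError
from moistspec.preprocess import PreprocessParams, replicate_spread_statistic

from .oracles import natural_cubic_spline, sd_of_sds, sliding_polyfit


def _set(values, grid=None, **kw):
    values = np.atleast_2d(values)
    grid = np.arange(values.shape[1], dtype=float) if grid is None else grid
    kw.setdefault("ids", [f"r{i}" for i in range(values.shape[0])])
    return SpectraSet(grid=grid, values=values, **kw)


class TestReplicateScreen:
    def test_identical_replicates_have_zero_spread(self):
        row = np.linspace(0.2, 0.8, 50)
        assert replicate_spread_statistic(np.vstack([row] * 3)) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_uniform_offset_is_invisible(self):
        row = np.linspace(0.2, 0.8, 50)
        bundle = np.vstack([row, row + 0.3, row - 0.1])
        assert replicate_spread_statistic(bundle) == pytest.approx(0.0, abs=1e-15)

    def test_matches_two_pass_oracle(self, rng):
        bundle = np.full((3, 40), 0.5)
        bundle[2, :20] += 0.2  # half-grid bump
        assert replicate_spread_statistic(bundle) == pytest.approx(
            sd_of_sds(bundle), abs=1e-14
        )
        random_bundle = rng.uniform(0.1, 0.9, size=(5, 60))
        assert replicate_spread_statistic(random_bundle) == pytest.approx(
            sd_of_sds(random_bundle), abs=1e-14
        )

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            replicate_spread_statistic(np.ones((1, 10)))

    def test_quiet_bundle_fully_kept(self):
        bundle = np.vstack([np.linspace(0.2, 0.8, 50)] * 4) + 1e-4
        kept, log = screen_replicates(bundle)
        assert len(kept) == 4 and log == []

    def test_injected_bump_replicate_removed(self):
        grid = np.arange(100)
        base = np.full(100, 0.5)
        bundle = np.vstack([base, base, base + 1e-4])
        bundle = np.vstack([bundle, base + 0.2 * np.exp(-0.5 * ((grid - 50) / 5) ** 2)])
        kept, log = screen_replicates(bundle)
        assert 3 not in kept
        assert [e["removed_replicate"] for e in log] == [3]

    def test_floor_of_two_with_warning(self):
        rng = np.random.default_rng(0)
        bundle = rng.uniform(0, 1, size=(3, 50))  # mutually spiky
        with pytest.warns(UserWarning):
            kept, _ = screen_replicates(bundle)
        assert len(kept) == 2


class TestAveraging:
    def test_single_replicate_identity(self):
        row = np.linspace(0.1, 0.9, 20)
        assert np.array_equal(average_replicates(row[None, :]), row)

    def test_known_mean(self):
        out = average_replicates(np.vstack([np.full(10, 0.2), np.full(10, 0.4)]))
        assert np.allclose(out, 0.3)

    def test_matches_columnwise_oracle(self, rng):
        bundle = rng.uniform(0.1, 0.9, size=(4, 30))
        oracle = np.array([bundle[:, j].sum() / 4 for j in range(30)])
        assert np.allclose(average_replicates(bundle), oracle, atol=1e-14)


class TestUnitConversion:
    def test_known_values(self):
        s = _set([[0.5, 0.6]], grid=np.array([4000.0, 7407.4]), xunit="cm-1")
        out = wavenumber_to_wavelength(s)
        assert out.grid[-1] == pytest.approx(2500.0)
        assert out.grid[0] == pytest.approx(1350.0, abs=0.01)
        # values follow their grid points through the re-sort
        assert out.values[0, 0] == 0.6 and out.values[0, -1] == 0.5

    def test_round_trip(self):
        nu = np.linspace(4000, 7400, 30)
        s = _set(np.full((1, 30), 0.5), grid=nu, xunit="cm-1")
        lam_set = wavenumber_to_wavelength(s)
        assert np.allclose(np.sort(1e7 / lam_set.grid), nu, rtol=1e-9)

    def test_rejects_nonpositive_wavenumbers(self):
        s = _set([[0.5, 0.6]], grid=np.array([1.0, 2.0]), xunit="nm")
        with pytest.raises(ValueError):
            wavenumber_to_wavelength(s)


class TestResample:
    def test_identity_on_source_grid(self, rng):
        grid = np.linspace(1000, 2000, 40)
        s = _set(rng.uniform(0.2, 0.8, size=(3, 40)), grid=grid)
        out = resample(s, grid)
        assert np.allclose(out.values, s.values, atol=1e-10)

    def test_linear_spectra_reproduced_exactly(self):
        grid = np.linspace(1000, 2000, 20)
        s = _set((0.0001 * grid + 0.1)[None, :], grid=grid)
        target = np.linspace(1003, 1997, 77)
        out = resample(s, target)
        assert np.allclose(out.values[0], 0.0001 * target + 0.1, atol=1e-10)

    def test_matches_natural_spline_oracle(self, rng):
        grid = np.linspace(1000, 2000, 30)
        smooth = 0.5 + 0.2 * np.sin(grid / 150) + 0.05 * np.cos(grid / 80)
        s = _set(smooth[None, :], grid=grid)
        mid = (grid[:-1] + grid[1:]) / 2
        out = resample(s, mid)
        assert np.allclose(out.values[0], natural_cubic_spline(grid, smooth, mid), atol=1e-8)

    def test_extrapolation_rejected(self):
        grid = np.linspace(1000, 2000, 10)
        s = _set(np.full((1, 10), 0.5), grid=grid)
        with pytest.raises(ValueError):
            resample(s, np.array([900.0, 1500.0]))


class TestAbsorbance:
    @pytest.mark.parametrize(
        "refl, absorb", [(1.0, 0.0), (0.1, 1.0), (0.5, 0.30103)]
    )
    def test_known_values(self, refl, absorb):
        s = _set(np.full((1, 2), refl))
        assert to_absorbance(s).values[0, 0] == pytest.approx(absorb, abs=1e-4)

    def test_unit_flag_flips(self):
        s = _set(np.full((1, 3), 0.5))
        out = to_absorbance(s)
        assert out.yunit == "absorbance"
        with pytest.raises(ValueError):
            to_absorbance(out)


class TestSavitzkyGolay:
    def test_polynomials_pass_through(self):
        grid = np.arange(100, dtype=float)
        params = PreprocessParams(sg_window=11, sg_polyorder=2)
        for poly in (0.2 + 0.001 * grid, 0.1 + 0.002 * grid + 1e-5 * grid**2):
            s = _set(poly[None, :], grid=grid, yunit="absorbance")
            out = savitzky_golay(s, params)
            assert np.allclose(out.values[0], poly, atol=1e-10)

    def test_matches_sliding_polyfit_oracle(self, rng):
        grid = np.arange(80, dtype=float)
        y = rng.normal(0.5, 0.1, size=80)
        s = _set(y[None, :], grid=grid, yunit="absorbance")
        params = PreprocessParams(sg_window=9, sg_polyorder=3)
        out = savitzky_golay(s, params)
        oracle = sliding_polyfit(y, 9, 3)
        interior = slice(4, -4)
        assert np.allclose(out.values[0][interior], oracle[interior], atol=1e-10)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            PreprocessParams(sg_window=10)


class TestSNV:
    def test_hand_computed_row(self):
        s = _set(np.array([[1.0, 2.0, 3.0]]), yunit="absorbance")
        assert np.allclose(snv(s).values[0], [-1.0, 0.0, 1.0], atol=1e-14)

    def test_idempotent(self, rng):
        s = _set(rng.normal(0.5, 0.2, size=(4, 30)), yunit="absorbance")
        once = snv(s)
        twice = snv(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_constant_row_names_sample(self):
        s = SpectraSet(
            ids=["good", "flat"],
            grid=np.arange(5.0),
            values=np.vstack([np.arange(5.0), np.full(5, 2.0)]),
            yunit="absorbance",
        )
        with pytest.raises(DegenerateInputError, match="flat"):
            snv(s)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(-10, 10), min_size=8, max_size=8),
            min_size=1,
            max_size=5,
        )
    )
    def test_normalization_property(self, rows):
        values = np.asarray(rows)
        if np.any(values.std(axis=1, ddof=1) < 1e-6):
            return
        s = _set(values, yunit="absorbance")
        out = snv(s).values
        assert np.all(np.abs(out.mean(axis=1)) < 1e-10)
        assert np.all(np.abs(out.std(axis=1, ddof=1) - 1) < 1e-10)


class TestPipeline:
    def test_full_range_shape_contract(self, small_config):
        raw, _ = generate_dataset(small_config, "full_range")
        processed, log = preprocess_pipeline(raw.select(treatment="lab_sieved"))
        assert processed.n_spectra == small_config.n_samples
        assert processed.yunit == "absorbance"
        stages = [e["stage"] for e in log]
        assert stages == ["screen_and_average", "to_absorbance", "savitzky_golay", "snv"]

    def test_short_range_lands_on_2nm_grid(self, small_config):
        raw, _ = generate_dataset(small_config, "short_range")
        processed, log = preprocess_pipeline(raw.select(treatment="lab_fine"))
        stages = [e["stage"] for e in log]
        assert stages == [
            "screen_and_average",
            "wavenumber_to_wavelength",
            "resample",
            "to_absorbance",
            "savitzky_golay",
            "snv",
        ]
        assert processed.xunit == "nm"
        assert np.allclose(np.diff(processed.grid), 2.0)
        assert processed.grid[0] <= 1356 and processed.grid[-1] >= 2490

    def test_duplicate_replicates_collapse_identically(self, quiet_config):
        raw, _ = generate_dataset(quiet_config, "full_range")
        sieved = raw.select(treatment="lab_sieved")
        processed, _ = preprocess_pipeline(sieved)
        # noise-free duplicates of the same sample average to themselves
        single = sieved._take(np.flatnonzero(sieved.replicate == 0))
        processed_single, _ = preprocess_pipeline(single)
        assert np.allclose(processed.values, processed_single.values, atol=1e-12)

    def test_snv_normalization_holds_end_to_end(self, small_processed):
        processed, _ = small_processed
        for spectra in processed.values():
            assert np.all(np.abs(spectra.values.mean(axis=1)) < 1e-10)
            assert np.all(np.abs(spectra.values.std(axis=1, ddof=1) - 1) < 1e-10)

    def test_swapping_snv_and_smoothing_changes_output(self, rng):
        grid = np.arange(60, dtype=float)
        s = _set(rng.uniform(0.2, 0.8, size=(2, 60)), grid=grid, yunit="absorbance")
        params = PreprocessParams(sg_window=9, sg_polyorder=2)
        canonical = snv(savitzky_golay(s, params))
        swapped = savitzky_golay(snv(s), params)
        assert not np.allclose(canonical.values, swapped.values, atol=1e-6)

    def test_pure_function(self, small_config):
        raw, _ = generate_dataset(small_config, "full_range")
        a, _ = preprocess_pipeline(raw.select(treatment="field_moist"))
        b, _ = preprocess_pipeline(raw.select(treatment="field_moist"))
        assert np.array_equal(a.values, b.values)
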