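"""Dataset I/O, background subtraction, chirp correction, and merging."""

import numpy as np
import pytest

from porcycle.errors import (
    FormatError,
    IllConditionedScaleError,
    PreconditionError,
)
from porcycle.schemes import InstrumentResponse
from porcycle.synthetic import NoiseSpec, preset_pair, simulate_ta_pair
from porcycle.ta_preprocess import (
    ChirpModel,
    TASpectraSet,
    apply_chirp,
    correct_chirp,
    merge_fast_slow,
    read_ta_matrix,
    subtract_background,
    write_ta_matrix,
)


def toy_dataset() -> TASpectraSet:
    return TASpectraSet(
        wavelengths=np.array([500.0, 600.0, 700.0]),
        times=np.array([1e-12, 2e-12, 4e-12]),
        delta_A=np.arange(9, dtype=float).reshape(3, 3) - 4.0,
    )


def static_bleach(times, wavelengths, tag, irf_sigma) -> TASpectraSet:
    """Time-independent bleach profile: ideal for scale-factor identities."""
    band = -10.0 * np.exp(-0.5 * ((wavelengths - 642.0) / 12.0) ** 2)
    return TASpectraSet(
        wavelengths=wavelengths,
        times=times,
        delta_A=np.tile(band, (times.size, 1)),
        instrument_tag=tag,
        irf=InstrumentResponse(0.0, irf_sigma),
    )


class TestDialectIO:
    def test_time_rows_roundtrip_exact(self, tmp_path):
        ds = toy_dataset()
        p = tmp_path / "toy.tsv"
        write_ta_matrix(ds, p)
        back = read_ta_matrix(p, "time-rows")
        np.testing.assert_array_equal(back.delta_A, ds.delta_A)
        np.testing.assert_array_equal(back.times, ds.times)
        np.testing.assert_array_equal(back.wavelengths, ds.wavelengths)

    def test_time_columns_equals_time_rows(self, tmp_path):
        ds = toy_dataset()
        p = tmp_path / "cols.tsv"
        with open(p, "w") as fh:
            fh.write("\t" + "\t".join(f"{t:.17g}" for t in ds.times) + "\n")
            for j, w in enumerate(ds.wavelengths):
                fh.write(f"{w:.17g}\t" + "\t".join(f"{v:.17g}" for v in ds.delta_A[:, j]) + "\n")
        back = read_ta_matrix(p, "time-columns")
        np.testing.assert_array_equal(back.delta_A, ds.delta_A)
        np.testing.assert_array_equal(back.times, ds.times)

    def test_time_unit_header_conversion(self, tmp_path):
        p = tmp_path / "ps.tsv"
        with open(p, "w") as fh:
            fh.write("# units: time=ps wavelength=nm\n")
            fh.write("\t500\t600\n1\t0.1\t0.2\n2\t0.3\t0.4\n")
        ds = read_ta_matrix(p)
        np.testing.assert_allclose(ds.times, [1e-12, 2e-12])

    def test_duplicate_wavelength_is_format_error(self, tmp_path):
        p = tmp_path / "dup.tsv"
        with open(p, "w") as fh:
            fh.write("\t500\t500\t700\n1\t0\t0\t0\n2\t1\t1\t1\n")
        with pytest.raises(FormatError):
            read_ta_matrix(p)

    def test_ragged_row_is_format_error(self, tmp_path):
        p = tmp_path / "ragged.tsv"
        with open(p, "w") as fh:
            fh.write("\t500\t600\n1\t0\t0\n2\t1\n")
        with pytest.raises(FormatError, match="row 3"):
            read_ta_matrix(p)

    def test_non_numeric_cell_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        with open(p, "w") as fh:
            fh.write("\t500\t600\n1\t0\tx\n2\t1\t1\n")
        with pytest.raises(FormatError):
            read_ta_matrix(p)


class TestBackgroundSubtraction:
    def make(self, offset_per_wavelength):
        t = np.concatenate([np.linspace(-5e-12, -1e-12, 5), np.geomspace(1e-12, 1e-9, 40)])
        w = np.linspace(475, 725, 16)
        signal = 5.0 * np.exp(-np.maximum(t, 0)[:, None] / 1e-10) * np.exp(
            -0.5 * ((w[None, :] - 642) / 12.0) ** 2
        )
        signal[t < 0] = 0.0
        return TASpectraSet(w, t, signal + np.asarray(offset_per_wavelength)[None, :])

    def test_clean_data_unchanged(self):
        ds = self.make(np.zeros(16))
        out = subtract_background(ds, -0.5e-12)
        assert np.abs(out.delta_A - ds.delta_A).max() < 1e-12

    def test_constant_offset_removed_exactly(self):
        ds = self.make(np.full(16, 0.5))
        out = subtract_background(ds, -0.5e-12)
        pre = out.delta_A[out.times < -0.5e-12]
        assert np.abs(pre.mean(axis=0)).max() < 1e-12

    def test_seeded_per_wavelength_offsets_recovered(self):
        rng = np.random.default_rng(5)
        offsets = rng.normal(0.0, 0.3, 16)
        clean = self.make(np.zeros(16))
        dirty = self.make(offsets)
        out = subtract_background(dirty, -0.5e-12)
        recovered = dirty.delta_A - out.delta_A
        assert np.abs(recovered[0] - offsets).max() < 1e-9
        assert np.abs(out.delta_A - clean.delta_A).max() < 1e-9

    def test_too_few_pre_excitation_points(self):
        ds = toy_dataset()
        with pytest.raises(PreconditionError):
            subtract_background(ds, 1.5e-12)

    def test_non_destructive_and_one_provenance_entry(self):
        ds = self.make(np.full(16, 1.0))
        before = ds.delta_A.copy()
        n_log = len(ds.provenance_log)
        out = subtract_background(ds, -0.5e-12)
        np.testing.assert_array_equal(ds.delta_A, before)
        assert len(out.provenance_log) == n_log + 1


class TestChirp:
    def smooth(self):
        t = np.linspace(-1e-12, 9e-12, 101)  # 0.1 ps grid
        w = np.linspace(475, 725, 26)
        sig = 7.0 * (1 - np.exp(-np.maximum(t, 0)[:, None] / 2e-12)) * np.exp(
            -0.5 * ((w[None, :] - 600) / 60.0) ** 2
        )
        return TASpectraSet(w, t, sig)

    def test_zero_chirp_is_identity(self):
        ds = self.smooth()
        out = correct_chirp(ds, ChirpModel((0.0,), 600.0))
        assert np.abs(out.delta_A - ds.delta_A).max() < 1e-10

    def test_inject_then_correct_recovers_within_2_percent(self):
        ds = self.smooth()
        chirp = ChirpModel((0.0, 2e-15, 1e-17), 600.0)
        back = correct_chirp(apply_chirp(ds, chirp), chirp)
        assert np.abs(back.delta_A - ds.delta_A).max() < 0.02 * np.abs(ds.delta_A).max()

    def test_linear_chirp_shifts_single_column_by_analytic_amount(self):
        ds = self.smooth()
        per_nm = 0.1e-12 / 100.0  # 0.1 ps per 100 nm
        chirp = ChirpModel((0.0, per_nm), 600.0)
        shifted = apply_chirp(ds, chirp)
        j = int(np.argmin(np.abs(ds.wavelengths - 695)))
        dt = per_nm * (ds.wavelengths[j] - 600.0)
        # compare to the signal evaluated at t - dt analytically
        t = ds.times
        expected = 7.0 * (1 - np.exp(-np.maximum(t - dt, 0) / 2e-12)) * np.exp(
            -0.5 * ((ds.wavelengths[j] - 600) / 60.0) ** 2
        )
        interior = (t - dt >= t[0]) & (t - dt <= t[-1])
        assert np.abs(shifted.delta_A[interior, j] - expected[interior]).max() < 0.005 * np.abs(
            ds.delta_A
        ).max()

    def test_oversized_shift_rejected(self):
        ds = self.smooth()
        with pytest.raises(PreconditionError):
            correct_chirp(ds, ChirpModel((1e-9,), 600.0))


class TestMergeFastSlow:
    def grids(self):
        w = np.linspace(475, 725, 20)
        tf = np.geomspace(1e-12, 2.6e-9, 50)
        ts = np.geomspace(0.5e-9, 2e-6, 40)
        return w, tf, ts

    def test_identity_scale(self):
        w, tf, ts = self.grids()
        fast = static_bleach(tf, w, "fast", 0.2e-12)
        slow = static_bleach(ts, w, "slow", 0.5e-9)
        merged = merge_fast_slow(fast, slow)
        assert merged.metadata["merge_scale"] == pytest.approx(1.0, abs=1e-9)

    def test_halved_slow_gives_scale_two(self):
        w, tf, ts = self.grids()
        fast = static_bleach(tf, w, "fast", 0.2e-12)
        slow = static_bleach(ts, w, "slow", 0.5e-9)
        slow.delta_A *= 0.5
        merged = merge_fast_slow(fast, slow)
        assert merged.metadata["merge_scale"] == pytest.approx(2.0, abs=1e-6)

    def test_merged_axis_strictly_increasing_and_irf_carried(self):
        scheme, spectra = preset_pair("wildtype_branched")
        fast, slow = simulate_ta_pair(scheme, spectra, noise=NoiseSpec(0.01, 1, relative=True))
        merged = merge_fast_slow(fast, slow)
        assert np.all(np.diff(merged.times) > 0)
        assert merged.irf_sigma_per_time is not None
        assert merged.irf_sigma_per_time[0] == pytest.approx(0.2e-12)
        assert merged.irf_sigma_per_time[-1] == pytest.approx(0.5e-9)

    def test_merge_is_idempotent_in_scale(self):
        scheme, spectra = preset_pair("wildtype_branched")
        fast, slow = simulate_ta_pair(scheme, spectra, noise=NoiseSpec(0.01, 2, relative=True))
        s1 = merge_fast_slow(fast, slow).metadata["merge_scale"]
        slow2 = slow.copy()
        slow2.delta_A *= s1
        s2 = merge_fast_slow(fast, slow2).metadata["merge_scale"]
        assert s2 == pytest.approx(1.0, abs=1e-6)

    def test_zero_signal_is_ill_conditioned(self):
        w, tf, ts = self.grids()
        fast = static_bleach(tf, w, "fast", 0.2e-12)
        slow = static_bleach(ts, w, "slow", 0.5e-9)
        fast.delta_A[:] = 0.0
        slow.delta_A[:] = 0.0
        with pytest.raises(IllConditionedScaleError):
            merge_fast_slow(fast, slow)

    def test_empty_overlap_rejected(self):
        w, tf, ts = self.grids()
        fast = static_bleach(tf, w, "fast", 0.2e-12)
        slow = static_bleach(ts, w, "slow", 0.5e-9)
        with pytest.raises(PreconditionError):
            merge_fast_slow(fast, slow, overlap_window=(3e-6, 4e-6))
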