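"""Time-resolved difference-absorbance matrices and their preconditioning.

The on-disk dialect is delimited text: comment lines start with ``#``
(``# units: time=<ps|ns|us|s> wavelength=nm`` declares the time unit,
``# truth: {...}`` may carry generator ground truth as JSON), then a header
row whose first cell is blank followed by the wavelengths in nm, then one
row per time point (time-rows orientation).  The transposed orientation
(first row times, first column wavelengths) is also accepted.

All preprocessing operations are non-destructive: they return a new
:class:`TASpectraSet` and append exactly one provenance entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import (
    FormatError,
    IllConditionedScaleError,
    InvalidParameterError,
    PreconditionError,
)
from .schemes import InstrumentResponse

__all__ = [
    "TASpectraSet",
    "ChirpModel",
    "read_ta_matrix",
    "write_ta_matrix",
    "subtract_background",
    "apply_chirp",
    "correct_chirp",
    "merge_fast_slow",
]

_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9, "ps": 1e-12, "fs": 1e-15}


@dataclass
class TASpectraSet:
    """A difference-absorbance matrix dA(t, lambda) in mAbs.

    ``times`` are seconds (strictly increasing, may include pre-excitation
    points < t0), ``wavelengths`` are nm (strictly increasing).
    ``irf_sigma_per_time`` holds a per-time-point IRF width after merging
    datasets with different time resolution.
    """

    wavelengths: np.ndarray
    times: np.ndarray
    delta_A: np.ndarray
    instrument_tag: str = "fast"
    irf: InstrumentResponse | None = None
    irf_sigma_per_time: np.ndarray | None = None
    provenance_log: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.delta_A.shape != (self.times.size, self.wavelengths.size):
            raise InvalidParameterError(
                f"matrix shape {self.delta_A.shape} does not match axes "
                f"({self.times.size} times, {self.wavelengths.size} wavelengths)"
            )
        for name, ax in (("times", self.times), ("wavelengths", self.wavelengths)):
            if not np.all(np.isfinite(ax)):
                raise InvalidParameterError(f"{name} must be finite")
            if ax.size > 1 and np.any(np.diff(ax) <= 0):
                raise InvalidParameterError(f"{name} must be strictly increasing")
        if not np.all(np.isfinite(self.delta_A)):
            raise InvalidParameterError("delta_A must be finite")
        if self.irf_sigma_per_time is not None:
            self.irf_sigma_per_time = np.asarray(self.irf_sigma_per_time, dtype=float)
            if self.irf_sigma_per_time.shape != self.times.shape:
                raise InvalidParameterError("irf_sigma_per_time must match times")

    def copy(self) -> "TASpectraSet":
        return replace(
            self,
            wavelengths=self.wavelengths.copy(),
            times=self.times.copy(),
            delta_A=self.delta_A.copy(),
            irf_sigma_per_time=None
            if self.irf_sigma_per_time is None
            else self.irf_sigma_per_time.copy(),
            provenance_log=list(self.provenance_log),
            metadata=dict(self.metadata),
        )

    @property
    def peak_abs(self) -> float:
        return float(np.abs(self.delta_A).max(initial=0.0))


@dataclass(frozen=True)
class ChirpModel:
    """Per-wavelength time-zero shift: a polynomial in (lambda - lambda_ref).

    ``coefficients`` are ascending powers (constant first), in seconds per
    nm^k.  The identity model has all-zero coefficients.
    """

    coefficients: tuple[float, ...] = (0.0,)
    reference_wavelength: float = 600.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(c) for c in self.coefficients):
            raise InvalidParameterError("chirp coefficients must be finite")

    def shift(self, wavelengths) -> np.ndarray:
        """Time-zero shift (seconds) at each wavelength."""
        x = np.asarray(wavelengths, dtype=float) - self.reference_wavelength
        return np.polynomial.polynomial.polyval(x, np.asarray(self.coefficients))


# ---------------------------------------------------------------------------
# dialect I/O


def _check_axis(values: np.ndarray, what: str) -> None:
    if np.any(~np.isfinite(values)):
        raise FormatError(f"non-finite {what} value")
    if np.unique(values).size != values.size:
        srt = np.sort(values)
        dup = srt[:-1][np.diff(srt) == 0]
        raise FormatError(f"duplicate {what} value {dup[0]:g}")


def read_ta_matrix(path, dialect: str = "time-rows") -> TASpectraSet:
    """Read a delimited dA(t, lambda) matrix.

    ``dialect='time-rows'``: first header row = wavelengths, first column =
    times.  ``'time-columns'``: transposed.  Axes are sorted ascending and
    the matrix permuted accordingly; times are converted to seconds using
    the ``# units:`` header (default seconds).
    """
    if dialect not in ("time-rows", "time-columns"):
        raise InvalidParameterError(f"unknown dialect {dialect!r}")
    time_scale = 1.0
    metadata: dict = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if body.startswith("units:"):
                    for tok in body[len("units:"):].split():
                        key, _, val = tok.partition("=")
                        if key == "time":
                            if val not in _TIME_UNITS:
                                raise FormatError(f"line {lineno}: unknown time unit {val!r}")
                            time_scale = _TIME_UNITS[val]
                elif body.startswith("truth:"):
                    metadata["truth"] = json.loads(body[len("truth:"):])
                continue
            rows.append(line.split("\t") if "\t" in line else line.split(","))
    if len(rows) < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(f"{path}: ragged row {i + 1} ({len(r)} cells, expected {width})")

    def parse(cell: str, where: str) -> float:
        try:
            return float(cell)
        except ValueError:
            raise FormatError(f"{path}: non-numeric cell {cell!r} in {where}") from None

    header = np.array([parse(c, "header row") for c in rows[0][1:]])
    first_col = np.array([parse(r[0], f"row {i + 2}") for i, r in enumerate(rows[1:])])
    values = np.array(
        [[parse(c, f"row {i + 2}") for c in r[1:]] for i, r in enumerate(rows[1:])]
    )
    if dialect == "time-rows":
        times, wavelengths, mat = first_col * time_scale, header, values
    else:
        times, wavelengths, mat = header * time_scale, first_col, values.T
    _check_axis(times, "time")
    _check_axis(wavelengths, "wavelength")
    ti, wi = np.argsort(times), np.argsort(wavelengths)
    return TASpectraSet(
        wavelengths=wavelengths[wi],
        times=times[ti],
        delta_A=mat[np.ix_(ti, wi)],
        instrument_tag=metadata.get("truth", {}).get("instrument_tag", "fast"),
        metadata=metadata,
        provenance_log=[f"read_ta_matrix({path!s}, dialect={dialect})"],
    )


def write_ta_matrix(ds: TASpectraSet, path, time_unit: str = "s") -> None:
    """Write in the time-rows orientation with a ``# units:`` header."""
    if time_unit not in _TIME_UNITS:
        raise InvalidParameterError(f"unknown time unit {time_unit!r}")
    scale = _TIME_UNITS[time_unit]
    with open(path, "w") as fh:
        fh.write(f"# units: time={time_unit} wavelength=nm\n")
        if "truth" in ds.metadata:
            fh.write(f"# truth: {json.dumps(ds.metadata['truth'])}\n")
        fh.write("\t" + "\t".join(f"{w:.17g}" for w in ds.wavelengths) + "\n")
        for t, row in zip(ds.times, ds.delta_A):
            fh.write(
                f"{t / scale:.17g}\t" + "\t".join(f"{v:.17g}" for v in row) + "\n"
            )


# ---------------------------------------------------------------------------
# preprocessing


def subtract_background(ds: TASpectraSet, pre_window_end: float) -> TASpectraSet:
    """Subtract the per-wavelength mean over the pre-excitation window
    (times < ``pre_window_end``) from every time point."""
    mask = ds.times < pre_window_end
    if mask.sum() < 3:
        raise PreconditionError(
            f"need >= 3 pre-excitation points before t={pre_window_end:g} s, "
            f"found {int(mask.sum())}"
        )
    out = ds.copy()
    background = ds.delta_A[mask].mean(axis=0)
    out.delta_A = ds.delta_A - background[None, :]
    out.provenance_log.append(f"subtract_background(pre_window_end={pre_window_end:g})")
    return out


def apply_chirp(ds: TASpectraSet, chirp: ChirpModel) -> TASpectraSet:
    """Inject spectral chirp (generator direction): the signal at wavelength
    lambda is what an unchirped instrument would have measured at
    ``t - shift(lambda)``."""
    return _shift_columns(ds, -chirp.shift(ds.wavelengths), f"apply_chirp({chirp.coefficients})")


def correct_chirp(ds: TASpectraSet, chirp: ChirpModel) -> TASpectraSet:
    """Undo spectral chirp: re-interpolate each wavelength column onto the
    common time axis after shifting by the chirp polynomial.  Edge samples
    are extrapolated as the nearest value and flagged in the provenance."""
    return _shift_columns(ds, chirp.shift(ds.wavelengths), f"correct_chirp({chirp.coefficients})")


def _shift_columns(ds: TASpectraSet, shifts: np.ndarray, tag: str) -> TASpectraSet:
    span = ds.times[-1] - ds.times[0]
    if np.abs(shifts).max(initial=0.0) > span:
        raise PreconditionError(
            f"chirp shift {np.abs(shifts).max():g} s exceeds the time span {span:g} s"
        )
    out = ds.copy()
    clipped = 0
    for j, dt in enumerate(shifts):
        if dt == 0.0:
            continue
        src = ds.times + dt
        interp = PchipInterpolator(ds.times, ds.delta_A[:, j], extrapolate=False)
        vals = interp(np.clip(src, ds.times[0], ds.times[-1]))
        clipped += int(np.sum((src < ds.times[0]) | (src > ds.times[-1])))
        out.delta_A[:, j] = vals
    out.provenance_log.append(f"{tag}; edge_samples_clamped={clipped}")
    return out


def merge_fast_slow(
    fast: TASpectraSet,
    slow: TASpectraSet,
    bleach_band: tuple[float, float] = (630.0, 650.0),
    overlap_window: tuple[float, float] = (0.6e-9, 2.4e-9),
    noise_floor: float = 0.0,
    scale: float | None = None,
) -> TASpectraSet:
    """Merge fast- and slow-instrument datasets on a common time axis.

    The slow matrix is multiplied by the scale factor ``s`` that matches its
    mean ground-state-bleach amplitude over ``bleach_band`` x
    ``overlap_window`` to the fast dataset's (the slow profile is
    interpolated onto the fast sample times inside the window so unequal
    sampling densities do not bias the ratio); fast data are preferred
    inside the overlap (better time resolution), so slow time points are
    kept only beyond the last fast time.  ``scale`` overrides the estimate
    (ideal merging with a known factor).  A per-time-point IRF width is
    attached so a downstream global fit can model both resolutions.
    """
    lo_w, hi_w = bleach_band
    lo_t, hi_t = overlap_window
    if hi_w <= lo_w or hi_t <= lo_t:
        raise PreconditionError("bleach band / overlap window must have positive width")

    def band_profile(ds: TASpectraSet) -> tuple[np.ndarray, np.ndarray]:
        tmask = (ds.times >= lo_t) & (ds.times <= hi_t)
        wmask = (ds.wavelengths >= lo_w) & (ds.wavelengths <= hi_w)
        if not tmask.any() or not wmask.any():
            raise PreconditionError(
                f"{ds.instrument_tag}: empty overlap (band {bleach_band}, window {overlap_window})"
            )
        return ds.times[tmask], ds.delta_A[np.ix_(tmask, wmask)].mean(axis=1)

    if scale is None:
        tf_, pf = band_profile(fast)
        ts_, ps = band_profile(slow)
        if tf_.size >= 2 and ts_.size >= 2 and tf_.min() > 0 and ts_.min() > 0:
            # common-time comparison (log-time interpolation of the slow profile)
            ps_on_fast = np.interp(np.log(tf_), np.log(ts_), ps)
            mf, ms = float(pf.mean()), float(ps_on_fast.mean())
        else:
            mf, ms = float(pf.mean()), float(ps.mean())
        floor = noise_floor if noise_floor > 0 else 1e-9 * max(fast.peak_abs, 1e-30)
        if abs(ms) < floor or abs(mf) < floor:
            raise IllConditionedScaleError(
                f"matching-region means ({mf:g}, {ms:g} mAbs) below the noise floor"
            )
        s = mf / ms
    else:
        s = float(scale)

    if fast.wavelengths.shape != slow.wavelengths.shape or not np.allclose(
        fast.wavelengths, slow.wavelengths
    ):
        raise PreconditionError("fast and slow wavelength axes must match for merging")

    keep = slow.times > fast.times[-1]
    times = np.concatenate([fast.times, slow.times[keep]])
    mat = np.concatenate([fast.delta_A, s * slow.delta_A[keep]], axis=0)

    def sigmas(ds: TASpectraSet, n: int) -> np.ndarray:
        if ds.irf_sigma_per_time is not None:
            return ds.irf_sigma_per_time
        w = ds.irf.effective_sigma if ds.irf is not None else 0.0
        return np.full(n, w)

    sigma = np.concatenate([sigmas(fast, fast.times.size), sigmas(slow, slow.times.size)[keep]])
    merged = TASpectraSet(
        wavelengths=fast.wavelengths.copy(),
        times=times,
        delta_A=mat,
        instrument_tag="merged",
        irf=fast.irf,
        irf_sigma_per_time=sigma,
        provenance_log=list(fast.provenance_log)
        + [
            f"merge_fast_slow(scale={s!r}, bleach_band={bleach_band}, "
            f"overlap_window={overlap_window})"
        ],
        metadata={**slow.metadata, **fast.metadata, "merge_scale": s},
    )
    return merged
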