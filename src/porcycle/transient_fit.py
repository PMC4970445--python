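"""Flash-photolysis transients at 696 nm: hydride- and proton-transfer rates.

The 696 nm band reports on the hydride-transfer intermediate of the POR
photocycle: its rise after the laser pulse is the hydride transfer from
NADPH (rate ``k_hydride``), its decay the subsequent proton transfer that
forms chlorophyllide (rate ``k_proton``).  Under first-order kinetics the
transient is the classic intermediate time course

    dA(t) = A * k1/(k1 - k2) * (exp(-k2 (t-t0)) - exp(-k1 (t-t0)))

with ``k1 = k_hydride``, ``k2 = k_proton`` and ``A`` the extrapolated
plateau amplitude at 696 nm (mAbs).

Two estimators are provided: windowed single-exponential fits on the
formation and decay phases (the routine measurement practice; the formation
fit is corrected for the slow decay using the decay-window estimate, which
makes it exact for well-separated phases), and a direct biexponential fit
as the cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import (
    DegenerateModelError,
    InvalidParameterError,
    PhaseSeparationError,
    PreconditionError,
)

__all__ = [
    "FlashTransient",
    "RateFitResult",
    "average_transients",
    "default_windows",
    "fit_phase_rates",
    "fit_rise_decay_biexp",
    "intermediate_time_course",
]


@dataclass
class FlashTransient:
    """A single-wavelength absorption transient (seconds, mAbs)."""

    times: np.ndarray
    delta_A: np.ndarray
    n_averaged: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        if self.times.shape != self.delta_A.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and delta_A must be matching 1-D arrays")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.n_averaged < 1:
            raise InvalidParameterError("n_averaged must be >= 1")


@dataclass
class RateFitResult:
    """Hydride/proton transfer rates and the 696 nm amplitude."""

    k_hydride: float
    k_hydride_stderr: float
    k_proton: float
    k_proton_stderr: float
    amplitude_696: float
    amplitude_stderr: float
    method: str

    def __post_init__(self) -> None:
        if self.k_hydride <= self.k_proton or self.k_proton <= 0:
            raise PhaseSeparationError(
                f"require k_hydride > k_proton > 0; got {self.k_hydride:g}, {self.k_proton:g}"
            )
        if self.amplitude_696 < 0:
            raise InvalidParameterError("amplitude_696 must be >= 0")

    @property
    def peak_time(self) -> float:
        """Time of maximum 696 nm signal, ln(k1/k2)/(k1 - k2)."""
        return float(np.log(self.k_hydride / self.k_proton) / (self.k_hydride - self.k_proton))


def intermediate_time_course(times, amplitude, k_hydride, k_proton, t0=0.0):
    """Noise-free 696 nm intermediate kinetics (rise then decay)."""
    t = np.asarray(times, dtype=float) - t0
    k1, k2 = k_hydride, k_proton
    out = amplitude * k1 / (k1 - k2) * (np.exp(-k2 * t) - np.exp(-k1 * t))
    return np.where(t >= 0, out, 0.0)


def average_transients(replicates: list[FlashTransient]) -> FlashTransient:
    """Pointwise mean of replicate transients measured on one time grid."""
    if len(replicates) < 2:
        raise PreconditionError("need at least 2 replicates to average")
    ref = replicates[0].times
    scale = np.maximum(np.abs(ref), np.abs(ref).max())
    for i, rep in enumerate(replicates[1:], start=2):
        if rep.times.shape != ref.shape or np.any(np.abs(rep.times - ref) > 1e-12 * scale):
            raise PreconditionError(f"replicate {i} is on a different time grid")
    if len(replicates) < 5:
        warnings.warn(
            f"averaging only {len(replicates)} transients; five or more are "
            "typically measured",
            UserWarning,
            stacklevel=2,
        )
    first = replicates[0].delta_A
    if all(np.array_equal(r.delta_A, first) for r in replicates[1:]):
        mean = first.copy()  # bitwise-exact mean of identical replicates
    else:
        mean = np.mean([r.delta_A for r in replicates], axis=0)
    return FlashTransient(ref.copy(), mean, n_averaged=len(replicates))


def default_windows(k_guess_hydride: float, t_end: float, t0: float = 0.0):
    """Default formation/decay windows from a hydride-rate guess:
    formation [t0, 5/k], decay [20/k, end]."""
    return (t0, t0 + 5.0 / k_guess_hydride), (t0 + 20.0 / k_guess_hydride, t_end)


def _window_mask(t: np.ndarray, window, what: str) -> np.ndarray:
    lo, hi = window
    if hi <= lo:
        raise PreconditionError(f"{what} window {window} has non-positive width")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 10:
        raise PreconditionError(
            f"{what} window {window} contains {int(mask.sum())} points, need >= 10"
        )
    return mask


def fit_phase_rates(
    transient: FlashTransient,
    formation_window: tuple[float, float],
    decay_window: tuple[float, float],
    t0: float = 0.0,
) -> RateFitResult:
    """Windowed single-exponential estimates of k_hydride and k_proton.

    The decay window is fitted first with a single exponential giving
    ``k_proton``; the formation window is then fitted with a single
    exponential rise multiplied by the (now known) slow decay, so the
    plateau amplitude matches the extrapolated amplitude a biexponential
    fit would report.  Raises :class:`PhaseSeparationError` when the two
    phases cannot be ordered (use the biexponential method instead).
    """
    t, y = transient.times, transient.delta_A
    if formation_window[0] >= decay_window[0]:
        raise PreconditionError("formation window must start before the decay window")
    if formation_window[1] > decay_window[0]:
        raise PreconditionError("formation and decay windows overlap")
    fmask = _window_mask(t, formation_window, "formation")
    dmask = _window_mask(t, decay_window, "decay")

    # --- decay phase: y = b exp(-k (t - t_d0))
    td, yd = t[dmask], y[dmask]
    td0 = td[0]
    pos = yd > 0
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(td[pos] - td0, np.log(yd[pos]), 1)
        k2_guess = max(-slope, 1.0 / (td[-1] - td0))
        b_guess = np.exp(intercept)
    else:
        k2_guess, b_guess = 1.0 / (td[-1] - td0), max(np.abs(yd).max(), 1e-12)
    try:
        popt_d, pcov_d = curve_fit(
            lambda tt, b, k: b * np.exp(-k * (tt - td0)),
            td, yd, p0=(b_guess, k2_guess), maxfev=20000,
        )
    except RuntimeError as exc:
        raise PhaseSeparationError(f"decay-window fit failed: {exc}") from exc
    b_fit, k2 = popt_d
    k2_err = float(np.sqrt(max(pcov_d[1, 1], 0.0)))
    if k2 <= 0 or b_fit <= 0:
        raise PhaseSeparationError("decay window does not show a positive decaying signal")

    # --- formation phase: y = a (1 - exp(-k (t - t0))) exp(-k2 (t - t0))
    tf, yf = t[fmask], y[fmask]
    q = max(yf.size // 4, 1)
    if yf[-q:].mean() <= yf[:q].mean():
        raise PhaseSeparationError(
            "no rising phase in the formation window; try fit_rise_decay_biexp"
        )
    a_guess = max(yf.max(), 1e-12)
    above = tf[yf >= 0.5 * yf.max()] if yf.max() > 0 else tf[-1:]
    k_guess = np.log(2.0) / max(above[0] - t0, (tf[1] - tf[0])) if above.size else 1.0 / (tf[-1] - t0)

    def rise(tt, a, k):
        dt = tt - t0
        return a * (1.0 - np.exp(-k * dt)) * np.exp(-k2 * dt)

    try:
        popt_f, pcov_f = curve_fit(rise, tf, yf, p0=(a_guess, k_guess), maxfev=20000)
    except RuntimeError as exc:
        raise PhaseSeparationError(f"formation-window fit failed: {exc}") from exc
    amp_raw, k_rise = popt_f
    k1 = k_rise + k2  # data rise as exp(-(k1 - k2) t) once the decay is divided out
    k1_err = float(np.sqrt(max(pcov_f[1, 1], 0.0)))
    if amp_raw <= 0 or k1 <= k2:
        raise PhaseSeparationError(
            "formation window does not show a rise faster than the decay; "
            "try fit_rise_decay_biexp"
        )
    # amp_raw estimates A * k1/(k1-k2); convert to the plateau amplitude A
    amplitude = amp_raw * (k1 - k2) / k1
    amp_err = float(np.sqrt(max(pcov_f[0, 0], 0.0))) * (k1 - k2) / k1
    return RateFitResult(
        k_hydride=float(k1),
        k_hydride_stderr=k1_err,
        k_proton=float(k2),
        k_proton_stderr=k2_err,
        amplitude_696=float(amplitude),
        amplitude_stderr=amp_err,
        method="windowed",
    )


def fit_rise_decay_biexp(
    transient: FlashTransient,
    guesses: tuple[float, float, float] | None = None,
    t0: float = 0.0,
) -> RateFitResult:
    """Direct nonlinear fit of the biexponential intermediate time course.

    ``guesses`` is (amplitude, k_hydride, k_proton); if omitted they are
    derived from the peak position and the tail slope.
    """
    t, y = transient.times, transient.delta_A
    if t.size < 25:
        raise PreconditionError("need >= 25 points spanning both phases")
    if guesses is None:
        i_peak = int(np.argmax(y))
        t_peak = max(t[i_peak] - t0, (t[1] - t[0]))
        tail = t > t0 + 3 * t_peak
        ytail = y[tail]
        pos = ytail > 0
        if pos.sum() >= 3:
            slope, _ = np.polyfit(t[tail][pos] - t0, np.log(ytail[pos]), 1)
            k2_guess = max(-slope, 1e-3 / t_peak)
        else:
            k2_guess = 0.1 / t_peak
        k1_guess = 5.0 / t_peak
        guesses = (max(y.max(), 1e-12), k1_guess, k2_guess)
    a0, k10, k20 = guesses

    def resid(x):
        a, lk1, lk2 = x
        return intermediate_time_course(t, a, np.exp(lk1), np.exp(lk2), t0) - y

    res = least_squares(
        resid, np.array([a0, np.log(k10), np.log(k20)]),
        method="lm" if t.size > 3 else "trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    a, k1, k2 = res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    if abs(k1 - k2) <= 1e-6 * max(k1, k2):
        raise DegenerateModelError(
            f"k_hydride and k_proton collapsed ({k1:g} ~ {k2:g}); "
            "the confluent form is not fitted"
        )
    if k1 < k2:  # label by role: faster rate is the formation step
        k1, k2 = k2, k1
        res.x[1], res.x[2] = res.x[2], res.x[1]
    dof = max(t.size - 3, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        errs = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        errs = np.full(3, np.nan)
    return RateFitResult(
        k_hydride=k1,
        k_hydride_stderr=float(k1 * errs[1]),
        k_proton=k2,
        k_proton_stderr=float(k2 * errs[2]),
        amplitude_696=float(abs(a)),
        amplitude_stderr=float(errs[0]),
        method="biexponential",
    )
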