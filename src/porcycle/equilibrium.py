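"""Equilibrium binding and steady-state kinetics of POR variants.

Dissociation constants are fitted from titrations with either the
tight-binding (Morrison) quadratic — exact when ligand depletion matters,
i.e. Kd comparable to or below the macromolecule concentration, as for
nM-scale NADPH binding followed by FRET — or the hyperbolic (weak-binding)
approximation.  Turnover numbers come from linear initial rates of
steady-state progress curves.  The module also carries the reference table
of measured parameters for the wild-type enzyme and its sixteen active-site
variants, used throughout as the source of simulation ground truths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidParameterError, PreconditionError

__all__ = [
    "Titration",
    "BindingFitResult",
    "ProgressCurve",
    "VariantKineticsRecord",
    "morrison_bound_fraction",
    "fit_kd_quadratic",
    "fit_kd_hyperbolic",
    "initial_rate_kcat",
    "table1_fixture",
    "lookup_variant",
]


@dataclass
class Titration:
    """Ligand titration: total ligand (M, increasing) vs binding signal."""

    ligand_total: np.ndarray
    signal: np.ndarray
    macromolecule_total: float
    signal_kind: str = "FRET"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ligand_total.shape != self.signal.shape:
            raise InvalidParameterError("ligand_total and signal must match")
        if self.ligand_total.size < 6:
            raise InvalidParameterError("need at least 6 titration points")
        if np.any(self.ligand_total < 0):
            raise InvalidParameterError("concentrations must be >= 0")
        if self.signal_kind not in ("FRET", "red-shift-absorbance"):
            raise InvalidParameterError(f"unknown signal kind {self.signal_kind!r}")


@dataclass
class BindingFitResult:
    kd: float
    kd_stderr: float
    signal_max: float
    signal_max_stderr: float
    signal_offset: float
    model: str

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise InvalidParameterError("fitted Kd must be > 0")


@dataclass
class ProgressCurve:
    """Steady-state product accumulation trace.

    ``extinction_pathlength`` (mAbs per molar) converts the product signal
    to concentration.
    """

    times: np.ndarray
    product_signal: np.ndarray
    extinction_pathlength: float
    enzyme_total: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.product_signal = np.asarray(self.product_signal, dtype=float)
        if self.times.shape != self.product_signal.shape:
            raise InvalidParameterError("times and product_signal must match")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be increasing")
        if self.enzyme_total <= 0 or self.extinction_pathlength <= 0:
            raise InvalidParameterError("enzyme_total and extinction must be > 0")


def morrison_bound_fraction(e_total, l_total, kd):
    """Exact bound fraction of the macromolecule under ligand depletion.

    fbound = ((E + L + Kd) - sqrt((E + L + Kd)^2 - 4 E L)) / (2 E),
    evaluated cancellation-free: the discriminant as
    (E - L)^2 + 2 Kd (E + L) + Kd^2 and the small quadratic root in the
    rationalized form 2 L / ((E + L + Kd) + sqrt(disc)).
    """
    e = np.asarray(e_total, dtype=float)
    l = np.asarray(l_total, dtype=float)
    disc = (e - l) ** 2 + 2.0 * kd * (e + l) + kd * kd
    return 2.0 * l / ((e + l + kd) + np.sqrt(disc))


def _linearized_errors(pcov) -> np.ndarray:
    return np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))


def _bootstrap_kd_stderr(model, l, signal, popt, n_resamples, seed) -> float:
    """Seeded residual-resampling bootstrap of the fitted log-Kd."""
    fitted = model(l, *popt)
    resid = signal - fitted
    rng = np.random.default_rng(seed)
    kds = []
    for _ in range(n_resamples):
        resampled = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            p, _ = curve_fit(model, l, resampled, p0=popt, maxfev=20000)
            kds.append(np.exp(p[2]))
        except RuntimeError:
            continue
    return float(np.std(kds)) if len(kds) >= 2 else float("nan")


def _finish_binding_fit(model, t, p0, name, bootstrap, bootstrap_seed):
    popt, pcov = curve_fit(model, t.ligand_total, t.signal, p0=p0, maxfev=20000)
    offset, smax, log_kd = popt
    errs = _linearized_errors(pcov)
    kd = float(np.exp(log_kd))
    kd_stderr = float(kd * errs[2])
    if bootstrap:
        kd_stderr = _bootstrap_kd_stderr(
            model, t.ligand_total, t.signal, popt, bootstrap, bootstrap_seed
        )
    return BindingFitResult(
        kd=kd,
        kd_stderr=kd_stderr,
        signal_max=float(smax),
        signal_max_stderr=float(errs[1]),
        signal_offset=float(offset),
        model=name,
    )


def fit_kd_quadratic(
    t: Titration, bootstrap: int = 0, bootstrap_seed: int = 0
) -> BindingFitResult:
    """Tight-binding (Morrison) fit: signal = offset + smax * fbound.

    ``bootstrap > 0`` replaces the linearized Kd standard error with a
    seeded residual-resampling bootstrap of that many refits (200 is
    typical).
    """
    e = t.macromolecule_total
    if e <= 0:
        raise PreconditionError("macromolecule_total must be > 0")
    lmax = t.ligand_total.max()
    if e > 5.0 * lmax:
        warnings.warn(
            "macromolecule far exceeds all ligand concentrations; the fit is "
            "bound-limited and Kd is poorly identifiable",
            UserWarning,
            stacklevel=2,
        )

    span = t.signal.max() - t.signal.min()
    p0 = (t.signal.min(), span if span > 0 else 1.0, np.log(max(np.median(t.ligand_total), e) / 10))

    def model(l, offset, smax, log_kd):
        return offset + smax * morrison_bound_fraction(e, l, np.exp(log_kd))

    return _finish_binding_fit(model, t, p0, "quadratic", bootstrap, bootstrap_seed)


def fit_kd_hyperbolic(
    t: Titration, bootstrap: int = 0, bootstrap_seed: int = 0
) -> BindingFitResult:
    """Weak-binding fit: signal = offset + smax * L / (Kd + L); intended for
    Kd much larger than the macromolecule concentration."""
    span = t.signal.max() - t.signal.min()
    p0 = (t.signal.min(), span if span > 0 else 1.0, np.log(max(np.median(t.ligand_total), 1e-12)))

    def model(l, offset, smax, log_kd):
        return offset + smax * l / (np.exp(log_kd) + l)

    return _finish_binding_fit(model, t, p0, "hyperbolic", bootstrap, bootstrap_seed)


def initial_rate_kcat(curve: ProgressCurve, linear_fraction: float = 0.1):
    """Turnover number from the initial linear phase of a progress curve.

    Fits a line over the earliest points covering ``linear_fraction`` of the
    total signal change, converts the slope to molar product per second via
    the extinction/pathlength factor, and divides by the total enzyme
    concentration.  Returns ``(kcat, stderr)`` in s^-1.
    """
    if not 0.0 < linear_fraction <= 0.2:
        raise PreconditionError("linear_fraction must be in (0, 0.2]")
    y = curve.product_signal
    total = np.abs(y - y[0]).max()
    if total == 0.0:
        mask = np.ones(y.size, dtype=bool)  # flat curve: rate is zero
    else:
        within = np.abs(y - y[0]) <= linear_fraction * total
        cutoff = np.argmin(within) if not within.all() else y.size
        mask = np.zeros(y.size, dtype=bool)
        mask[:max(cutoff, 1)] = True
    if mask.sum() < 5:
        raise PreconditionError(
            f"only {int(mask.sum())} points in the initial-rate window, need >= 5"
        )
    tt, yy = curve.times[mask], y[mask]
    coeffs, cov = np.polyfit(tt, yy, 1, cov=True)
    slope = coeffs[0] / curve.extinction_pathlength  # M/s
    slope_err = np.sqrt(max(cov[0, 0], 0.0)) / curve.extinction_pathlength
    return float(slope / curve.enzyme_total), float(slope_err / curve.enzyme_total)


# ---------------------------------------------------------------------------
# reference parameter table


@dataclass(frozen=True)
class VariantKineticsRecord:
    """Measured parameters of one enzyme variant.

    Units: kcat s^-1; kd_nadph nM; kd_pchlide uM; k_hydride and k_proton
    s^-1; amplitude_696 mAbs.  Fields are ``None`` when not determined
    (photochemistry too impaired to measure the transfer rates).
    """

    variant_name: str
    kcat: float
    kcat_err: float
    kd_nadph: float
    kd_nadph_err: float
    kd_pchlide: float
    kd_pchlide_err: float
    k_hydride: float | None
    k_hydride_err: float | None
    k_proton: float | None
    k_proton_err: float | None
    amplitude_696: float
    amplitude_696_err: float

    @property
    def photochemistry_measurable(self) -> bool:
        return self.k_hydride is not None


def _rec(name, kcat, kdn, kdp, kh, kp, amp):
    kh_v, kh_e = (kh[0] * 1e6, kh[1] * 1e6) if kh else (None, None)
    kp_v, kp_e = (kp[0] * 1e4, kp[1] * 1e4) if kp else (None, None)
    return VariantKineticsRecord(
        name, kcat[0], kcat[1], kdn[0], kdn[1], kdp[0], kdp[1],
        kh_v, kh_e, kp_v, kp_e, amp[0], amp[1],
    )


_TABLE1 = (
    _rec("Wild-type", (0.17, 0.002), (21, 1), (5.6, 0.6), (2.21, 0.06), (2.72, 0.04), (102, 1)),
    _rec("S16C", (0.16, 0.001), (325, 90), (3.5, 0.5), (2.11, 0.03), (2.68, 0.03), (61, 3)),
    _rec("G19A", (0.16, 0.001), (182, 31), (3.5, 0.4), (2.08, 0.07), (2.67, 0.02), (92, 2)),
    _rec("R38V", (0.16, 0.001), (411, 76), (5.4, 0.6), (2.12, 0.03), (2.69, 0.01), (54, 4)),
    _rec("N39V", (0.02, 0.001), (23, 6), (28.9, 1.4), (1.98, 0.02), (2.71, 0.03), (10, 0.4)),
    _rec("K42A", (0.16, 0.001), (230, 81), (4.5, 0.4), (2.14, 0.09), (2.67, 0.04), (85, 3)),
    _rec("N90A", (0.07, 0.002), (94, 7), (21.4, 0.6), (2.28, 0.04), (3.17, 0.04), (31, 2)),
    _rec("Y94F", (0.17, 0.003), (63, 4), (11.8, 0.7), (2.23, 0.02), (3.11, 0.01), (80, 1)),
    _rec("T145A", (0.01, 0.001), (33, 2), (39.7, 2.1), None, None, (2, 0.2)),
    _rec("T147S", (0.02, 0.003), (60, 3), (6.5, 0.7), None, None, (2, 0.2)),
    _rec("T147F", (0.01, 0.003), (117, 3), (10.3, 0.6), None, None, (1, 0.1)),
    _rec("N149V", (0.01, 0.003), (55, 2), (19.2, 1.2), None, None, (2, 0.2)),
    _rec("S189A", (0.16, 0.001), (38, 16), (4.9, 0.4), (2.15, 0.07), (2.69, 0.01), (69, 4)),
    _rec("T230A", (0.16, 0.001), (181, 16), (11.9, 1.4), (1.63, 0.07), (2.26, 0.03), (51, 3)),
    _rec("T230S", (0.16, 0.001), (48, 17), (4.6, 0.5), (1.71, 0.06), (2.38, 0.06), (60, 1)),
    _rec("T230F", (0.01, 0.001), (436, 87), (44.9, 3.5), None, None, (2, 0.2)),
    _rec("H236A", (0.10, 0.004), (30, 11), (9.4, 0.6), (2.18, 0.03), (2.72, 0.01), (33, 1)),
)


def table1_fixture() -> list[VariantKineticsRecord]:
    """The transcribed reference table: wild-type plus 16 variants."""
    return list(_TABLE1)


def lookup_variant(name: str) -> VariantKineticsRecord:
    for rec in _TABLE1:
        if rec.variant_name == name:
            return rec
    raise KeyError(f"unknown variant {name!r}")
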