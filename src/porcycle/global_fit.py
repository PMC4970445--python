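"""Global target analysis of dA(t, lambda) matrices by variable projection.

The separable structure of the model — unitless compartment populations
C(theta) carrying the kinetics, species-associated difference spectra (SADS)
carrying all amplitude in mAbs — is exploited by solving the SADS as the
exact linear least-squares solution at every step of the nonlinear search
over rates, so the optimizer only sees the kinetic parameters.  Rates are
optimized on a log scale (positivity by construction; they span many
decades).  Standard errors come from the linearized covariance of the
projected residual at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svdvals
from scipy.optimize import least_squares

from .errors import DegenerateModelError, InvalidParameterError, PreconditionError
from .schemes import (
    DEFAULT_BRANCHED_RATES,
    ConcentrationMatrix,
    KineticScheme,
    build_branched_scheme,
    build_sequential_scheme,
    solve_populations,
)
from .ta_preprocess import TASpectraSet

__all__ = [
    "FitParameter",
    "TargetModelSpec",
    "GlobalFitResult",
    "fit_target",
    "fit_sequential",
    "estimate_component_count",
]


@dataclass
class FitParameter:
    """One nonlinear model parameter (a rate in s^-1, or the branch fraction)."""

    name: str
    guess: float
    fixed: bool = False
    bounds: tuple[float, float] = (1e-2, 1e15)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (np.isfinite(self.guess) and self.guess > 0):
            raise InvalidParameterError(f"{self.name}: guess must be finite > 0")
        if not lo < hi:
            raise InvalidParameterError(f"{self.name}: empty bounds {self.bounds}")
        if not lo <= self.guess <= hi:
            raise InvalidParameterError(
                f"{self.name}: guess {self.guess:g} outside bounds {self.bounds}"
            )


@dataclass
class TargetModelSpec:
    """A kinetic target model with parameters marked free or fixed.

    Use the :meth:`sequential` / :meth:`branched` constructors; ``kind``
    selects the scheme builder.  Compartments listed in
    ``dark_compartments`` (ground-state sinks) have a zero difference
    spectrum by definition and are excluded from the SADS solve.
    """

    kind: str
    parameters: list[FitParameter]
    dark_compartments: tuple[str, ...] = ()
    terminal_persists: bool = False
    irf_policy: str = "fixed"

    def __post_init__(self) -> None:
        if self.kind not in ("sequential", "branched"):
            raise InvalidParameterError(f"unknown model kind {self.kind!r}")
        if self.irf_policy != "fixed":
            raise InvalidParameterError("only irf_policy='fixed' is supported")
        if not any(not p.fixed for p in self.parameters):
            raise InvalidParameterError("at least one parameter must be free")

    @classmethod
    def sequential(
        cls,
        lifetime_guesses,
        fixed: tuple[str, ...] = (),
        terminal_persists: bool = False,
    ) -> "TargetModelSpec":
        """Sequential chain with one free rate 1/tau_i per compartment."""
        taus = np.atleast_1d(np.asarray(lifetime_guesses, dtype=float))
        params = [
            FitParameter(f"k{i + 1}", 1.0 / tau, fixed=f"k{i + 1}" in fixed)
            for i, tau in enumerate(taus)
        ]
        return cls(kind="sequential", parameters=params, terminal_persists=terminal_persists)

    @classmethod
    def branched(
        cls,
        stage_rate_guesses: dict[str, float] | None = None,
        catalytic_fraction: float = 0.4,
        free_fraction: bool = False,
    ) -> "TargetModelSpec":
        """Branched photocycle model; the catalytic branch fraction is fixed
        by default and may be freed explicitly."""
        rates = dict(DEFAULT_BRANCHED_RATES)
        if stage_rate_guesses:
            rates.update(stage_rate_guesses)
        params = [FitParameter(name, rate) for name, rate in rates.items()]
        params.append(
            FitParameter(
                "catalytic_fraction",
                catalytic_fraction,
                fixed=not free_fraction,
                bounds=(1e-3, 1.0),
            )
        )
        return cls(kind="branched", parameters=params, dark_compartments=("ground",))

    # -- scheme construction ----------------------------------------------
    def build_scheme(self, values: dict[str, float]) -> KineticScheme:
        if self.kind == "sequential":
            n = len(self.parameters)
            lifetimes = [1.0 / values[f"k{i + 1}"] for i in range(n)]
            return build_sequential_scheme(lifetimes, terminal_persists=self.terminal_persists)
        stage = {k: values[k] for k in DEFAULT_BRANCHED_RATES}
        return build_branched_scheme(values["catalytic_fraction"], stage)


@dataclass
class GlobalFitResult:
    """Lifetimes with standard errors, SADS, and residual diagnostics."""

    lifetimes: dict[str, float]
    lifetime_stderr: dict[str, float]
    rates: dict[str, float]
    rate_stderr: dict[str, float]
    sads: np.ndarray
    sads_compartments: tuple[str, ...]
    wavelengths: np.ndarray
    residual: np.ndarray
    rmse: float
    model: KineticScheme
    concentrations: ConcentrationMatrix
    converged: bool
    n_free: int
    metadata: dict = field(default_factory=dict)


def _concentrations(
    spec: TargetModelSpec, values: dict[str, float], ds: TASpectraSet
) -> tuple[KineticScheme, ConcentrationMatrix, np.ndarray, list[str]]:
    scheme = spec.build_scheme(values)
    conc = solve_populations(scheme, ds.times, ds.irf, ds.irf_sigma_per_time)
    keep = [i for i, n in enumerate(scheme.compartment_names) if n not in spec.dark_compartments]
    names = [scheme.compartment_names[i] for i in keep]
    return scheme, conc, conc.populations[:, keep], names


def _project(c_matrix: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sads, *_ = np.linalg.lstsq(c_matrix, data, rcond=None)
    return sads, data - c_matrix @ sads


def fit_target(ds: TASpectraSet, spec: TargetModelSpec, weights=None) -> GlobalFitResult:
    """Fit a kinetic target model to a preprocessed dataset.

    ``weights`` optionally gives per-time-point weights (e.g. to deweight
    sparse log-spaced regions); default is uniform.
    """
    data = ds.delta_A
    if not np.all(np.isfinite(data)):
        raise PreconditionError("dataset contains non-finite values; preprocess first")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != ds.times.shape or np.any(weights < 0):
            raise PreconditionError("weights must be non-negative, one per time point")
        w = weights[:, None]
    else:
        w = None

    free = [p for p in spec.parameters if not p.fixed]
    fixed_values = {p.name: p.guess for p in spec.parameters if p.fixed}

    def unpack(x: np.ndarray) -> dict[str, float]:
        values = dict(fixed_values)
        values.update({p.name: np.exp(xi) for p, xi in zip(free, x)})
        return values

    def residuals(x: np.ndarray) -> np.ndarray:
        _, _, c_matrix, _ = _concentrations(spec, unpack(x), ds)
        _, resid = _project(c_matrix if w is None else w * c_matrix, data if w is None else w * data)
        return resid.ravel()

    x0 = np.log([p.guess for p in free])
    lb = np.log([p.bounds[0] for p in free])
    ub = np.log([p.bounds[1] for p in free])
    res = least_squares(
        residuals, x0, bounds=(lb, ub), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, x_scale=1.0,
    )

    values = unpack(res.x)
    scheme, conc, c_matrix, sads_names = _concentrations(spec, values, ds)
    sv = svdvals(c_matrix)
    if sv[-1] <= 0 or sv[0] / sv[-1] > 1e8:
        lifetimes = {n: 1.0 / values[n] for n in values if n != "catalytic_fraction"}
        raise DegenerateModelError(
            "concentration matrix is rank deficient: indistinguishable compartments "
            f"(lifetimes {lifetimes})"
        )
    sads, resid = _project(c_matrix, data)
    rmse = float(np.sqrt(np.mean(resid**2)))

    # linearized covariance of the projected residual at the optimum
    dof = max(resid.size - len(free), 1)
    jac = res.jac
    jtj = jac.T @ jac
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(jtj)
        stderr_log = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        stderr_log = np.full(len(free), np.nan)

    rates = {p.name: values[p.name] for p in spec.parameters}
    rate_stderr = {p.name: 0.0 for p in spec.parameters}
    for p, se in zip(free, stderr_log):
        rate_stderr[p.name] = float(values[p.name] * se)  # delta method on log scale
    lifetimes, lifetime_stderr = {}, {}
    for name, k in rates.items():
        if name == "catalytic_fraction":
            continue
        lifetimes[name] = 1.0 / k
        lifetime_stderr[name] = rate_stderr[name] / k**2

    return GlobalFitResult(
        lifetimes=lifetimes,
        lifetime_stderr=lifetime_stderr,
        rates=rates,
        rate_stderr=rate_stderr,
        sads=sads,
        sads_compartments=tuple(sads_names),
        wavelengths=ds.wavelengths.copy(),
        residual=resid,
        rmse=rmse,
        model=scheme,
        concentrations=conc,
        converged=bool(res.success),
        n_free=len(free),
        metadata={"optimizer_status": res.status, "cost": float(res.cost), **conc.metadata},
    )


def fit_sequential(
    ds: TASpectraSet, n_components: int, guesses, **kwargs
) -> GlobalFitResult:
    """Fit a sequential chain of ``n_components`` species (each converting
    to the next, the last decaying to ground) with lifetime ``guesses``."""
    guesses = np.atleast_1d(np.asarray(guesses, dtype=float))
    if n_components < 1:
        raise InvalidParameterError("n_components must be >= 1")
    if guesses.size != n_components:
        raise InvalidParameterError(
            f"need {n_components} lifetime guesses, got {guesses.size}"
        )
    return fit_target(ds, TargetModelSpec.sequential(guesses), **kwargs)


def _auto_guesses(ds: TASpectraSet, n: int) -> np.ndarray:
    """Log-spaced lifetime guesses spanning the post-excitation time range."""
    pos = ds.times[ds.times > 0]
    lo = max(pos[0], 1e-15)
    hi = max(pos[-1], 10 * lo)
    return np.geomspace(lo * 2, hi / 2, n)


def estimate_component_count(
    ds: TASpectraSet,
    noise_sigma: float | None = 0.0,
    multiplier: float = 5.0,
    cross_check: bool = False,
    rmse_ratio: float = 0.02,
    max_components: int = 6,
) -> int:
    """Number of kinetic components resolvable in the data matrix.

    Counts singular values above the analytic noise floor
    ``noise_sigma * (sqrt(n_t) + sqrt(n_lambda))`` — the expected largest
    singular value of a pure-noise matrix — never below the numerical rank
    floor.  With ``noise_sigma=None`` the floor is estimated as
    ``multiplier`` times the median singular value.  ``cross_check=True``
    additionally runs nested sequential fits, retaining an extra component
    only if it improves the rmse by more than ``rmse_ratio``.
    """
    if noise_sigma is not None and noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    sv = svdvals(ds.delta_A)
    if sv.size == 0 or sv[0] == 0.0:
        return 0
    m, n = ds.delta_A.shape
    numeric_floor = sv[0] * max(m, n) * np.finfo(float).eps
    if noise_sigma is None:
        floor = max(multiplier * float(np.median(sv)), numeric_floor)
    else:
        floor = max(noise_sigma * (np.sqrt(m) + np.sqrt(n)), numeric_floor)
    count = int(np.sum(sv > floor))
    if not cross_check or count == 0:
        return count

    best_n, prev_rmse = 0, float(np.sqrt(np.mean(ds.delta_A**2)))
    for k in range(1, min(count + 1, max_components) + 1):
        try:
            fit = fit_sequential(ds, k, _auto_guesses(ds, k))
        except DegenerateModelError:
            break
        if prev_rmse > 0 and (prev_rmse - fit.rmse) / prev_rmse > rmse_ratio:
            best_n, prev_rmse = k, fit.rmse
        else:
            break
    return min(count, best_n) if best_n else count
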