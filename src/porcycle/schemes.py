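"""Compartmental photocycle models and their IRF-convolved populations.

A :class:`KineticScheme` is a first-order compartmental model ``dp/dt = K p``
with the column convention: ``K[i, j]`` (i != j) is the microscopic rate of
flow from compartment ``j`` into compartment ``i`` (per second), and the
diagonal ``K[j, j]`` is minus the total outflow of ``j``.  Any excess of the
diagonal over the explicit inflows credited to other compartments is an
implicit loss to the ground state.

Populations are solved analytically by eigendecomposition; each eigenmode
``exp(lambda * t)`` convolved with a Gaussian instrument response function is
an exponentially modified Gaussian, evaluated in the numerically stable
scaled-complementary-error-function form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.special import erfcx, wofz

from .errors import InvalidParameterError

__all__ = [
    "InstrumentResponse",
    "KineticScheme",
    "ConcentrationMatrix",
    "build_sequential_scheme",
    "build_branched_scheme",
    "solve_populations",
    "flux_fraction",
]

#: default microscopic rates for the branched wild-type photocycle (s^-1):
#: branch decision out of the ICT state on the ~25 ps scale, solvated-ICT
#: decay to ground/triplet on the ~3.5 ns scale, and reactive-ICT conversion
#: to the 696 nm hydride-transfer intermediate with a 500 ns lifetime.
DEFAULT_BRANCHED_RATES = {
    "branch": 4.0e10,
    "solvated_decay": 1.0 / 3.5e-9,
    "intermediate_formation": 2.0e6,
}

BRANCHED_COMPARTMENTS = ("S_ICT", "ICT_solvated", "ICT_reactive", "I696", "ground")


@dataclass(frozen=True)
class InstrumentResponse:
    """Gaussian instrument response: center time t0 and standard deviation.

    ``width_sigma = 0`` (or ``enabled=False``) reduces every convolution to
    step-function kinetics starting at ``center_time``.
    """

    center_time: float = 0.0
    width_sigma: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.center_time):
            raise InvalidParameterError("IRF center_time must be finite")
        if not np.isfinite(self.width_sigma) or self.width_sigma < 0:
            raise InvalidParameterError("IRF width_sigma must be >= 0 and finite")

    @property
    def effective_sigma(self) -> float:
        return self.width_sigma if self.enabled else 0.0


@dataclass
class KineticScheme:
    """Compartmental kinetic model with a per-second first-order rate matrix."""

    compartment_names: tuple[str, ...]
    rate_matrix: np.ndarray
    initial_vector: np.ndarray
    branch_fractions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.compartment_names = tuple(self.compartment_names)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.initial_vector = np.asarray(self.initial_vector, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_compartments(self) -> int:
        return len(self.compartment_names)

    def index(self, name: str) -> int:
        try:
            return self.compartment_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown compartment {name!r}; have {list(self.compartment_names)}"
            ) from None

    def outflow(self, j: int) -> float:
        """Total first-order outflow rate of compartment ``j`` (>= 0)."""
        return -float(self.rate_matrix[j, j])

    def validate(self) -> None:
        n = self.n_compartments
        k = self.rate_matrix
        if k.shape != (n, n):
            raise InvalidParameterError(
                f"rate matrix shape {k.shape} does not match {n} compartments"
            )
        if self.initial_vector.shape != (n,):
            raise InvalidParameterError("initial vector length mismatch")
        if not np.all(np.isfinite(k)):
            raise InvalidParameterError("rate matrix must be finite")
        off = k - np.diag(np.diag(k))
        if np.any(off < 0):
            raise InvalidParameterError("off-diagonal rates must be >= 0")
        # column outflow must cover the inflows credited to other compartments
        outflows = -np.diag(k)
        inflows = off.sum(axis=0)
        if np.any(outflows + 1e-9 * np.maximum(1.0, np.abs(outflows)) < inflows):
            raise InvalidParameterError(
                "diagonal outflow smaller than credited inflows (negative ground loss)"
            )
        if abs(self.initial_vector.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("initial excitation fractions must sum to 1")
        for src, targets in self.branch_fractions.items():
            total = sum(targets.values())
            if abs(total - 1.0) > 1e-12:
                raise InvalidParameterError(
                    f"branch fractions out of {src!r} sum to {total}, not 1"
                )
            for f in targets.values():
                if not 0.0 <= f <= 1.0:
                    raise InvalidParameterError("branch fractions must lie in [0, 1]")

    def with_ground_sink(self, name: str = "__ground__") -> "KineticScheme":
        """Return a copy with implicit ground-state losses routed to an
        explicit terminal sink, making total population conserved."""
        n = self.n_compartments
        k = self.rate_matrix
        loss = -np.diag(k) - (k - np.diag(np.diag(k))).sum(axis=0)
        k2 = np.zeros((n + 1, n + 1))
        k2[:n, :n] = k
        k2[n, :n] = loss
        return KineticScheme(
            compartment_names=self.compartment_names + (name,),
            rate_matrix=k2,
            initial_vector=np.append(self.initial_vector, 0.0),
            branch_fractions=dict(self.branch_fractions),
        )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "compartments": list(self.compartment_names),
            "rates_per_second": self.rate_matrix.tolist(),
            "initial_vector": self.initial_vector.tolist(),
            "branch_fractions": {
                src: dict(t) for src, t in self.branch_fractions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        return cls(
            compartment_names=tuple(d["compartments"]),
            rate_matrix=np.asarray(d["rates_per_second"], dtype=float),
            initial_vector=np.asarray(d["initial_vector"], dtype=float),
            branch_fractions={
                src: dict(t) for src, t in d.get("branch_fractions", {}).items()
            },
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KineticScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ConcentrationMatrix:
    """Unitless compartment populations on a time grid (time x compartment)."""

    times: np.ndarray
    populations: np.ndarray
    compartment_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)


def build_sequential_scheme(
    lifetimes,
    names: tuple[str, ...] | None = None,
    terminal_persists: bool = False,
) -> KineticScheme:
    """Unidirectional chain A -> B -> C -> ... with rate ``1/tau_i`` out of
    compartment ``i``; the last compartment's outflow goes to the ground
    state unless ``terminal_persists`` is set (or its lifetime is ``inf``),
    in which case the terminal species persists for the whole experiment.
    """
    taus = [float(t) for t in np.atleast_1d(np.asarray(lifetimes, dtype=float))]
    if len(taus) < 1:
        raise InvalidParameterError("need at least one lifetime")
    for i, tau in enumerate(taus):
        terminal = i == len(taus) - 1
        if np.isinf(tau) and terminal:
            continue
        if not np.isfinite(tau) or tau <= 0:
            raise InvalidParameterError(f"lifetime #{i + 1} = {tau} must be finite > 0")
    n = len(taus)
    if names is None:
        names = tuple(f"S{i + 1}" for i in range(n))
    elif len(names) != n:
        raise InvalidParameterError("names length must match number of lifetimes")
    k = np.zeros((n, n))
    for i, tau in enumerate(taus):
        terminal = i == n - 1
        if terminal and (terminal_persists or np.isinf(tau)):
            continue
        k[i, i] = -1.0 / tau
        if not terminal:
            k[i + 1, i] = 1.0 / tau
    p0 = np.zeros(n)
    p0[0] = 1.0
    return KineticScheme(tuple(names), k, p0)


def build_branched_scheme(
    catalytic_fraction: float = 0.4,
    stage_rates: dict[str, float] | None = None,
) -> KineticScheme:
    """Branched photocycle of the wild-type ternary complex.

    The intramolecular charge-transfer state S_ICT partitions between a
    non-catalytic limb (fraction ``1 - f`` solvates and is lost to
    ground/triplet) and a catalytic limb (fraction ``f`` forms a reactive
    ICT state that converts to the 696 nm hydride-transfer intermediate
    I696, which persists within the observation window).  An explicit
    ``ground`` sink collects all losses so that total population is
    conserved.

    ``stage_rates`` keys: ``branch`` (outflow of S_ICT), ``solvated_decay``
    (ICT_solvated -> ground), ``intermediate_formation``
    (ICT_reactive -> I696); defaults in :data:`DEFAULT_BRANCHED_RATES`.
    """
    f = float(catalytic_fraction)
    if not 0.0 <= f <= 1.0:
        raise InvalidParameterError(f"catalytic_fraction {f} outside [0, 1]")
    rates = dict(DEFAULT_BRANCHED_RATES)
    if stage_rates:
        unknown = set(stage_rates) - set(rates)
        if unknown:
            raise InvalidParameterError(f"unknown stage rates: {sorted(unknown)}")
        rates.update({k: float(v) for k, v in stage_rates.items()})
    for name, rate in rates.items():
        if not np.isfinite(rate) or rate <= 0:
            raise InvalidParameterError(f"stage rate {name!r} = {rate} must be > 0")

    kb, ks, kf = rates["branch"], rates["solvated_decay"], rates["intermediate_formation"]
    # order: S_ICT, ICT_solvated, ICT_reactive, I696, ground
    k = np.zeros((5, 5))
    k[0, 0] = -kb
    k[1, 0] = (1.0 - f) * kb
    k[2, 0] = f * kb
    k[1, 1] = -ks
    k[4, 1] = ks
    k[2, 2] = -kf
    k[3, 2] = kf
    p0 = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    branches = {"S_ICT": {"ICT_solvated": 1.0 - f, "ICT_reactive": f}}
    return KineticScheme(BRANCHED_COMPARTMENTS, k, p0, branches)


# ---------------------------------------------------------------------------
# population solver


def _gaussian_convolved_mode(lam, dt, sigma):
    """exp(lam*t) * step(t), convolved with a unit-area Gaussian of width
    sigma, evaluated at t = dt.

    Uses the identity  EMG(t) = 0.5 * exp(-t^2 / (2 sigma^2)) * erfcx(b)
    with b = -(t/sigma + lam*sigma)/sqrt(2), which never overflows.
    """
    dt = np.asarray(dt, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), dt.shape)
    out = np.zeros(dt.shape, dtype=complex if np.iscomplexobj(lam) else float)
    zero = sigma == 0.0
    if np.any(zero):
        d = dt[zero]
        step = np.where(d >= 0, np.exp(lam * d), 0.0)
        out[zero] = step
    if np.any(~zero):
        d = dt[~zero]
        s = sigma[~zero]
        b = -(d / s + lam * s) / np.sqrt(2.0)
        gauss = np.exp(-(d**2) / (2.0 * s**2))
        cplx = np.iscomplexobj(np.asarray(lam))

        def ecx(z):
            return wofz(1j * z) if cplx else erfcx(z)

        res = np.empty(d.shape, dtype=complex if cplx else float)
        # erfcx grows as 2 exp(b^2) for b << 0; split off that term analytically:
        # 0.5 erfcx(b) exp(-d^2/2s^2) = exp(lam d + lam^2 s^2 / 2) - 0.5 erfcx(-b) exp(-d^2/2s^2)
        neg = (b.real if cplx else b) < 0
        if np.any(neg):
            res[neg] = (
                np.exp(lam * d[neg] + 0.5 * lam**2 * s[neg] ** 2)
                - 0.5 * ecx(-b[neg]) * gauss[neg]
            )
        if np.any(~neg):
            res[~neg] = 0.5 * ecx(b[~neg]) * gauss[~neg]
        out[~zero] = res
    return out


def _eigensystem(k: np.ndarray):
    lam, v = np.linalg.eig(k)
    if np.allclose(k, np.tril(k)):
        # chains/trees give triangular K: eigenvalues are exactly the diagonal
        lam = lam.real.astype(complex)
        v = v.astype(complex)
    return lam, v


def solve_populations(
    scheme: KineticScheme,
    times,
    irf: InstrumentResponse | None = None,
    irf_sigma_per_time=None,
) -> ConcentrationMatrix:
    """Analytic populations of every compartment on ``times`` (seconds).

    Each eigenmode of the rate matrix is convolved with the Gaussian IRF in
    closed form.  ``irf_sigma_per_time`` optionally supplies a per-time-point
    IRF width (seconds), as arises after merging instruments with different
    time resolution; it overrides ``irf.width_sigma`` but not the center.
    If the rate matrix is defective (non-diagonalizable within tolerance)
    the solver falls back to adaptive ODE integration convolved numerically,
    and flags it in the result metadata.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or not np.all(np.isfinite(times)):
        raise InvalidParameterError("times must be a finite 1-D array")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise InvalidParameterError("times must be strictly increasing")

    t0 = irf.center_time if irf is not None else 0.0
    if irf_sigma_per_time is not None:
        sigma = np.asarray(irf_sigma_per_time, dtype=float)
        if sigma.shape != times.shape:
            raise InvalidParameterError("irf_sigma_per_time must match times")
    else:
        sigma = np.broadcast_to(irf.effective_sigma if irf is not None else 0.0, times.shape)

    k = scheme.rate_matrix.copy()
    meta: dict = {}

    lam, v = _eigensystem(k)
    cond = np.linalg.cond(v)
    scale = max(np.abs(lam).max(), 1.0)
    if not np.isfinite(cond) or cond > 1e10:
        dist = np.abs(lam[:, None] - lam[None, :])
        np.fill_diagonal(dist, np.inf)
        if dist.min() < 1e-9 * scale:
            # defective repeated eigenvalues: jitter the diagonal rather
            # than implement the confluent closed form
            warnings.warn(
                "near-degenerate eigenvalues; applying 1e-6 relative jitter",
                RuntimeWarning,
                stacklevel=2,
            )
            jitter = 1e-6 * scale * (np.arange(k.shape[0]) + 1)
            k = k - np.diag(jitter)
            lam, v = _eigensystem(k)
            cond = np.linalg.cond(v)
            meta["eigenvalue_jitter"] = True

    if not np.isfinite(cond) or cond > 1e10:
        pops = _solve_populations_ode(scheme, times, t0, sigma)
        meta["method"] = "ode_fallback"
        return ConcentrationMatrix(times, pops, scheme.compartment_names, meta)

    c = np.linalg.solve(v, scheme.initial_vector.astype(complex))
    dt = times - t0
    modes = np.empty((times.size, lam.size), dtype=complex)
    for m in range(lam.size):
        modes[:, m] = _gaussian_convolved_mode(lam[m], dt, sigma)
    pops = (modes * c[None, :]) @ v.T
    pops = np.ascontiguousarray(pops.real)
    meta["method"] = "eigen"
    return ConcentrationMatrix(times, pops, scheme.compartment_names, meta)


def _solve_populations_ode(scheme, times, t0, sigma):
    """Adaptive ODE fallback; the IRF is applied by Gauss-Hermite quadrature
    over the excitation time."""
    k = scheme.rate_matrix
    p0 = scheme.initial_vector

    def rhs(_t, p):
        return k @ p

    def step_solution(ts):
        ts = np.asarray(ts)
        out = np.zeros((ts.size, p0.size))
        pos = ts > 0
        if np.any(pos):
            tgrid = np.sort(ts[pos])
            sol = solve_ivp(
                rhs, (0.0, tgrid[-1]), p0, t_eval=tgrid, method="LSODA",
                rtol=1e-10, atol=1e-12,
            )
            order = np.argsort(ts[pos])
            res = np.empty((pos.sum(), p0.size))
            res[order] = sol.y.T
            out[pos] = res
        out[ts == 0] = p0
        return out

    dt = times - t0
    if np.all(sigma == 0):
        return step_solution(dt)
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    pops = np.zeros((times.size, p0.size))
    for i, (d, s) in enumerate(zip(dt, sigma)):
        if s == 0:
            pops[i] = step_solution(np.array([d]))[0]
        else:
            shifted = d - s * nodes
            vals = step_solution(shifted)
            pops[i] = (weights[:, None] * vals).sum(axis=0) / np.sqrt(2 * np.pi)
    return pops


def flux_fraction(scheme: KineticScheme, compartment: str) -> float:
    """Time-integrated fraction of the initial excitation entering
    ``compartment`` (entry fluxes plus any initial population there).

    Computed analytically from the transient sub-system: for compartments
    with non-zero outflow, the time integrals x satisfy K_TT x = -p0_T.
    """
    c = scheme.index(compartment)
    k = scheme.rate_matrix
    n = scheme.n_compartments
    transient = [j for j in range(n) if scheme.outflow(j) > 0.0]
    x = np.zeros(n)
    if transient:
        ktt = k[np.ix_(transient, transient)]
        x[transient] = np.linalg.solve(ktt, -scheme.initial_vector[transient])
    entry = float(scheme.initial_vector[c])
    for j in range(n):
        if j != c:
            entry += k[c, j] * x[j]
    return entry
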