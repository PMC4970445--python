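"""Synthetic instrument emulation with embedded ground truth.

Every input the pipeline consumes can be generated here: transient
absorption matrices for a fast (~1 ps - 2.6 ns, 0.2 ps resolution) and a
slow (~0.5 ns - 2 us, 0.5 ns resolution) pump-probe window over
475-725 nm, single-wavelength 696 nm flash-photolysis transients, binding
titrations, and steady-state progress curves.  Difference spectra are sums
of Gaussian bands: every excited compartment carries the ground-state
bleach near 642 nm plus a broad excited-state absorption, and the
hydride-transfer intermediate carries its characteristic positive band at
696 nm.  Band placements other than the 642/696 nm centers are generator
conventions, not measured shapes.

All generators are seeded and embed their full ground truth in the output
metadata so downstream recovery tests need no external files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibrium import ProgressCurve, Titration, morrison_bound_fraction
from .errors import ContractError, InvalidParameterError
from .schemes import (
    InstrumentResponse,
    KineticScheme,
    build_branched_scheme,
    build_sequential_scheme,
    solve_populations,
)
from .ta_preprocess import ChirpModel, TASpectraSet
from .transient_fit import FlashTransient, intermediate_time_course

__all__ = [
    "GaussianBand",
    "SpeciesSpectralModel",
    "InstrumentPreset",
    "NoiseSpec",
    "make_pchlide_spectral_model",
    "wildtype_branched_scheme",
    "variant_sequential_scheme",
    "preset_pair",
    "simulate_ta_pair",
    "simulate_flash_transient",
    "simulate_titration",
    "simulate_progress_curve",
    "DEFAULT_EXTINCTION",
]

#: product extinction x pathlength used by the progress-curve fixtures,
#: in mAbs per molar (69 mM^-1 cm^-1 in a 1 cm cuvette).
DEFAULT_EXTINCTION = 6.9e7

#: lifetimes of the photochemistry-deficient variant preset (seconds):
#: ICT solvation (ps), decay into the triplet state (ns), triplet
#: relaxation back to ground (us).
VARIANT_SEQUENTIAL_LIFETIMES = (4e-12, 2e-9, 1.5e-6)
VARIANT_COMPARTMENTS = ("excited", "ICT_solvated", "triplet")


@dataclass(frozen=True)
class GaussianBand:
    """One spectral band: center (nm), width sigma (nm), amplitude (mAbs)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidParameterError("band width must be > 0")

    def __call__(self, wavelengths) -> np.ndarray:
        w = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((w - self.center) / self.width) ** 2)


@dataclass
class SpeciesSpectralModel:
    """Per-compartment Gaussian band sets.  Compartments absent from
    ``bands`` (ground-state sinks) have a zero difference spectrum."""

    bands: dict[str, list[GaussianBand]]

    def __post_init__(self) -> None:
        for comp, blist in self.bands.items():
            if not blist:
                raise InvalidParameterError(f"compartment {comp!r} needs >= 1 band")

    def matrix(self, wavelengths, compartment_names) -> np.ndarray:
        """Species spectra stacked as (compartment x wavelength), mAbs."""
        w = np.asarray(wavelengths, dtype=float)
        out = np.zeros((len(compartment_names), w.size))
        for i, name in enumerate(compartment_names):
            for band in self.bands.get(name, []):
                out[i] += band(w)
        return out

    def to_dict(self) -> dict:
        return {
            comp: [[b.center, b.width, b.amplitude] for b in blist]
            for comp, blist in self.bands.items()
        }


@dataclass(frozen=True)
class InstrumentPreset:
    """Sampling description of one pump-probe instrument window."""

    label: str
    time_range: tuple[float, float]
    n_times: int
    sampling: str
    irf: InstrumentResponse
    wavelength_range: tuple[float, float] = (475.0, 725.0)
    n_wavelengths: int = 64
    pre_time_range: tuple[float, float] | None = None
    n_pre_times: int = 6

    def __post_init__(self) -> None:
        if self.time_range[1] <= self.time_range[0] or self.wavelength_range[1] <= self.wavelength_range[0]:
            raise InvalidParameterError("ranges must have positive width")
        if self.n_times < 8 or self.n_wavelengths < 8:
            raise InvalidParameterError("need at least 8 samples per axis")
        if self.sampling not in ("log", "random"):
            raise InvalidParameterError(f"unknown sampling {self.sampling!r}")

    @classmethod
    def fast(cls, **overrides) -> "InstrumentPreset":
        kw = dict(
            label="fast",
            time_range=(1e-12, 2.6e-9),
            n_times=120,
            sampling="log",
            irf=InstrumentResponse(center_time=0.0, width_sigma=0.2e-12),
            pre_time_range=(-3e-12, -1e-12),
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def slow(cls, **overrides) -> "InstrumentPreset":
        kw = dict(
            label="slow",
            time_range=(0.5e-9, 2e-6),
            n_times=110,
            sampling="log",
            irf=InstrumentResponse(center_time=0.0, width_sigma=0.5e-9),
            pre_time_range=(-30e-9, -5e-9),
        )
        kw.update(overrides)
        return cls(**kw)

    def time_grid(self, rng: np.random.Generator | None = None) -> np.ndarray:
        lo, hi = self.time_range
        if self.sampling == "log":
            main = np.geomspace(lo, hi, self.n_times)
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            main = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), self.n_times)))
        if self.pre_time_range is not None:
            pre = np.linspace(*self.pre_time_range, self.n_pre_times)
            main = np.concatenate([pre, main])
        return main

    def wavelength_grid(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_wavelengths)


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded additive Gaussian noise; ``relative=True`` scales ``sigma``
    by the peak |signal| of the noiseless trace."""

    sigma: float = 0.0
    seed: int = 0
    relative: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("noise sigma must be >= 0")

    def absolute_sigma(self, signal: np.ndarray) -> float:
        if not self.relative:
            return self.sigma
        peak = float(np.abs(signal).max(initial=0.0))
        return self.sigma * peak


_BLEACH = GaussianBand(642.0, 12.0, -8.0)

_SPECTRAL_PRESETS = {
    "wildtype_branched": {
        "S_ICT": [_BLEACH, GaussianBand(510.0, 40.0, 6.0)],
        "ICT_solvated": [_BLEACH, GaussianBand(535.0, 45.0, 5.0)],
        "ICT_reactive": [_BLEACH, GaussianBand(500.0, 38.0, 6.5)],
        "I696": [_BLEACH, GaussianBand(696.0, 14.0, 5.0)],
    },
    "variant_sequential": {
        "excited": [_BLEACH, GaussianBand(505.0, 40.0, 6.0)],
        "ICT_solvated": [_BLEACH, GaussianBand(540.0, 45.0, 5.5)],
        "triplet": [_BLEACH, GaussianBand(520.0, 30.0, 4.0)],
    },
}


def make_pchlide_spectral_model(preset_name: str) -> SpeciesSpectralModel:
    """Documented band sets for the wild-type branched photocycle (with the
    696 nm intermediate band) or the photochemistry-deficient sequential
    preset (no band anywhere near 696 nm)."""
    try:
        bands = _SPECTRAL_PRESETS[preset_name]
    except KeyError:
        raise KeyError(
            f"unknown spectral preset {preset_name!r}; "
            f"have {sorted(_SPECTRAL_PRESETS)}"
        ) from None
    return SpeciesSpectralModel({c: list(b) for c, b in bands.items()})


def wildtype_branched_scheme(catalytic_fraction: float = 0.4) -> KineticScheme:
    return build_branched_scheme(catalytic_fraction)


def variant_sequential_scheme() -> KineticScheme:
    return build_sequential_scheme(
        VARIANT_SEQUENTIAL_LIFETIMES, names=VARIANT_COMPARTMENTS
    )


def preset_pair(preset_name: str) -> tuple[KineticScheme, SpeciesSpectralModel]:
    """Scheme + spectral model for a named study preset."""
    if preset_name == "wildtype_branched":
        return wildtype_branched_scheme(), make_pchlide_spectral_model(preset_name)
    if preset_name == "variant_sequential":
        return variant_sequential_scheme(), make_pchlide_spectral_model(preset_name)
    raise KeyError(f"unknown preset {preset_name!r}")


def _simulate_one(
    scheme: KineticScheme,
    spectra: SpeciesSpectralModel,
    preset: InstrumentPreset,
    noise: NoiseSpec,
    rng: np.random.Generator,
    chirp: ChirpModel | None,
) -> TASpectraSet:
    times = preset.time_grid(rng if preset.sampling == "random" else None)
    wavelengths = preset.wavelength_grid()
    bmat = spectra.matrix(wavelengths, scheme.compartment_names)
    conc = solve_populations(scheme, times, preset.irf)
    ideal = conc.populations @ bmat
    if chirp is not None and preset.label == "fast":
        shifts = chirp.shift(wavelengths)
        for j, dt in enumerate(shifts):
            if dt == 0.0:
                continue
            # the chirped instrument samples wavelength j at t - shift
            cj = solve_populations(scheme, times - dt, preset.irf)
            ideal[:, j] = cj.populations @ bmat[:, j]
    sigma = noise.absolute_sigma(ideal)
    mat = ideal + rng.normal(0.0, sigma, ideal.shape) if sigma > 0 else ideal.copy()
    truth = {
        "scheme": scheme.to_dict(),
        "spectra": spectra.to_dict(),
        "chirp": None if chirp is None else list(chirp.coefficients),
        "chirp_reference_wavelength": None if chirp is None else chirp.reference_wavelength,
        "noise_sigma": sigma,
        "instrument_tag": preset.label,
    }
    return TASpectraSet(
        wavelengths=wavelengths,
        times=times,
        delta_A=mat,
        instrument_tag=preset.label,
        irf=preset.irf,
        metadata={"truth": truth, "ideal": ideal, "populations": conc.populations},
        provenance_log=[f"simulate({preset.label}, seed={noise.seed})"],
    )


def simulate_ta_pair(
    scheme: KineticScheme,
    spectra: SpeciesSpectralModel,
    fast: InstrumentPreset | None = None,
    slow: InstrumentPreset | None = None,
    noise: NoiseSpec = NoiseSpec(),
    chirp: ChirpModel | None = None,
) -> tuple[TASpectraSet, TASpectraSet]:
    """Simulate one photocycle on both instrument windows.

    dA(t, lambda) = populations x species spectra on each preset's grid,
    convolved with each preset's IRF; optional chirp is injected into the
    fast window only; seeded Gaussian noise is added last.
    """
    unknown = set(spectra.bands) - set(scheme.compartment_names)
    if unknown:
        raise ContractError(
            f"spectral model names compartments not in the scheme: {sorted(unknown)}"
        )
    fast = fast or InstrumentPreset.fast()
    slow = slow or InstrumentPreset.slow()
    rng = np.random.default_rng(noise.seed)
    ds_fast = _simulate_one(scheme, spectra, fast, noise, rng, chirp)
    ds_slow = _simulate_one(scheme, spectra, slow, noise, rng, None)
    return ds_fast, ds_slow


def default_transient_grid(
    t_min: float = 1e-9, t_max: float = 2e-4, n: int = 600
) -> np.ndarray:
    """Log-spaced flash-photolysis time grid covering both phases."""
    return np.geomspace(t_min, t_max, n)


def simulate_flash_transient(
    k_hydride: float,
    k_proton: float,
    amplitude: float,
    times: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> FlashTransient:
    """696 nm transient of the hydride-transfer intermediate with seeded
    noise; requires ``k_hydride > k_proton > 0`` and ``amplitude >= 0``."""
    if not (k_hydride > k_proton > 0):
        raise ContractError(
            f"require k_hydride > k_proton > 0, got {k_hydride:g}, {k_proton:g}"
        )
    if amplitude < 0:
        raise ContractError("amplitude must be >= 0")
    if times is None:
        times = default_transient_grid()
    ideal = intermediate_time_course(times, amplitude, k_hydride, k_proton)
    sigma = noise.absolute_sigma(ideal)
    rng = np.random.default_rng(noise.seed)
    y = ideal + rng.normal(0.0, sigma, ideal.shape) if sigma > 0 else ideal.copy()
    return FlashTransient(
        times=np.asarray(times, dtype=float),
        delta_A=y,
        n_averaged=1,
        metadata={
            "truth": {
                "k_hydride": k_hydride,
                "k_proton": k_proton,
                "amplitude_696": amplitude,
                "noise_sigma": sigma,
            }
        },
    )


def simulate_titration(
    kd: float,
    e_total: float = 10e-9,
    points: int = 10,
    noise: NoiseSpec = NoiseSpec(),
    model: str = "quadratic",
    signal_max: float = 1.0,
    signal_offset: float = 0.0,
    signal_kind: str = "FRET",
) -> Titration:
    """Log-spaced ligand titration (0.05-20 x Kd) with the exact
    tight-binding bound fraction as the noiseless signal.

    The default macromolecule concentration (10 nM) keeps the titration in
    a regime where the dissociation constant is identifiable: with the
    enzyme far above Kd the curve collapses onto the stoichiometric limit
    and carries almost no Kd information.  Ligand depletion remains
    non-negligible at the low end of the series, so the tight-binding
    quadratic is still the correct fitting model.
    """
    if kd <= 0 or e_total <= 0:
        raise ContractError("kd and e_total must be > 0")
    if points < 6:
        raise ContractError("need at least 6 titration points")
    if model != "quadratic":
        raise ContractError(f"unknown titration model {model!r}")
    ligand = np.geomspace(0.05 * kd, 20.0 * kd, points)
    ideal = signal_offset + signal_max * morrison_bound_fraction(e_total, ligand, kd)
    sigma = noise.absolute_sigma(ideal - signal_offset)
    rng = np.random.default_rng(noise.seed)
    y = ideal + rng.normal(0.0, sigma, ideal.shape) if sigma > 0 else ideal.copy()
    return Titration(
        ligand_total=ligand,
        signal=y,
        macromolecule_total=e_total,
        signal_kind=signal_kind,
        metadata={
            "truth": {
                "kd": kd,
                "e_total": e_total,
                "signal_max": signal_max,
                "signal_offset": signal_offset,
                "noise_sigma": sigma,
            }
        },
    )


def simulate_progress_curve(
    kcat: float,
    e_total: float = 0.1e-6,
    duration: float = 600.0,
    noise: NoiseSpec = NoiseSpec(),
    extinction_pathlength: float = DEFAULT_EXTINCTION,
    n_points: int = 61,
) -> ProgressCurve:
    """Linear product accumulation at rate kcat * e_total, reported in mAbs
    through the fixture extinction/pathlength factor."""
    if kcat < 0 or e_total <= 0:
        raise ContractError("kcat must be >= 0 and e_total > 0")
    if duration <= 0:
        raise ContractError("duration must be > 0")
    times = np.linspace(0.0, duration, n_points)
    ideal = extinction_pathlength * kcat * e_total * times
    sigma = noise.absolute_sigma(ideal)
    rng = np.random.default_rng(noise.seed)
    y = ideal + rng.normal(0.0, sigma, ideal.shape) if sigma > 0 else ideal.copy()
    return ProgressCurve(
        times=times,
        product_signal=y,
        extinction_pathlength=extinction_pathlength,
        enzyme_total=e_total,
        metadata={
            "truth": {
                "kcat": kcat,
                "e_total": e_total,
                "extinction_pathlength": extinction_pathlength,
                "noise_sigma": sigma,
            }
        },
    )
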