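"""Beer-Lambert forward simulator for seawater UV absorbance spectra.

A measured spectrum is modelled as

    A(lambda) = b * (eps_no3 * C_no3 + eps_no2 * C_no2 + eps_salt * S)
                + A_cdom(lambda) + noise

with ``b`` the cuvette pathlength (cm), concentrations in mol/L (the public
API takes uM and converts internally), salinity in psu, and the CDOM
(chromophoric dissolved organic matter) background the exponential

    A_cdom(lambda) = a0 * exp(s * (lambda0 - lambda)) + k.

The CDOM term is an absorbance measured through the same cuvette and sits
outside the pathlength factor; a flag allows the alternative placement inside
``b`` for sensitivity analysis.

The bundled molar-absorptivity curves are parametric surrogates (Gaussian
bands for the nitrate and nitrite deep-UV absorption, an exponential decay
for sea salt) chosen so that the three components overlap strongly over
200-240 nm -- the deconvolution difficulty the calibration method exists to
solve. They are generator plumbing, not calibrated physical constants: all
downstream validation is on recovery of known simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .reference import reference_design
from .spectra import AbsorbanceSpectrum, Composition, SpectraSet, WavelengthGrid

__all__ = [
    "ComponentLibrary",
    "CDOMParams",
    "NoiseSpec",
    "default_grid",
    "default_library",
    "cdom_absorbance",
    "gaussian_interferent",
    "simulate_spectrum",
    "simulate_dataset",
    "default_cdom_sampler",
    "SimulatedDataset",
    "reference_design",
]

DEFAULT_NOISE_SD = 5e-4  # AU; typical dual-beam photometric noise
DEFAULT_PATHLENGTH = 3.0  # cm quartz cuvette


def default_grid(lo: float = 200.0, hi: float = 300.0, spacing: float = 1.0) -> WavelengthGrid:
    """The instrument's acquisition grid: 200-300 nm at 1 nm resolution."""
    n = int(round((hi - lo) / spacing)) + 1
    return WavelengthGrid(lo + spacing * np.arange(n))


@dataclass
class ComponentLibrary:
    """Absorptivity curves of the three modelled absorbers on a shared grid.

    ``eps_no3`` and ``eps_no2`` are molar absorptivities (L mol^-1 cm^-1);
    ``eps_salt`` is a per-salinity-unit absorptivity (psu^-1 cm^-1). All three
    absorb in the deep UV: each curve peaks below 230 nm.
    """

    grid: WavelengthGrid
    eps_no3: np.ndarray
    eps_no2: np.ndarray
    eps_salt: np.ndarray

    def __post_init__(self) -> None:
        for name in ("eps_no3", "eps_no2", "eps_salt"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (len(self.grid),):
                raise ValueError(f"{name} length does not match grid")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} must be non-negative and finite")
            peak_nm = self.grid.values[int(np.argmax(v))]
            if peak_nm >= 230.0:
                raise ValueError(
                    f"{name} peaks at {peak_nm} nm; all modelled absorbers are "
                    "deep-UV (peak < 230 nm)"
                )
            setattr(self, name, v)

    def window(self, lo: float, hi: float) -> "ComponentLibrary":
        sl = self.grid.window_slice(lo, hi)
        return ComponentLibrary(
            self.grid.restrict(lo, hi),
            self.eps_no3[sl],
            self.eps_no2[sl],
            self.eps_salt[sl],
        )

    def as_matrix(self) -> np.ndarray:
        """m x 3 matrix of curves in response order (no3, no2, salinity)."""
        return np.column_stack([self.eps_no3, self.eps_no2, self.eps_salt])


@dataclass(frozen=True)
class CDOMParams:
    """Exponential CDOM background: a0*exp(s*(lambda0 - lambda)) + k.

    a0 is the CDOM absorbance at the reference wavelength lambda0 (default
    300 nm), s the spectral slope (nm^-1), k a background offset absorbing
    cuvette scattering and instrument drift. Values are unconstrained here
    (fitters may return slightly negative estimates); generator inputs are
    validated in :func:`simulate_spectrum`.
    """

    a0: float
    s: float
    k: float = 0.0
    lambda0: float = 300.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive homoscedastic Gaussian instrument noise."""

    sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def default_library(
    g: WavelengthGrid,
    *,
    no3_center: float = 205.0,
    no3_sd: float = 11.0,
    no3_peak: float = 9600.0,
    no2_center: float = 210.0,
    no2_sd: float = 13.0,
    no2_peak: float = 5400.0,
    salt_ref: float = 0.02,
    salt_decay: float = 8.0,
) -> ComponentLibrary:
    """Surrogate absorptivity library on grid ``g`` (must cover 200-300 nm).

    Nitrate: Gaussian band centred at 205 nm (sd 11 nm, peak 9600 L/mol/cm).
    Nitrite: Gaussian band centred at 210 nm (sd 13 nm, peak 5400 L/mol/cm).
    Sea salt: exponential decay exp(-(lambda-200)/8), 0.02 psu^-1 cm^-1 at
    200 nm. All parameters configurable.
    """
    if g.lo > 200.0 + 1e-9 or g.hi < 300.0 - 1e-9:
        raise ValueError(
            f"default library requires a grid covering 200-300 nm, got "
            f"[{g.lo}, {g.hi}]"
        )
    lam = g.values
    eps_no3 = no3_peak * np.exp(-0.5 * ((lam - no3_center) / no3_sd) ** 2)
    eps_no2 = no2_peak * np.exp(-0.5 * ((lam - no2_center) / no2_sd) ** 2)
    eps_salt = salt_ref * np.exp(-(lam - 200.0) / salt_decay)
    return ComponentLibrary(g, eps_no3, eps_no2, eps_salt)


def cdom_absorbance(params: CDOMParams, wavelengths: np.ndarray) -> np.ndarray:
    lam = np.asarray(wavelengths, dtype=float)
    return params.a0 * np.exp(params.s * (params.lambda0 - lam)) + params.k


def gaussian_interferent(
    grid: WavelengthGrid, amplitude: float, center: float = 225.0, sd: float = 10.0
) -> np.ndarray:
    """Absorbance of an unmodelled Gaussian-band absorber (AU at its peak)."""
    return amplitude * np.exp(-0.5 * ((grid.values - center) / sd) ** 2)


def simulate_spectrum(
    c: Composition,
    lib: ComponentLibrary,
    cdom: CDOMParams | None = None,
    noise: NoiseSpec | None = None,
    pathlength: float = DEFAULT_PATHLENGTH,
    sample_id: str = "",
    extra_absorbance: np.ndarray | None = None,
    cdom_inside_pathlength: bool = False,
) -> AbsorbanceSpectrum:
    """Forward-simulate one spectrum from a composition.

    Concentrations are uM (converted to mol/L internally before multiplying
    the molar-absorptivity curves); salinity multiplies the per-psu curve
    directly. ``extra_absorbance`` adds an arbitrary unmodelled background
    (e.g. an interferent band). Reproducible for a fixed noise seed.
    """
    for name, val in zip(Composition.names(), c.as_array()):
        if val < 0:
            raise ValueError(f"generator composition must be >= 0, got {name}={val}")
    if pathlength <= 0:
        raise ValueError("pathlength must be > 0 cm")
    mix = lib.as_matrix() @ np.array([c.no3 * 1e-6, c.no2 * 1e-6, c.salinity])
    a = pathlength * mix
    if cdom is not None:
        if cdom.a0 < 0 or cdom.s <= 0:
            raise ValueError("generator CDOM requires a0 >= 0 and s > 0")
        bg = cdom_absorbance(cdom, lib.grid.values)
        a = a + (pathlength * bg if cdom_inside_pathlength else bg)
    if extra_absorbance is not None:
        extra = np.asarray(extra_absorbance, dtype=float)
        if extra.shape != (len(lib.grid),):
            raise ValueError("extra_absorbance length does not match grid")
        a = a + extra
    if noise is not None and noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        a = a + rng.normal(0.0, noise.sd, size=a.shape)
    return AbsorbanceSpectrum(lib.grid, a, pathlength=pathlength, sample_id=sample_id)


def default_cdom_sampler(rng: np.random.Generator) -> CDOMParams:
    """Per-sample CDOM draw emulating estuarine variability.

    a0 ~ U(0.01, 0.1) AU at 300 nm and s ~ U(0.014, 0.03) nm^-1 follow the
    range reported for coastal/estuarine CDOM; k ~ U(0, 0.005) AU emulates
    small cuvette/drift offsets.
    """
    return CDOMParams(
        a0=rng.uniform(0.01, 0.1),
        s=rng.uniform(0.014, 0.03),
        k=rng.uniform(0.0, 0.005),
    )


@dataclass
class SimulatedDataset:
    """A simulated SpectraSet plus the per-sample truth used to build it."""

    spectra: SpectraSet
    cdom: list[CDOMParams | None] = field(default_factory=list)


def simulate_dataset(
    design: Sequence[Composition],
    lib: ComponentLibrary | None = None,
    cdom: CDOMParams | Callable[[np.random.Generator], CDOMParams] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    pathlength: float = DEFAULT_PATHLENGTH,
    id_prefix: str = "s",
    extra_sampler: Callable[[np.random.Generator, WavelengthGrid], np.ndarray] | None = None,
) -> SimulatedDataset:
    """Simulate one spectrum per design composition.

    ``cdom`` may be fixed :class:`CDOMParams`, a sampler drawing per-sample
    parameters from an rng (see :func:`default_cdom_sampler`), or None for a
    CDOM-free dataset. The per-sample CDOM truth is returned alongside the
    spectra. All randomness (CDOM draws, interferent draws, noise) derives
    from ``seed``.
    """
    design = list(design)
    if not design:
        raise ValueError("design must contain at least one composition")
    if lib is None:
        lib = default_library(default_grid())
    rng = np.random.default_rng(seed)
    spectra: list[AbsorbanceSpectrum] = []
    cdom_log: list[CDOMParams | None] = []
    for i, comp in enumerate(design):
        params = cdom(rng) if callable(cdom) else cdom
        extra = extra_sampler(rng, lib.grid) if extra_sampler is not None else None
        noise = NoiseSpec(noise_sd, seed=int(rng.integers(0, 2**31 - 1)))
        spectra.append(
            simulate_spectrum(
                comp,
                lib,
                cdom=params,
                noise=noise,
                pathlength=pathlength,
                sample_id=f"{id_prefix}{i + 1:02d}",
                extra_absorbance=extra,
            )
        )
        cdom_log.append(params)
    return SimulatedDataset(SpectraSet(spectra, compositions=design), cdom_log)
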