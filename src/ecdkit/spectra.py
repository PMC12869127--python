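"""Spectral engine: Gaussian band broadening and spectral algebra.

Calculated electronic circular dichroism (ECD) spectra are obtained by
assigning a Gaussian band shape to each electronic transition's rotational
strength.  The band width is specified as a half-width at half-maximum
(HWHM) on the wavelength axis; the conventional value for small peptides
is 10 nm.  Because the downstream population fit compares spectral
*shapes* (a scale-invariant cosine objective), the Gaussian carries a unit
prefactor and no absolute intensity calibration is attempted.

Broadening is performed directly on the wavelength axis (not the energy /
wavenumber axis).  With a scale-invariant fitting objective and a fixed
10-nm HWHM this is a documented convention, not a physical claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks


class GridMismatchError(ValueError):
    """Two spectra were combined or compared on different wavelength grids."""


@dataclass(frozen=True)
class Spectrum:
    """A signal sampled on a strictly ascending wavelength grid (nm).

    Parameters
    ----------
    wavelengths_nm :
        Strictly increasing wavelength grid in nanometres.
    values :
        Signal values, one per grid point.  Units are tracked by ``unit``.
    unit :
        One of ``"delta_epsilon"`` (molar CD, L mol^-1 cm^-1),
        ``"millidegrees"`` (raw ellipticity) or ``"arbitrary"``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    unit: str = "arbitrary"

    VALID_UNITS = ("delta_epsilon", "millidegrees", "arbitrary")

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equally long")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if self.unit not in self.VALID_UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.wavelengths_nm, other.wavelengths_nm, atol=atol, rtol=0.0)
        )

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, values, unit or self.unit)

    def norm(self) -> float:
        """Euclidean norm of the value vector over the grid."""
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class TransitionSet:
    """Electronic transitions: excitation wavelengths (nm) and rotational strengths.

    Rotational strengths are in arbitrary but mutually consistent (cgs-like)
    units; only relative magnitudes and signs matter for shape fitting.
    """

    wavelengths_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    strengths: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        st = np.asarray(self.strengths, dtype=float)
        if wl.shape != st.shape or wl.ndim != 1:
            raise ValueError("wavelengths and strengths must be equal-length 1-D")
        if np.any(wl <= 0):
            raise ValueError("transition wavelengths must be positive")
        order = np.argsort(wl, kind="stable")
        object.__setattr__(self, "wavelengths_nm", wl[order])
        object.__setattr__(self, "strengths", st[order])

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


@dataclass(frozen=True)
class BroadeningSettings:
    """Gaussian broadening parameters.

    ``hwhm_nm`` is the half-width at half-maximum of each band; the Gaussian
    standard parameter is sigma = hwhm / sqrt(ln 2), so that the band value
    at ``center +- hwhm`` is exactly half the band maximum.  The default
    grid, 185-320 nm in 0.5-nm steps, covers the far-UV range accessible in
    aqueous solution.
    """

    hwhm_nm: float = 10.0
    grid_start_nm: float = 185.0
    grid_end_nm: float = 320.0
    grid_step_nm: float = 0.5

    def __post_init__(self) -> None:
        if self.hwhm_nm <= 0:
            raise ValueError("hwhm_nm must be positive")
        if self.grid_step_nm <= 0:
            raise ValueError("grid_step_nm must be positive")
        if self.grid_start_nm >= self.grid_end_nm:
            raise ValueError("grid_start_nm must be below grid_end_nm")

    @property
    def sigma_nm(self) -> float:
        return self.hwhm_nm / np.sqrt(np.log(2.0))

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_end_nm - self.grid_start_nm) / self.grid_step_nm))
        return self.grid_start_nm + self.grid_step_nm * np.arange(n + 1)


@dataclass(frozen=True)
class Band:
    """A signed spectral band: extremum position, sign and value."""

    center_nm: float
    sign: int  # +1 or -1
    extremum_value: float


def broaden(transitions: TransitionSet, settings: BroadeningSettings | None = None) -> Spectrum:
    """Convolve rotational strengths with Gaussian band shapes.

    The spectrum is ``sum_i R_i * exp(-((lambda - lambda_i) / sigma)^2)``
    with ``sigma = hwhm / sqrt(ln 2)``.  The operation is linear in the
    transition set; an empty set yields the zero spectrum.  The result
    carries the ``arbitrary`` unit tag — absolute scale is set later, if at
    all, by normalization.
    """
    settings = settings or BroadeningSettings()
    grid = settings.grid()
    if len(transitions) == 0:
        return Spectrum(grid, np.zeros_like(grid), "arbitrary")
    # (n_grid, n_transitions) Gaussian design summed over transitions
    diff = (grid[:, None] - transitions.wavelengths_nm[None, :]) / settings.sigma_nm
    values = np.exp(-(diff**2)) @ transitions.strengths
    return Spectrum(grid, values, "arbitrary")


def resample(spec: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = spec.wavelengths_nm[0], spec.wavelengths_nm[-1]
    if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
        raise ValueError(
            f"resampling grid [{grid.min():g}, {grid.max():g}] nm extends outside "
            f"the source range [{lo:g}, {hi:g}] nm"
        )
    values = np.interp(grid, spec.wavelengths_nm, spec.values)
    return Spectrum(grid, values, spec.unit)


def l2_normalize(spec: Spectrum) -> Spectrum:
    """Scale a spectrum to unit Euclidean norm (direction preserved)."""
    n = spec.norm()
    if n == 0.0:
        raise ValueError("cannot normalize an identically zero spectrum")
    return spec.with_values(spec.values / n, "arbitrary")


def similarity(a: Spectrum, b: Spectrum) -> float:
    """Cosine similarity of two spectra on a common grid, in [-1, 1].

    Symmetric and invariant under positive rescaling of either argument;
    negating one argument flips the sign.  This is the scale-invariant
    shape criterion used by the population fit.
    """
    if not a.same_grid(b):
        raise GridMismatchError("spectra are on different wavelength grids; resample first")
    na, nb = a.norm(), b.norm()
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero spectrum")
    return float(np.clip(np.dot(a.values, b.values) / (na * nb), -1.0, 1.0))


def peak_pick(spec: Spectrum, min_prominence: float = 0.0) -> list[Band]:
    """Locate signed bands: positive maxima and negative minima.

    Local maxima with positive value are reported as ``+`` bands and local
    minima with negative value as ``-`` bands, keeping only extrema whose
    prominence reaches ``min_prominence``.  Bands are listed in descending
    wavelength, the customary reading order of CD band tables.
    """
    if min_prominence < 0:
        raise ValueError("min_prominence must be >= 0")
    bands: list[Band] = []
    for sign, sig in ((+1, spec.values), (-1, -spec.values)):
        idx, _ = find_peaks(sig, prominence=min_prominence if min_prominence > 0 else None)
        for i in idx:
            if sig[i] > 0:  # band sign must match the sign of the extremum
                bands.append(
                    Band(float(spec.wavelengths_nm[i]), sign, float(spec.values[i]))
                )
    bands.sort(key=lambda band: -band.center_nm)
    return bands
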