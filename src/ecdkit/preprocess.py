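"""Measurement processing for CD scans.

Replicate averaging, solvent-baseline subtraction, and conversion of the
raw instrument ellipticity (millidegrees) to molar circular dichroism
Delta-epsilon.  Final experimental spectra are customarily the average of
several scans (five is typical) with the blank — distilled water or the
SDS solution — measured under identical conditions subtracted.

No smoothing or denoising is applied anywhere: averaging and subtraction
are the only transformations between instrument output and the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import GridMismatchError, Spectrum

#: mdeg per (L mol^-1 cm^-1 * mol L^-1 * cm): theta[mdeg] = 32980 * Delta_eps * c * l
MDEG_PER_DELTA_EPSILON = 32980.0


@dataclass
class MeasurementSeries:
    """Replicate CD scans of one sample under one condition.

    All scans must share a wavelength grid.  ``concentration_mol_per_L`` and
    ``pathlength_cm`` describe the cuvette contents (a 1-mm cell is 0.1 cm)
    and are used only by the unit conversion.
    """

    scans: list[Spectrum]
    concentration_mol_per_L: float = 1.0
    pathlength_cm: float = 0.1
    label: str = ""

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError("a measurement series needs at least one scan")
        first = self.scans[0]
        if any(not s.same_grid(first) for s in self.scans[1:]):
            raise GridMismatchError("all scans in a series must share one wavelength grid")
        if self.concentration_mol_per_L <= 0 or self.pathlength_cm <= 0:
            raise ValueError("concentration and pathlength must be positive")


def average_scans(series: MeasurementSeries) -> Spectrum:
    """Pointwise arithmetic mean of the replicate scans."""
    stack = np.stack([s.values for s in series.scans])
    return series.scans[0].with_values(stack.mean(axis=0))


def subtract_baseline(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Subtract a blank (solvent) spectrum measured under identical conditions."""
    if not sample.same_grid(blank):
        raise GridMismatchError("sample and blank are on different grids")
    return sample.with_values(sample.values - blank.values)


def mdeg_to_delta_epsilon(
    spec: Spectrum, concentration_mol_per_L: float, pathlength_cm: float
) -> Spectrum:
    """Convert raw ellipticity (mdeg) to Delta-epsilon (L mol^-1 cm^-1).

    Delta_eps(lambda) = theta_mdeg(lambda) / (32980 * c * l).
    """
    if concentration_mol_per_L <= 0 or pathlength_cm <= 0:
        raise ValueError("concentration and pathlength must be positive")
    if spec.unit not in ("millidegrees", "arbitrary"):
        raise ValueError(f"expected a millidegree spectrum, got unit {spec.unit!r}")
    factor = MDEG_PER_DELTA_EPSILON * concentration_mol_per_L * pathlength_cm
    return spec.with_values(spec.values / factor, "delta_epsilon")


def mg_ml_to_mol_per_L(concentration_mg_per_mL: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration (mg/mL) to molarity using the molar mass."""
    if concentration_mg_per_mL <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("concentration and molar mass must be positive")
    return concentration_mg_per_mL / molar_mass_g_per_mol
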