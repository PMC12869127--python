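"""Synthetic-data generators for every pipeline input.

The quantum-chemistry stage (conformer search + TD-DFT rotational
strengths) and the spectrometer are emulated by seeded generators:

* transition libraries standing in for per-conformer TD-DFT output,
* mixture spectra with known non-negative abundances, Gaussian noise and
  a slow half-sine baseline drift,
* replicate scans for averaging tests,
* peptide backbones built from prescribed (phi, psi) torsions by
  natural-extension (NeRF) placement with standard bond lengths/angles.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fit import ConformerRecord
from .geometry import BackboneMap
from .io import GeometryRecord
from .preprocess import MeasurementSeries
from .spectra import BroadeningSettings, Spectrum, TransitionSet, broaden


@dataclass(frozen=True)
class MixtureSpec:
    """Composition and noise model of a synthetic target spectrum.

    ``true_weights`` are the abundances of the first conformers of the
    library; ``noise_sigma`` is the Gaussian noise standard deviation as a
    fraction of the clean mixture's peak amplitude; the drift amplitude is
    in the same units as the spectrum.
    """

    true_weights: tuple[float, ...]
    noise_sigma: float = 0.0
    baseline_drift_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if np.any(w < 0) or w.sum() > 1.0 + 1e-12:
            raise ValueError("weights must be non-negative and sum to at most 1")
        if self.noise_sigma < 0 or self.baseline_drift_amplitude < 0:
            raise ValueError("noise and drift amplitudes must be >= 0")


@dataclass(frozen=True)
class BackboneBuildSpec:
    """Internal-coordinate recipe for an ideal peptide backbone.

    ``torsions`` holds one (phi, psi) pair per residue 2..n (n-1 pairs for
    n residues); the first residue's psi (``psi1_deg``) orients the first
    peptide unit but never enters the reported torsion table.  Bond lengths
    and angles are standard peptide values; the build only needs to be
    self-consistent for torsion round trips, not physically refined.
    """

    n_residues: int
    torsions: tuple[tuple[float, float], ...]
    omega_deg: float = 180.0
    psi1_deg: float = 140.0
    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.0
    angle_ca_c_n: float = 117.2
    angle_c_n_ca: float = 121.7
    c_terminal_amide: bool = True

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("at least 2 residues required")
        if len(self.torsions) != self.n_residues - 1:
            raise ValueError(
                f"{self.n_residues} residues need {self.n_residues - 1} (phi, psi) "
                f"pairs, got {len(self.torsions)}"
            )
        for b in (self.bond_n_ca, self.bond_ca_c, self.bond_c_n):
            if b <= 0:
                raise ValueError("bond lengths must be positive")
        for a in (self.angle_n_ca_c, self.angle_ca_c_n, self.angle_c_n_ca):
            if a <= 0:
                raise ValueError("bond angles must be positive")


def gen_transition_library(
    n_conformers: int = 20,
    n_transitions: int = 8,
    wavelength_range: tuple[float, float] = (190.0, 310.0),
    strength_scale: float = 10.0,
    seed: int = 0,
) -> list[ConformerRecord]:
    """A seeded library of conformers with random electronic transitions.

    Transition wavelengths are uniform over ``wavelength_range`` (which
    must lie within 180-330 nm, the far-UV window), rotational strengths
    normal with standard deviation ``strength_scale``, and relative
    energies uniform in [0, 3] kcal/mol.
    """
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    lo, hi = wavelength_range
    if not (180.0 <= lo < hi <= 330.0):
        raise ValueError("wavelength_range must be increasing and within 180-330 nm")
    rng = np.random.default_rng(seed)
    library = []
    width = len(str(n_conformers))
    for i in range(n_conformers):
        wl = rng.uniform(lo, hi, size=n_transitions)
        strengths = rng.normal(0.0, strength_scale, size=n_transitions)
        energy = rng.uniform(0.0, 3.0)
        library.append(
            ConformerRecord(
                id=f"conf-{i + 1:0{width}d}",
                rel_energy_kcal_mol=float(energy),
                transitions=TransitionSet(wl, strengths),
            )
        )
    return library


def gen_mixture_spectrum(
    library: list[ConformerRecord],
    spec: MixtureSpec,
    settings: BroadeningSettings | None = None,
) -> Spectrum:
    """Weighted conformer mixture plus optional baseline drift and noise.

    The clean part is sum_i w_i * broaden(conformer_i) over the first
    ``len(true_weights)`` library members; drift is a half-sine across the
    grid, noise is white Gaussian scaled by the clean peak amplitude.
    """
    settings = settings or BroadeningSettings()
    weights = np.asarray(spec.true_weights, dtype=float)
    if len(weights) > len(library):
        raise ValueError("more weights than library conformers")
    grid = settings.grid()
    values = np.zeros_like(grid)
    for w, rec in zip(weights, library):
        values += w * broaden(rec.transitions, settings).values
    if spec.baseline_drift_amplitude > 0:
        phase = (grid - grid[0]) / (grid[-1] - grid[0])
        values = values + spec.baseline_drift_amplitude * np.sin(np.pi * phase)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        peak = np.max(np.abs(values))
        values = values + rng.normal(0.0, spec.noise_sigma * peak, size=grid.size)
    return Spectrum(grid, values, "arbitrary")


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: new atom D with |C-D| = bond,
    angle(B,C,D) = angle and dihedral(A,B,C,D) = torsion (IUPAC sign)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(spec: BackboneBuildSpec) -> tuple[GeometryRecord, BackboneMap]:
    """Build an N/CA/C backbone (plus optional amide N) from torsions.

    Atoms are placed sequentially by internal coordinates; recomputing the
    torsions of the result returns the prescribed values (the round trip is
    exact to numerical precision).  Every peptide bond uses ``omega_deg``
    (default 180, trans).
    """
    n = spec.n_residues
    coords = [
        np.zeros(3),
        np.array([spec.bond_n_ca, 0.0, 0.0]),
    ]
    theta = np.radians(spec.angle_n_ca_c)
    coords.append(coords[1] + spec.bond_ca_c * np.array([-np.cos(theta), np.sin(theta), 0.0]))

    def idx(res: int, kind: int) -> int:  # kind 0=N, 1=CA, 2=C
        return 3 * (res - 1) + kind

    for k in range(2, n + 1):
        phi_k, _ = spec.torsions[k - 2]
        psi_prev = spec.psi1_deg if k == 2 else spec.torsions[k - 3][1]
        coords.append(
            _place_atom(
                coords[idx(k - 1, 0)], coords[idx(k - 1, 1)], coords[idx(k - 1, 2)],
                spec.bond_c_n, spec.angle_ca_c_n, psi_prev,
            )
        )
        coords.append(
            _place_atom(
                coords[idx(k - 1, 1)], coords[idx(k - 1, 2)], coords[idx(k, 0)],
                spec.bond_n_ca, spec.angle_c_n_ca, spec.omega_deg,
            )
        )
        coords.append(
            _place_atom(
                coords[idx(k - 1, 2)], coords[idx(k, 0)], coords[idx(k, 1)],
                spec.bond_ca_c, spec.angle_n_ca_c, phi_k,
            )
        )

    amide_index = None
    if spec.c_terminal_amide:
        psi_n = spec.torsions[n - 2][1]
        coords.append(
            _place_atom(
                coords[idx(n, 0)], coords[idx(n, 1)], coords[idx(n, 2)],
                spec.bond_c_n, spec.angle_ca_c_n, psi_n,
            )
        )
        amide_index = 3 * n

    symbols = []
    names = []
    resids = []
    for k in range(1, n + 1):
        symbols.extend(["N", "C", "C"])
        names.extend(["N", "CA", "C"])
        resids.extend([k, k, k])
    if amide_index is not None:
        symbols.append("N")
        names.append("NT")
        resids.append(n + 1)

    geom = GeometryRecord(symbols, np.asarray(coords), names, resids)
    backbone_map = BackboneMap(list(range(3 * n)), amide_index, source="explicit_indices")
    return geom, backbone_map


def backbone_from_torsion_table(
    pairs: list[tuple[float, float]], **kwargs
) -> tuple[GeometryRecord, BackboneMap]:
    """Convenience: an amidated (n+1)-residue backbone whose torsion table
    reproduces ``pairs`` (one (phi, psi) row per residue 2..n+1)."""
    spec = BackboneBuildSpec(
        n_residues=len(pairs) + 1, torsions=tuple(tuple(p) for p in pairs), **kwargs
    )
    return build_backbone(spec)


def gen_replicate_scans(
    truth: Spectrum, n_scans: int = 5, noise_sigma: float = 0.0, seed: int = 0
) -> MeasurementSeries:
    """``n_scans`` seeded noisy copies of a true spectrum on its own grid."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    scans = [
        truth.with_values(truth.values + rng.normal(0.0, noise_sigma, size=len(truth)))
        if noise_sigma > 0
        else truth
        for _ in range(n_scans)
    ]
    return MeasurementSeries(scans=list(scans))
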