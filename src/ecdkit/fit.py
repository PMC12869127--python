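"""Conformer population fitting against an experimental ECD spectrum.

A conformational search of a flexible peptide yields hundreds of stable
conformers; quantum-chemical ECD calculations are affordable only for the
lowest-energy few tens.  The question the fit answers is: which small
subset of calculated conformer spectra, mixed with non-negative
abundances, best reproduces the measured spectral *shape*?

The objective is purely mathematical: cosine similarity between the
weighted combination of broadened conformer spectra and the target
spectrum.  For each candidate subset the non-negative least-squares (NNLS)
solution is the Euclidean projection of the target onto the convex cone
spanned by the subset's spectra, which is also the cosine maximizer over
that cone.  All subsets up to ``max_subset_size`` are enumerated (at the
default 3 over a 20-conformer library that is 1350 small solves), so the
reported optimum is exact rather than greedy.

Abundances are the projection coefficients on the target's own intensity
scale and are constrained to sum to at most ``weight_sum_cap`` (default 1;
reported conformer populations need not exhaust the ensemble — the
remainder is unassigned minor conformers).  Subset choice, similarity and
abundance *ratios* are invariant under positive rescaling of the target;
the absolute abundances scale with it, so target and library should be on
comparable intensity scales when absolute populations are of interest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io import FitResult, GeometryRecord
from .spectra import BroadeningSettings, Spectrum, TransitionSet, broaden, resample

__all__ = [
    "ConformerRecord",
    "FitResult",
    "select_lowest_n",
    "boltzmann_weights",
    "fit_weights",
]

#: gas constant in kcal mol^-1 K^-1
R_KCAL_PER_MOL_K = 1.98720425e-3

_TOL = 1e-10


@dataclass
class ConformerRecord:
    """One conformer: identifier, relative energy and its electronic transitions."""

    id: str
    rel_energy_kcal_mol: float
    transitions: TransitionSet = field(default_factory=TransitionSet)
    geometry: GeometryRecord | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.rel_energy_kcal_mol):
            raise ValueError(f"conformer {self.id!r} has non-finite energy")


def select_lowest_n(library: list[ConformerRecord], n: int) -> list[ConformerRecord]:
    """The ``n`` lowest-energy conformers, energy-ascending, stable on ties."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(library):
        raise ValueError(f"requested {n} conformers from a library of {len(library)}")
    order = sorted(range(len(library)), key=lambda i: library[i].rel_energy_kcal_mol)
    return [library[i] for i in order[:n]]


def boltzmann_weights(
    records: list[ConformerRecord], temperature_K: float = 298.15
) -> np.ndarray:
    """Normalized Boltzmann populations from relative energies.

    w_i proportional to exp(-E_i / (R T)); useful as an energy-based prior
    for reporting, independent of any spectral fit.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    energies = np.array([r.rel_energy_kcal_mol for r in records], dtype=float)
    w = np.exp(-(energies - energies.min()) / (R_KCAL_PER_MOL_K * temperature_K))
    return w / w.sum()


# --- small exact NNLS on Gram matrices ------------------------------------


def _solve_support(G: np.ndarray, c: np.ndarray, support: tuple[int, ...]) -> np.ndarray | None:
    """Unconstrained solve restricted to a support; None if infeasible/singular."""
    idx = np.asarray(support)
    try:
        x_s = np.linalg.solve(G[np.ix_(idx, idx)], c[idx])
    except np.linalg.LinAlgError:
        return None
    if np.any(x_s < -_TOL):
        return None
    x = np.zeros(len(c))
    x[idx] = np.maximum(x_s, 0.0)
    return x


def _nnls_gram(G: np.ndarray, c: np.ndarray) -> np.ndarray:
    """argmin_{x >= 0} x'Gx - 2c'x by exhaustive support enumeration.

    Exact for the small systems arising here (subset size <= ~10); the
    full-support solution is tried first since it is usually the optimum.
    """
    k = len(c)
    full = _solve_support(G, c, tuple(range(k)))
    if full is not None:
        return full
    best, best_obj = np.zeros(k), 0.0
    for size in range(1, k):
        for support in itertools.combinations(range(k), size):
            x = _solve_support(G, c, support)
            if x is None:
                continue
            obj = x @ G @ x - 2.0 * c @ x
            if obj < best_obj - _TOL:
                best, best_obj = x, obj
    return best


def _nnls_gram_capped(G: np.ndarray, c: np.ndarray, cap: float) -> np.ndarray:
    """NNLS with the extra constraint sum(x) = cap (active sum constraint)."""
    k = len(c)
    best, best_obj = None, np.inf
    for size in range(1, k + 1):
        for support in itertools.combinations(range(k), size):
            idx = np.asarray(support)
            m = len(idx)
            kkt = np.zeros((m + 1, m + 1))
            kkt[:m, :m] = 2.0 * G[np.ix_(idx, idx)]
            kkt[:m, m] = 1.0
            kkt[m, :m] = 1.0
            rhs = np.concatenate([2.0 * c[idx], [cap]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            x_s = sol[:m]
            if np.any(x_s < -_TOL):
                continue
            x = np.zeros(k)
            x[idx] = np.maximum(x_s, 0.0)
            obj = x @ G @ x - 2.0 * c @ x
            if obj < best_obj - _TOL:
                best, best_obj = x, obj
    if best is None:  # cap unreachable only in degenerate all-zero cases
        best = np.zeros(k)
    return best


def fit_weights(
    library: list[ConformerRecord],
    target: Spectrum,
    max_subset_size: int = 3,
    weight_sum_cap: float = 1.0,
    settings: BroadeningSettings | None = None,
    wavelength_shift_nm: float = 0.0,
) -> FitResult:
    """Fit non-negative conformer abundances to a target spectrum.

    Every conformer's transition set is broadened on the settings grid, all
    subsets of size 1..``max_subset_size`` are enumerated, and for each the
    best non-negative weights (sum capped at ``weight_sum_cap``) are found
    by exact NNLS.  The subset with the highest cosine similarity between
    its weighted combination and the target wins; ties go to the smaller
    subset, then to the lower summed relative energy.

    ``wavelength_shift_nm`` optionally shifts every calculated transition
    by a fixed amount before broadening (off by default), compensating a
    systematic excitation-energy bias of the electronic-structure method.
    """
    if not library:
        raise ValueError("conformer library is empty")
    if not 1 <= max_subset_size <= len(library):
        raise ValueError("max_subset_size must be in [1, library size]")
    if not 0 < weight_sum_cap <= 1:
        raise ValueError("weight_sum_cap must be in (0, 1]")
    settings = settings or BroadeningSettings()
    grid = settings.grid()

    columns = []
    for rec in library:
        tr = rec.transitions
        if wavelength_shift_nm != 0.0 and len(tr) > 0:
            tr = TransitionSet(tr.wavelengths_nm + wavelength_shift_nm, tr.strengths)
        columns.append(broaden(tr, settings).values)
    S = np.column_stack(columns)  # (n_grid, n_conformers)

    col_norms = np.linalg.norm(S, axis=0)
    active = np.flatnonzero(col_norms > 0)
    if active.size == 0:
        raise ValueError("all library spectra are identically zero on the fitting grid")

    if not np.allclose(target.wavelengths_nm, grid):
        target = resample(target, grid)
    t = target.values
    t_norm = float(np.linalg.norm(t))
    if t_norm == 0.0:
        raise ValueError("target spectrum is identically zero on the fitting grid")

    G = S.T @ S
    c = S.T @ t
    energies = np.array([r.rel_energy_kcal_mol for r in library])

    best: dict | None = None
    sim_tol = 1e-12
    for size in range(1, max_subset_size + 1):
        for subset in itertools.combinations(active.tolist(), size):
            idx = np.asarray(subset)
            Gs, cs = G[np.ix_(idx, idx)], c[idx]
            x = _nnls_gram(Gs, cs)
            if x.sum() > weight_sum_cap + _TOL:
                x = _nnls_gram_capped(Gs, cs, weight_sum_cap)
            fit_norm_sq = float(x @ Gs @ x)
            if fit_norm_sq <= 0.0:
                continue  # projection hit the cone apex; no direction to compare
            sim = float(x @ cs / (np.sqrt(fit_norm_sq) * t_norm))
            e_sum = float(energies[idx].sum())
            cand = {"subset": idx, "weights": x, "similarity": min(sim, 1.0), "energy": e_sum}
            if (
                best is None
                or cand["similarity"] > best["similarity"] + sim_tol
                or (
                    abs(cand["similarity"] - best["similarity"]) <= sim_tol
                    and (size, e_sum) < (len(best["subset"]), best["energy"])
                )
            ):
                best = cand

    poor_fit = False
    if best is None:
        # target anti-correlates with every conformer: the cone projection is
        # the origin everywhere.  Report the single best (least bad) cosine so
        # the failure is visible instead of silent.
        sims = c[active] / (col_norms[active] * t_norm)
        j = int(active[np.argmax(sims)])
        best = {
            "subset": np.asarray([j]),
            "weights": np.zeros(1),
            "similarity": float(sims.max()),
            "energy": float(energies[j]),
        }
        poor_fit = True

    order = np.argsort(-best["weights"], kind="stable")
    subset_ids = [library[int(best["subset"][i])].id for i in order]
    weights = best["weights"][order]
    return FitResult(
        subset=subset_ids,
        weights=weights,
        similarity=best["similarity"],
        settings={
            "hwhm_nm": settings.hwhm_nm,
            "grid_nm": [settings.grid_start_nm, settings.grid_end_nm, settings.grid_step_nm],
            "max_subset_size": max_subset_size,
            "weight_sum_cap": weight_sum_cap,
            "wavelength_shift_nm": wavelength_shift_nm,
        },
        diagnostics={
            "poor_fit": bool(poor_fit or best["similarity"] < 0.9),
            "weight_sum": float(weights.sum()),
            "n_candidates_considered": int(active.size),
        },
    )
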