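"""Monte-Carlo self-checks of the pipeline on synthetic data.

These studies quantify, under the generator's stated conditions, how well
the population fit recovers known abundances and how much replicate
averaging suppresses noise.  They are used by the test suite and the
reproduction script; on real data the corresponding figures depend on the
instrument and the electronic-structure method and cannot be inferred
from these numbers.
"""

from __future__ import annotations

import numpy as np

from .fit import fit_weights
from .preprocess import average_scans
from .spectra import BroadeningSettings, Spectrum
from .synth import MixtureSpec, gen_mixture_spectrum, gen_replicate_scans, gen_transition_library

#: total abundance assigned in synthetic mixtures; shape fits of real
#: ensembles typically leave a few percent to unassigned minor conformers
MIXTURE_TOTAL_ABUNDANCE = 0.98


def weight_recovery_study(
    n_trials: int = 200,
    n_conformers: int = 20,
    mixture_size: int = 3,
    noise_sigma: float = 0.01,
    tolerance: float = 0.05,
    seed: int = 0,
    settings: BroadeningSettings | None = None,
) -> dict:
    """Recovery of known 3-conformer abundances from noisy mixtures.

    Each trial draws a fresh transition library, picks ``mixture_size``
    random members with Dirichlet(1,..,1) abundances scaled to a 0.98
    total, adds Gaussian noise (``noise_sigma`` as a fraction of peak
    amplitude), fits with subset enumeration, and scores the trial as a
    success when every per-conformer abundance error (absent conformers
    count as zero) is below ``tolerance``.
    """
    settings = settings or BroadeningSettings()
    rng = np.random.default_rng(seed)
    successes = 0
    max_errors = []
    for trial in range(n_trials):
        lib_seed = int(rng.integers(0, 2**31 - 1))
        library = gen_transition_library(n_conformers=n_conformers, seed=lib_seed)
        members = rng.choice(n_conformers, size=mixture_size, replace=False)
        weights = rng.dirichlet(np.ones(mixture_size)) * MIXTURE_TOTAL_ABUNDANCE
        # reorder the library so the mixture members lead, as the generator
        # weights the leading conformers
        reordered = [library[i] for i in members] + [
            library[i] for i in range(n_conformers) if i not in set(members.tolist())
        ]
        target = gen_mixture_spectrum(
            reordered,
            MixtureSpec(tuple(weights), noise_sigma=noise_sigma, seed=lib_seed + 1),
            settings,
        )
        result = fit_weights(reordered, target, max_subset_size=mixture_size, settings=settings)
        fitted = dict(zip(result.subset, result.weights))
        true = {reordered[i].id: weights[i] for i in range(mixture_size)}
        errs = [
            abs(fitted.get(rec.id, 0.0) - true.get(rec.id, 0.0)) for rec in reordered
        ]
        max_err = max(errs)
        max_errors.append(max_err)
        if max_err <= tolerance:
            successes += 1
    return {
        "n_trials": n_trials,
        "success_rate": successes / n_trials,
        "median_max_abs_error": float(np.median(max_errors)),
        "worst_max_abs_error": float(np.max(max_errors)),
        "tolerance": tolerance,
    }


def replicate_averaging_study(
    n_trials: int = 200,
    n_scans: int = 5,
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> dict:
    """Noise suppression by replicate averaging vs the 1/sqrt(n) law.

    Pools the residuals (average minus truth) over trials and grid points
    and compares their standard deviation with sigma/sqrt(n_scans).
    """
    grid = np.linspace(185.0, 320.0, 136)
    truth = Spectrum(grid, np.sin(np.pi * (grid - grid[0]) / (grid[-1] - grid[0])))
    rng = np.random.default_rng(seed)
    residuals = []
    for _ in range(n_trials):
        series = gen_replicate_scans(
            truth, n_scans=n_scans, noise_sigma=noise_sigma, seed=int(rng.integers(0, 2**31 - 1))
        )
        residuals.append(average_scans(series).values - truth.values)
    empirical = float(np.std(np.concatenate(residuals)))
    theoretical = noise_sigma / np.sqrt(n_scans)
    return {
        "n_trials": n_trials,
        "empirical_residual_sd": empirical,
        "theoretical_residual_sd": float(theoretical),
        "ratio": empirical / theoretical,
    }
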