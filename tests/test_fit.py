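"""Conformer selection, Boltzmann weighting and the population fit."""

import itertools

import numpy as np
import pytest
import scipy.optimize

from ecdkit import (
    BroadeningSettings,
    ConformerRecord,
    TransitionSet,
    boltzmann_weights,
    broaden,
    fit_weights,
    select_lowest_n,
)
from ecdkit.fit import _nnls_gram
from ecdkit.synth import MixtureSpec, gen_mixture_spectrum


def records(energies):
    return [ConformerRecord(f"r{i}", e) for i, e in enumerate(energies)]


class TestSelectLowestN:
    def test_orders_by_energy(self):
        lib = records([0.0, 1.2, 0.3])
        assert [r.id for r in select_lowest_n(lib, 2)] == ["r0", "r2"]

    def test_stable_tie_break(self):
        lib = records([1.0, 1.0, 1.0])
        assert [r.id for r in select_lowest_n(lib, 2)] == ["r0", "r1"]

    def test_n_too_large(self):
        with pytest.raises(ValueError):
            select_lowest_n(records([0.0, 1.0, 2.0]), 4)


class TestBoltzmannWeights:
    def test_equal_energies_equal_weights(self):
        w = boltzmann_weights(records([1.5, 1.5, 1.5]))
        assert np.allclose(w, 1 / 3)

    def test_rt_ln2_gap_gives_two_to_one(self):
        gap = 1.98720425e-3 * 298.15 * np.log(2.0)  # = 0.4106 kcal/mol
        w = boltzmann_weights(records([0.0, gap]), 298.15)
        assert np.allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            boltzmann_weights(records([0.0]), 0.0)


def simplex_grid_oracle(library, target, settings, max_subset_size, step):
    """Dense grid search over the weight simplex: independent fit oracle."""
    S = np.column_stack([broaden(r.transitions, settings).values for r in library])
    t = target.values
    t_norm = np.linalg.norm(t)
    n_steps = int(round(1.0 / step))
    best = (-np.inf, None, None)
    for size in range(1, max_subset_size + 1):
        for subset in itertools.combinations(range(len(library)), size):
            A = S[:, subset]
            ticks = [np.arange(n_steps + 1) for _ in range(size)]
            for combo in itertools.product(*ticks):
                if sum(combo) == 0 or sum(combo) > n_steps:
                    continue
                w = np.array(combo) * step
                f = A @ w
                norm = np.linalg.norm(f)
                if norm == 0:
                    continue
                sim = f @ t / (norm * t_norm)
                if sim > best[0]:
                    best = (sim, subset, w)
    return best


class TestNnlsAgainstScipy:
    def test_matches_scipy_nnls(self, rng):
        for _ in range(50):
            A = rng.normal(size=(30, 3))
            b = rng.normal(size=30)
            x_ref, _ = scipy.optimize.nnls(A, b)
            x = _nnls_gram(A.T @ A, A.T @ b)
            assert np.allclose(x, x_ref, atol=1e-8)


class TestFitWeights:
    def test_self_match(self, separated_library, settings):
        target = broaden(separated_library[1].transitions, settings)
        result = fit_weights(separated_library, target, settings=settings)
        assert result.subset == ["c-b"]
        assert result.weights == pytest.approx([1.0], abs=1e-9)
        assert result.similarity == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_three_component_recovery(self, separated_library, settings):
        target = gen_mixture_spectrum(
            separated_library, MixtureSpec((0.65, 0.25, 0.08)), settings
        )
        result = fit_weights(separated_library, target, settings=settings)
        fitted = dict(zip(result.subset, result.weights))
        assert fitted["c-a"] == pytest.approx(0.65, abs=1e-6)
        assert fitted["c-b"] == pytest.approx(0.25, abs=1e-6)
        assert fitted["c-c"] == pytest.approx(0.08, abs=1e-6)
        assert result.similarity > 0.999999

    def test_oracle_equivalence_small_library(self, separated_library, settings):
        """Enumerated-NNLS optimum equals the simplex grid-search oracle."""
        step = 0.02
        target = gen_mixture_spectrum(
            separated_library, MixtureSpec((0.64, 0.26, 0.08)), settings
        )
        sim, subset, w = simplex_grid_oracle(separated_library, target, settings, 3, step)
        result = fit_weights(separated_library, target, settings=settings)
        fitted = dict(zip(result.subset, result.weights))
        oracle = {separated_library[i].id: w[j] for j, i in enumerate(subset)}
        for cid in oracle:
            assert fitted.get(cid, 0.0) == pytest.approx(oracle[cid], abs=step)
        assert result.similarity >= sim - 1e-12

    def test_sign_inverted_target_flagged(self, settings):
        lib = [ConformerRecord("only", 0.0, TransitionSet([220.0], [5.0]))]
        target = broaden(lib[0].transitions, settings)
        result = fit_weights(lib, target.with_values(-target.values), max_subset_size=1,
                             settings=settings)
        assert result.subset == ["only"]
        assert result.similarity == pytest.approx(-1.0, abs=1e-9)
        assert result.diagnostics["poor_fit"]

    def test_scale_invariance_of_subset_and_ratios(self, separated_library, settings):
        target = gen_mixture_spectrum(
            separated_library, MixtureSpec((0.5, 0.3, 0.1), noise_sigma=0.01, seed=5), settings
        )
        r1 = fit_weights(separated_library, target, settings=settings)
        r2 = fit_weights(
            separated_library, target.with_values(0.37 * target.values), settings=settings
        )
        assert r1.subset == r2.subset
        assert r1.similarity == pytest.approx(r2.similarity, abs=1e-12)
        assert np.allclose(r2.weights / r2.weights.sum(), r1.weights / r1.weights.sum(), atol=1e-9)

    def test_monotone_in_subset_size(self, separated_library, settings, rng):
        target = gen_mixture_spectrum(
            separated_library, MixtureSpec((0.4, 0.3, 0.28), noise_sigma=0.05, seed=9), settings
        )
        sims = [
            fit_weights(separated_library, target, max_subset_size=k, settings=settings).similarity
            for k in (1, 2, 3)
        ]
        assert sims[0] <= sims[1] + 1e-12 <= sims[2] + 2e-12

    def test_weight_cap_enforced(self, settings):
        # target is 3x one conformer's spectrum: uncapped NNLS would need w=3
        lib = [
            ConformerRecord("a", 0.0, TransitionSet([210.0], [5.0])),
            ConformerRecord("b", 0.5, TransitionSet([280.0], [5.0])),
        ]
        target = broaden(lib[0].transitions, settings)
        result = fit_weights(
            lib, target.with_values(3.0 * target.values), max_subset_size=2, settings=settings
        )
        assert result.weights.sum() <= 1.0 + 1e-9
        assert result.similarity == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_library_rejected(self, settings):
        lib = [ConformerRecord("z", 0.0, TransitionSet())]
        target = broaden(TransitionSet([220.0], [1.0]), settings)
        with pytest.raises(ValueError, match="identically zero"):
            fit_weights(lib, target, max_subset_size=1, settings=settings)

    def test_tie_prefers_smaller_subset_then_lower_energy(self, settings):
        # two identical conformers; either alone fits perfectly -> the
        # lower-energy one must win, and no 2-subset should displace it
        ts = TransitionSet([230.0], [4.0])
        lib = [ConformerRecord("hi", 2.0, ts), ConformerRecord("lo", 0.5, ts)]
        target = broaden(ts, settings)
        result = fit_weights(lib, target, max_subset_size=2, settings=settings)
        assert result.subset == ["lo"]
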