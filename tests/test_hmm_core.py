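from collections import Counter

import numpy as np
import pytest

from oracle_hmm import filtering_marginal, posterior_paths

from kirphase.datamodel import (
    Code,
    Dialect,
    DiploidState,
    Diplotype,
    Haplotype,
    HMMParameters,
    ObservedGenotype,
    PatternSet,
    WeightedReferencePanel,
    observe,
)
from kirphase.hmm_core import (
    ConstraintInfeasibleError,
    InfeasibleGenotypeError,
    allele_emission,
    backward_sample,
    forward_pass,
    genotype_emission,
)

H = Haplotype.from_string


def make_panel(rows, weights=None):
    haps = tuple(H(r) for r in rows)
    if weights is None:
        weights = (1.0,) * len(haps)
    return WeightedReferencePanel(haps, tuple(weights), (False,) * len(haps))


def random_observation(rng, L, allow_full=False):
    if allow_full and rng.random() < 0.5:
        codes = [
            (Code.ABSENT, Code.FULL1, Code.FULL2, Code.MISSING)[rng.integers(4)]
            for _ in range(L)
        ]
        return ObservedGenotype(tuple(codes), Dialect.FULL)
    codes = [
        (Code.ABSENT, Code.PRESENT, Code.MISSING)[rng.integers(3)] for _ in range(L)
    ]
    return ObservedGenotype(tuple(codes), Dialect.PRESENT_ABSENT)


class TestEmission:
    def test_allele_emission_definition(self):
        assert allele_emission(1, 1, 0.0) == 1.0
        assert allele_emission(1, 0, 0.01) == 0.01
        for t in (0, 1):
            assert allele_emission(t, 0, 0.3) + allele_emission(t, 1, 0.3) == 1.0

    def test_genotype_emission_examples(self):
        panel = make_panel(["1 1", "0 0", "1 0"])
        s_11 = DiploidState(0, 0)  # both templates present at locus 0
        s_00 = DiploidState(1, 1)
        s_10 = DiploidState(0, 1)
        assert genotype_emission(Code.PRESENT, s_11, panel, 0, 0.0) == 1.0
        assert genotype_emission(Code.PRESENT, s_00, panel, 0, 0.0) == 0.0
        assert genotype_emission(Code.ABSENT, s_10, panel, 0, 0.01) == pytest.approx(
            0.01 * 0.99
        )
        assert genotype_emission(Code.MISSING, s_10, panel, 0, 0.3) == 1.0

    def test_present_absent_classes_partition(self, rng):
        panel = make_panel(["1 0 1", "0 1 1", "1 1 0"])
        for _ in range(20):
            state = DiploidState(rng.integers(3), rng.integers(3))
            l = int(rng.integers(3))
            eps = float(rng.random() * 0.49)
            pa = genotype_emission(Code.ABSENT, state, panel, l, eps)
            pp = genotype_emission(Code.PRESENT, state, panel, l, eps)
            assert pa + pp == pytest.approx(1.0)


class TestForward:
    def test_single_reference_is_degenerate(self):
        panel = make_panel(["1 0 1"])
        obs = ObservedGenotype((Code.PRESENT, Code.ABSENT, Code.PRESENT))
        fwd = forward_pass(obs, panel, HMMParameters())
        assert np.allclose(fwd.filtering, 1.0)

    def test_zero_rates_keep_only_truth_emitting_states(self):
        panel = make_panel(["1 0 1", "0 1 1"])
        obs = observe(Diplotype((H("1 0 1"), H("1 0 1"))), Dialect.FULL)
        params = HMMParameters(crossover_rate=0.0, error_rate=0.0)
        fwd = forward_pass(obs, panel, params)
        # only the homozygous template-0 state can emit copy sums (2,0,2)
        expected = np.zeros((2, 2))
        expected[0, 0] = 1.0
        for l in range(3):
            assert np.allclose(fwd.filtering[l], expected)

    def test_infeasible_signals_instead_of_renormalizing(self):
        panel = make_panel(["1 1", "1 0"])
        obs = ObservedGenotype((Code.ABSENT, Code.MISSING))
        with pytest.raises(InfeasibleGenotypeError):
            forward_pass(obs, panel, HMMParameters(error_rate=0.0))

    def test_weight_rescaling_invariance(self, rng):
        panel1 = make_panel(["1 0 1", "0 1 1"], weights=(1.0, 3.0))
        panel2 = make_panel(["1 0 1", "0 1 1"], weights=(2.5, 7.5))
        obs = random_observation(rng, 3)
        params = HMMParameters(crossover_rate=0.1, error_rate=0.05)
        f1 = forward_pass(obs, panel1, params)
        f2 = forward_pass(obs, panel2, params)
        assert np.allclose(f1.filtering, f2.filtering)
        assert np.allclose(f1.norms, f2.norms)

    def test_transition_preserves_probability_mass(self, rng):
        # with all-MISSING observations every layer must stay normalized,
        # which exercises row-sums of the diploid transition kernel
        for _ in range(10):
            Hn, L = int(rng.integers(1, 5)), int(rng.integers(2, 6))
            rows = [" ".join(str(rng.integers(0, 2)) for _ in range(L)) for _ in range(Hn)]
            try:
                panel = make_panel(rows, weights=rng.random(Hn) + 0.1)
            except ValueError:  # duplicate rows drawn
                continue
            obs = ObservedGenotype((Code.MISSING,) * L)
            params = HMMParameters(
                crossover_rate=tuple(rng.random(L - 1)), error_rate=0.1
            )
            fwd = forward_pass(obs, panel, params)
            assert np.allclose(fwd.predictive.sum(axis=(1, 2)), 1.0)
            assert np.allclose(fwd.norms, 1.0)

    @pytest.mark.parametrize("Hn,L", [(2, 3), (3, 4), (2, 4), (3, 2)])
    def test_marginals_match_exhaustive_enumeration(self, Hn, L, rng):
        for trial in range(3):
            hap = rng.integers(0, 2, size=(Hn, L)).astype(np.int8)
            while len({r.tobytes() for r in hap}) < Hn:
                hap = rng.integers(0, 2, size=(Hn, L)).astype(np.int8)
            w = rng.random(Hn) + 0.2
            panel = make_panel(
                [" ".join(map(str, r)) for r in hap], weights=tuple(w)
            )
            theta = rng.random(L - 1)
            eps = 0.05 + 0.2 * rng.random()
            obs = random_observation(rng, L, allow_full=True)
            params = HMMParameters(crossover_rate=tuple(theta), error_rate=eps)
            fwd = forward_pass(obs, panel, params)
            for l in range(L):
                oracle = filtering_marginal(
                    hap, w, [int(c) for c in obs.codes], theta, eps, l
                )
                assert np.max(np.abs(fwd.filtering[l] - oracle)) < 1e-10


class TestBackwardSample:
    def test_unconstrained_sampling_matches_enumerated_posterior(self, rng):
        hap = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
        w = np.array([1.0, 2.0])
        theta = np.array([0.2, 0.4])
        eps = 0.1
        obs = ObservedGenotype((Code.PRESENT, Code.PRESENT, Code.ABSENT))
        panel = make_panel(["1 0 1", "0 1 1"], weights=(1.0, 2.0))
        params = HMMParameters(crossover_rate=(0.2, 0.4), error_rate=eps)
        fwd = forward_pass(obs, panel, params)
        oracle = posterior_paths(hap, w, [int(c) for c in obs.codes], theta, eps)
        n = 20000
        counts = Counter()
        for i in range(n):
            path = backward_sample(fwd, obs, panel, params, seed=i)
            counts[tuple((s.x, s.y) for s in path.states)] += 1
        tv = 0.5 * sum(
            abs(counts.get(k, 0) / n - v) for k, v in oracle.items()
        ) + 0.5 * sum(counts[k] / n for k in counts if k not in oracle)
        assert tv < 0.03

    def test_absent_locus_always_imputes_double_zero(self):
        panel = make_panel(["1 0 1", "0 1 1"])
        obs = ObservedGenotype((Code.PRESENT, Code.ABSENT, Code.PRESENT))
        params = HMMParameters(error_rate=0.2)
        fwd = forward_pass(obs, panel, params)
        for i in range(200):
            path = backward_sample(fwd, obs, panel, params, seed=i)
            assert tuple(path.imputed_alleles[1]) == (0, 0)
            assert tuple(path.imputed_alleles[0]) != (0, 0)  # PRESENT excludes (0,0)

    def test_anchors_everywhere_force_all_ones(self):
        panel = make_panel(["1 1 1", "1 0 1"])
        obs = ObservedGenotype((Code.PRESENT, Code.MISSING, Code.PRESENT))
        patterns = PatternSet(anchors={0, 1, 2})
        params = HMMParameters(error_rate=0.1)
        fwd = forward_pass(obs, panel, params)
        for i in range(100):
            path = backward_sample(fwd, obs, panel, params, patterns, seed=i)
            h1, h2 = path.haplotypes()
            assert h1.alleles == (1, 1, 1) and h2.alleles == (1, 1, 1)

    def test_hard_constraint_dead_end_raises(self):
        panel = make_panel(["1 0", "0 1"])
        obs = ObservedGenotype((Code.ABSENT, Code.MISSING))
        patterns = PatternSet(anchors={0})  # anchor contradicts ABSENT
        params = HMMParameters(error_rate=0.1)
        fwd = forward_pass(obs, panel, params)
        with pytest.raises(ConstraintInfeasibleError):
            backward_sample(fwd, obs, panel, params, patterns, seed=0)

    def test_relaxed_constraint_allows_escape(self):
        panel = make_panel(["1 0", "0 1"])
        obs = ObservedGenotype((Code.ABSENT, Code.MISSING))
        patterns = PatternSet(anchors={0})
        params = HMMParameters(error_rate=0.1, pattern_relaxation=1e-6)
        fwd = forward_pass(obs, panel, params)
        path = backward_sample(fwd, obs, panel, params, patterns, seed=0)
        assert tuple(path.imputed_alleles[0]) == (0, 0)

    def test_seed_reproducibility_and_rng_interface(self, rng):
        panel = make_panel(["1 0 1", "0 1 1"])
        obs = ObservedGenotype((Code.PRESENT, Code.MISSING, Code.PRESENT))
        params = HMMParameters()
        fwd = forward_pass(obs, panel, params)
        a = backward_sample(fwd, obs, panel, params, seed=7)
        b = backward_sample(fwd, obs, panel, params, seed=7)
        assert a.states == b.states
        assert np.array_equal(a.imputed_alleles, b.imputed_alleles)
        with pytest.raises(ValueError):
            backward_sample(fwd, obs, panel, params)
        with pytest.raises(ValueError):
            backward_sample(fwd, obs, panel, params, rng=rng, seed=1)
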