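import numpy as np
import pytest

from kirphase.datamodel import (
    Code,
    Dialect,
    Diplotype,
    FrequencyTable,
    Haplotype,
    HMMParameters,
    ObservedGenotype,
    PatternSet,
    observe,
)
from kirphase.metrics import sad
from kirphase.patterns import haplotype_compatible
from kirphase.sampler import estimate_frequencies, initialize, run_inference
from kirphase.simulator import identified_references, simulate_sample

H = Haplotype.from_string


class TestEstimateFrequencies:
    def test_relative_counts(self):
        h1, h2 = H("1 0"), H("0 1")
        table = estimate_frequencies([h1, h1, h1, h2])
        assert table[h1] == 0.75 and table[h2] == 0.25

    def test_degenerate_and_sum(self, table1, rng):
        _, src = table1
        assert estimate_frequencies([H("1 1")] * 5)[H("1 1")] == 1.0
        haps = [list(src)[rng.integers(17)] for _ in range(200)]
        table = estimate_frequencies(haps)
        assert len(table) <= 17
        assert table.total == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            estimate_frequencies([])


class TestInitialize:
    def test_anchor_only_observation_is_forced(self, rng):
        patterns = PatternSet(anchors={0, 3})
        codes = [Code.ABSENT] * 5
        codes[0] = codes[3] = Code.PRESENT
        obs = ObservedGenotype(tuple(codes))
        (d,) = initialize([obs], [], patterns, rng)
        assert d.pair[0].alleles == (1, 0, 0, 1, 0)
        assert d.pair[1].alleles == (1, 0, 0, 1, 0)

    def test_external_homozygote_pair_is_selected(self, rng):
        ref = H("1 0 1 1")
        obs = observe(Diplotype((ref, ref)))
        (d,) = initialize([obs], [ref, H("0 1 1 1")], None, rng)
        # the observation (P A P P) is only reproducible from (ref, ref)
        assert d == Diplotype((ref, ref))

    def test_full_dialect_copy_sums_respected(self, table1, rng):
        _, table = table1
        truth, obs = simulate_sample(table, None, 30, Dialect.FULL, 0.0, rng)
        start = initialize(obs, [], None, rng)
        for d, o in zip(start, obs):
            for l, c in enumerate(o.codes):
                expected = {Code.ABSENT: 0, Code.FULL1: 1, Code.FULL2: 2}[c]
                assert d.copy_sum(l) == expected

    def test_pattern_compatible_completion_found(self, table1, kir_patterns, rng):
        _, table = table1
        _, obs = simulate_sample(table, None, 200, Dialect.PRESENT_ABSENT, 0.0, rng)
        start = initialize(obs, [], kir_patterns, rng)
        for d in start:
            assert haplotype_compatible(d.pair[0], kir_patterns)
            assert haplotype_compatible(d.pair[1], kir_patterns)

    def test_empty_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            initialize([], [], None, rng)


class TestRunInference:
    def test_unambiguous_full_homozygotes_recovered_exactly(self):
        h1, h2 = H("1 0 1"), H("0 1 1")
        truth = [Diplotype((h1, h1)), Diplotype((h2, h2))]
        obs = [observe(d, Dialect.FULL) for d in truth]
        for iterations in (2, 8):
            params = HMMParameters(error_rate=0.0, iterations=iterations, burn_in=1, seed=3)
            res = run_inference(obs, [], None, params, reestimate_rates=False)
            assert list(res.consensus) == truth
            assert np.all(res.support == 1.0)

    def test_two_reference_closure(self, rng):
        # all-equal-allele patterns admit only the two reference haplotypes
        a, b = H("1 1 1"), H("0 0 0")
        patterns = PatternSet(together={(0, 1), (1, 2)})
        freqs = FrequencyTable({a: 0.6, b: 0.4})
        truth, obs = simulate_sample(freqs, None, 20, Dialect.PRESENT_ABSENT, 0.0, rng)
        params = HMMParameters(error_rate=0.0, iterations=10, burn_in=2, seed=5)
        res = run_inference(obs, [a, b], patterns, params, reestimate_rates=False)
        assert set(res.frequencies) <= {a, b}
        for d in res.consensus:
            assert set(d.pair) <= {a, b}

    def test_final_round_uses_exactly_2n_haplotypes(self, table1, kir_patterns):
        _, table = table1
        refs = identified_references(table, 10)
        truth, obs = simulate_sample(
            table, None, 100, Dialect.PRESENT_ABSENT, 0.0, np.random.default_rng(11)
        )
        params = HMMParameters(iterations=5, burn_in=1, seed=11)
        res = run_inference(obs, refs, kir_patterns, params)
        counts = [res.frequencies[h] * 200 for h in res.frequencies]
        assert all(abs(c - round(c)) < 1e-9 for c in counts)
        assert sum(round(c) for c in counts) == 200

    def test_consensus_haplotypes_satisfy_patterns(self, table1, kir_patterns):
        _, table = table1
        refs = identified_references(table, 10)
        truth, obs = simulate_sample(
            table, None, 60, Dialect.PRESENT_ABSENT, 0.0, np.random.default_rng(7)
        )
        res = run_inference(obs, refs, kir_patterns, HMMParameters(iterations=12, burn_in=2, seed=7))
        assert not res.fallbacks and not res.flagged
        for d in res.consensus:
            assert haplotype_compatible(d.pair[0], kir_patterns)
            assert haplotype_compatible(d.pair[1], kir_patterns)
        for h in res.frequencies:
            assert haplotype_compatible(h, kir_patterns)

    def test_exchangeability_under_permutation(self, table1, kir_patterns):
        _, table = table1
        refs = identified_references(table, 10)
        truth, obs = simulate_sample(
            table, None, 8, Dialect.PRESENT_ABSENT, 0.0, np.random.default_rng(23)
        )
        params = HMMParameters(iterations=6, burn_in=2, seed=23)
        base = run_inference(obs, refs, kir_patterns, params, ids=list(range(8)))
        perm = [5, 2, 7, 0, 1, 6, 3, 4]
        shuffled = run_inference(
            [obs[i] for i in perm], refs, kir_patterns, params, ids=perm
        )
        for pos, i in enumerate(perm):
            assert shuffled.consensus[pos] == base.consensus[i]
            assert shuffled.support[pos] == base.support[i]
        assert dict(shuffled.frequencies) == dict(base.frequencies)

    def test_run_is_deterministic(self, table1, kir_patterns):
        _, table = table1
        refs = identified_references(table, 10)
        _, obs = simulate_sample(
            table, None, 15, Dialect.PRESENT_ABSENT, 0.0, np.random.default_rng(2)
        )
        params = HMMParameters(iterations=6, burn_in=1, seed=99)
        r1 = run_inference(obs, refs, kir_patterns, params)
        r2 = run_inference(obs, refs, kir_patterns, params)
        assert list(r1.consensus) == list(r2.consensus)
        assert np.array_equal(r1.support, r2.support)
        assert dict(r1.frequencies) == dict(r2.frequencies)

    def test_external_reference_weighting_option(self, table1, kir_patterns):
        _, table = table1
        refs = identified_references(table, 10)
        _, obs = simulate_sample(
            table, None, 10, Dialect.PRESENT_ABSENT, 0.0, np.random.default_rng(41)
        )
        params = HMMParameters(iterations=5, burn_in=1, seed=41)
        weighted = run_inference(
            obs, refs, kir_patterns, params,
            external_weights=[100.0 * table[h] for h in refs],
        )
        assert len(weighted.consensus) == 10
        with pytest.raises(ValueError):
            run_inference(obs, refs, kir_patterns, params, external_weights=[1.0])
        with pytest.raises(ValueError):
            run_inference(
                obs, refs, kir_patterns, params, external_weights=[0.0] * 10
            )

    def test_pooled_frequency_estimator(self, table1, kir_patterns):
        _, table = table1
        refs = identified_references(table, 10)
        _, obs = simulate_sample(
            table, None, 20, Dialect.PRESENT_ABSENT, 0.0, np.random.default_rng(31)
        )
        params = HMMParameters(iterations=8, burn_in=2, seed=31)
        pooled = run_inference(
            obs, refs, kir_patterns, params, frequency_estimator="pooled"
        )
        assert pooled.frequencies.total == pytest.approx(1.0, abs=1e-9)
        # pooled counts cover 6 sweeps x 40 haplotypes
        counts = [pooled.frequencies[h] * 240 for h in pooled.frequencies]
        assert all(abs(c - round(c)) < 1e-6 for c in counts)
        with pytest.raises(ValueError):
            run_inference(obs, refs, kir_patterns, params, frequency_estimator="mean")

    def test_sample_size_has_small_effect_on_frequency_recovery(self, table1):
        # full-dialect (no-missing) data: frequency estimates from n=200
        # should be at least as good as from n=50, up to a small margin
        _, table = table1
        means = {}
        for n in (50, 200):
            sads = []
            for rep in range(20):
                rng = np.random.default_rng(1000 + rep)
                truth, obs = simulate_sample(table, None, n, Dialect.FULL, 0.0, rng)
                res = run_inference(
                    obs, [], None, HMMParameters(iterations=20, burn_in=5, seed=1000 + rep)
                )
                sads.append(sad(table, res.frequencies))
            means[n] = np.mean(sads)
        assert means[200] < means[50] + 0.02
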