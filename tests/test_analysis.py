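import numpy as np
import pytest

import dnatwin as dt
from dnatwin.seqio import ReadSet


def make_reads(r1, r2=None):
    if r2 is None:
        r2 = [dt.reverse_complement(s) for s in r1]
    return ReadSet(r1=r1, r2=r2)


class TestMapReads:
    def test_perfect_read_similarity_one(self, small_refs):
        reads = make_reads([small_refs.sequences[3]])
        maps = dt.map_reads(reads, small_refs)
        assert len(maps) == 2  # forward and reverse
        for m in maps:
            assert m.ref_index == 3
            assert m.similarity == 1.0
            assert m.error_free

    def test_similarity_threshold_filters(self, refs_150):
        # 30 mismatches on a 150-mer: similarity 0.80 < 0.85
        ref = refs_150.sequences[0]
        bad = list(ref)
        for i in range(30):
            bad[i * 5] = "ACGT"[("ACGT".index(bad[i * 5]) + 1) % 4]
        maps = dt.map_reads(
            make_reads(["".join(bad)], [dt.reverse_complement(ref)]), refs_150
        )
        directions = {m.direction for m in maps}
        assert "forward" not in directions  # filtered
        assert "reverse" in directions  # clean copy mapped

    def test_deletion_event_position(self, small_refs):
        # classic 3-vs-4 instance embedded in a real reference
        ref = small_refs.sequences[0]
        read = ref[:9] + ref[10:]  # delete reference position 10
        maps = [m for m in dt.map_reads(
            make_reads([read], [dt.reverse_complement(ref)]), small_refs)
                if m.direction == "forward"]
        assert maps[0].events == [("del", 10, 1)]

    def test_heuristic_matches_exhaustive(self, small_refs):
        rng = np.random.default_rng(8)
        r1 = []
        for _ in range(30):
            t = int(rng.integers(0, len(small_refs)))
            s = list(small_refs.sequences[t])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, len(s)))
                s[p] = "ACGT"[int(rng.integers(0, 4))]
            if rng.random() < 0.4 and len(s) > 2:
                s.pop(int(rng.integers(0, len(s))))
            r1.append("".join(s))
        reads = make_reads(r1, r1)  # map the same set in both slots
        fast = dt.map_reads(reads, small_refs)
        slow = dt.map_reads(reads, small_refs, exhaustive=True)
        key = lambda ms: sorted((m.read_index, m.direction, m.ref_index, m.similarity) for m in ms)
        assert key(fast) == key(slow)

    def test_simulated_reads_map_to_true_reference(self, refs_150):
        pool = dt.pool_from_references(refs_150, [20] * len(refs_150))
        reads = dt.sequence(pool, dt.sequencing_params("iseq100", read_count=2000), seed=4)
        maps = dt.map_reads(reads, refs_150, read_length=150)
        agree = np.mean([m.ref_index == reads.true_ref[m.read_index] for m in maps])
        assert agree >= 0.99

    def test_empty_reference_pool_rejected(self):
        with pytest.raises(ValueError):
            dt.map_reads(make_reads(["ACGT"]), dt.ReferencePool(ids=[], sequences=[]))


class TestErrorRates:
    def test_perfect_reads_zero_rates(self, small_refs):
        reads = make_reads(list(small_refs.sequences))
        rep = dt.error_rates(dt.map_reads(reads, small_refs), small_refs)
        assert rep.rates == {"sub": 0.0, "del": 0.0, "ins": 0.0}

    def test_rate_is_events_over_aligned_nt(self, small_refs):
        ref = small_refs.sequences[0]
        read = ref[:19] + ref[20:]  # one deleted base
        rep = dt.error_rates(
            dt.map_reads(
                make_reads([read], [dt.reverse_complement(ref)]), small_refs
            ),
            small_refs,
        )
        assert rep.rates["del"] == pytest.approx(1 / (2 * len(ref)))

    def test_empty_mappings_rejected(self, small_refs):
        with pytest.raises(ValueError):
            dt.error_rates([], small_refs)

    def test_direction_stratification(self, small_refs):
        ref = small_refs.sequences[0]
        mutated = "ACGT"[("ACGT".index(ref[4]) + 1) % 4]
        read = ref[:4] + mutated + ref[5:]
        rep = dt.error_rates(
            dt.map_reads(
                make_reads([read], [dt.reverse_complement(ref)]), small_refs
            ),
            small_refs,
        )
        fwd = rep.positional.query("direction == 'forward' and type == 'sub'")
        assert fwd.loc[fwd.position == 5, "rate"].iloc[0] == 1.0
        rev = rep.positional.query("direction == 'reverse' and type == 'sub'")
        assert (rev.rate == 0).all()


class TestIndependenceStats:
    def test_geometric_reference_values(self, small_refs):
        reads = make_reads(list(small_refs.sequences[:4]))
        rep = dt.error_rates(dt.map_reads(reads, small_refs), small_refs)
        rep.rates["del"] = 0.01  # probe the reference pmf at a known rate
        stats_ = dt.independence_stats(rep, kind="del")
        assert stats_["run_length_geometric"][1] == pytest.approx(0.99)
        assert stats_["run_length_geometric"][2] == pytest.approx(0.0099)

    def test_binomial_reference_values(self, refs_150):
        reads = make_reads(list(refs_150.sequences[:4]))
        rep = dt.error_rates(dt.map_reads(reads, refs_150), refs_150)
        rep.rates["sub"] = 0.001
        stats_ = dt.independence_stats(rep, kind="sub")
        assert stats_["per_read_binomial"][0] == pytest.approx(0.999**150, rel=1e-6)

    def test_pmfs_normalized(self, refs_150):
        pool = dt.pool_from_references(refs_150, [20] * len(refs_150))
        reads = dt.sequence(pool, dt.sequencing_params("iseq100", read_count=2000), seed=5)
        rep = dt.error_rates(dt.map_reads(reads, refs_150, read_length=150), refs_150)
        stats_ = dt.independence_stats(rep, kind="sub")
        per_read = sum(stats_["per_read_empirical"].values())
        assert per_read == pytest.approx(1.0, abs=1e-9)
        # theoretical pmfs sum to 1 over their (truncated) support
        assert sum(stats_["per_read_binomial"].values()) == pytest.approx(1.0, abs=1e-3)
        assert sum(stats_["run_length_geometric"].values()) == pytest.approx(1.0, abs=1e-3)

    def test_substitutions_match_binomial_null(self, refs_150):
        # independent substitutions: empirical errors-per-read pmf is binomial
        from scipy.stats import chisquare

        pool = dt.pool_from_references(refs_150, [50] * len(refs_150))
        params = dt.error_free_sequencing_params(20000)
        params.forward_profile = dt.PositionalRateProfile(np.full(150, 2e-3))
        params.reverse_profile = dt.PositionalRateProfile(np.full(150, 2e-3))
        reads = dt.sequence(pool, params, seed=6)
        rep = dt.error_rates(dt.map_reads(reads, refs_150, read_length=150), refs_150)
        stats_ = dt.independence_stats(rep, kind="sub")
        n = rep.n_reads
        kmax = 4
        obs = np.array([stats_["per_read_empirical"].get(k, 0) * n for k in range(kmax)])
        exp = np.array([stats_["per_read_binomial"][k] * n for k in range(kmax)])
        obs = np.append(obs, n - obs.sum())
        exp = np.append(exp, max(n - exp.sum(), 1e-9))
        _, p = chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.01


class TestCoverageFit:
    def test_all_equal_sigma_zero(self):
        cov = dt.pools.coverage_from_counts(list("abcd"), [5.0, 5, 5, 5])
        assert dt.fit_lognormal_coverage(cov) == 0.0

    @pytest.mark.parametrize("sigma,tol", [(1.30, 0.05), (0.27, 0.02)])
    def test_mle_consistency(self, sigma, tol):
        rng = np.random.default_rng(12)
        vals = rng.lognormal(0, sigma, 12000)
        cov = dt.pools.coverage_from_counts([f"r{i}" for i in range(12000)], vals)
        assert dt.fit_lognormal_coverage(cov) == pytest.approx(sigma, abs=tol)

    def test_zeros_excluded(self):
        vals = np.concatenate([np.exp(np.random.default_rng(1).normal(0, 0.3, 5000)), [0, 0]])
        cov = dt.pools.coverage_from_counts([f"r{i}" for i in range(vals.size)], vals)
        assert dt.fit_lognormal_coverage(cov) == pytest.approx(0.3, abs=0.02)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dt.pools.coverage_from_counts(list("ab"), [0.0, 0.0])


class TestEfficiencyEstimator:
    def test_direct_evaluation(self):
        pre = dt.pools.coverage_from_counts(["a"], [100.0])
        pre.values = np.array([1.0])
        post = dt.pools.coverage_from_counts(["a"], [100.0])
        post.values = np.array([2.0])
        est = dt.estimate_efficiencies(pre, post, cycles=10, min_reads=1)
        assert est.relative_efficiency[0] == pytest.approx(2 ** 0.1)

    def test_identical_vectors_sigma_zero(self):
        vals = np.array([50.0, 100.0, 150.0, 200.0])
        pre = dt.pools.coverage_from_counts(list("abcd"), vals)
        post = dt.pools.coverage_from_counts(list("abcd"), vals)
        est = dt.estimate_efficiencies(pre, post, cycles=5, min_reads=1)
        assert np.allclose(est.relative_efficiency, 1.0)
        assert est.sigma == 0.0

    def test_exact_in_deterministic_limit(self):
        # counts as expectations: recovered efficiencies equal configured ones
        rng = np.random.default_rng(3)
        rel = 1.0 + rng.normal(0, 0.005, 500)
        c = 31
        pre_counts = np.full(500, 1000.0)
        post_counts = pre_counts * rel**c
        pre = dt.pools.coverage_from_counts([f"r{i}" for i in range(500)], pre_counts)
        post = dt.pools.coverage_from_counts([f"r{i}" for i in range(500)], post_counts)
        est = dt.estimate_efficiencies(pre, post, cycles=c, min_reads=10)
        norm = (np.mean(rel**c)) ** (1 / c)
        assert np.allclose(est.relative_efficiency * norm, rel, rtol=1e-12)

    def test_min_reads_exclusion(self):
        pre = dt.pools.coverage_from_counts(list("abc"), [100.0, 100.0, 5.0])
        post = dt.pools.coverage_from_counts(list("abc"), [100.0, 100.0, 5.0])
        est = dt.estimate_efficiencies(pre, post, cycles=5, min_reads=10)
        assert est.n_excluded == 1
        assert est.ids == ["a", "b"]


class TestDecayFit:
    def test_exact_half_life(self):
        out = dt.fit_decay([1.0, 0.5], [0.0, 3.5])
        assert out["tau"] == pytest.approx(3.5)

    def test_exact_exponential_series(self):
        t = np.array([0.0, 1, 2, 3])
        out = dt.fit_decay(2.0 ** (-t), t)
        assert out["k"] == pytest.approx(np.log(2))
        assert out["tau"] == pytest.approx(1.0)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(9)
        tau = 4.0
        t = np.linspace(0, 8, 8)
        c = np.exp(-np.log(2) / tau * t) * np.exp(rng.normal(0, 0.1, 8))
        out = dt.fit_decay(c, t)
        assert out["tau"] == pytest.approx(tau, rel=0.15)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dt.fit_decay([1.0, 0.0], [0.0, 1.0])


class TestDropout:
    def test_all_present_zero(self, small_refs):
        reads = make_reads(list(small_refs.sequences))
        maps = dt.map_reads(reads, small_refs)
        assert dt.dropout_rate(maps, small_refs) == 0.0

    def test_missing_reference_counted(self, small_refs):
        reads = make_reads(list(small_refs.sequences[:2]))
        maps = dt.map_reads(reads, small_refs)
        assert dt.dropout_rate(maps, small_refs) == pytest.approx(
            1 - 2 / len(small_refs)
        )

    def test_error_free_only_stricter(self, small_refs):
        ref = small_refs.sequences[0]
        errored = "ACGT"[("ACGT".index(ref[0]) + 1) % 4] + ref[1:]
        reads = make_reads([errored], [ref])
        maps = dt.map_reads(reads, small_refs)
        all_rate = dt.dropout_rate(maps, small_refs)
        ef_rate = dt.dropout_rate(maps, small_refs, error_free_only=True)
        assert ef_rate >= all_rate
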