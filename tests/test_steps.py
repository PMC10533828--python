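import gzip

import numpy as np
import pytest

import dnatwin as dt


class TestSynthesize:
    def test_no_bias_no_errors_exact_copies(self, small_refs):
        params = dt.SynthesisParams(
            mean_coverage=100, coverage_sigma=0.0, insertion_rate=0.0
        )
        pool = dt.synthesize(small_refs, params, seed=1)
        per_ref = pool.counts_per_reference()
        assert np.all(per_ref == 100)
        assert sorted(pool.sequences) == sorted(small_refs.sequences)

    def test_coverage_sigma_recovered(self):
        refs_ids = [f"r{i}" for i in range(12000)]
        rng = np.random.default_rng(0)
        counts = dt.steps.draw_synthesis_counts(12000, 200, 0.27, rng)
        cov = dt.pools.coverage_from_counts(refs_ids, counts)
        assert dt.fit_lognormal_coverage(cov) == pytest.approx(0.27, abs=0.02)

    def test_electrochemical_mean_deletion_rate(self, refs_150):
        params = dt.synthesis_params(
            "electrochemical", mean_coverage=40, coverage_sigma=0.0, insertion_rate=0.0
        )
        pool = dt.synthesize(refs_150, params, seed=2)
        mean_len = sum(
            len(s) * c for s, c in zip(pool.sequences, pool.counts)
        ) / pool.total_count
        realized = (150 - mean_len) / 150
        assert realized == pytest.approx(0.0135, rel=0.10)


class TestPCR:
    def test_perfect_efficiency_exact_growth(self, small_refs):
        pool = dt.pool_from_references(small_refs, [10] * len(small_refs))
        params = dt.PCRParams(
            cycles=3, mean_efficiency=1.0, efficiency_sigma=0.0,
            substitution_rate_taq=0.0, max_molecules=None,
        )
        out = dt.pcr(pool, params, seed=1)
        assert out.total_count == 8 * pool.total_count
        assert np.all(out.counts_per_reference() == 80)

    def test_branching_growth_law(self, small_refs):
        pool = dt.pool_from_references(small_refs, [1000] * len(small_refs))
        params = dt.PCRParams(
            cycles=15, mean_efficiency=0.9, efficiency_sigma=0.0,
            substitution_rate_taq=0.0, max_molecules=None,
        )
        out = dt.pcr(pool, params, seed=2)
        growth = out.total_count / pool.total_count
        # branching-process sd of the growth factor at n0 = 20000
        sd = 1.9**15 * np.sqrt((1 - 0.9) / (1 + 0.9) / pool.total_count)
        assert abs(growth - 1.9**15) < 3 * sd / np.sqrt(1)

    def test_thinning_preserves_expected_growth(self, small_refs):
        pool = dt.pool_from_references(small_refs, [1000] * len(small_refs))
        params = dt.PCRParams(
            cycles=15, mean_efficiency=0.9, efficiency_sigma=0.0,
            substitution_rate_taq=0.0, max_molecules=5e4,
        )
        out = dt.pcr(pool, params, seed=3)
        assert out.tracked_count <= 5e4
        assert out.total_count / pool.total_count == pytest.approx(1.9**15, rel=0.05)

    def test_fidelity_scales_substitution_accrual(self, refs_150):
        pool = dt.pool_from_references(refs_150, [200] * len(refs_150))
        rates = {}
        for fid in (1.0, 280.0):
            params = dt.pcr_params(
                "taq", cycles=20, fidelity_relative_to_taq=fid,
                efficiency_sigma=0.0, max_molecules=2e5,
            )
            out = dt.pcr(pool, params, seed=4)
            rng = np.random.default_rng(0)
            idx = rng.choice(len(out.sequences), 20000, p=out.counts / out.counts.sum())
            nm = sum(
                sum(a != b for a, b in zip(out.sequences[i], refs_150.sequences[out.ref_index[i]]))
                for i in idx
            )
            rates[fid] = nm / (20000 * 150)
        assert rates[1.0] == pytest.approx(20 * 1.09e-4, rel=0.1)
        # Q5: 1/280 of the Taq accrual; just require a drastic reduction
        assert rates[280.0] < rates[1.0] / 50

    def test_efficiency_bias_skews_coverage_with_cycles(self, refs_150):
        pool = dt.pool_from_references(refs_150, [2000] * len(refs_150))
        sigmas = []
        for cycles in (5, 15):
            params = dt.PCRParams(
                cycles=cycles, efficiency_sigma=0.05,
                substitution_rate_taq=0.0, max_molecules=None,
            )
            out = dt.pcr(pool, params, seed=5)
            sigmas.append(dt.fit_lognormal_coverage(dt.normalized_coverage(out)))
        assert sigmas[1] > sigmas[0] > 0


class TestAge:
    def test_zero_half_lives_identity(self, small_refs):
        pool = dt.pool_from_references(small_refs, [50] * len(small_refs))
        out = dt.age(pool, dt.AgingParams(half_lives=0.0), seed=1)
        assert out.total_count == pool.total_count
        assert sorted(out.sequences) == sorted(pool.sequences)

    def test_eight_half_lives_survival(self, small_refs):
        pool = dt.pool_from_references(small_refs, [20000] * len(small_refs))
        out = dt.age(
            pool, dt.AgingParams(half_lives=8.0, substitution_rate_per_half_life=0.0), seed=2
        )
        n, p = pool.total_count, 2.0**-8
        assert abs(out.total_count - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_aging_substitution_load_and_bias(self, refs_150):
        pool = dt.pool_from_references(refs_150, [2000] * len(refs_150))
        out = dt.age(pool, dt.aging_params(half_lives=1.0), seed=3)
        nm = 0
        ct_ga = 0
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for s, c, r in zip(out.sequences, out.counts, out.ref_index):
            for a, b in zip(refs_150.sequences[r], s):
                if a != b:
                    nm += c
                    if (a, b) in (("C", "T"), ("G", "A")):
                        ct_ga += c
        rate = nm / (out.total_count * 150)
        assert rate == pytest.approx(1.64e-4, rel=0.15)
        assert ct_ga / nm == pytest.approx(0.77, abs=0.04)


class TestDilute:
    def test_keep_everything_is_identity(self, small_refs):
        pool = dt.pool_from_references(small_refs, [100] * len(small_refs))
        out = dt.dilute(pool, pool.mean_coverage, seed=1)
        assert out.total_count == pool.total_count

    def test_binomial_subsampling(self, small_refs):
        pool = dt.pool_from_references(small_refs, [1000] * len(small_refs))
        out = dt.dilute(pool, 100, seed=2)
        per_ref = out.counts_per_reference()
        sd = np.sqrt(1000 * 0.1 * 0.9)
        assert np.all(np.abs(per_ref - 100) < 5 * sd)

    def test_low_coverage_creates_dropout(self, refs_150):
        pool = dt.pool_from_references(refs_150, [100] * len(refs_150))
        out = dt.dilute(pool, 0.5, seed=3)
        assert (out.counts_per_reference() == 0).any()

    def test_dilute_up_rejected(self, small_refs):
        pool = dt.pool_from_references(small_refs, [10] * len(small_refs))
        with pytest.raises(ValueError, match="dilute up"):
            dt.dilute(pool, 20, seed=4)

    def test_sequential_dilutions_compose(self, small_refs):
        # dilute(p1) then dilute(p2) has the same mean as dilute(p1*p2)
        pool = dt.pool_from_references(small_refs, [40000] * len(small_refs))
        once = dt.dilute(pool, 40000 * 0.04 / 1, seed=5)  # p = 0.04
        twice = dt.dilute(dt.dilute(pool, 40000 * 0.2, seed=6), 40000 * 0.04, seed=7)
        n, p = pool.total_count, 0.04
        sd = np.sqrt(n * p)
        assert abs(once.total_count - n * p) < 4 * sd
        assert abs(twice.total_count - n * p) < 4 * sd


class TestSequence:
    def test_zero_error_reads_match_references(self, refs_150):
        pool = dt.pool_from_references(refs_150, [10] * len(refs_150))
        reads = dt.sequence(pool, dt.error_free_sequencing_params(500), seed=1)
        for r1, r2, t in zip(reads.r1, reads.r2, reads.true_ref):
            assert r1 == refs_150.sequences[t]
            assert r2 == dt.reverse_complement(refs_150.sequences[t])

    def test_sampling_proportional_to_counts(self, small_refs):
        counts = np.ones(len(small_refs), dtype=int)
        counts[0] = 9 * (len(small_refs) - 1)  # reference 0 holds 90% of copies
        pool = dt.pool_from_references(small_refs, counts)
        reads = dt.sequence(pool, dt.error_free_sequencing_params(5000), seed=2)
        frac = np.mean([t == 0 for t in reads.true_ref])
        assert abs(frac - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 5000)

    def test_short_molecules_give_short_reads(self, small_refs):
        pool = dt.OligoPool(
            ref_ids=list(small_refs.ids),
            sequences=[small_refs.sequences[0][:40]],
            counts=np.array([5]),
            ref_index=np.array([0]),
        )
        reads = dt.sequence(pool, dt.error_free_sequencing_params(10, read_length=60), seed=3)
        assert all(len(r) == 40 for r in reads.r1)


class TestWorkflow:
    def test_error_free_channel_is_identity(self, refs_150):
        config = [
            ("synthesize", dt.SynthesisParams(mean_coverage=20, insertion_rate=0.0)),
            ("sequence", dt.error_free_sequencing_params(200)),
        ]
        result = dt.run_workflow(config, refs_150, seed=9)
        for r1, t in zip(result.reads.r1, result.reads.true_ref):
            assert r1 == refs_150.sequences[t]

    def test_same_seed_byte_identical_fastq(self, small_refs, tmp_path):
        config = [
            ("synthesize", dt.synthesis_params("material_deposition", mean_coverage=20)),
            ("pcr", dt.pcr_params("taq", cycles=5, max_molecules=1e4)),
            ("sequence", dt.sequencing_params("iseq100", read_count=300)),
        ]
        outs = []
        for d in ("a", "b"):
            result = dt.run_workflow(config, small_refs, seed=42, outdir=tmp_path / d)
            with gzip.open(tmp_path / d / "reads_R1.fastq.gz") as fh:
                outs.append(fh.read())
        assert outs[0] == outs[1]

    def test_unknown_step_rejected_before_execution(self, small_refs):
        with pytest.raises(ValueError, match="unknown workflow step"):
            dt.run_workflow([("amplify", None)], small_refs, seed=0)

    def test_wrong_params_type_rejected(self, small_refs):
        with pytest.raises(TypeError):
            dt.run_workflow(
                [("synthesize", dt.PCRParams())], small_refs, seed=0
            )

    def test_provenance_log_structure(self, small_refs, tmp_path):
        config = [
            ("synthesize", dt.SynthesisParams(mean_coverage=10, insertion_rate=0.0)),
            ("dilute", 5.0),
        ]
        result = dt.run_workflow(config, small_refs, seed=1, outdir=tmp_path)
        assert [e["name"] for e in result.log] == ["synthesize", "dilute"]
        assert (tmp_path / "run_log.jsonl").exists()
        assert (tmp_path / "pool_snapshot.tsv").exists()
        assert result.log[1]["mean_coverage"] == pytest.approx(5.0, rel=0.4)
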