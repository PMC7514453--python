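"""Online estimator: trace identities, conjugate oracle accuracy, reservoir,
streaming, shift flagging."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import sgais as sg
from sgais.engine import EvidenceTrace, Reservoir, SGAISConfig, detect_shift, sgais_run
from sgais.model_api import ContractError, Dataset


class TestTrace:
    def test_empty_stream_single_origin_row(self, conjugate_model):
        trace = sgais_run(conjugate_model, Dataset(np.empty((0, 1))), SGAISConfig())
        assert trace.n_seen == [0]
        assert trace.final_log_evidence == 0.0

    def test_telescoping_identity_exact(self, conjugate_model, conjugate_data):
        trace = sgais_run(conjugate_model, conjugate_data,
                          SGAISConfig(chunk_size=20), seed=2)
        assert np.sum(trace.predictive_logprob) == pytest.approx(
            trace.final_log_evidence, abs=1e-10
        )
        assert trace.predictive_log_prob(1) == trace.log_evidence[1]

    def test_predictive_index_bounds(self, conjugate_model, conjugate_data):
        trace = sgais_run(conjugate_model, conjugate_data,
                          SGAISConfig(chunk_size=50), seed=2)
        with pytest.raises(IndexError):
            trace.predictive_log_prob(0)
        with pytest.raises(IndexError):
            trace.predictive_log_prob(trace.n_chunks + 1)

    def test_n_seen_strictly_increasing_enforced(self):
        trace = EvidenceTrace()
        trace.append(5, -1.0, 1, 10)
        with pytest.raises(ContractError):
            trace.append(5, -2.0, 1, 10)


class TestConjugateOracle:
    def test_log_evidence_matches_closed_form(self, conjugate_model, conjugate_data):
        exact = conjugate_model.exact_log_evidence(conjugate_data)
        cfg = SGAISConfig(n_particles=50, target_ess=25.0, chunk_size=20,
                          batch_size=None)
        trace = sgais_run(conjugate_model, conjugate_data, cfg, seed=0)
        assert abs(trace.final_log_evidence - exact) < 0.5

    def test_chunk_predictives_match_closed_form(self, conjugate_model, conjugate_data):
        cfg = SGAISConfig(n_particles=50, target_ess=25.0, chunk_size=20,
                          batch_size=None)
        trace = sgais_run(conjugate_model, conjugate_data, cfg, seed=0)
        records = conjugate_data.records
        for k in range(1, trace.n_chunks + 1):
            exact_pred = conjugate_model.exact_log_evidence(
                Dataset(records[: 20 * k])
            ) - conjugate_model.exact_log_evidence(Dataset(records[: 20 * (k - 1)]))
            assert trace.predictive_log_prob(k) == pytest.approx(exact_pred, abs=0.6)


class TestDeterminismAndStreaming:
    def test_same_seed_identical_trace(self, conjugate_model, conjugate_data):
        cfg = SGAISConfig(chunk_size=25)
        a = sgais_run(conjugate_model, conjugate_data, cfg, seed=9)
        b = sgais_run(conjugate_model, conjugate_data, cfg, seed=9)
        assert a.log_evidence == b.log_evidence

    def test_block_stream_equals_dataset_run(self, conjugate_model, conjugate_data):
        cfg = SGAISConfig(chunk_size=25)
        ref = sgais_run(conjugate_model, conjugate_data, cfg, seed=4)

        def stream():
            # ragged blocks; the engine must rechunk to chunk_size
            rec = conjugate_data.records
            for start, stop in [(0, 7), (7, 60), (60, 61), (61, 200)]:
                yield rec[start:stop]

        out = sgais_run(conjugate_model, stream(), cfg, seed=4)
        assert out.log_evidence == ref.log_evidence

    def test_record_width_mismatch_raises(self, conjugate_model):
        with pytest.raises(ContractError):
            sgais_run(conjugate_model, np.ones((10, 3)), SGAISConfig(chunk_size=5))


class TestReservoir:
    def test_below_capacity_always_stored(self, rng):
        res = Reservoir(10, 1)
        for i in range(7):
            sg.reservoir_update(res, np.array([float(i)]), rng)
        assert res.records.shape == (7, 1)
        assert res.stream_length == 7

    def test_zero_capacity_counts_but_stores_nothing(self, rng):
        res = Reservoir(0, 1)
        for i in range(5):
            sg.reservoir_update(res, np.array([1.0]), rng)
        assert res.stream_length == 5
        assert res.records.shape == (0, 1)

    def test_retention_uniform_over_stream(self):
        # every index retained with probability capacity / stream_length
        capacity, stream, reps = 50, 2000, 400
        counts = np.zeros(stream)
        rng = np.random.default_rng(123)
        for _ in range(reps):
            res = Reservoir(capacity, 1)
            for i in range(stream):
                res.update(np.array([float(i)]), rng)
            kept = res.records[:, 0].astype(int)
            counts[kept] += 1
        p = capacity / stream
        freqs = counts / reps
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(freqs.mean() - p) < 3 * se / np.sqrt(stream) + 1e-12
        # Bonferroni-style bound across all stream indices
        assert np.max(np.abs(freqs - p)) < 5 * se

    def test_reservoir_run_statistically_matches_exhaustive(self):
        model = sg.make_linreg_model()
        theta = sg.draw_true_parameters(model, seed=17)
        data = sg.simulate_dataset(model, theta, 10_000, seed=18)
        base = SGAISConfig()
        resv = SGAISConfig(reservoir_capacity=2_000)
        a = [sgais_run(model, data, base, seed=s).final_log_evidence for s in range(25)]
        b = [sgais_run(model, data, resv, seed=1000 + s).final_log_evidence
             for s in range(25)]
        assert mannwhitneyu(a, b).pvalue > 0.01


class TestAdaptiveScheduleEdge:
    def test_target_ess_one_single_jump_per_chunk(self, conjugate_model, conjugate_data):
        cfg = SGAISConfig(target_ess=1.0, chunk_size=20)
        trace = sgais_run(conjugate_model, conjugate_data, cfg, seed=0)
        assert all(s == 1 for s in trace.annealing_steps[1:])

    def test_resampling_preserves_estimate_path(self, conjugate_model, conjugate_data):
        cfg = SGAISConfig(chunk_size=20, resample=True)
        trace = sgais_run(conjugate_model, conjugate_data, cfg, seed=0)
        assert np.isfinite(trace.final_log_evidence)
        assert np.sum(trace.predictive_logprob) == pytest.approx(
            trace.final_log_evidence, abs=1e-10
        )


class TestDetectShift:
    def test_constant_trace_clean(self):
        trace = EvidenceTrace()
        for k in range(1, 40):
            trace.append(10 * k, -1.3 * 10 * k, 1, 100)
        assert detect_shift(trace) == []

    def test_stationary_conjugate_trace_clean(self, conjugate_model):
        data = sg.simulate_dataset(conjugate_model, [0.4], 2000, seed=3)
        trace = sgais_run(conjugate_model, data, SGAISConfig(chunk_size=50), seed=1)
        assert detect_shift(trace) == []

    def test_short_trace_never_flags(self):
        trace = EvidenceTrace()
        trace.append(10, -20.0, 1, 10)
        assert detect_shift(trace, window=5) == []


class TestUnbiasedness:
    def test_replicate_mean_matches_true_evidence(self, conjugate_model):
        # exact full-batch gradients; mean of Zhat over replicates close to Z
        data = sg.simulate_dataset(conjugate_model, [0.5], 30, seed=2)
        exact = conjugate_model.exact_log_evidence(data)
        cfg = SGAISConfig(chunk_size=10, batch_size=None)
        ratios = np.exp(
            [
                sgais_run(conjugate_model, data, cfg, seed=s).final_log_evidence - exact
                for s in range(300)
            ]
        )
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) < 3 * se


def test_config_validation():
    with pytest.raises(ContractError):
        SGAISConfig(target_ess=11.0, n_particles=10)
    with pytest.raises(ContractError):
        SGAISConfig(chunk_size=0)
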