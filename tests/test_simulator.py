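"""Time stepping: filters, run semantics, probes, CSV output."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nefsim import (
    EnsembleSpec,
    LIFParams,
    ModelSpec,
    NodeSpec,
    build,
    connect,
    lowpass_step,
    probe,
)
from nefsim.metrics import lowpass_filter, rmse
from nefsim.simulator import read_probe_csv, write_probe_csv


class TestLowpassStep:
    def test_no_tau_is_passthrough(self):
        assert np.array_equal(lowpass_step(np.ones(3), np.full(3, 2.0), 0.001, None),
                              np.full(3, 2.0))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(tau=st.floats(min_value=1e-3, max_value=1.0),
           steps=st.integers(min_value=1, max_value=300))
    def test_step_response_matches_closed_form(self, tau, steps):
        dt = 0.001
        y = 0.0
        for _ in range(steps):
            y = lowpass_step(y, 1.0, dt, tau)
        assert y == pytest.approx(1.0 - np.exp(-steps * dt / tau), abs=1e-9)

    def test_impulse_response_decays_exponentially(self):
        dt, tau = 0.001, 0.02
        y = lowpass_step(0.0, 1.0 / dt, dt, tau)
        trace = [y]
        for _ in range(50):
            y = lowpass_step(y, 0.0, dt, tau)
            trace.append(y)
        trace = np.asarray(trace)
        ratios = trace[1:] / trace[:-1]
        assert np.allclose(ratios, np.exp(-dt / tau), atol=1e-12)


class TestRunSemantics:
    def test_step_count_for_one_second(self, two_ensemble_model):
        m, p = two_ensemble_model
        plan = build(m, seed=0)
        data = plan.run(1.0)
        assert len(data[p]) == 1000

    def test_two_timestep_run(self):
        m = ModelSpec("m")
        n = NodeSpec("n", lambda t: np.array([t]), size_out=1)
        m.add(n)
        p = probe(n, "node_output", name="p")
        m.add(p)
        plan = build(m, dt=0.001, seed=0)
        data = plan.run(0.002)
        assert len(data[p]) == 2
        # nodes receive the time at the end of each step
        assert np.allclose(data[p].values[:, 0], [0.001, 0.002])

    def test_two_half_runs_equal_one_full_run(self, two_ensemble_model):
        m, p = two_ensemble_model
        plan_a = build(m, seed=4)
        full = plan_a.run(1.0)[p]
        plan_b = build(m, seed=4)
        plan_b.run(0.5)
        halves = plan_b.run(0.5)[p]
        assert np.array_equal(full.values, halves.values)
        assert np.array_equal(full.times, halves.times)

    def test_model_spec_not_mutated_by_build_or_run(self):
        m = ModelSpec("m")
        e = EnsembleSpec("A", LIFParams(20), 1)
        m.add(e)
        m.add(connect(e, e, filter_tau=0.05))
        assert e.encoders is None
        plan = build(m, seed=0)
        plan.run(0.01)
        assert e.encoders is None  # resolution stays inside the plan

    def test_identical_seeds_identical_builds(self, two_ensemble_model):
        m, p = two_ensemble_model
        v1 = build(m, seed=9).run(0.05)[p].values
        v2 = build(m, seed=9).run(0.05)[p].values
        assert np.array_equal(v1, v2)

    def test_wrong_node_output_length_reports_step_and_name(self):
        m = ModelSpec("m")
        bad = NodeSpec("bad", lambda t: np.ones(3 if t > 0.002 else 1), size_out=1)
        m.add(bad)
        plan = build(m, seed=0)
        with pytest.raises(RuntimeError, match="bad"):
            plan.run(0.01)

    def test_sample_every_subsamples_uniformly(self):
        m = ModelSpec("m")
        n = NodeSpec("n", lambda t: np.array([t]), size_out=1)
        m.add(n)
        p = probe(n, "node_output", sample_every=0.01, name="p")
        m.add(p)
        data = build(m, seed=0).run(0.1)
        rec = data[p]
        assert len(rec) == 10
        assert np.allclose(np.diff(rec.times), 0.01)


class TestProbeFiltering:
    def test_probe_filter_equals_posthoc_filtering(self):
        m = ModelSpec("m")
        e = EnsembleSpec("A", LIFParams(30), 1)
        n = NodeSpec("n", lambda t: np.array([np.sin(2 * np.pi * t)]), size_out=1)
        m.add(e)
        m.add(n)
        m.add(connect(n, e))
        p_raw = probe(e, "decoded_output", name="raw")
        p_filt = probe(e, "decoded_output", filter_tau=0.01, name="filt")
        m.add(p_raw)
        m.add(p_filt)
        data = build(m, seed=2).run(0.3)
        posthoc = lowpass_filter(data[p_raw].values, 0.001, 0.01)
        assert np.allclose(data[p_filt].values, posthoc, atol=1e-9)

    def test_halving_dt_keeps_decode_error_stable(self):
        """The communication channel's tracking error is dt-robust (< 20%)."""
        from nefsim.examples import NoiseSpec, communication_channel_model

        errors = {}
        for dt in (0.001, 0.0005):
            em = communication_channel_model(
                50, noise=NoiseSpec(duration=1.0, dt=dt, seed=0))
            plan = build(em.model, dt=dt, seed=0)
            data = plan.run(1.0)
            stim = data[em.probes["stim"]].values
            target = lowpass_filter(lowpass_filter(stim, dt, 0.005), dt, 0.005)
            errors[dt] = rmse(data[em.probes["decoded_B"]].values, target)
        rel_change = abs(errors[0.0005] - errors[0.001]) / errors[0.001]
        assert rel_change < 0.20


class TestProbeCSV:
    def test_round_trip_preserves_values_exactly(self, tmp_path, two_ensemble_model):
        m, p = two_ensemble_model
        rec = build(m, seed=1).run(0.05)[p]
        path = tmp_path / "out.csv"
        write_probe_csv(rec, path)
        back = read_probe_csv(path)
        assert np.array_equal(back.values, rec.values)
        assert np.array_equal(back.times, rec.times)

    def test_header_names_columns(self, tmp_path, two_ensemble_model):
        m, p = two_ensemble_model
        rec = build(m, seed=1).run(0.01)[p]
        path = tmp_path / "out.csv"
        write_probe_csv(rec, path)
        header = path.read_text().splitlines()[0]
        assert header == "time,pb[0]"
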