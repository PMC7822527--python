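import hashlib
from pathlib import Path

import numpy as np
import pytest

import dyadeda as dd
from dyadeda.errors import DataError, ParameterError


def dir_digest(root: Path) -> dict:
    return {p.relative_to(root).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(root.rglob("*")) if p.is_file()}


class TestSimConfig:
    def test_invalid_shared_fraction(self):
        with pytest.raises(ParameterError):
            dd.SimConfig(shared_fraction=1.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            dd.SimConfig(baseline_rate=-1.0)

    def test_saturating_window_rate_rejected(self):
        with pytest.raises(ParameterError, match="saturat"):
            dd.SimConfig(condition_rates={("proposer", 0): 2.0 * 64.0 * 60.0})

    def test_window_rate_lookup_fallbacks(self):
        cfg = dd.SimConfig(condition_rates={
            ("proposer", 0, "accepting"): 9.0, ("proposer", 0): 5.0,
            ("recipient",): 2.0})
        assert cfg.window_rate("proposer", 0, "accepting") == 9.0
        assert cfg.window_rate("proposer", 0, "non_accepting") == 5.0
        assert cfg.window_rate("recipient", 1, "accepting") == 2.0
        # no key at all: baseline
        assert cfg.window_rate("proposer", 1, "accepting") == cfg.baseline_rate

    def test_study_design_preset(self):
        cfg = dd.study_design_config()
        assert cfg.n_dyads == 30 and cfg.n_mixed_dyads == 15
        mixed = dd.simulate_dyad(cfg, 0)
        control = dd.simulate_dyad(cfg, 29)
        assert sorted(m.diagnosis for m in mixed.meta) == [0, 1]
        assert [m.diagnosis for m in control.meta] == [0, 0]


class TestSimulateDyad:
    CFG = dict(n_dyads=2, n_mixed_dyads=2, events_per_dyad=8,
               task_duration=220.0)

    def test_deterministic_given_seed_and_index(self):
        a = dd.simulate_dyad(dd.SimConfig(**self.CFG, seed=5), 0)
        b = dd.simulate_dyad(dd.SimConfig(**self.CFG, seed=5), 0)
        assert np.array_equal(a.traces[0].samples, b.traces[0].samples)
        assert a.events == b.events
        c = dd.simulate_dyad(dd.SimConfig(**self.CFG, seed=6), 0)
        assert not np.array_equal(a.traces[0].samples, c.traces[0].samples)

    def test_events_respect_min_gap_and_task_span(self):
        sim = dd.simulate_dyad(dd.SimConfig(**self.CFG, seed=2), 1)
        ends = [e.t_end for e in sim.events]
        assert all(b - a >= 10.0 for a, b in zip(ends, ends[1:]))
        assert all(0 < e.t_start < e.t_end < 220.0 for e in sim.events)
        assert len(sim.events) == 8

    def test_proposer_alternates(self):
        sim = dd.simulate_dyad(dd.SimConfig(**self.CFG, seed=2), 0)
        proposers = [e.proposer_id for e in sim.events]
        assert len(set(proposers)) == 2
        assert all(a != b for a, b in zip(proposers, proposers[1:]))

    def test_task_too_short_rejected(self):
        with pytest.raises(ParameterError, match="too short"):
            dd.simulate_dyad(
                dd.SimConfig(n_dyads=1, n_mixed_dyads=0, events_per_dyad=30,
                             task_duration=120.0), 0)

    def test_zero_rates_give_quiet_traces(self):
        cfg = dd.SimConfig(**self.CFG, seed=3, baseline_rate=0.0,
                           condition_rates={("proposer",): 0.0,
                                            ("recipient",): 0.0})
        sim = dd.simulate_dyad(cfg, 0)
        assert sim.truth.impulse_times[sim.traces[0].participant_id] == []
        _, peaks = dd.process_participant(sim.traces[0], dd.PipelineConfig())
        assert len(peaks) == 0

    def test_truth_counts_match_poisson_expectation(self):
        # baseline 3/min for 10 minutes -> ~30 impulses on average
        total = 0
        n_rep = 60
        cfg_base = dict(n_dyads=1, n_mixed_dyads=0, events_per_dyad=2,
                        task_duration=600.0, baseline_rate=3.0,
                        condition_rates={("proposer",): 3.0,
                                         ("recipient",): 3.0})
        for seed in range(n_rep):
            sim = dd.simulate_dyad(dd.SimConfig(**cfg_base, seed=seed), 0)
            total += len(sim.truth.impulse_times[sim.traces[0].participant_id])
        mean = total / n_rep
        se = np.sqrt(30.0 / n_rep)
        assert abs(mean - 30.0) < 4 * se

    def test_full_sharing_yields_highly_correlated_drivers(self):
        cfg = dd.SimConfig(n_dyads=1, n_mixed_dyads=0, events_per_dyad=4,
                           task_duration=160.0, shared_fraction=1.0,
                           noise_sd=1e-4, drift_sd=0.0,
                           baseline_rate=6.0,
                           condition_rates={("proposer",): 6.0,
                                            ("recipient",): 6.0}, seed=8)
        sim = dd.simulate_dyad(cfg, 0)
        pc = dd.PipelineConfig()
        da, _ = dd.process_participant(sim.traces[0], pc)
        db, _ = dd.process_participant(sim.traces[1], pc)
        r, _ = dd.segment_correlation(da, db, [(0.0, 160.0)])
        assert r > 0.95

    def test_synchrony_monotone_in_shared_fraction(self):
        rs = []
        for rho in (0.0, 0.5, 1.0):
            cfg = dd.SimConfig(n_dyads=1, n_mixed_dyads=0, events_per_dyad=4,
                               task_duration=200.0, shared_fraction=rho,
                               noise_sd=1e-3, drift_sd=0.0, baseline_rate=8.0,
                               condition_rates={("proposer",): 8.0,
                                                ("recipient",): 8.0}, seed=4)
            sim = dd.simulate_dyad(cfg, 0)
            pc = dd.PipelineConfig()
            da, _ = dd.process_participant(sim.traces[0], pc)
            db, _ = dd.process_participant(sim.traces[1], pc)
            r, _ = dd.segment_correlation(da, db, [(0.0, 200.0)])
            rs.append(r)
        assert rs == sorted(rs)
        assert abs(rs[0]) < 0.2  # no sharing, no event co-occurrence boost

    def test_response_mix_follows_probabilities(self):
        cfg = dd.SimConfig(n_dyads=8, n_mixed_dyads=4, events_per_dyad=30,
                           task_duration=480.0, p_accepting=0.44,
                           p_rejecting=0.01, seed=0)
        responses = []
        for k in range(cfg.n_dyads):
            responses += [e.response for e in dd.simulate_dyad(cfg, k).events]
        frac_acc = np.mean([r == "accepting" for r in responses])
        assert frac_acc == pytest.approx(0.44, abs=0.06)
        assert "rejecting" in set(responses) or cfg.p_rejecting == 0


class TestSimulateStudy:
    def test_file_layout_and_counts(self, study_dir):
        traces = sorted((study_dir / "traces").glob("*.csv"))
        grids = sorted((study_dir / "annotations").glob("*.TextGrid"))
        assert len(traces) == 4
        assert len(grids) == 2
        events = dd.read_proposal_events(study_dir / "events.csv",
                                         dialect="columnar")
        assert len(events) == 16
        meta = dd.read_participant_meta(study_dir / "meta.csv")
        assert len(meta) == 4
        assert (study_dir / "truth.json").exists()

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = dd.SimConfig(n_dyads=2, n_mixed_dyads=1, events_per_dyad=4,
                           task_duration=160.0, seed=9)
        dd.simulate_study(cfg, outdir=tmp_path / "a")
        dd.simulate_study(cfg, outdir=tmp_path / "b")
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_existing_output_dir_needs_overwrite(self, tmp_path):
        cfg = dd.SimConfig(n_dyads=2, n_mixed_dyads=1, events_per_dyad=4,
                           task_duration=160.0, seed=9)
        out = tmp_path / "s"
        dd.simulate_study(cfg, outdir=out)
        with pytest.raises(DataError, match="overwrite"):
            dd.simulate_study(cfg, outdir=out)
        dd.simulate_study(cfg, outdir=out, overwrite=True)

    def test_textgrid_annotations_round_trip_events(self, study_dir):
        events = dd.read_proposal_events(study_dir / "events.csv",
                                         dialect="columnar")
        d1 = [e for e in events if e.dyad_id == "d001"]
        back = dd.read_proposal_events(
            study_dir / "annotations" / "d001.TextGrid",
            dialect="textgrid", dyad_id="d001")
        assert len(back) == len(d1)
        for a, b in zip(d1, back):
            assert a.proposer_id == b.proposer_id
            assert a.response == b.response
            assert a.t_end == pytest.approx(b.t_end, abs=1e-5)
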