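"""Synthetic dyadic skin-conductance studies with known ground truth.

Each simulated participant's SCR impulses follow an inhomogeneous Poisson
process: a baseline rate outside proposal windows, and a condition-specific
rate (keyed by role, diagnosis and response type) inside the [-1 s, +4 s]
window around each proposal end. A configurable fraction of impulses is
drawn from a dyad-common stream and copied to both members, which controls
physiological synchrony. Every impulse receives a lognormal peak amplitude,
is convolved with the peak-normalized Bateman kernel, and is superimposed
on a tonic level with slow Gaussian-random-walk drift plus white
measurement noise.

Defaults mirror the study conditions the analysis is meant for: 128 Hz
sampling, condition rates at the observed group means (proposer 4.60/5.99
and recipient 2.91/3.91 SCR/min for non-depressed/depressed participants),
baseline 2.76 SCR/min, accepting responses with probability 0.44, and a
15 mixed + 15 control dyad design. Amplitudes (median 0.3 μS,
sigma_log 0.25) sit far above the 0.05 μS detection cut-off so recovery
experiments exercise the pipeline rather than the signal-to-noise ratio.

The generator records everything needed to verify recovery (impulse times,
shared-stream times, per-window generating rates) in :class:`SimTruth`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import signal

from .deconvolution import bateman_kernel
from .errors import DataError, ParameterError
from .io_formats import (ParticipantMeta, ProposalEvent, SCTrace,
                         write_participant_meta, write_proposal_events,
                         write_sc_trace, write_textgrid)

#: Default condition rates (SCR/min inside proposal windows), keyed by
#: (role, diagnosis): the observed group means of the four cells.
DEFAULT_CONDITION_RATES: dict[tuple, float] = {
    ("proposer", 0): 4.60,
    ("proposer", 1): 5.99,
    ("recipient", 0): 2.91,
    ("recipient", 1): 3.91,
}
DEFAULT_BASELINE_RATE = 2.76


@dataclass
class SimConfig:
    """Generating parameters of a synthetic study."""

    n_dyads: int = 30
    n_mixed_dyads: int = 15          # dyads whose first member has diagnosis=1
    events_per_dyad: int = 35        # ~1046 proposals over 30 dyads
    fs: float = 128.0
    task_duration: float = 600.0     # s
    baseline_rate: float = DEFAULT_BASELINE_RATE          # SCR/min
    condition_rates: Mapping[tuple, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_RATES))
    amplitude_mu_log: float = math.log(0.3)   # lognormal median 0.3 μS
    amplitude_sigma_log: float = 0.25
    shared_fraction: float = 0.15    # ρ: dyad-common impulse fraction
    tonic_level: float = 2.0         # μS
    drift_sd: float = 0.01           # μS per sqrt(s), random-walk drift
    noise_sd: float = 0.005          # μS white measurement noise
    p_accepting: float = 0.44
    p_rejecting: float = 0.0
    pre: float = 1.0                 # window extent before proposal end (s)
    post: float = 4.0                # window extent after proposal end (s)
    min_gap: float = 10.0            # min spacing between proposal ends (s)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.shared_fraction <= 1:
            raise ParameterError(f"shared_fraction must be in [0,1], got {self.shared_fraction}")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.baseline_rate < 0 or any(v < 0 for v in self.condition_rates.values()):
            raise ParameterError("rates must be non-negative")
        if self.amplitude_sigma_log <= 0:
            raise ParameterError("amplitude_sigma_log must be positive")
        if not 0 <= self.p_accepting + self.p_rejecting <= 1:
            raise ParameterError("response probabilities must sum to at most 1")
        max_rate = max([self.baseline_rate, *self.condition_rates.values()])
        if max_rate / 60.0 > self.fs / 2.0:
            raise ParameterError(
                "window impulse rate saturates the sampling grid "
                "(more than one impulse per 2 samples)"
            )

    def window_rate(self, role: str, diagnosis: int, response: str) -> float:
        """Generating SCR rate inside a proposal window for one participant."""
        for key in ((role, diagnosis, response), (role, diagnosis), (role,)):
            if key in self.condition_rates:
                return float(self.condition_rates[key])
        return float(self.baseline_rate)


def study_design_config(**overrides) -> SimConfig:
    """The 30-dyad design: 15 dyads with one diagnosed member, 15 controls."""
    cfg = SimConfig()
    return replace(cfg, n_dyads=30, n_mixed_dyads=15, **overrides)


@dataclass
class SimTruth:
    """Ground truth of one simulated dyad."""

    dyad_id: str
    config: dict
    diagnosis: dict[str, int]
    window_rates: dict[str, list[float]]      # pid -> per-event generating rate
    impulse_times: dict[str, list[float]]     # pid -> all impulse times (s)
    shared_times: list[float]
    amplitudes: dict[str, list[float]]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DyadSim:
    traces: tuple[SCTrace, SCTrace]
    events: list[ProposalEvent]
    meta: tuple[ParticipantMeta, ParticipantMeta]
    truth: SimTruth


@dataclass
class StudyBundle:
    traces: dict[str, SCTrace]
    events: list[ProposalEvent]
    meta: list[ParticipantMeta]
    truths: dict[str, SimTruth]
    config: SimConfig


def _dyad_rng(config: SimConfig, dyad_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(dyad_index,))
    )


def _place_events(config: SimConfig, rng: np.random.Generator,
                  dyad_id: str, pids: tuple[str, str]) -> list[ProposalEvent]:
    """Non-overlapping proposals: consecutive ends at least min_gap apart."""
    n = config.events_per_dyad
    lead = config.pre + 6.0          # room for the window and RL edge
    tail = config.post + 6.0
    span = config.task_duration - lead - tail
    spacing = span / max(n - 1, 1)
    if n > 1 and spacing < config.min_gap:
        raise ParameterError(
            f"task_duration {config.task_duration}s too short for {n} events "
            f"with min_gap {config.min_gap}s"
        )
    jitter = 0.45 * max(0.0, spacing - config.min_gap) if n > 1 else 0.0
    jitter = min(jitter, 2.0)
    resp_p = [config.p_accepting, 1 - config.p_accepting - config.p_rejecting,
              config.p_rejecting]
    events = []
    for k in range(n):
        t_end = lead + k * spacing + rng.uniform(-jitter, jitter)
        dur = rng.uniform(1.5, 4.0)
        response = rng.choice(["accepting", "non_accepting", "rejecting"], p=resp_p)
        events.append(ProposalEvent(
            dyad_id=dyad_id, event_id=f"{dyad_id}_e{k + 1}",
            proposer_id=pids[k % 2],
            t_start=t_end - dur, t_end=t_end, response=str(response),
        ))
    return events


def _sample_poisson_times(rng: np.random.Generator, rate_per_min: float,
                          t0: float, t1: float) -> np.ndarray:
    lam = rate_per_min / 60.0 * (t1 - t0)
    if lam <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(lam)
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_dyad(config: SimConfig, dyad_index: int) -> DyadSim:
    """One dyad's traces, annotations, metadata and ground truth.

    Deterministic given ``(config.seed, dyad_index)``.
    """
    if not 0 <= dyad_index < config.n_dyads:
        raise ParameterError(f"dyad_index {dyad_index} outside 0..{config.n_dyads - 1}")
    rng = _dyad_rng(config, dyad_index)
    dyad_id = f"d{dyad_index + 1:03d}"
    pids = (f"{dyad_id}a", f"{dyad_id}b")
    mixed = dyad_index < config.n_mixed_dyads
    diagnosis = {pids[0]: 1 if mixed else 0, pids[1]: 0}

    events = _place_events(config, rng, dyad_id, pids)

    # piecewise-constant rate boundaries: baseline outside windows,
    # condition rate inside each event's window
    cuts = [0.0]
    seg_rates: list[tuple[float, float]] = []  # per segment (rate_a, rate_b)
    cursor = 0.0
    window_rates: dict[str, list[float]] = {pids[0]: [], pids[1]: []}
    for e in events:
        w0, w1 = e.t_end - config.pre, e.t_end + config.post
        rates = {}
        for pid in pids:
            role = "proposer" if pid == e.proposer_id else "recipient"
            rates[pid] = config.window_rate(role, diagnosis[pid], e.response)
            window_rates[pid].append(rates[pid])
        seg_rates.append((config.baseline_rate, config.baseline_rate))
        cuts.append(w0)
        seg_rates.append((rates[pids[0]], rates[pids[1]]))
        cuts.append(w1)
        cursor = w1
    seg_rates.append((config.baseline_rate, config.baseline_rate))
    cuts.append(config.task_duration)

    rho = config.shared_fraction
    times: dict[str, list[np.ndarray]] = {pids[0]: [], pids[1]: []}
    shared_all: list[np.ndarray] = []
    shared_flag: dict[str, list[np.ndarray]] = {pids[0]: [], pids[1]: []}
    for (t0, t1), (ra, rb) in zip(zip(cuts[:-1], cuts[1:]), seg_rates):
        r_shared = rho * min(ra, rb)
        ts = _sample_poisson_times(rng, r_shared, t0, t1)
        ta = _sample_poisson_times(rng, ra - r_shared, t0, t1)
        tb = _sample_poisson_times(rng, rb - r_shared, t0, t1)
        shared_all.append(ts)
        for pid, own in ((pids[0], ta), (pids[1], tb)):
            times[pid].append(own)
            times[pid].append(ts)
            shared_flag[pid].append(np.zeros(own.size, dtype=bool))
            shared_flag[pid].append(np.ones(ts.size, dtype=bool))

    shared_times = np.concatenate(shared_all) if shared_all else np.empty(0)
    order_s = np.argsort(shared_times)
    shared_times = shared_times[order_s]
    shared_amp = np.exp(rng.normal(config.amplitude_mu_log,
                                   config.amplitude_sigma_log,
                                   size=shared_times.size))

    n_samples = int(round(config.task_duration * config.fs))
    kernel = bateman_kernel(fs=config.fs)
    h_peak = kernel.samples / kernel.samples.max()

    traces = []
    impulse_times: dict[str, list[float]] = {}
    amplitudes: dict[str, list[float]] = {}
    for pid in pids:
        t_all = np.concatenate(times[pid]) if times[pid] else np.empty(0)
        is_shared = (np.concatenate(shared_flag[pid]) if shared_flag[pid]
                     else np.empty(0, dtype=bool))
        amp = np.exp(rng.normal(config.amplitude_mu_log,
                                config.amplitude_sigma_log, size=t_all.size))
        # shared impulses reuse the dyad-common amplitude draw
        if shared_times.size:
            pos = np.searchsorted(shared_times, t_all[is_shared])
            amp[is_shared] = shared_amp[np.clip(pos, 0, shared_times.size - 1)]
        order = np.argsort(t_all)
        t_all, amp = t_all[order], amp[order]

        imp = np.zeros(n_samples)
        idx = np.clip(np.round(t_all * config.fs).astype(int), 0, n_samples - 1)
        np.add.at(imp, idx, amp)
        phasic = signal.oaconvolve(imp, h_peak)[:n_samples] if t_all.size else imp

        drift = np.cumsum(rng.normal(0.0, config.drift_sd / math.sqrt(config.fs),
                                     size=n_samples))
        noise = rng.normal(0.0, config.noise_sd, size=n_samples)
        sc = config.tonic_level + drift + phasic + noise
        traces.append(SCTrace(participant_id=pid, dyad_id=dyad_id,
                              fs=config.fs, samples=np.maximum(sc, 1e-3)))
        impulse_times[pid] = [float(v) for v in t_all]
        amplitudes[pid] = [float(v) for v in amp]

    cfg_dict = asdict(config)
    cfg_dict["condition_rates"] = {
        "|".join(map(str, k)): v for k, v in config.condition_rates.items()
    }
    truth = SimTruth(
        dyad_id=dyad_id, config=cfg_dict, diagnosis=diagnosis,
        window_rates=window_rates, impulse_times=impulse_times,
        shared_times=[float(v) for v in shared_times],
        amplitudes=amplitudes,
    )
    meta = (ParticipantMeta(pids[0], dyad_id, diagnosis[pids[0]]),
            ParticipantMeta(pids[1], dyad_id, diagnosis[pids[1]]))
    return DyadSim(traces=(traces[0], traces[1]), events=events,
                   meta=meta, truth=truth)


def simulate_study(config: SimConfig, outdir: str | Path | None = None,
                   overwrite: bool = False) -> StudyBundle:
    """Simulate every dyad; optionally write the study to disk.

    On-disk layout: ``traces/<pid>.csv`` (two-column CSV),
    ``annotations/<dyad>.TextGrid``, ``events.csv`` (columnar dialect),
    ``meta.csv`` and ``truth.json``.
    """
    bundle = StudyBundle(traces={}, events=[], meta=[], truths={}, config=config)
    for k in range(config.n_dyads):
        sim = simulate_dyad(config, k)
        for tr in sim.traces:
            bundle.traces[tr.participant_id] = tr
        bundle.events.extend(sim.events)
        bundle.meta.extend(sim.meta)
        bundle.truths[sim.truth.dyad_id] = sim.truth
    if outdir is not None:
        outdir = Path(outdir)
        if outdir.exists() and any(outdir.iterdir()) and not overwrite:
            raise DataError(f"output directory {outdir} exists; pass overwrite=True")
        (outdir / "traces").mkdir(parents=True, exist_ok=True)
        (outdir / "annotations").mkdir(parents=True, exist_ok=True)
        for pid, tr in bundle.traces.items():
            write_sc_trace(tr, outdir / "traces" / f"{pid}.csv")
        for dyad_id, truth in bundle.truths.items():
            dyad_events = [e for e in bundle.events if e.dyad_id == dyad_id]
            write_textgrid(dyad_events, outdir / "annotations" / f"{dyad_id}.TextGrid",
                           xmin=0.0, xmax=config.task_duration)
        write_proposal_events(bundle.events, outdir / "events.csv")
        write_participant_meta(bundle.meta, outdir / "meta.csv")
        (outdir / "truth.json").write_text(json.dumps(
            {d: t.to_dict() for d, t in bundle.truths.items()},
            indent=1, sort_keys=True) + "\n")
    return bundle


# ---------------------------------------------------------------------------
# Direct rate-table simulation (mixed-model ground truth, no signal synthesis)
# ---------------------------------------------------------------------------

def simulate_rate_records(
    n_dyads: int = 30,
    events_per_dyad: int = 10,
    beta: tuple[float, float, float, float] = (2.9, 1.7, 1.2, 0.4),
    sd_dyad: float = 0.8,
    sd_participant: float = 0.6,
    sd_resid: float = 2.0,
    design: str = "role_diagnosis",
    p_accepting: float = 0.5,
    seed: int = 0,
):
    """Draw RateRecords straight from the Gaussian mixed model.

    ``beta`` is (intercept, factor1, factor2, interaction) on the model's 0/1
    coding — factor1 is Role (or Response for the ``response_diagnosis``
    design), factor2 is Diagnosis. Every dyad has one diagnosed member so
    both factors vary within and between dyads. Rates may go negative at
    large noise; that is fine for exercising the estimator.
    """
    from .dyad_metrics import RateRecord

    if design not in ("role_diagnosis", "response_diagnosis"):
        raise ParameterError(f"unknown design {design!r}")
    rng = np.random.default_rng(seed)
    b0, b1, b2, b12 = beta
    records = []
    for d in range(n_dyads):
        dyad_id = f"s{d + 1:03d}"
        pids = (f"{dyad_id}a", f"{dyad_id}b")
        diag = {pids[0]: 1, pids[1]: 0}
        u_d = rng.normal(0, sd_dyad)
        u_p = {pid: rng.normal(0, sd_participant) for pid in pids}
        for k in range(events_per_dyad):
            proposer = pids[k % 2]
            response = "accepting" if rng.random() < p_accepting else "non_accepting"
            for pid in pids:
                role = "proposer" if pid == proposer else "recipient"
                if design == "response_diagnosis" and role != "proposer":
                    continue
                x1 = (1.0 if role == "proposer" else 0.0) \
                    if design == "role_diagnosis" \
                    else (1.0 if response == "accepting" else 0.0)
                x2 = float(diag[pid])
                mu = b0 + b1 * x1 + b2 * x2 + b12 * x1 * x2
                rate = mu + u_d + u_p[pid] + rng.normal(0, sd_resid)
                records.append(RateRecord(
                    dyad_id=dyad_id, participant_id=pid,
                    event_id=f"{dyad_id}_e{k + 1}", role=role,
                    diagnosis=diag[pid], response=response, rate=float(rate),
                ))
    return records
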