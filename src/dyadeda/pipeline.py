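"""End-to-end orchestration: traces + annotations -> stats report.

Stages run in the order the analysis is defined: deconvolution of every
trace into a z-normalized phasic driver, SCR peak detection, proposal
window construction and task segmentation, the per-event rate table,
per-dyad synchrony with its proposal vs non-proposal contrast, and the two
mixed models. Each stage is exposed on its own (and as a CLI subcommand)
so any intermediate product can be regenerated from its predecessor's
files.

All analysis parameters default to the study's stated values: 0.05 μS
prominence, 1 SD height, window from 1 s before to 4 s after the proposal
end, 128 Hz sampling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconvolution as dec
from .dyad_metrics import (RateRecord, SynchronyContrast, SynchronyResult,
                           build_rate_table, dyad_synchrony, overall_rate)
from .errors import DyadEdaError, FormatError
from .event_windows import (Segmentation, Window, build_proposal_windows,
                            infer_task_span, segment_task)
from .io_formats import (ParticipantMeta, ProposalEvent, SCTrace,
                         read_participant_meta, read_proposal_events,
                         read_sc_trace, validate_dyads, write_json_report)
from .scr_detect import SCRPeak, detect_scr_peaks
from .stats_models import (GLMMResult, fit_response_diagnosis_glmm,
                           fit_role_diagnosis_glmm, records_to_frame)

logger = logging.getLogger("dyadeda")
if not logger.handlers:  # stderr logging, configured once at import
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)  # CLI raises this to INFO


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults are the study's stated values."""

    input_dir: str | None = None      # simulate_study layout
    output_dir: str | None = None
    fs: float = 128.0
    tau_rise: float = dec.DEFAULT_TAU_RISE
    tau_decay: float = dec.DEFAULT_TAU_DECAY
    kernel_support: float | None = None
    n_iter: int = dec.DEFAULT_N_ITER
    detrend_window: float = dec.DEFAULT_DETREND_WINDOW
    rl_tol: float = 1e-6
    rl_accelerate: bool = True
    prominence_min: float = 0.05     # μS
    height_min_sd: float = 1.0       # SD units
    pre: float = 1.0                 # s before proposal end
    post: float = 4.0                # s after proposal end
    task_start: float | None = None  # None: infer from annotations
    task_end: float | None = None
    fit_role_model: bool = True
    fit_response_model: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"config file not found: {path}")
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} \
            else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    """All pipeline products for one study."""

    drivers: dict[str, dec.DriverSignal]
    peaks: dict[str, list[SCRPeak]]
    windows: dict[str, list[Window]]
    segmentations: dict[str, Segmentation]
    rate_table: list[RateRecord]
    synchrony: list[SynchronyResult]
    contrast: SynchronyContrast | None
    glmm_role: GLMMResult | None
    glmm_response: GLMMResult | None
    overall_rates: dict[str, float]           # per participant
    dyad_mean_rates: dict[str, float]
    notes: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        dyad_means = list(self.dyad_mean_rates.values())
        out = {
            "n_participants": len(self.drivers),
            "n_dyads": len(self.dyad_mean_rates),
            "n_rate_records": len(self.rate_table),
            "overall_rate_mean_of_dyad_means":
                float(np.mean(dyad_means)) if dyad_means else None,
            "mean_window_rate":
                float(np.mean([r.rate for r in self.rate_table]))
                if self.rate_table else None,
            "notes": self.notes,
        }
        if self.contrast is not None:
            c = self.contrast
            out["synchrony"] = {
                "mean_r_proposal": c.mean_r_proposal,
                "mean_r_nonproposal": c.mean_r_nonproposal,
                "t": c.t, "p": c.p, "cohens_d": c.d, "n_dyads": c.n_dyads,
            }
        if self.glmm_role is not None:
            out["glmm_role_diagnosis"] = self.glmm_role.to_dict()
        if self.glmm_response is not None:
            out["glmm_response_diagnosis"] = self.glmm_response.to_dict()
        return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def process_participant(trace: SCTrace, config: PipelineConfig
                        ) -> tuple[dec.DriverSignal, list[SCRPeak]]:
    """Deconvolve one trace, z-normalize, and detect SCR peaks."""
    kernel = dec.bateman_kernel(config.tau_rise, config.tau_decay,
                                fs=trace.fs, support=config.kernel_support)
    driver = dec.deconvolve_rl(trace, kernel, n_iter=config.n_iter,
                               detrend_window=config.detrend_window,
                               tol=config.rl_tol,
                               accelerate=config.rl_accelerate)
    if np.ptp(driver.samples) == 0:
        return driver, []
    driver = dec.znormalize(driver)
    peaks = detect_scr_peaks(driver, config.prominence_min, config.height_min_sd)
    return driver, peaks


def analyze_study(
    traces: dict[str, SCTrace],
    events: list[ProposalEvent],
    meta: list[ParticipantMeta],
    config: PipelineConfig | None = None,
) -> StudyReport:
    """Run the full analysis in memory on an already-loaded study."""
    config = config or PipelineConfig()
    dyads = validate_dyads(meta)
    notes: list[str] = []

    drivers: dict[str, dec.DriverSignal] = {}
    peaks: dict[str, list[SCRPeak]] = {}
    for pid, trace in sorted(traces.items()):
        logger.info("deconvolving %s (%d samples at %g Hz)",
                    pid, trace.samples.size, trace.fs)
        drivers[pid], peaks[pid] = process_participant(trace, config)

    kept_events = [e for e in events if e.response != "rejecting"]
    n_rej = len(events) - len(kept_events)
    if n_rej:
        notes.append(f"excluded {n_rej} rejecting events")

    windows: dict[str, list[Window]] = {}
    segmentations: dict[str, Segmentation] = {}
    rate_table: list[RateRecord] = []
    synchrony: list[SynchronyResult] = []
    overall: dict[str, float] = {}
    dyad_means: dict[str, float] = {}

    for dyad_id, members in sorted(dyads.items()):
        dyad_events = [e for e in kept_events if e.dyad_id == dyad_id]
        if not dyad_events:
            notes.append(f"dyad {dyad_id}: no retained events")
            continue
        pid_a, pid_b = members[0].participant_id, members[1].participant_id
        rec_end = min(traces[pid_a].duration + traces[pid_a].t0,
                      traces[pid_b].duration + traces[pid_b].t0)
        rec_start = max(traces[pid_a].t0, traces[pid_b].t0)
        if config.task_start is not None and config.task_end is not None:
            span = (config.task_start, config.task_end)
        else:
            span = infer_task_span(dyad_events, config.pre, config.post)
            span = (max(span[0], rec_start), min(span[1], rec_end))
        wins = build_proposal_windows(dyad_events, config.pre, config.post,
                                      recording_start=rec_start,
                                      recording_end=rec_end)
        windows[dyad_id] = wins
        segmentations[dyad_id] = segment_task(wins, *span)
        rate_table.extend(build_rate_table(
            dyad_events, wins,
            {pid_a: peaks[pid_a], pid_b: peaks[pid_b]}, list(members)))
        try:
            synchrony.append(dyad_synchrony(drivers[pid_a], drivers[pid_b],
                                            segmentations[dyad_id], dyad_id))
        except DyadEdaError as exc:
            notes.append(f"dyad {dyad_id}: synchrony undefined ({exc})")
        rates = [overall_rate(peaks[p], *span) for p in (pid_a, pid_b)]
        overall[pid_a], overall[pid_b] = rates
        dyad_means[dyad_id] = float(np.mean(rates))

    contrast = None
    if len(synchrony) >= 2:
        from .dyad_metrics import synchrony_contrast
        try:
            contrast = synchrony_contrast(synchrony)
        except DyadEdaError as exc:
            notes.append(f"synchrony contrast unavailable ({exc})")

    glmm_role = glmm_response = None
    df = records_to_frame(rate_table)
    if config.fit_role_model and len(df):
        if df["Diagnosis"].nunique() == 2:
            try:
                glmm_role = fit_role_diagnosis_glmm(df)
            except DyadEdaError as exc:
                notes.append(f"role model not fit ({exc})")
        else:
            notes.append("role model skipped: diagnosis does not vary")
    if config.fit_response_model and len(df):
        prop = df[df["role"] == "proposer"]
        if prop["Response"].nunique() == 2 and prop["Diagnosis"].nunique() == 2:
            try:
                glmm_response = fit_response_diagnosis_glmm(prop)
            except DyadEdaError as exc:
                notes.append(f"response model not fit ({exc})")
        else:
            notes.append("response model skipped: a factor does not vary "
                         "among proposer rows")

    return StudyReport(drivers=drivers, peaks=peaks, windows=windows,
                       segmentations=segmentations, rate_table=rate_table,
                       synchrony=synchrony, contrast=contrast,
                       glmm_role=glmm_role, glmm_response=glmm_response,
                       overall_rates=overall, dyad_mean_rates=dyad_means,
                       notes=notes)


# ---------------------------------------------------------------------------
# Disk-level run
# ---------------------------------------------------------------------------

def load_study(input_dir: str | Path, fs_hint: float | None = None):
    """Load a study written in the simulate_study layout."""
    input_dir = Path(input_dir)
    meta_path = input_dir / "meta.csv"
    meta = read_participant_meta(meta_path)
    events_path = input_dir / "events.csv"
    if events_path.exists():
        events = read_proposal_events(events_path, dialect="columnar")
    else:
        events = []
        tg_dir = input_dir / "annotations"
        if not tg_dir.exists():
            raise FormatError(f"no events.csv or annotations/ under {input_dir}")
        for tg in sorted(tg_dir.glob("*.TextGrid")):
            events.extend(read_proposal_events(tg, dialect="textgrid",
                                               dyad_id=tg.stem))
        events.sort(key=lambda e: (e.dyad_id, e.t_start))
    traces = {}
    for m in meta:
        tpath = input_dir / "traces" / f"{m.participant_id}.csv"
        traces[m.participant_id] = read_sc_trace(
            tpath, m.participant_id, m.dyad_id, fs=fs_hint)
    return traces, events, meta


def _stage(name: str):
    """Decorate a pipeline step so failures name their stage."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DyadEdaError as exc:
                raise DyadEdaError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Disk-in, disk-out: load the study, analyze, write every product."""
    if config.input_dir is None:
        raise FormatError("config.input_dir is required")
    traces, events, meta = _stage("load")(load_study)(config.input_dir)
    report = analyze_study(traces, events, meta, config)
    if config.output_dir is not None:
        write_report(report, config, Path(config.output_dir))
    return report


def write_report(report: StudyReport, config: PipelineConfig,
                 outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "drivers").mkdir(exist_ok=True)
    for pid, drv in report.drivers.items():
        df = pd.DataFrame({"time_s": drv.times, "driver": drv.samples})
        if drv.znorm:
            df["driver_z"] = drv.z
        df.to_csv(outdir / "drivers" / f"{pid}.csv", index=False,
                  float_format="%.6f")
    pd.DataFrame([
        {"participant_id": p.participant_id, "time_s": p.time,
         "height_z": p.height_z, "prominence_us": p.prominence_us}
        for pk in report.peaks.values() for p in pk
    ]).to_csv(outdir / "peaks.csv", index=False, float_format="%.6f")
    pd.DataFrame([
        {"dyad_id": d, "kind": kind, "t0": a, "t1": b}
        for d, seg in report.segmentations.items()
        for kind, segs in (("proposal", seg.proposal_segments),
                           ("nonproposal", seg.nonproposal_segments))
        for a, b in segs
    ]).to_csv(outdir / "segments.csv", index=False, float_format="%.6f")
    records_to_frame(report.rate_table).to_csv(
        outdir / "rate_table.csv", index=False, float_format="%.6f")
    pd.DataFrame([
        {"dyad_id": s.dyad_id, "r_proposal": s.r_proposal,
         "r_nonproposal": s.r_nonproposal,
         "n_proposal": s.n_proposal, "n_nonproposal": s.n_nonproposal}
        for s in report.synchrony
    ]).to_csv(outdir / "synchrony.csv", index=False, float_format="%.6f")
    write_json_report(report.summary_dict(), outdir / "report.json")
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "versions": _versions(),
    }
    write_json_report(manifest, outdir / "run_manifest.json")
    logger.info("report written to %s", outdir)


def _versions() -> dict:
    import scipy
    import statsmodels
    from . import __version__
    return {"dyadeda": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "python": sys.version.split()[0]}


# ---------------------------------------------------------------------------
# Calibrated-recovery experiments (simulation in, estimated rates out)
# ---------------------------------------------------------------------------

def recover_condition_rates(bundle, config: PipelineConfig | None = None
                            ) -> pd.DataFrame:
    """Pipeline-estimated mean window rate per (role, diagnosis, response).

    Runs the full deconvolve -> detect -> window-rate path on a simulated
    study and aggregates the rate table by condition cell. Columns:
    role, diagnosis, response, mean_rate, n_windows.
    """
    config = config or PipelineConfig(task_start=0.0,
                                      task_end=bundle.config.task_duration,
                                      fit_role_model=False,
                                      fit_response_model=False)
    report = analyze_study(bundle.traces, bundle.events, bundle.meta, config)
    df = records_to_frame(report.rate_table)
    out = (df.groupby(["role", "diagnosis", "response"])
             .agg(mean_rate=("rate", "mean"), n_windows=("rate", "size"))
             .reset_index())
    return out


def recover_overall_rate(bundle, config: PipelineConfig | None = None) -> float:
    """Pipeline-estimated mean-of-dyad-means rate over the whole task."""
    config = config or PipelineConfig(task_start=0.0,
                                      task_end=bundle.config.task_duration,
                                      fit_role_model=False,
                                      fit_response_model=False)
    report = analyze_study(bundle.traces, bundle.events, bundle.meta, config)
    return float(np.mean(list(report.dyad_mean_rates.values())))


# The four calibrated-recovery experiments: the generator is set to the
# observed group rates and the full forward-synthesis -> deconvolution ->
# detection -> window-rate path must give them back. Shared by the test
# suite and the acceptance script.

def _study_geometry(n_events: int, events_per_dyad: int = 50
                    ) -> tuple[int, float]:
    """Dyad count and task duration that accommodate n_events comfortably."""
    n_dyads = max(2, -(-n_events // events_per_dyad))
    task_duration = events_per_dyad * 14.0 + 40.0
    return n_dyads, task_duration


def table1_recovery(n_events: int = 3000, seed: int = 0) -> pd.DataFrame:
    """Role x diagnosis cell recovery against the four reported group rates.

    Every dyad is mixed (one diagnosed member) with alternating proposers,
    so ``n_events`` events spread evenly over all four (role, diagnosis)
    cells. Returns columns role, diagnosis, estimated, generating, n_windows.
    """
    from .synthetic_data import DEFAULT_CONDITION_RATES, SimConfig, simulate_study

    n_dyads, task_duration = _study_geometry(n_events)
    cfg = SimConfig(n_dyads=n_dyads, n_mixed_dyads=n_dyads,
                    events_per_dyad=-(-n_events // n_dyads),
                    task_duration=task_duration, seed=seed)
    bundle = simulate_study(cfg)
    est = recover_condition_rates(bundle)
    est = (est.groupby(["role", "diagnosis"])
              .apply(lambda g: pd.Series({
                  "estimated": np.average(g.mean_rate, weights=g.n_windows),
                  "n_windows": g.n_windows.sum()}), include_groups=False)
              .reset_index())
    est["generating"] = [
        DEFAULT_CONDITION_RATES[(r.role, r.diagnosis)] for r in est.itertuples()
    ]
    return est


def table3_recovery(n_events: int = 3000, seed: int = 0) -> pd.DataFrame:
    """Accepting-response proposer-cell recovery (reported accepting-cell rates).

    All responses are accepting so every proposal contributes to the two
    target cells (non-depressed / depressed proposer under acceptance).
    """
    from .synthetic_data import SimConfig, simulate_study

    rates = {("proposer", 0, "accepting"): 5.61,
             ("proposer", 1, "accepting"): 7.50,
             ("recipient", 0): 2.91,
             ("recipient", 1): 3.91}
    n_dyads, task_duration = _study_geometry(n_events)
    cfg = SimConfig(n_dyads=n_dyads, n_mixed_dyads=n_dyads,
                    events_per_dyad=-(-n_events // n_dyads),
                    task_duration=task_duration,
                    condition_rates=rates, p_accepting=1.0, seed=seed)
    bundle = simulate_study(cfg)
    est = recover_condition_rates(bundle)
    est = est[est.role == "proposer"].copy()
    est["generating"] = [rates[("proposer", r.diagnosis, "accepting")]
                         for r in est.itertuples()]
    return est.rename(columns={"mean_rate": "estimated"})


def overall_rate_recovery(n_dyads: int = 30, task_duration: float = 600.0,
                          seed: int = 0) -> tuple[float, float]:
    """Whole-task mean-of-dyad-means recovery at a homogeneous 2.76 SCR/min.

    No event boost: the condition rates equal the baseline, so the overall
    rate is the only quantity in play. Returns (estimated, generating).
    """
    from .synthetic_data import DEFAULT_BASELINE_RATE, SimConfig, simulate_study

    base = DEFAULT_BASELINE_RATE
    cfg = SimConfig(n_dyads=n_dyads, n_mixed_dyads=n_dyads // 2,
                    events_per_dyad=16, task_duration=task_duration,
                    baseline_rate=base,
                    condition_rates={("proposer",): base, ("recipient",): base},
                    seed=seed)
    bundle = simulate_study(cfg)
    return recover_overall_rate(bundle), base


def proposal_rate_recovery(n_events: int = 1200, seed: int = 0
                           ) -> tuple[float, float]:
    """Mean window-rate recovery at the proposal-sequence rate 4.03 SCR/min.

    Both dyad members receive the proposal-sequence rate inside every
    window against the lower 2.76 baseline; the estimate is the mean over
    all (event x participant) window rates. Returns (estimated, generating).
    """
    from .synthetic_data import SimConfig, simulate_study

    target = 4.03
    n_dyads, task_duration = _study_geometry(n_events // 2)
    cfg = SimConfig(n_dyads=n_dyads, n_mixed_dyads=n_dyads,
                    events_per_dyad=-(-(n_events // 2) // n_dyads),
                    task_duration=task_duration,
                    condition_rates={("proposer",): target, ("recipient",): target},
                    seed=seed)
    bundle = simulate_study(cfg)
    est = recover_condition_rates(bundle)
    return float(np.average(est.mean_rate, weights=est.n_windows)), target
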