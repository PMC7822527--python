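"""Per-event SCR rates and dyadic physiological synchrony.

The rate of a window is ``60 * count / duration`` (SCR per minute) where the
count is of detected peaks falling in the half-open window. Each retained
proposal yields two rate observations — one per dyad member, with the role
(proposer vs recipient) assigned from the annotation — which become the rows
of the mixed-model analysis. Rejecting responses are excluded here: they are
too rare in this paradigm to analyse.

Synchrony is the Pearson correlation between the two members' deconvoluted
drivers over the samples of a segmentation (proposal vs non-proposal time),
aggregated across dyads on the variance-stabilizing Fisher z scale and
contrasted with a dependent t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deconvolution import DriverSignal
from .errors import (DataError, DegenerateSignalError, InsufficientDataError,
                     ParameterError)
from .event_windows import Segmentation, Window
from .io_formats import ParticipantMeta, ProposalEvent, validate_dyads
from .scr_detect import SCRPeak, peak_times


@dataclass(frozen=True)
class RateRecord:
    """One (event x participant) SCR-per-minute observation with covariates."""

    dyad_id: str
    participant_id: str
    event_id: str
    role: str           # "proposer" | "recipient"
    diagnosis: int      # 0/1
    response: str       # "accepting" | "non_accepting"
    rate: float


@dataclass
class SynchronyResult:
    """Per-dyad driver correlations in proposal vs non-proposal time."""

    dyad_id: str
    r_proposal: float
    r_nonproposal: float
    n_proposal: int
    n_nonproposal: int

    @property
    def z_proposal(self) -> float:
        return float(np.arctanh(self.r_proposal))

    @property
    def z_nonproposal(self) -> float:
        return float(np.arctanh(self.r_nonproposal))


@dataclass
class SynchronyContrast:
    """Dependent-samples contrast of proposal vs non-proposal synchrony."""

    t: float
    p: float
    d: float
    mean_r_proposal: float      # Fisher-retransformed means
    mean_r_nonproposal: float
    mean_diff_z: float
    n_dyads: int


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def rate_in_window(peaks: list[SCRPeak] | np.ndarray, window: Window) -> float:
    """SCR per minute inside [t0, t1): 60 * count / duration."""
    if window.duration <= 0:
        raise ParameterError(f"window {window.event_id} has zero duration")
    t = peaks if isinstance(peaks, np.ndarray) else peak_times(peaks)
    count = int(np.count_nonzero((t >= window.t0) & (t < window.t1)))
    return 60.0 * count / window.duration


def overall_rate(peaks: list[SCRPeak], task_start: float, task_end: float) -> float:
    """SCR per minute over the whole task span."""
    if task_end <= task_start:
        raise ParameterError("task span must have positive duration")
    t = peak_times(peaks)
    count = int(np.count_nonzero((t >= task_start) & (t < task_end)))
    return 60.0 * count / (task_end - task_start)


def build_rate_table(
    events: list[ProposalEvent],
    windows: list[Window],
    peaks_by_participant: dict[str, list[SCRPeak]],
    meta: list[ParticipantMeta],
) -> list[RateRecord]:
    """Two RateRecords per retained proposal: proposer and recipient rows.

    Rejecting events contribute no rows. The proposer must be a member of
    the event's dyad and both members' peak lists must be available.
    """
    dyads = validate_dyads(meta)
    meta_by_pid = {m.participant_id: m for m in meta}
    win_by_event = {w.event_id: w for w in windows}
    records: list[RateRecord] = []
    for e in events:
        if e.response == "rejecting":
            continue
        if e.dyad_id not in dyads:
            raise DataError(f"event {e.event_id}: unknown dyad {e.dyad_id}")
        members = dyads[e.dyad_id]
        if e.proposer_id not in (members[0].participant_id, members[1].participant_id):
            raise DataError(
                f"event {e.event_id}: proposer {e.proposer_id} is not a member "
                f"of dyad {e.dyad_id}"
            )
        if e.event_id not in win_by_event:
            raise DataError(f"event {e.event_id}: no window built for it")
        w = win_by_event[e.event_id]
        for m in members:
            if m.participant_id not in peaks_by_participant:
                raise DataError(f"no peaks available for {m.participant_id}")
            role = "proposer" if m.participant_id == e.proposer_id else "recipient"
            records.append(RateRecord(
                dyad_id=e.dyad_id, participant_id=m.participant_id,
                event_id=e.event_id, role=role,
                diagnosis=meta_by_pid[m.participant_id].diagnosis,
                response=e.response,
                rate=rate_in_window(peaks_by_participant[m.participant_id], w),
            ))
    return records


# ---------------------------------------------------------------------------
# Synchrony
# ---------------------------------------------------------------------------

def _segment_sample_indices(driver: DriverSignal,
                            segments: list[tuple[float, float]]) -> np.ndarray:
    n = driver.samples.size
    idx = []
    for a, b in segments:
        i0 = max(0, int(np.ceil((a - driver.t0) * driver.fs - 1e-9)))
        i1 = min(n, int(np.ceil((b - driver.t0) * driver.fs - 1e-9)))
        if i1 > i0:
            idx.append(np.arange(i0, i1))
    if not idx:
        return np.empty(0, dtype=int)
    return np.concatenate(idx)


def segment_correlation(
    driver_a: DriverSignal,
    driver_b: DriverSignal,
    segments: list[tuple[float, float]],
) -> tuple[float, int]:
    """Pearson r of the two drivers over all samples in ``segments``.

    Both drivers must share the sampling grid; samples from every segment
    are pooled before correlating. Returns (r, n_samples).
    """
    if abs(driver_a.fs - driver_b.fs) > 1e-9 or abs(driver_a.t0 - driver_b.t0) > 1e-9:
        raise ParameterError("drivers must share sampling rate and clock")
    idx = _segment_sample_indices(driver_a, segments)
    idx = idx[idx < min(driver_a.samples.size, driver_b.samples.size)]
    if idx.size < 2:
        raise InsufficientDataError(
            "need at least 2 samples in the segment union to correlate"
        )
    a = driver_a.samples[idx]
    b = driver_b.samples[idx]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateSignalError(
            "correlation undefined: a signal is constant on the segment union"
        )
    r = float(np.corrcoef(a, b)[0, 1])
    return r, int(idx.size)


def dyad_synchrony(
    driver_a: DriverSignal,
    driver_b: DriverSignal,
    segmentation: Segmentation,
    dyad_id: str,
) -> SynchronyResult:
    r_p, n_p = segment_correlation(driver_a, driver_b, segmentation.proposal_segments)
    r_n, n_n = segment_correlation(driver_a, driver_b, segmentation.nonproposal_segments)
    return SynchronyResult(dyad_id=dyad_id, r_proposal=r_p, r_nonproposal=r_n,
                           n_proposal=n_p, n_nonproposal=n_n)


def fisher_mean(r_values) -> float:
    """tanh(mean(atanh(r))): the Fisher-retransformed mean correlation."""
    r = np.asarray(list(r_values), dtype=float)
    if r.size == 0:
        raise InsufficientDataError("fisher_mean of an empty list")
    if np.any(np.abs(r) >= 1):
        raise ParameterError("fisher_mean requires |r| < 1 (finite z)")
    return float(np.tanh(np.mean(np.arctanh(r))))


def synchrony_contrast(results: list[SynchronyResult]) -> SynchronyContrast:
    """Dependent t-test of proposal vs non-proposal synchrony across dyads.

    The test runs on per-dyad Fisher-z differences (variance-stabilized);
    the summary also reports the retransformed mean r per condition.
    Cohen's d is mean(diff) / SD(diff).
    """
    from .stats_models import paired_t  # local import to avoid a cycle

    if len(results) < 2:
        raise InsufficientDataError("need at least 2 dyads for the contrast")
    z_p = np.array([s.z_proposal for s in results])
    z_n = np.array([s.z_nonproposal for s in results])
    if np.all(z_p == z_n):
        # no dyad differs at all: the contrast is exactly null
        t, p, d = 0.0, 1.0, 0.0
    else:
        t, p, d = paired_t(z_p, z_n)
    return SynchronyContrast(
        t=t, p=p, d=d,
        mean_r_proposal=fisher_mean([s.r_proposal for s in results]),
        mean_r_nonproposal=fisher_mean([s.r_nonproposal for s in results]),
        mean_diff_z=float(np.mean(z_p - z_n)),
        n_dyads=len(results),
    )
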