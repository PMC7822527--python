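"""SCR peak detection on the deconvoluted driver.

A sample is an SCR peak when it is a local maximum of the driver satisfying
both study thresholds: topographic prominence of at least 0.05 μS, measured
on the un-normalized driver, and height of at least one standard deviation
above the mean level, measured on the z-normalized driver. Plateau maxima
count once, at the plateau midpoint. Edge samples cannot be peaks
(prominence is undefined there). No minimum inter-peak distance is imposed:
separating overlapping SCRs is the deconvolution's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .deconvolution import DriverSignal
from .errors import ParameterError, StateError

#: Study thresholds: prominence in μS, height in SD units of the driver.
DEFAULT_PROMINENCE_MIN = 0.05
DEFAULT_HEIGHT_MIN_SD = 1.0


@dataclass(frozen=True)
class SCRPeak:
    """One detected skin-conductance response."""

    time: float
    height_z: float
    prominence_us: float
    participant_id: str | None = None


def detect_scr_peaks(
    driver: DriverSignal,
    prominence_min: float = DEFAULT_PROMINENCE_MIN,
    height_min_sd: float = DEFAULT_HEIGHT_MIN_SD,
) -> list[SCRPeak]:
    """All local maxima meeting both the prominence and height criteria.

    Returns peaks in increasing time order. The driver must carry
    normalization metadata (see :func:`dyadeda.deconvolution.znormalize`)
    because the two criteria are evaluated on different views of the same
    signal.
    """
    if not driver.znorm:
        raise StateError(
            "driver lacks z-normalization metadata; call znormalize() first"
        )
    if prominence_min < 0 or height_min_sd < 0:
        raise ParameterError("thresholds must be non-negative")
    x = driver.samples
    # find_peaks places a plateau's peak at its midpoint and never returns
    # the first or last sample
    idx, props = signal.find_peaks(x, prominence=prominence_min)
    if idx.size == 0:
        return []
    z = driver.z[idx]
    keep = z >= height_min_sd
    times = driver.t0 + idx[keep] / driver.fs
    return [
        SCRPeak(time=float(t), height_z=float(zz), prominence_us=float(pp),
                participant_id=driver.participant_id)
        for t, zz, pp in zip(times, z[keep], props["prominences"][keep])
    ]


def peak_times(peaks: list[SCRPeak]) -> np.ndarray:
    return np.asarray([p.time for p in peaks], dtype=float)
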