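"""Oscillation feature extraction: amplitude H, period P, peak-pairs N.

The confirmatory factors for oscillatory outputs are

    R = 2H / P          (nM/s)  — overall steepness of the oscillation
    A = H * P * N       (reported in nM*s*10^6) — aggregate magnitude,
                        the summed area of the N peak-pair rectangles

computed by a five-step procedure: (1) detect all interior maxima and
minima within the analysis window; (2) drop a leading minimum and a
trailing maximum, which depend on the chosen window and may not belong to
complete peak-pairs; (3) H = mean(maxima values) - mean(minima values);
(4) P = (P_max + P_min)/2 where P_max and P_min are the mean gaps between
adjacent maxima and adjacent minima; (5) evaluate R and A.  P is converted
to seconds before computing R and A even though times are tracked in hours.

For noisy clinical series, peak detection should run after a centered
moving-average smoother (:func:`smooth`); both the smoothing window and the
prominence threshold are exposed in :class:`PeakConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .simulate import SECONDS_PER_HOUR, Trajectory

__all__ = ["PeakConfig", "PeakList", "OscillationFeatures",
           "detect_peaks", "trim_peaks", "features", "smooth",
           "oscillation_features"]

#: A-factor reporting rescale: with H in nM and P in seconds, raw H*P*N is
#: of order 10^6; the reported unit is nM*s*10^6.
A_SCALE = 1e6


@dataclass(frozen=True)
class PeakConfig:
    """Knobs for peak detection on (possibly noisy) sampled series."""

    prominence_fraction: float = 0.05   # of the series' global range
    smooth_window: int = 5              # samples; for noisy data only


@dataclass(frozen=True)
class PeakList:
    """Detected extrema: ordered ``(time_h, value, type)`` entries."""

    entries: tuple[tuple[float, float, str], ...]
    window_h: float

    def __post_init__(self):
        times = [e[0] for e in self.entries]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("peak times must be strictly increasing")
        for t, _, typ in self.entries:
            if typ not in ("max", "min"):
                raise ValueError(f"bad extremum type {typ!r}")
            if not (0 <= t <= self.window_h):
                raise ValueError(f"peak at {t} h outside window "
                                 f"[0, {self.window_h}] h")

    def __len__(self) -> int:
        return len(self.entries)

    def of_type(self, typ: str) -> list[tuple[float, float]]:
        return [(t, v) for t, v, ty in self.entries if ty == typ]


@dataclass(frozen=True)
class OscillationFeatures:
    """H (nM), P (s), N (count), R = 2H/P (nM/s), A = HPN/1e6 (nM*s*1e6).

    ``defined`` is False when fewer than two maxima and two minima survive
    trimming (no adjacent same-type pair exists to estimate a period from);
    all numeric fields are then zero.
    """

    H: float
    P: float
    N: int
    R: float
    A: float
    A_raw: float
    defined: bool

    @staticmethod
    def undefined() -> "OscillationFeatures":
        return OscillationFeatures(0.0, 0.0, 0, 0.0, 0.0, 0.0, False)


def smooth(traj: Trajectory, window: int = 5) -> Trajectory:
    """Centered moving average of each output (edges use shrunk windows)."""
    if window <= 1:
        return traj
    half = window // 2
    n = len(traj.times)
    out = np.empty_like(traj.values)
    csum = np.cumsum(np.vstack([np.zeros((1, traj.values.shape[1])),
                                traj.values]), axis=0)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return Trajectory(times=traj.times, values=out,
                      output_names=traj.output_names)


def _plateau_extrema(t: np.ndarray, y: np.ndarray, prominence: float,
                     sign: float) -> list[tuple[float, float]]:
    """Interior extrema of sign*y with plateau midpoints, as (time, value)."""
    idx, props = find_peaks(sign * y, prominence=prominence, plateau_size=1)
    out = []
    for j, i in enumerate(idx):
        left, right = props["left_edges"][j], props["right_edges"][j]
        tt = 0.5 * (t[left] + t[right]) if right > left else t[i]
        out.append((float(tt), float(y[i])))
    return out


def detect_peaks(traj: Trajectory, output: str,
                 prominence_fraction: float = 0.05) -> PeakList:
    """Interior strict local extrema of one sampled output series.

    Only extrema whose prominence is at least ``prominence_fraction`` times
    the series' global range are kept; plateaus of equal consecutive values
    yield a single extremum at the plateau midpoint; endpoints are never
    peaks.  Where the prominence filter leaves two same-type extrema
    adjacent, the more extreme one is kept so the returned list alternates.
    """
    t, y = traj.times, traj.column(output)
    if len(y) < 3:
        raise ValueError(f"need at least 3 samples to detect peaks, "
                         f"got {len(y)}")
    rng = float(np.max(y) - np.min(y))
    if rng == 0:
        return PeakList(entries=(), window_h=float(t[-1]))
    prom = prominence_fraction * rng
    entries = ([(tt, v, "max") for tt, v in _plateau_extrema(t, y, prom, 1.0)]
               + [(tt, v, "min") for tt, v in _plateau_extrema(t, y, prom, -1.0)])
    entries.sort(key=lambda e: e[0])
    # enforce max/min alternation: among same-type runs keep the most extreme
    cleaned: list[tuple[float, float, str]] = []
    for e in entries:
        if cleaned and cleaned[-1][2] == e[2]:
            keep_new = (e[1] > cleaned[-1][1]) if e[2] == "max" \
                else (e[1] < cleaned[-1][1])
            if keep_new:
                cleaned[-1] = e
        else:
            cleaned.append(e)
    return PeakList(entries=tuple(cleaned), window_h=float(t[-1]))


def trim_peaks(peaks: PeakList) -> PeakList:
    """Drop a leading minimum and a trailing maximum (each if present).

    A series that starts by falling opens with a minimum whose preceding
    rise lies outside the window, and one that ends by rising closes with a
    maximum whose following fall does — both depend on the chosen window
    and may not belong to complete peak-pairs, so they are excluded.
    Interior extrema are never removed, which keeps max/min alternation
    intact.
    """
    entries = list(peaks.entries)
    if entries and entries[0][2] == "min":
        entries = entries[1:]
    if entries and entries[-1][2] == "max":
        entries = entries[:-1]
    return PeakList(entries=tuple(entries), window_h=peaks.window_h)


def features(peaks: PeakList) -> OscillationFeatures:
    """Compute H, P, N, R, A from an already-trimmed peak list.

    Requires at least two maxima and two minima (so both mean periods
    exist); otherwise returns the zeroed record with ``defined = False``.
    """
    maxima = peaks.of_type("max")
    minima = peaks.of_type("min")
    if len(maxima) < 2 or len(minima) < 2:
        return OscillationFeatures.undefined()
    H = float(np.mean([v for _, v in maxima])
              - np.mean([v for _, v in minima]))
    p_max = float(np.mean(np.diff([t for t, _ in maxima])))
    p_min = float(np.mean(np.diff([t for t, _ in minima])))
    P = 0.5 * (p_max + p_min) * SECONDS_PER_HOUR
    # complete (max, min) ordered pairs among surviving entries
    N = sum(1 for a, b in zip(peaks.entries, peaks.entries[1:])
            if a[2] == "max" and b[2] == "min")
    if N < 1 or P <= 0:
        return OscillationFeatures.undefined()
    R = 2.0 * H / P
    A_raw = H * P * N
    return OscillationFeatures(H=H, P=P, N=N, R=R, A=A_raw / A_SCALE,
                               A_raw=A_raw, defined=True)


def oscillation_features(traj: Trajectory, output: str | None = None, *,
                         config: PeakConfig = PeakConfig(),
                         noisy: bool = False) -> OscillationFeatures:
    """End-to-end detect → trim → features for one trajectory output.

    With ``noisy=True`` the series is moving-average smoothed before peak
    detection to suppress noise ripples.
    """
    if output is None:
        if len(traj.output_names) != 1:
            raise ValueError("output must be named for a multi-output "
                             "trajectory")
        output = traj.output_names[0]
    if noisy and config.smooth_window > 1:
        traj = smooth(traj, config.smooth_window)
    peaks = detect_peaks(traj, output, config.prominence_fraction)
    return features(trim_peaks(peaks))
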