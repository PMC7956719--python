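"""Fiducial-point detection: Pan-Tompkins QRS plus RR-scaled P/T search windows.

The QRS complex is found with the Pan-Tompkins chain (bandpass, derivative,
squaring, 150 ms moving-window integration, adaptive dual thresholds with a
200 ms refractory period and searchback). Q and S are the nearest local
minima within +-60 ms of R. P and T are the signal maxima inside windows
scaled by the record's average RR interval:

    Rloc - RRint/6  < Ploc < Rloc - RRint/10
    Rloc + RRint/10 < Tloc < Rloc + RRint/2

with the open-interval bounds rounded inward when converted to samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthio import ECGRecord

__all__ = ["BeatFiducials", "detect_qrs", "compute_rr_average", "locate_p_t",
           "delineate", "WindowError"]

logger = logging.getLogger(__name__)

REFRACTORY_MS = 200.0
QS_HALF_WINDOW_MS = 60.0


class WindowError(ValueError):
    """A P or T search window falls partly outside the record."""


@dataclass(frozen=True)
class BeatFiducials:
    """Sample indices of the five peaks of one beat, plus the RR average used."""

    ploc: int
    qloc: int
    rloc: int
    sloc: int
    tloc: int
    rr_ms: float

    def __post_init__(self) -> None:
        order = (self.ploc, self.qloc, self.rloc, self.sloc, self.tloc)
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError(f"fiducials must satisfy P < Q < R < S < T, got {order}")
        if self.rr_ms <= 0:
            raise ValueError("RR average must be positive")


def _moving_window_integral(x: np.ndarray, fs: float, width_ms: float = 150.0) -> np.ndarray:
    w = max(1, int(round(width_ms * fs / 1000.0)))
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _pan_tompkins_feature(x: np.ndarray, fs: float) -> np.ndarray:
    """Bandpass (5-15 Hz) -> derivative -> squaring -> 150 ms integration.

    Zero-phase variants of the stages are used so the integrated waveform
    stays aligned with the input and no group-delay bookkeeping is needed.
    """
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    bp = sps.filtfilt(b, a, x)
    deriv = np.convolve(bp, np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0), mode="same")
    return _moving_window_integral(deriv ** 2, fs)


def _candidate_peaks(mwi: np.ndarray, fs: float) -> np.ndarray:
    dist = int(round(REFRACTORY_MS * fs / 1000.0))
    peaks, _ = sps.find_peaks(mwi, distance=dist)
    return peaks


def _adaptive_threshold_pass(mwi: np.ndarray, peaks: np.ndarray, fs: float) -> list[int]:
    """Classic adaptive dual-threshold pass with searchback.

    All running estimates are derived from the data itself, so detection is
    invariant to an overall amplitude rescaling of the record.
    """
    if peaks.size == 0:
        return []
    init = mwi[: int(2 * fs)]
    spki = float(init.max()) * 0.5 if init.size else float(mwi.max()) * 0.5
    npki = float(init.mean()) * 0.5 if init.size else 0.0
    qrs: list[int] = []
    rr_hist: list[float] = []
    noise_peaks: list[int] = []

    def thr1() -> float:
        return npki + 0.25 * (spki - npki)

    for pk in peaks:
        if mwi[pk] > thr1():
            qrs.append(int(pk))
            spki = 0.125 * mwi[pk] + 0.875 * spki
            if len(qrs) >= 2:
                rr_hist.append(float(qrs[-1] - qrs[-2]))
                rr_hist[:] = rr_hist[-8:]
        else:
            noise_peaks.append(int(pk))
            npki = 0.125 * mwi[pk] + 0.875 * npki
            # searchback: if a beat is overdue, accept the best sub-threshold
            # candidate above the second threshold in the missed stretch
            if rr_hist and qrs and (pk - qrs[-1]) > 1.66 * np.mean(rr_hist):
                window = [p for p in noise_peaks if p > qrs[-1]]
                if window:
                    best = max(window, key=lambda p: mwi[p])
                    if mwi[best] > 0.5 * thr1():
                        qrs.append(int(best))
                        qrs.sort()
                        spki = 0.25 * mwi[best] + 0.75 * spki
                        noise_peaks = [p for p in noise_peaks if p != best]
    return qrs


def _refine_r(x: np.ndarray, loc: int, fs: float, half_ms: float = 75.0) -> int:
    half = int(round(half_ms * fs / 1000.0))
    lo, hi = max(0, loc - half), min(x.size, loc + half + 1)
    return lo + int(np.argmax(x[lo:hi]))


def _nearest_local_min(x: np.ndarray, r: int, side: int, fs: float) -> int | None:
    """Nearest local minimum within +-60 ms of R, on the given side (-1 left, +1 right)."""
    half = int(round(QS_HALF_WINDOW_MS * fs / 1000.0))
    if side < 0:
        lo, hi = max(0, r - half), r
        if hi - lo < 2:
            return None
        seg = x[lo:hi]
        mins, _ = sps.find_peaks(-seg)
        if mins.size:
            return lo + int(mins.max())  # nearest to R from the left
        return lo + int(np.argmin(seg))
    lo, hi = r + 1, min(x.size, r + half + 1)
    if hi - lo < 2:
        return None
    seg = x[lo:hi]
    mins, _ = sps.find_peaks(-seg)
    if mins.size:
        return lo + int(mins.min())  # nearest to R from the right
    return lo + int(np.argmin(seg))


def detect_qrs(rec: ECGRecord) -> list[tuple[int, int, int]]:
    """Detect beats; returns one (Qloc, Rloc, Sloc) triple per beat.

    R locations are strictly increasing with a 200 ms refractory period;
    a record with no QRS energy yields an empty list. Beats whose Q/S search
    window leaves the record are dropped.
    """
    x = rec.samples
    fs = rec.fs
    if x.size < 2 * fs:
        raise ValueError("record shorter than 2 s")
    if np.ptp(x) == 0.0:
        return []
    mwi = _pan_tompkins_feature(x, fs)
    peaks = _candidate_peaks(mwi, fs)
    qrs = _adaptive_threshold_pass(mwi, peaks, fs)
    refract = int(round(REFRACTORY_MS * fs / 1000.0))
    rlocs: list[int] = []
    for pk in qrs:
        r = _refine_r(x, pk, fs)
        if rlocs and r - rlocs[-1] < refract:
            if x[r] > x[rlocs[-1]]:
                rlocs[-1] = r
            continue
        rlocs.append(r)
    triples = []
    for r in rlocs:
        q = _nearest_local_min(x, r, -1, fs)
        s = _nearest_local_min(x, r, +1, fs)
        if q is None or s is None or not (q < r < s):
            logger.debug("dropping beat at %d: Q/S localization failed", r)
            continue
        triples.append((q, r, s))
    return triples


def compute_rr_average(rlocs, fs: float) -> float:
    """Arithmetic mean of successive R-to-R differences, in ms."""
    rlocs = np.asarray(rlocs)
    if rlocs.size < 2:
        raise ValueError("need at least 2 R peaks to average RR intervals")
    return float(np.mean(np.diff(rlocs))) * 1000.0 / fs


def locate_p_t(rec: ECGRecord, rloc: int, rr_ms: float) -> tuple[int, int]:
    """P and T peak locations from the RR-scaled open search windows.

    Bounds are converted from ms to samples and rounded inward (the windows
    are open intervals), ties in the argmax broken by the earliest sample.
    Raises :class:`WindowError` when a window leaves the record.
    """
    fs = rec.fs
    rr = rr_ms * fs / 1000.0  # samples
    p_lo = int(np.floor(rloc - rr / 6.0)) + 1
    p_hi = int(np.ceil(rloc - rr / 10.0)) - 1
    t_lo = int(np.floor(rloc + rr / 10.0)) + 1
    t_hi = int(np.ceil(rloc + rr / 2.0)) - 1
    n = rec.samples.size
    if p_lo < 0 or t_hi >= n or p_hi < p_lo or t_hi < t_lo:
        raise WindowError(f"P/T window outside record for R at {rloc}")
    ploc = p_lo + int(np.argmax(rec.samples[p_lo: p_hi + 1]))
    tloc = t_lo + int(np.argmax(rec.samples[t_lo: t_hi + 1]))
    return ploc, tloc


def delineate(rec: ECGRecord) -> list[BeatFiducials]:
    """Full per-beat delineation: QRS detection, record-average RR, P/T search.

    Beats whose search windows exit the record, or whose fiducials end up out
    of order, are dropped (counted in the log).
    """
    triples = detect_qrs(rec)
    if len(triples) < 2:
        return []
    rlocs = [r for _, r, _ in triples]
    rr_ms = compute_rr_average(rlocs, rec.fs)
    beats: list[BeatFiducials] = []
    dropped = 0
    for q, r, s in triples:
        try:
            p, t = locate_p_t(rec, r, rr_ms)
            beats.append(BeatFiducials(p, q, r, s, t, rr_ms))
        except (WindowError, ValueError):
            dropped += 1
    if dropped:
        logger.info("delineate: dropped %d/%d beats (window/order violations)",
                    dropped, len(triples))
    return beats
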