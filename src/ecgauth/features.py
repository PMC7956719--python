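"""Per-beat fiducial feature vectors: 4 amplitudes, 6 intervals, 3 angles.

Amplitudes are signed differences amp_XY = signal(Y) - signal(X) in mV (so
amp_RS is typically negative). Intervals are positive spans in ms; int_RR of
beat i uses the next beat's R. Angles are vertex angles at the Q, R and S
peaks between rays to their flanking peaks, measured in a plane with time in
ms and amplitude in mV multiplied by an aspect constant (default 100 ms/mV),
reported in degrees. The aspect constant is unavoidable because an angle
mixes time and voltage units; it is configurable and documented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .fiducial import BeatFiducials
from .synthio import ECGRecord

__all__ = ["FeatureVector", "FEATURE_COLUMNS", "DEFAULT_ASPECT_MS_PER_MV",
           "extract_features", "build_feature_table"]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["amp_PR", "amp_QR", "amp_RS", "amp_RT",
                   "int_PR", "int_QR", "int_RS", "int_RT", "int_ST", "int_RR",
                   "ang_Q", "ang_R", "ang_S"]

DEFAULT_ASPECT_MS_PER_MV = 100.0


@dataclass(frozen=True)
class FeatureVector:
    """The 13-dimensional fiducial descriptor of one beat (fixed field order)."""

    amp_PR: float
    amp_QR: float
    amp_RS: float
    amp_RT: float
    int_PR: float
    int_QR: float
    int_RS: float
    int_RT: float
    int_ST: float
    int_RR: float
    ang_Q: float
    ang_R: float
    ang_S: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    def is_valid(self) -> bool:
        """True when all intervals are positive and all angles strictly inside (0, 180)."""
        intervals = (self.int_PR, self.int_QR, self.int_RS, self.int_RT,
                     self.int_ST, self.int_RR)
        angles = (self.ang_Q, self.ang_R, self.ang_S)
        return all(v > 0 for v in intervals) and all(0.0 < a < 180.0 for a in angles)


def vertex_angle(p_prev: tuple[float, float], p_vertex: tuple[float, float],
                 p_next: tuple[float, float]) -> float:
    """Angle in degrees at ``p_vertex`` between rays to the two flanking points."""
    u = np.asarray(p_prev, dtype=float) - np.asarray(p_vertex, dtype=float)
    v = np.asarray(p_next, dtype=float) - np.asarray(p_vertex, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: coincident fiducial points")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def extract_features(rec: ECGRecord, b: BeatFiducials, next_rloc: int,
                     aspect_ms_per_mv: float = DEFAULT_ASPECT_MS_PER_MV) -> FeatureVector:
    """Compute the 13 features for one beat; ``next_rloc`` supplies the RR span.

    Degenerate geometry (collinear fiducials) still returns the computed
    arccos value (e.g. 180 deg); callers reject it via ``is_valid``.
    """
    if next_rloc <= b.rloc:
        raise ValueError("next R location must follow this beat's R")
    x = rec.samples
    ms = 1000.0 / rec.fs

    def pt(loc: int) -> tuple[float, float]:
        return (loc * ms, x[loc] * aspect_ms_per_mv)

    return FeatureVector(
        amp_PR=x[b.rloc] - x[b.ploc],
        amp_QR=x[b.rloc] - x[b.qloc],
        amp_RS=x[b.sloc] - x[b.rloc],
        amp_RT=x[b.tloc] - x[b.rloc],
        int_PR=(b.rloc - b.ploc) * ms,
        int_QR=(b.rloc - b.qloc) * ms,
        int_RS=(b.sloc - b.rloc) * ms,
        int_RT=(b.tloc - b.rloc) * ms,
        int_ST=(b.tloc - b.sloc) * ms,
        int_RR=(next_rloc - b.rloc) * ms,
        ang_Q=vertex_angle(pt(b.ploc), pt(b.qloc), pt(b.rloc)),
        ang_R=vertex_angle(pt(b.qloc), pt(b.rloc), pt(b.sloc)),
        ang_S=vertex_angle(pt(b.rloc), pt(b.sloc), pt(b.tloc)),
    )


def build_feature_table(rec: ECGRecord, beats: list[BeatFiducials],
                        aspect_ms_per_mv: float = DEFAULT_ASPECT_MS_PER_MV) -> pd.DataFrame:
    """One row per retained beat, columns in FEATURE_COLUMNS order plus labels.

    Beats are sorted by R location internally, so the result does not depend
    on the input order. The final beat (no successor for RR) and any beat
    with degenerate geometry are dropped; drops are logged.
    """
    if len(beats) < 2:
        raise ValueError("need at least 2 beats (RR requires a successor)")
    beats = sorted(beats, key=lambda b: b.rloc)
    rows, dropped = [], 0
    for i, b in enumerate(beats[:-1]):
        fv = extract_features(rec, b, beats[i + 1].rloc, aspect_ms_per_mv)
        if not fv.is_valid():
            dropped += 1
            continue
        rows.append({**dict(zip(FEATURE_COLUMNS, fv.as_array())),
                     "subject": rec.subject, "day": rec.day, "beat": i})
    if dropped:
        logger.info("build_feature_table: dropped %d degenerate beats", dropped)
    if not rows:
        raise ValueError("no beats retained")
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["subject", "day", "beat"])
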