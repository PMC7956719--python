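"""Bandpass-filter a noisy record and recover its fiducial points.

The generator embeds baseline wander and white noise; the 1-35 Hz FIR
removes both, and the Pan-Tompkins chain plus RR-scaled search windows
recover P/Q/R/S/T. Printed: detection rate against the generator's exact
R-peak ground truth, and the P/T localization error.
"""

import numpy as np

from ecgauth import (DriftSpec, apply_filter, delineate, detect_qrs,
                     generate_subject_morphology, synthesize_record)

m = generate_subject_morphology(seed=7)
rec = synthesize_record(m, DriftSpec.default(), day=1, duration_s=60,
                        fs=1000, seed=1, subject="S01")
filt = apply_filter(rec)
print(f"raw record: {rec.duration_s:.0f} s at {rec.fs:.0f} Hz, "
      f"{rec.truth_r.size} true beats")

rlocs = np.array([r for _, r, _ in detect_qrs(filt)])
hits = sum(np.min(np.abs(rlocs - t)) <= 20 for t in rec.truth_r)
print(f"QRS detection: {rlocs.size} beats found, "
      f"{100 * hits / rec.truth_r.size:.1f}% of truth within +-20 ms")

beats = delineate(filt)
perr = [abs(b.ploc - (rec.truth_r[np.argmin(np.abs(rec.truth_r - b.rloc))]
                      + m.P.center_ms)) for b in beats]
print(f"delineation: {len(beats)} full PQRST beats, "
      f"P-peak error <= {max(perr):.1f} ms")
print("near-perfect recovery on synthetic data is the precondition for")
print("trusting the features extracted downstream.")
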