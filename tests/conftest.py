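import numpy as np
import pytest

from ecgauth import (DriftSpec, SubjectMorphology, WaveParams,
                     apply_filter, delineate, extract_cohort_features,
                     generate_cohort, synthesize_record)


@pytest.fixture(scope="session")
def metronome():
    """A fixed 60 bpm morphology with zero RR jitter (exact periodicity)."""
    return SubjectMorphology(
        P=WaveParams(0.15, -130.0, 25.0),
        Q=WaveParams(-0.1, -30.0, 10.0),
        R=WaveParams(1.2, 0.0, 10.0),
        S=WaveParams(-0.25, 30.0, 10.0),
        T=WaveParams(0.35, 250.0, 45.0),
        heart_rate_bpm=60.0,
        rr_jitter_ms=0.0,
    )


@pytest.fixture(scope="session")
def clean_record():
    """30 s of noiseless single-subject ECG with ground truth, filtered."""
    from ecgauth import generate_subject_morphology
    m = generate_subject_morphology(3)
    rec = synthesize_record(m, DriftSpec.none(), 1, 30.0, 1000.0, 5, subject="S01")
    return rec, apply_filter(rec)


@pytest.fixture(scope="session")
def small_cohort_table():
    """3 subjects x 6 days x ~40 s with the default drift; featurized."""
    recs = generate_cohort(n_subjects=3, n_days=6, minutes=0.7, seed=7)
    return extract_cohort_features(recs)


@pytest.fixture()
def two_gaussians():
    """Factory for 2-D two-Gaussian binary sets with controllable overlap."""

    def make(n, seed, spread=1.0, sep=2.0):
        rng = np.random.default_rng(seed)
        half = n // 2
        X = np.vstack([
            rng.normal([-sep / 2, -sep / 2], spread, (half, 2)),
            rng.normal([sep / 2, sep / 2], spread, (n - half, 2)),
        ])
        y = np.concatenate([-np.ones(half), np.ones(n - half)])
        perm = rng.permutation(n)
        return X[perm], y[perm]

    return make
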