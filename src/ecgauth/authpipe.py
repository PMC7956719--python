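"""Authentication protocol: per-subject one-vs-rest models updated day by day.

For every subject, the positive class is that subject's beats and the
negative class is the pooled beats of all other subjects (the imposters).
Day-1 beats train the initial model (minority class balanced by SMOTE);
days 2-5 are integrated beat-by-beat with the incremental SVM. After each
stage the model is scored per single beat on two schedules: the held-out
final day, and the day following the latest trained day. Metrics are the
standard biometric triplet,

    ACC = (TP + TN) / (TP + TN + FP + FN)
    FAR = FP / (TN + FP)        (imposter beats falsely accepted)
    TAR = TP / (TP + FN)        (genuine beats correctly accepted)

reported in percent. Baselines: a fully retrained batch SVM on the pooled
training days, and a template-update scheme (distance to a running feature
centroid).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, build_feature_table
from .fiducial import delineate
from .preprocess import FilterSpec, apply_filter
from .isvm import (SVMConfig, IncrementalSVM, fit_initial, smote_balance,
                   batch_qp_oracle)
from .synthio import ECGRecord

__all__ = ["ConfusionCounts", "MetricUndefinedError", "compute_metrics",
           "ProtocolConfig", "ProtocolResult", "Standardizer",
           "extract_cohort_features", "run_incremental_protocol",
           "run_batch_baseline", "run_template_baseline", "timing_benchmark",
           "majority_vote"]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["subject", "stage", "schedule", "test_day",
                  "TP", "FP", "TN", "FN", "ACC", "FAR", "TAR"]


class MetricUndefinedError(ZeroDivisionError):
    """A requested rate has an empty denominator (e.g. FAR with no negatives)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-beat confusion counts for one subject and stage."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def compute_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(ACC, FAR, TAR) in percent; raises MetricUndefinedError on empty denominators."""
    if c.total == 0:
        raise MetricUndefinedError("ACC undefined: no evaluated beats")
    if c.TN + c.FP == 0:
        raise MetricUndefinedError("FAR undefined: no negative beats")
    if c.TP + c.FN == 0:
        raise MetricUndefinedError("TAR undefined: no positive beats")
    acc = 100.0 * (c.TP + c.TN) / c.total
    far = 100.0 * c.FP / (c.TN + c.FP)
    tar = 100.0 * c.TP / (c.TP + c.FN)
    return acc, far, tar


@dataclass(frozen=True)
class ProtocolConfig:
    """Everything the experiment needs besides the data and the seed."""

    svm: SVMConfig = field(default_factory=SVMConfig)
    smote_k: int = 5
    smote_each_day: bool = False
    n_train_days: int = 5
    test_day: int = 6
    template_threshold: float = 3.0   # pooled-s.d. units
    template_update_rate: float = 0.1
    vote_window: int = 1              # >1 enables the optional multi-beat vote

    def __post_init__(self) -> None:
        if self.n_train_days < 1 or self.test_day <= self.n_train_days:
            raise ValueError("need test_day > n_train_days >= 1")
        if not (0.0 <= self.template_update_rate <= 1.0):
            raise ValueError("template update rate must be in [0, 1]")
        if self.template_threshold <= 0:
            raise ValueError("template threshold must be positive")


@dataclass
class Standardizer:
    """Z-scoring frozen at day-1 training statistics.

    Freezing keeps later increments consistent with the initial model: a
    feature scale that shifted with each day would silently re-train the
    kernel geometry.
    """

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        sd = np.std(X, axis=0)
        return cls(mean=np.mean(X, axis=0), sd=np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) / self.sd


@dataclass
class ProtocolResult:
    report: pd.DataFrame
    models: dict[str, IncrementalSVM]
    scalers: dict[str, Standardizer]
    set_sizes: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Cohort-average metrics per stage and schedule."""
        return (self.report.groupby(["stage", "schedule"])[["ACC", "FAR", "TAR"]]
                .mean().reset_index())


def extract_cohort_features(records: list[ECGRecord],
                            filter_spec: FilterSpec | None = None) -> pd.DataFrame:
    """Filter, delineate and featurize every record; one table for the cohort."""
    tables = []
    for rec in records:
        filtered = apply_filter(rec, filter_spec)
        beats = delineate(filtered)
        if len(beats) < 2:
            logger.warning("record %s day %d: only %d beats delineated, skipped",
                           rec.subject, rec.day, len(beats))
            continue
        tables.append(build_feature_table(filtered, beats))
    if not tables:
        raise ValueError("no usable records")
    return pd.concat(tables, ignore_index=True)


def majority_vote(accepts: np.ndarray, window: int) -> np.ndarray:
    """Optional multi-beat aggregation: majority over a sliding window."""
    if window <= 1:
        return accepts
    kernel = np.ones(window)
    votes = np.convolve(accepts.astype(float), kernel, mode="same")
    return votes > window / 2.0


def _check_cohort(table: pd.DataFrame, cfg: ProtocolConfig) -> list[str]:
    subjects = sorted(table["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("protocol needs at least 2 subjects (no imposters otherwise)")
    days = set(table["day"].unique())
    needed = set(range(1, cfg.n_train_days + 1)) | {cfg.test_day}
    missing = needed - days
    if missing:
        raise ValueError(f"missing days in cohort table: {sorted(missing)}")
    return subjects


def _day1_training_set(table: pd.DataFrame, subject: str, cfg: ProtocolConfig,
                       rng: np.random.Generator):
    """Balanced, standardized, shuffled day-1 training set for one subject.

    Shared by the incremental route and the batch baseline so both start from
    the same samples (including identical SMOTE synthetics).
    """
    day1 = table[table["day"] == 1]
    pos = day1[day1["subject"] == subject][FEATURE_COLUMNS].to_numpy()
    neg = day1[day1["subject"] != subject][FEATURE_COLUMNS].to_numpy()
    if pos.shape[0] < 2 or neg.shape[0] < 1:
        raise ValueError(f"subject {subject}: not enough day-1 beats")
    scaler = Standardizer.fit(np.vstack([pos, neg]))
    posz = scaler.transform(pos)
    negz = scaler.transform(neg)
    posb = smote_balance(posz, negz, k=cfg.smote_k, seed=rng) \
        if posz.shape[0] < negz.shape[0] else posz
    X = np.vstack([posb, negz])
    y = np.concatenate([np.ones(len(posb)), -np.ones(len(negz))])
    perm = rng.permutation(len(y))
    return X[perm], y[perm], scaler


def _day_rows(table: pd.DataFrame, day: int) -> pd.DataFrame:
    """Beats of one day in chronological presentation order."""
    rows = table[table["day"] == day]
    return rows.sort_values(["beat", "subject"], kind="stable")


def _counts(f: np.ndarray, is_pos: np.ndarray, vote_window: int = 1) -> ConfusionCounts:
    accept = majority_vote(f >= 0.0, vote_window)
    return ConfusionCounts(
        TP=int(np.sum(accept & is_pos)),
        FP=int(np.sum(accept & ~is_pos)),
        TN=int(np.sum(~accept & ~is_pos)),
        FN=int(np.sum(~accept & is_pos)),
    )


def _report_row(subject: str, stage: int, schedule: str, test_day: int,
                c: ConfusionCounts) -> dict:
    acc, far, tar = compute_metrics(c)
    return {"subject": subject, "stage": stage, "schedule": schedule,
            "test_day": test_day, "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN,
            "ACC": acc, "FAR": far, "TAR": tar}


def _evaluate(model: IncrementalSVM, scaler: Standardizer, table: pd.DataFrame,
              subject: str, day: int, vote_window: int = 1) -> ConfusionCounts:
    rows = table[table["day"] == day]
    X = scaler.transform(rows[FEATURE_COLUMNS].to_numpy())
    f = model.decision_function(X)
    return _counts(f, (rows["subject"] == subject).to_numpy(), vote_window)


def run_incremental_protocol(table: pd.DataFrame, cfg: ProtocolConfig | None = None,
                             seed: int = 0) -> ProtocolResult:
    """The full adaptive experiment on a labelled cohort feature table.

    Returns per-subject per-stage reports on both evaluation schedules, the
    final models, the frozen scalers and the S/E/R set-size bookkeeping.
    A pure function of (table, cfg, seed).
    """
    if cfg is None:
        cfg = ProtocolConfig()
    subjects = _check_cohort(table, cfg)
    rows, sizes = [], []
    models: dict[str, IncrementalSVM] = {}
    scalers: dict[str, Standardizer] = {}
    for si, s in enumerate(subjects):
        rng = np.random.default_rng(np.random.SeedSequence([seed, si]))
        Xtr, ytr, scaler = _day1_training_set(table, s, cfg, rng)
        model = fit_initial(Xtr, ytr, cfg.svm)
        scalers[s] = scaler
        models[s] = model

        def record_stage(stage: int) -> None:
            c6 = _evaluate(model, scaler, table, s, cfg.test_day, cfg.vote_window)
            rows.append(_report_row(s, stage, "day6", cfg.test_day, c6))
            nxt = min(stage + 1, cfg.test_day)
            cn = _evaluate(model, scaler, table, s, nxt, cfg.vote_window)
            rows.append(_report_row(s, stage, "next_day", nxt, cn))
            sizes.append({"subject": s, "stage": stage, **model.set_sizes()})

        record_stage(1)
        for day in range(2, cfg.n_train_days + 1):
            day_rows = _day_rows(table, day)
            Xd = scaler.transform(day_rows[FEATURE_COLUMNS].to_numpy())
            yd = np.where(day_rows["subject"].to_numpy() == s, 1.0, -1.0)
            if cfg.smote_each_day and np.sum(yd == 1) < np.sum(yd == -1):
                extra = smote_balance(Xd[yd == 1], Xd[yd == -1],
                                      k=cfg.smote_k, seed=rng)[int(np.sum(yd == 1)):]
                Xd = np.vstack([Xd, extra])
                yd = np.concatenate([yd, np.ones(len(extra))])
            for xi, yi in zip(Xd, yd):
                model.increment(xi, yi)
            record_stage(day)
        logger.info("subject %s: final set sizes %s", s, model.set_sizes())
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return ProtocolResult(report=report, models=models, scalers=scalers,
                          set_sizes=pd.DataFrame(sizes))


def run_batch_baseline(table: pd.DataFrame, cfg: ProtocolConfig | None = None,
                       seed: int = 0, train_through_day: int | None = None) -> ProtocolResult:
    """Full retraining baseline: one batch SVM per subject on the pooled
    training days (same day-1 balanced set as the incremental route, same
    hyperparameters), evaluated on the held-out day."""
    if cfg is None:
        cfg = ProtocolConfig()
    if train_through_day is None:
        train_through_day = cfg.n_train_days
    subjects = _check_cohort(table, cfg)
    rows, sizes = [], []
    models: dict[str, IncrementalSVM] = {}
    scalers: dict[str, Standardizer] = {}
    for si, s in enumerate(subjects):
        rng = np.random.default_rng(np.random.SeedSequence([seed, si]))
        X1, y1, scaler = _day1_training_set(table, s, cfg, rng)
        parts_X, parts_y = [X1], [y1]
        for day in range(2, train_through_day + 1):
            day_rows = _day_rows(table, day)
            parts_X.append(scaler.transform(day_rows[FEATURE_COLUMNS].to_numpy()))
            parts_y.append(np.where(day_rows["subject"].to_numpy() == s, 1.0, -1.0))
        model = batch_qp_oracle(np.vstack(parts_X), np.concatenate(parts_y), cfg.svm)
        models[s] = model
        scalers[s] = scaler
        c6 = _evaluate(model, scaler, table, s, cfg.test_day, cfg.vote_window)
        rows.append(_report_row(s, train_through_day, "day6", cfg.test_day, c6))
        sizes.append({"subject": s, "stage": train_through_day, **model.set_sizes()})
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return ProtocolResult(report=report, models=models, scalers=scalers,
                          set_sizes=pd.DataFrame(sizes))


def run_template_baseline(table: pd.DataFrame, cfg: ProtocolConfig | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Template-update baseline on the next-day schedule.

    Per subject: the template starts as the mean standardized day-1 positive
    feature vector; a beat is accepted when its normalized Euclidean distance
    (RMS over the 13 standardized features) is at most the threshold; every
    accepted presented beat (genuine or imposter - that is the scheme's known
    failure mode) drags the template toward itself with the update rate.
    """
    if cfg is None:
        cfg = ProtocolConfig()
    subjects = _check_cohort(table, cfg)
    rows = []
    for s in subjects:
        day1 = table[table["day"] == 1]
        pos = day1[day1["subject"] == s][FEATURE_COLUMNS].to_numpy()
        neg = day1[day1["subject"] != s][FEATURE_COLUMNS].to_numpy()
        scaler = Standardizer.fit(np.vstack([pos, neg]))
        template = np.mean(scaler.transform(pos), axis=0)
        r = cfg.template_update_rate

        def dist(X: np.ndarray, tmpl: np.ndarray) -> np.ndarray:
            return np.sqrt(np.mean((scaler.transform(X) - tmpl) ** 2, axis=1))

        def eval_day(day: int, stage: int, tmpl: np.ndarray) -> None:
            rows_d = table[table["day"] == day]
            accept = dist(rows_d[FEATURE_COLUMNS].to_numpy(), tmpl) <= cfg.template_threshold
            is_pos = (rows_d["subject"] == s).to_numpy()
            c = ConfusionCounts(TP=int(np.sum(accept & is_pos)),
                                FP=int(np.sum(accept & ~is_pos)),
                                TN=int(np.sum(~accept & ~is_pos)),
                                FN=int(np.sum(~accept & is_pos)))
            rows.append(_report_row(s, stage, "next_day", day, c))

        eval_day(2, 1, template)
        for day in range(2, cfg.n_train_days + 1):
            day_rows = _day_rows(table, day)
            for x in day_rows[FEATURE_COLUMNS].to_numpy():
                xz = scaler.transform(x)[0]
                if np.sqrt(np.mean((xz - template) ** 2)) <= cfg.template_threshold:
                    template = (1.0 - r) * template + r * xz
            eval_day(min(day + 1, cfg.test_day), day, template)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def timing_benchmark(model: IncrementalSVM, X_new: np.ndarray, y_new: np.ndarray,
                     n_added: tuple[int, ...] = (1, 10, 100)) -> pd.DataFrame:
    """Wall-clock of incremental integration vs one batch refit.

    For each requested count, the first ``n`` new samples are incremented
    into a copy of the model, and separately a batch SVM is refit on the
    stored samples plus those ``n``. Qualitative comparison only; absolute
    times are hardware-dependent.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    y_new = np.asarray(y_new, dtype=float).ravel()
    out = []
    for n in n_added:
        if n == 0:
            out.append({"n_added": 0, "t_incremental_s": 0.0, "t_batch_s": 0.0})
            continue
        if n > X_new.shape[0]:
            raise ValueError(f"requested {n} additions but only {X_new.shape[0]} samples given")
        mc = model.copy()
        t0 = time.perf_counter()
        for i in range(n):
            mc.increment(X_new[i], y_new[i])
        t_inc = time.perf_counter() - t0
        Xb = np.vstack([model.X, X_new[:n]])
        yb = np.concatenate([model.y, y_new[:n]])
        t0 = time.perf_counter()
        batch_qp_oracle(Xb, yb, model.cfg, max_n=max(20_000, len(yb)))
        t_batch = time.perf_counter() - t0
        out.append({"n_added": n, "t_incremental_s": t_inc, "t_batch_s": t_batch})
    return pd.DataFrame(out, columns=["n_added", "t_incremental_s", "t_batch_s"])
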