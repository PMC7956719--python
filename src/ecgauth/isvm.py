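"""Incremental soft-margin SVM (Cauwenberghs-Poggio) with an RBF kernel.

A trained SVM partitions its stored samples by the KKT conditions of the
dual problem:

    alpha_i = 0      ->  y_i f(x_i) > 1   (reserve set R, beyond the margin)
    0 < alpha_i < C  ->  y_i f(x_i) = 1   (margin set S, on the margin)
    alpha_i = C      ->  y_i f(x_i) < 1   (error set E, violating the margin)

with f(x) = sum_i alpha_i y_i K(x_i, x) + b and sum_i alpha_i y_i = 0.

A new sample that is already classified beyond the margin (y f(x) > 1) is
stored in R and changes nothing. Otherwise its coefficient is grown
adiabatically: at each step the margin-set coefficients and the bias move
along the unique direction that keeps every margin sample exactly on the
margin and the class-balance constraint satisfied, the step length is the
largest that triggers no KKT event, and at each event a sample migrates
between S, E and R (or the new sample terminates on the margin or at the
box bound C). The final state is the exact batch solution of the enlarged
problem, independent of the order in which samples arrived.

Kernel convention: K(x, y) = exp(-||x - y||^2 / sigma^2). The other common
convention divides by 2 sigma^2; with this one, sklearn's gamma is 1/sigma^2.

A batch oracle (`batch_qp_oracle`, libsvm via scikit-learn) solves the same
soft-margin dual directly and serves as the independent cross-check, plus a
hand-rolled SMOTE for minority-class balancing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

__all__ = ["SVMConfig", "IncrementalSVM", "AuditReport", "ConvergenceError",
           "rbf_kernel", "fit_initial", "increment", "decision", "kkt_audit",
           "smote_balance", "batch_qp_oracle",
           "RESERVE", "MARGIN", "ERROR", "SET_NAMES"]

RESERVE, MARGIN, ERROR = 0, 1, 2
SET_NAMES = {RESERVE: "R", MARGIN: "S", ERROR: "E"}

_EPS = 1e-12  # direction-sense tolerance for event detection


class ConvergenceError(RuntimeError):
    """An increment exceeded the bookkeeping-event cap; carries a state dump."""

    def __init__(self, msg: str, dump: dict | None = None):
        super().__init__(msg)
        self.dump = dump or {}


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters: box constraint C, kernel scale sigma, numeric tolerances.

    ``kernel`` may be "rbf" (default) or "linear"; the linear kernel exists
    for closed-form unit checks only.
    """

    C: float = 7.0
    sigma: float = 2.0
    kernel: str = "rbf"
    kkt_tol: float = 1e-6
    jitter: float = 1e-10
    max_events: int = 100_000

    def __post_init__(self) -> None:
        if self.C <= 0 or self.sigma <= 0 or self.kkt_tol <= 0 or self.jitter < 0:
            raise ValueError("C, sigma, kkt_tol must be > 0 and jitter >= 0")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray | float:
    """K = exp(-||x-y||^2 / sigma^2); accepts vectors or (n, d) matrices."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError(f"dimension mismatch: {x.shape[1]} vs {y.shape[1]}")
    sq = (np.sum(x * x, axis=1)[:, None] + np.sum(y * y, axis=1)[None, :]
          - 2.0 * x @ y.T)
    out = np.exp(-np.maximum(sq, 0.0) / sigma**2)
    return float(out[0, 0]) if out.size == 1 and out.shape == (1, 1) else out


def _kernel_matrix(cfg: SVMConfig, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if cfg.kernel == "linear":
        return a @ b.T
    return np.atleast_2d(rbf_kernel(a, b, cfg.sigma))


@dataclass
class AuditReport:
    """Per-sample KKT violations beyond kkt_tol; empty iff the state is valid."""

    violations: list[tuple[int, str, float, float, str]] = field(default_factory=list)
    sum_alpha_y: float = 0.0

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        lines = [f"sum(alpha*y) = {self.sum_alpha_y:.3e}"]
        for idx, s, a, g, reason in self.violations:
            lines.append(f"  sample {idx} [{s}] alpha={a:.6g} g={g:.3e}: {reason}")
        return "\n".join(lines)


class IncrementalSVM:
    """Online binary SVM holding the full solution state.

    Attributes (first ``n`` entries are live):
      X, y      stored samples and labels in {-1, +1}
      alpha     dual coefficients in [0, C]
      g         cached KKT margins g_i = y_i f(x_i) - 1
      sets      per-sample membership: RESERVE / MARGIN / ERROR
      bias      the offset b
    """

    def __init__(self, cfg: SVMConfig, dim: int):
        self.cfg = cfg
        self.dim = int(dim)
        self.bias = 0.0
        self.n = 0
        cap = 256
        self._X = np.empty((cap, self.dim))
        self._y = np.empty(cap)
        self._alpha = np.zeros(cap)
        self._g = np.zeros(cap)
        self._sets = np.zeros(cap, dtype=np.int8)
        self._kcache: dict[int, np.ndarray] = {}

    # -- views ------------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return self._X[: self.n]

    @property
    def y(self) -> np.ndarray:
        return self._y[: self.n]

    @property
    def alpha(self) -> np.ndarray:
        return self._alpha[: self.n]

    @property
    def g(self) -> np.ndarray:
        return self._g[: self.n]

    @property
    def sets(self) -> np.ndarray:
        return self._sets[: self.n]

    def set_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.sets == label)

    def set_sizes(self) -> dict[str, int]:
        return {name: int(np.sum(self.sets == code)) for code, name in SET_NAMES.items()}

    # -- storage ----------------------------------------------------------
    def _ensure_capacity(self, need: int) -> None:
        cap = self._X.shape[0]
        if need <= cap:
            return
        while cap < need:
            cap *= 2
        for name in ("_X", "_y", "_alpha", "_g", "_sets"):
            old = getattr(self, name)
            new = np.zeros((cap,) + old.shape[1:], dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def _append(self, x: np.ndarray, y: float) -> int:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.dim:
            raise ValueError(f"expected dimension {self.dim}, got {x.size}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite feature values")
        if y not in (-1, 1):
            raise ValueError("labels must be -1 or +1")
        self._ensure_capacity(self.n + 1)
        i = self.n
        self._X[i] = x
        self._y[i] = y
        self._alpha[i] = 0.0
        self._sets[i] = RESERVE
        self.n += 1
        return i

    def _kcol(self, j: int) -> np.ndarray:
        """Cached kernel column K(X[:n], x_j), extended lazily as n grows."""
        col = self._kcache.get(j)
        if col is None or col.size < self.n:
            start = 0 if col is None else col.size
            tail = _kernel_matrix(self.cfg, self._X[start: self.n], self._X[j]).ravel()
            col = tail if col is None else np.concatenate([col, tail])
            self._kcache[j] = col
        return col[: self.n]

    # -- inference --------------------------------------------------------
    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """f(x) = sum_i alpha_i y_i K(x_i, x) + b, vectorized over rows of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError(f"dimension mismatch: {X.shape[1]} vs {self.dim}")
        sv = np.flatnonzero(self.alpha > 0.0)
        if sv.size == 0:
            return np.full(X.shape[0], self.bias)
        K = _kernel_matrix(self.cfg, X, self._X[sv])
        return K @ (self.alpha[sv] * self.y[sv]) + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 (accept) iff f(x) >= 0, else -1 (reject)."""
        f = self.decision_function(X)
        return np.where(f >= 0.0, 1.0, -1.0)

    def _g_fresh(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Recompute g_i = y_i f(x_i) - 1 from scratch (independent of the cache)."""
        if idx is None:
            idx = np.arange(self.n)
        if idx.size == 0:
            return np.zeros(0)
        return self.y[idx] * self.decision_function(self.X[idx]) - 1.0

    # -- incremental learning ---------------------------------------------
    def increment(self, x: np.ndarray, y: float) -> str:
        """Integrate one labelled sample; returns the set it ended in ("R"/"S"/"E").

        Samples with y*f(x) > 1 go straight to the reserve set and leave the
        coefficients and bias bit-identical. Anything else triggers the
        adiabatic update, after which all KKT invariants hold again.
        """
        x = np.asarray(x, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite feature values")
        g_new = float(y) * float(self.decision_function(x)[0]) - 1.0
        c = self._append(x, float(y))
        self._g[c] = g_new
        if g_new > 0.0:
            self._sets[c] = RESERVE  # fast path: alpha and bias untouched
            return "R"
        self._integrate(c)
        return SET_NAMES[int(self._sets[c])]

    def _integrate(self, c: int) -> None:
        if self._g[c] >= 0.0:
            self._sets[c] = MARGIN
            self._g[c] = 0.0
            return
        for _ in range(self.cfg.max_events):
            S = self.set_indices(MARGIN)
            done = (self._empty_margin_step(c) if S.size == 0
                    else self._adiabatic_step(c, S))
            if done:
                return
        raise ConvergenceError(
            f"increment of sample {c} did not converge within "
            f"{self.cfg.max_events} bookkeeping events",
            dump={"n": self.n, "bias": self.bias, "alpha_c": float(self._alpha[c]),
                  "g_c": float(self._g[c]), "set_sizes": self.set_sizes()},
        )

    def _empty_margin_step(self, c: int) -> bool:
        """With no margin vectors, only the bias can move; slide it toward
        satisfying the new sample until it, or some stored sample, lands on
        the margin and seeds the margin set."""
        n = self.n
        y = self.y
        yc = self._y[c]
        g = self._g[: n]
        t_cand = -float(g[c])  # distance for the new sample to reach the margin
        events: list[tuple[float, int]] = [(t_cand, c)]
        err = np.flatnonzero((self.sets == ERROR) & (y == yc) & (g[: n] < -_EPS))
        if err.size:
            j = int(np.argmin(-g[err]))
            events.append((-float(g[err[j]]), int(err[j])))
        res = np.flatnonzero((self.sets == RESERVE) & (y != yc) & (g[: n] > _EPS))
        res = res[res != c]
        if res.size:
            j = int(np.argmin(g[res]))
            events.append((float(g[res[j]]), int(res[j])))
        t, who = min(events, key=lambda e: e[0])
        t = max(t, 0.0)
        self.bias += yc * t
        self._g[: n] += y * yc * t
        self._sets[who] = MARGIN
        self._g[who] = 0.0
        return who == c

    def _adiabatic_step(self, c: int, S: np.ndarray) -> bool:
        cfg = self.cfg
        n = self.n
        y = self.y
        yS = y[S]
        m = S.size

        cols = [self._kcol(s) for s in S]  # cached K(X, x_s) columns
        kc = self._kcol(c)                 # K(X, x_c)

        A = np.zeros((m + 1, m + 1))
        A[0, 1:] = yS
        A[1:, 0] = yS
        KSS = np.empty((m, m))
        for j, col in enumerate(cols):
            KSS[:, j] = col[S]
        A[1:, 1:] = (yS[:, None] * yS[None, :]) * KSS + cfg.jitter * np.eye(m)
        rhs = -np.concatenate([[y[c]], yS * y[c] * kc[S]])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(A + 1e-8 * np.eye(m + 1), rhs, rcond=None)[0]
        beta_b, beta = sol[0], sol[1:]

        # sensitivity of every g_i to d(alpha_c), accumulated column by column
        # to avoid materializing K(X, X_S) at every bookkeeping event
        acc = y[c] * kc + beta_b
        for j, col in enumerate(cols):
            acc += (yS[j] * beta[j]) * col
        h = y * acc
        h[S] = 0.0

        C = cfg.C
        alpha = self.alpha
        g = self.g
        events: list[tuple[float, str, int]] = []
        if h[c] > _EPS:
            events.append((max(-g[c], 0.0) / h[c], "c_margin", c))
        events.append((C - alpha[c], "c_bound", c))
        for j_local, j in enumerate(S):
            bj = beta[j_local]
            if bj > _EPS:
                events.append(((C - alpha[j]) / bj, "s_to_e", int(j)))
            elif bj < -_EPS:
                events.append((-alpha[j] / bj, "s_to_r", int(j)))
        E = self.set_indices(ERROR)
        if E.size:
            mask = (h[E] > _EPS) & (g[E] < -_EPS)
            if np.any(mask):
                Em = E[mask]
                d = -g[Em] / h[Em]
                j = int(np.argmin(d))
                events.append((float(d[j]), "e_to_s", int(Em[j])))
        R = self.set_indices(RESERVE)
        if R.size:
            mask = (h[R] < -_EPS) & (g[R] > _EPS) & (R != c)
            if np.any(mask):
                Rm = R[mask]
                d = -g[Rm] / h[Rm]
                j = int(np.argmin(d))
                events.append((float(d[j]), "r_to_s", int(Rm[j])))

        delta, kind, who = min(events, key=lambda e: e[0])
        delta = max(delta, 0.0)

        self._alpha[c] += delta
        self._alpha[S] += beta * delta
        self.bias += beta_b * delta
        self._g[: n] += h * delta
        self._g[S] = 0.0
        np.clip(self._alpha[: n], 0.0, C, out=self._alpha[: n])

        if kind == "c_margin":
            self._sets[c] = MARGIN
            self._g[c] = 0.0
            return True
        if kind == "c_bound":
            self._alpha[c] = C
            self._sets[c] = ERROR
            return True
        if kind == "s_to_e":
            self._alpha[who] = C
            self._sets[who] = ERROR
        elif kind == "s_to_r":
            self._alpha[who] = 0.0
            self._sets[who] = RESERVE
        else:  # e_to_s / r_to_s
            self._sets[who] = MARGIN
            self._g[who] = 0.0
        return False

    # -- auditing ----------------------------------------------------------
    def audit(self) -> AuditReport:
        """Recompute every margin from scratch and list all KKT violations."""
        cfg = self.cfg
        tol = cfg.kkt_tol
        rep = AuditReport()
        g = self._g_fresh()
        alpha = self.alpha
        rep.sum_alpha_y = float(np.sum(alpha * self.y))
        for i in range(self.n):
            s = int(self.sets[i])
            name = SET_NAMES[s]
            a, gi = float(alpha[i]), float(g[i])
            if s == RESERVE:
                if a > tol:
                    rep.violations.append((i, name, a, gi, "reserve vector with alpha > 0"))
                if gi < -tol:
                    rep.violations.append((i, name, a, gi, "reserve vector inside the margin"))
            elif s == MARGIN:
                if not (-tol <= a <= cfg.C + tol):
                    rep.violations.append((i, name, a, gi, "margin alpha outside [0, C]"))
                if abs(gi) > tol:
                    rep.violations.append((i, name, a, gi, "margin vector off the margin"))
            else:
                if abs(a - cfg.C) > tol:
                    rep.violations.append((i, name, a, gi, "error vector with alpha != C"))
                if gi > tol:
                    rep.violations.append((i, name, a, gi, "error vector beyond the margin"))
        if abs(rep.sum_alpha_y) > tol:
            rep.violations.append((-1, "-", 0.0, 0.0,
                                   f"sum(alpha*y) = {rep.sum_alpha_y:.3e} != 0"))
        return rep

    # -- optional reserve pruning (off by default) -------------------------
    def prune_reserve(self, threshold: float = 10.0) -> int:
        """Discard reserve vectors with y*f > threshold; returns the count removed.

        Far-from-boundary reserve vectors rarely re-enter the solution; this
        trades exactness of future updates for memory. Off the default path.
        """
        yf = self._g_fresh() + 1.0
        drop = (self.sets == RESERVE) & (yf > threshold)
        keep = np.flatnonzero(~drop)
        removed = int(np.sum(drop))
        if removed == 0:
            return 0
        for name in ("_X", "_y", "_alpha", "_g", "_sets"):
            arr = getattr(self, name)
            arr[: keep.size] = arr[keep]
        self.n = keep.size
        self._kcache.clear()
        return removed

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-container serialization: arrays + config + set labels (.npz)."""
        np.savez(Path(path), X=self.X, y=self.y, alpha=self.alpha, g=self.g,
                 sets=self.sets, bias=np.array([self.bias]),
                 cfg=np.array([json.dumps(asdict(self.cfg))]))

    @classmethod
    def load(cls, path: str | Path) -> "IncrementalSVM":
        with np.load(Path(path), allow_pickle=False) as z:
            cfg = SVMConfig(**json.loads(str(z["cfg"][0])))
            model = cls(cfg, z["X"].shape[1])
            n = z["X"].shape[0]
            model._ensure_capacity(n)
            model.n = n
            model._X[:n] = z["X"]
            model._y[:n] = z["y"]
            model._alpha[:n] = z["alpha"]
            model._g[:n] = z["g"]
            model._sets[:n] = z["sets"]
            model.bias = float(z["bias"][0])
        return model

    def copy(self) -> "IncrementalSVM":
        other = IncrementalSVM(self.cfg, self.dim)
        other._ensure_capacity(self.n)
        other.n = self.n
        other._X[: self.n] = self.X
        other._y[: self.n] = self.y
        other._alpha[: self.n] = self.alpha
        other._g[: self.n] = self.g
        other._sets[: self.n] = self.sets
        other.bias = self.bias
        return other


# ---------------------------------------------------------------------------
# module-level operation wrappers

def fit_initial(X: np.ndarray, y: np.ndarray, cfg: SVMConfig | None = None) -> IncrementalSVM:
    """Train from scratch by sequential increments.

    The state is seeded with the first sample of each class (two-sample
    problem solved in closed form), then every remaining sample is
    incremented in the given order. Raises on single-class input.
    """
    if cfg is None:
        cfg = SVMConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    if not (np.any(y == 1) and np.any(y == -1)):
        raise ValueError("both classes must be present")
    i_pos = int(np.flatnonzero(y == 1)[0])
    i_neg = int(np.flatnonzero(y == -1)[0])

    model = IncrementalSVM(cfg, X.shape[1])
    _seed_pair(model, X[i_pos], X[i_neg])
    for i in range(X.shape[0]):
        if i in (i_pos, i_neg):
            continue
        model.increment(X[i], y[i])
    return model


def _seed_pair(model: IncrementalSVM, x_pos: np.ndarray, x_neg: np.ndarray) -> None:
    """Closed-form two-sample solution: equal coefficients, margin midpoint bias."""
    cfg = model.cfg
    ip = model._append(x_pos, +1.0)
    im = model._append(x_neg, -1.0)
    K = _kernel_matrix(cfg, model.X, model.X)
    k11, k22, k12 = K[ip, ip], K[im, im], K[ip, im]
    denom = k11 + k22 - 2.0 * k12
    a = cfg.C if denom <= 0 else min(cfg.C, 2.0 / denom)
    model._alpha[ip] = model._alpha[im] = a
    if a < cfg.C:
        model.bias = 1.0 - a * (k11 - k12)
        model._sets[ip] = model._sets[im] = MARGIN
        model._g[ip] = model._g[im] = 0.0
    else:
        # both at the box bound: bias at the midpoint of its feasible interval
        hi = 1.0 - cfg.C * (k11 - k12)
        lo = -1.0 - cfg.C * (k12 - k22)
        model.bias = 0.5 * (lo + hi)
        g = model._g_fresh()
        for i, gi in zip((ip, im), g):
            model._g[i] = gi
            model._sets[i] = MARGIN if abs(gi) <= cfg.kkt_tol else ERROR


def increment(state: IncrementalSVM, x_new: np.ndarray, y_new: float) -> IncrementalSVM:
    """Operation wrapper: integrate one sample in place and return the state."""
    state.increment(x_new, y_new)
    return state


def decision(state: IncrementalSVM, x: np.ndarray) -> tuple[float, int]:
    """Margin output f(x) and the accept(+1)/reject(-1) label (tie f=0 accepts)."""
    f = float(state.decision_function(x)[0])
    return f, (1 if f >= 0.0 else -1)


def kkt_audit(state: IncrementalSVM) -> AuditReport:
    return state.audit()


def smote_balance(X_min: np.ndarray, X_maj: np.ndarray, k: int = 5,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """SMOTE: grow the minority set to the majority size with convex interpolates.

    Each synthetic point is x + u*(n - x) for a random parent x, one of its k
    nearest minority neighbours n, and u ~ U[0, 1]. Deterministic per seed.
    """
    X_min = np.atleast_2d(np.asarray(X_min, dtype=float))
    X_maj = np.atleast_2d(np.asarray(X_maj, dtype=float))
    if X_min.shape[0] < 2:
        raise ValueError("minority class must have at least 2 samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_needed = X_maj.shape[0] - X_min.shape[0]
    if n_needed <= 0:
        return X_min.copy()
    rng = np.random.default_rng(seed)
    k_eff = min(k, X_min.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)  # column 0 is the point itself
    parents = rng.integers(0, X_min.shape[0], size=n_needed)
    picks = rng.integers(1, k_eff + 1, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    nbrs = X_min[idx[parents, picks]]
    synth = X_min[parents] + u[:, None] * (nbrs - X_min[parents])
    return np.vstack([X_min, synth])


def batch_qp_oracle(X: np.ndarray, y: np.ndarray, cfg: SVMConfig | None = None,
                    max_n: int = 20_000) -> IncrementalSVM:
    """Solve the soft-margin dual directly (libsvm) and package the solution
    as a valid incremental-SVM state.

    This is the independent reference route for equivalence tests and the
    full-retraining baseline; the state it returns supports further
    increments.
    """
    if cfg is None:
        cfg = SVMConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] > max_n:
        raise ValueError(f"oracle capped at {max_n} samples, got {X.shape[0]}")
    if not (np.any(y == 1) and np.any(y == -1)):
        raise ValueError("both classes must be present")
    if cfg.kernel == "linear":
        svc = SVC(C=cfg.C, kernel="linear", tol=1e-10)
    else:
        svc = SVC(C=cfg.C, kernel="rbf", gamma=1.0 / cfg.sigma**2, tol=1e-10,
                  cache_size=256)
    svc.fit(X, y)

    model = IncrementalSVM(cfg, X.shape[1])
    model._ensure_capacity(X.shape[0])
    model.n = X.shape[0]
    model._X[: model.n] = X
    model._y[: model.n] = y
    alpha = np.zeros(X.shape[0])
    alpha[svc.support_] = np.abs(svc.dual_coef_.ravel())
    a_tol = 1e-7 * cfg.C
    sets = np.full(X.shape[0], MARGIN, dtype=np.int8)
    sets[alpha <= a_tol] = RESERVE
    sets[alpha >= cfg.C - a_tol] = ERROR
    alpha[sets == RESERVE] = 0.0
    alpha[sets == ERROR] = cfg.C

    # polish: with the E/R assignment fixed, the margin coefficients and bias
    # solve the KKT equalities exactly; this removes libsvm's solver slack
    S = np.flatnonzero(sets == MARGIN)
    bias = float(svc.intercept_[0])
    if S.size:
        yS = y[S]
        KSS = _kernel_matrix(cfg, X[S], X[S])
        A = np.zeros((S.size + 1, S.size + 1))
        A[0, 1:] = yS
        A[1:, 0] = yS
        A[1:, 1:] = (yS[:, None] * yS[None, :]) * KSS + cfg.jitter * np.eye(S.size)
        E = np.flatnonzero(sets == ERROR)
        rhs = np.empty(S.size + 1)
        rhs[0] = -float(np.sum(alpha[E] * y[E]))
        fixed = (_kernel_matrix(cfg, X[S], X[E]) @ (alpha[E] * y[E])
                 if E.size else np.zeros(S.size))
        # margin equalities y_i f(x_i) = 1, written in Q-form:
        # sum_j Q_ij alpha_j + y_i b = 1 - y_i * (error-set contribution)
        rhs[1:] = 1.0 - yS * fixed
        sol = np.linalg.solve(A, rhs)
        bias = float(sol[0])
        alpha[S] = np.clip(sol[1:], 0.0, cfg.C)

    model._alpha[: model.n] = alpha
    model.bias = bias
    model._g[: model.n] = model._g_fresh()
    model._sets[: model.n] = sets
    return model
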