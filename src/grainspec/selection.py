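"""Characteristic-wavelength selection: SPA, random frog, NCA feature weights.

Three selectors, each reducing the 220-band analysis window to a handful of
informative wavelengths and returning a :class:`SelectionResult`:

* **SPA** (successive projections algorithm) — forward selection that grows a
  chain of maximally mutually-orthogonal band columns from every possible
  start, scoring each (start, size) prefix by the RMSE of a multiple linear
  regression on a held-out validation split (RMSEV) and keeping the global
  minimum.
* **Random frog** — a reversible-jump-style Monte Carlo walk over variable
  subsets.  Each iteration proposes a resized candidate subset (grown from a
  random pool or shrunk to the most important members, importance taken from
  a latent-variable inner model), accepts it when its cross-validated RMSE
  improves (or with a small probability otherwise), and finally reports each
  band's selection probability = fraction of iterations whose subset
  contained it.  Bands with probability >= a threshold (0.7) are selected.
* **NCA** (neighborhood component analysis) feature weighting — maximizes the
  expected leave-one-out accuracy of a stochastic nearest-neighbour
  classifier under a per-band weighted distance; the learned squared weights
  rank band relevance and a relative threshold picks the dominant ones.

Class labels (1-4) are treated as numeric responses for the regression-style
inner models of SPA and random frog, the usual chemometrics convention when a
regression selector feeds a classifier.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold

from .table import SpectraTable

__all__ = [
    "SelectionResult",
    "RandomFrogParams",
    "NcaParams",
    "spa_chain",
    "mlr_rmsev",
    "spa_select",
    "random_frog_select",
    "nca_fit",
    "nca_select",
    "select_by_score",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of one selector run.

    ``scores`` is per-band for random frog (selection probability) and NCA
    (squared feature weight); for SPA it is the RMSEV curve over candidate
    sizes at the winning start.  ``diagnostics`` records parameters, seed and
    the objective trace where applicable.
    """

    method: str
    indices: np.ndarray
    wavelengths: np.ndarray
    scores: np.ndarray
    score_kind: str
    diagnostics: dict = field(default_factory=dict)
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("selected indices must be unique and ascending")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)

    def reduction_percent(self, n_bands_in: int) -> float:
        """Dimensionality reduction, e.g. 8 kept of 220 -> 96.36%."""
        return round(100.0 * (1.0 - self.n_selected / n_bands_in), 2)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "indices": self.indices.tolist(),
            "wavelengths_nm": self.wavelengths.tolist(),
            "scores": self.scores.tolist(),
            "score_kind": self.score_kind,
            "diagnostics": _jsonable(self.diagnostics),
            "warning": self.warning,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def spa_chain(X: np.ndarray, start_index: int, max_len: int) -> List[int]:
    """Successive-projections chain of column indices.

    Starting from ``start_index``, repeatedly appends the column with the
    largest norm of its projection onto the orthogonal complement of the span
    of the columns already chosen (ties -> lowest index).  Columns are
    expected mean-centered.  Columns whose residual norm underflows are
    skipped with a log message.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start_index < p:
        raise ValueError(f"start_index {start_index} out of range for {p} columns")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    max_len = min(max_len, n - 1 if n > 1 else 1, p)

    residual = X.copy()
    chain = [start_index]
    available = np.ones(p, dtype=bool)
    available[start_index] = False
    for _ in range(max_len - 1):
        u = residual[:, chain[-1]]
        nu = u @ u
        if nu < 1e-24:
            logger.warning("SPA: zero-norm pivot column %d; chain stops", chain[-1])
            break
        # project all columns onto the orthocomplement of the newest pivot
        residual = residual - np.outer(u, (u @ residual) / nu)
        norms = np.einsum("ij,ij->j", residual, residual)
        norms[~available] = -1.0
        degenerate = available & (norms < 1e-24) & (norms >= 0)
        if degenerate.any():
            logger.info("SPA: skipping %d zero-norm columns", int(degenerate.sum()))
            norms[degenerate] = -1.0
        best = int(np.argmax(norms))  # argmax takes the lowest index on ties
        if norms[best] <= 0:
            break
        chain.append(best)
        available[best] = False
    return chain


def mlr_rmsev(
    X_cal_sel: np.ndarray,
    y_cal: np.ndarray,
    X_val_sel: np.ndarray,
    y_val: np.ndarray,
) -> float:
    """RMSE of an intercept OLS fit, evaluated on the validation rows.

    With zero columns this is the intercept-only model (predict mean(y_cal)).
    Raises on a rank-deficient design.
    """
    X_cal_sel = np.asarray(X_cal_sel, dtype=float)
    X_val_sel = np.asarray(X_val_sel, dtype=float)
    if X_cal_sel.ndim == 1:  # a single column
        X_cal_sel = X_cal_sel[:, None]
    if X_val_sel.ndim == 1:
        X_val_sel = X_val_sel[:, None]
    y_cal = np.asarray(y_cal, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    n, k = X_cal_sel.shape
    if k + 1 > n:
        raise ValueError(f"design with {k} columns + intercept exceeds {n} rows")
    A = np.column_stack([np.ones(n), X_cal_sel])
    coef, _, rank, _ = np.linalg.lstsq(A, y_cal, rcond=None)
    if rank < k + 1:
        raise ValueError(f"rank-deficient design: rank {rank} < {k + 1} columns")
    pred = np.column_stack([np.ones(X_val_sel.shape[0]), X_val_sel]) @ coef
    return float(np.sqrt(np.mean((pred - y_val) ** 2)))


def spa_select(
    table: SpectraTable,
    m_min: int = 1,
    m_max: int = 20,
    val_fraction: float = 0.25,
    seed: int = 0,
) -> SelectionResult:
    """SPA over all starts and sizes, scored by MLR RMSEV.

    The provided (calibration) rows are split internally into a seeded
    75/25 fit/validation partition.  For every start band and every chain
    prefix of size m in [m_min, m_max], an MLR is fit on the fit rows and
    scored on the validation rows; the global RMSEV minimum wins (ties ->
    smaller m, then lower start index).
    """
    if table.labels is None:
        raise ValueError("SPA needs labeled rows")
    if not 1 <= m_min <= m_max:
        raise ValueError("need 1 <= m_min <= m_max")
    X, y = table.x, table.labels.astype(float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction)))
    val_rows, fit_rows = perm[:n_val], perm[n_val:]
    if m_max > min(fit_rows.size - 1, p):
        raise ValueError(
            f"m_max={m_max} exceeds rank budget min(n_fit-1={fit_rows.size - 1}, "
            f"n_bands={p})"
        )

    col_mean = X[fit_rows].mean(axis=0)
    Xc_fit = X[fit_rows] - col_mean

    best = None  # (rmsev, m, start, chain_prefix)
    curves = {}
    for start in range(p):
        chain = spa_chain(Xc_fit, start, m_max)
        curve = np.full(m_max - m_min + 1, np.nan)
        for mi, m in enumerate(range(m_min, m_max + 1)):
            if m > len(chain):
                break
            sel = chain[:m]
            try:
                r = mlr_rmsev(X[fit_rows][:, sel], y[fit_rows],
                              X[val_rows][:, sel], y[val_rows])
            except ValueError:
                continue
            curve[mi] = r
            key = (r, m, start)
            if best is None or key < (best[0], best[1], best[2]):
                best = (r, m, start, tuple(sel))
        curves[start] = curve
    if best is None:
        raise ValueError("SPA found no evaluable subset")
    rmsev, m, start, sel = best
    indices = np.sort(np.array(sel))
    return SelectionResult(
        method="spa",
        indices=indices,
        wavelengths=table.wavelengths[indices],
        scores=curves[start],
        score_kind="rmsev_per_size",
        diagnostics={
            "best_start": start, "best_m": m, "best_rmsev": rmsev,
            "m_min": m_min, "m_max": m_max, "seed": seed,
            "n_fit": int(fit_rows.size), "n_val": int(val_rows.size),
        },
    )


# ---------------------------------------------------------------------------
# Random frog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomFrogParams:
    """Monte Carlo walk parameters.

    ``n_iterations`` (N) chain length; ``q_init`` (Q) size of the initial
    subset; ``n_latent_max`` (A) cap on the inner latent-variable model's
    components; ``theta`` spread of the proposal size Q* ~ |N(Q, theta*Q)|;
    ``eta`` acceptance factor for worse proposals; ``pool_factor`` sizes the
    random candidate pool when growing (pool = pool_factor * (Q*-Q) bands);
    ``threshold`` minimum selection probability for a band to be kept.
    """

    n_iterations: int = 1000
    q_init: int = 2
    n_latent_max: int = 10
    theta: float = 0.3
    eta: float = 0.1
    pool_factor: int = 3
    threshold: float = 0.7
    cv_folds: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.q_init < 1:
            raise ValueError("q_init must be >= 1")
        if self.n_latent_max < 1:
            raise ValueError("n_latent_max must be >= 1")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


def _pls_model(n_components: int) -> PLSRegression:
    return PLSRegression(n_components=n_components, scale=False)


def _pls_importance(X: np.ndarray, y: np.ndarray, cols: np.ndarray,
                    a_max: int) -> np.ndarray:
    """|regression coefficient| of each column in a latent-variable fit."""
    Xs = X[:, cols]
    ncomp = max(1, min(a_max, Xs.shape[1], Xs.shape[0] - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = _pls_model(ncomp).fit(Xs - Xs.mean(0), y - y.mean())
    return np.abs(model.coef_).ravel()


def _pls_rmsecv(X: np.ndarray, y: np.ndarray, cols: np.ndarray,
                a_max: int, folds) -> float:
    """5-fold cross-validated RMSE of the latent-variable inner model."""
    Xs = X[:, cols]
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train, test in folds:
            ncomp = max(1, min(a_max, Xs.shape[1], train.size - 1))
            mx, my = Xs[train].mean(0), y[train].mean()
            model = _pls_model(ncomp).fit(Xs[train] - mx, y[train] - my)
            pred = model.predict(Xs[test] - mx).ravel() + my
            errors.append((pred - y[test]) ** 2)
    return float(np.sqrt(np.mean(np.concatenate(errors))))


def random_frog_select(
    table: SpectraTable, params: RandomFrogParams = RandomFrogParams()
) -> SelectionResult:
    """Random-frog selection probabilities with threshold-based selection.

    Fully deterministic under ``params.rng_seed``.  When no band reaches the
    threshold an empty result is returned with a warning flag so the caller
    can decide how to proceed.
    """
    if table.labels is None:
        raise ValueError("random frog needs labeled rows")
    X, y = table.x, table.labels.astype(float)
    n, p = X.shape
    if params.q_init > p:
        raise ValueError(f"q_init={params.q_init} exceeds {p} bands")
    rng = np.random.default_rng(params.rng_seed)
    folds = list(
        KFold(params.cv_folds, shuffle=True,
              random_state=int(params.rng_seed % (2**31))).split(X)
    )

    V = np.sort(rng.choice(p, size=params.q_init, replace=False))
    rmsecv_V = _pls_rmsecv(X, y, V, params.n_latent_max, folds)
    counts = np.zeros(p)
    subset_sizes = np.zeros(params.n_iterations, dtype=int)
    accepted = 0
    for it in range(params.n_iterations):
        q = V.size
        q_star = int(min(p, max(1, round(abs(rng.normal(q, params.theta * q))))))
        if q_star > q:
            outside = np.setdiff1d(np.arange(p), V)
            pool_size = min(outside.size, params.pool_factor * (q_star - q))
            pool = rng.choice(outside, size=pool_size, replace=False)
            cand = np.concatenate([V, pool])
            imp = _pls_importance(X, y, cand, params.n_latent_max)
            extra_rank = np.argsort(-imp[q:], kind="stable")[: q_star - q]
            V_star = np.sort(np.concatenate([V, pool[extra_rank]]))
        elif q_star < q:
            imp = _pls_importance(X, y, V, params.n_latent_max)
            keep = np.argsort(-imp, kind="stable")[:q_star]
            V_star = np.sort(V[keep])
        else:
            V_star = V
        rmsecv_star = _pls_rmsecv(X, y, V_star, params.n_latent_max, folds)
        if rmsecv_star <= rmsecv_V or rng.uniform() < params.eta * (
            rmsecv_V / max(rmsecv_star, 1e-300)
        ):
            V, rmsecv_V = V_star, rmsecv_star
            accepted += 1
        counts[V] += 1.0
        subset_sizes[it] = V.size

    probs = counts / params.n_iterations
    selected = np.nonzero(probs >= params.threshold)[0]
    warning = None
    if selected.size == 0:
        warning = (
            f"no band reached selection probability {params.threshold}; "
            f"max was {probs.max():.3f}"
        )
        warnings.warn(warning, stacklevel=2)
    return SelectionResult(
        method="frog",
        indices=selected,
        wavelengths=table.wavelengths[selected],
        scores=probs,
        score_kind="selection_probability",
        diagnostics={**asdict(params), "accepted": accepted,
                     "final_rmsecv": rmsecv_V,
                     "subset_sizes": subset_sizes},
        warning=warning,
    )


# ---------------------------------------------------------------------------
# NCA feature weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NcaParams:
    """NCA feature-selection parameters.

    ``lam`` is the ridge penalty on squared weights (None -> 1/n);
    ``sigma`` the kernel width of exp(-d/sigma); weights are climbed with a
    quasi-Newton gradient method until the objective moves by less than
    ``tol`` or ``max_iter`` iterations are reached.
    """

    lam: Optional[float] = None
    sigma: float = 1.0
    max_iter: int = 100
    tol: float = 1e-6
    threshold_rule: str = "relative"
    threshold: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def nca_fit(
    table: SpectraTable, params: NcaParams = NcaParams()
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Learn per-band NCA weights by maximizing stochastic-1-NN accuracy.

    Features are standardized internally.  With weight vector w, sample i
    picks reference j with probability proportional to
    exp(-d_w(x_i, x_j)/sigma), d_w = sum_r w_r^2 |x_ir - x_jr|; the objective
    F(w) = mean_i P(reference of i shares i's class) - lam * sum_r w_r^2
    is climbed by gradient ascent.  Returns (w, objective trace, converged).
    """
    if table.labels is None:
        raise ValueError("NCA needs labeled rows")
    if np.unique(table.labels).size < 2:
        raise ValueError("NCA needs at least 2 classes")
    X = np.asarray(table.x, dtype=float)
    y = table.labels
    n, p = X.shape
    lam = params.lam if params.lam is not None else 1.0 / n

    mu, sd = X.mean(0), X.std(0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd

    # pairwise per-feature absolute differences, (n, n, p)
    D = np.abs(Xs[:, None, :] - Xs[None, :, :]).astype(np.float32)
    same = (y[:, None] == y[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)

    def objective_and_grad(w: np.ndarray):
        w2 = (w ** 2).astype(np.float32)
        dist = np.tensordot(D, w2, axes=([2], [0])).astype(np.float64)
        np.fill_diagonal(dist, np.inf)
        K = np.exp(-(dist - dist.min(axis=1, keepdims=True)) / params.sigma)
        np.fill_diagonal(K, 0.0)
        denom = K.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        P = K / denom
        p_i = (P * same).sum(axis=1)
        F = p_i.mean() - lam * float(w @ w)
        # dF/dw_r = (2 w_r / sigma) * mean_i [p_i * (P D)_ir - (P*same D)_ir] - 2 lam w_r
        A = p_i[:, None] * P - P * same
        core = np.tensordot(A.astype(np.float32), D, axes=([0, 1], [0, 1]))
        grad = (2.0 * w / params.sigma) * (core.astype(np.float64) / n) - 2.0 * lam * w
        return F, grad

    # climb F with L-BFGS on the analytic gradient; at a stationary point the
    # gradient -2*lam*w_r of an uninformative band forces its weight to zero
    from scipy.optimize import minimize

    trace: List[float] = []

    def neg(w):
        F, grad = objective_and_grad(w)
        return -F, -grad

    def record(w):
        trace.append(objective_and_grad(w)[0])

    # w = 0 is always a stationary point (every gradient component carries a
    # factor w_r); with few samples the ridge term at the all-ones start can
    # push the search straight into it.  Two deterministic starts — all-ones
    # and a small-norm scaling — and the better objective wins.
    best = None
    for w0 in (np.ones(p), np.ones(p) / np.sqrt(p)):
        run_trace = [objective_and_grad(w0)[0]]
        trace = run_trace
        res = minimize(
            neg, w0, jac=True, method="L-BFGS-B", callback=record,
            options={"maxiter": params.max_iter, "ftol": params.tol,
                     "gtol": 1e-7},
        )
        F_final = objective_and_grad(res.x)[0]
        if best is None or F_final > best[0]:
            best = (F_final, np.asarray(res.x), np.array(run_trace),
                    bool(res.success) or res.nit < params.max_iter)
    _, w_best, trace_best, converged = best
    if not converged:
        logger.warning("NCA did not converge in %d iterations", params.max_iter)
    return w_best, trace_best, converged


def select_by_score(
    scores: np.ndarray,
    rule: str = "relative",
    threshold: float = 0.05,
    wavelengths: Optional[np.ndarray] = None,
    method: str = "score",
    diagnostics: Optional[dict] = None,
) -> SelectionResult:
    """Threshold a per-band score vector into a selection.

    ``rule`` is ``"absolute"`` (keep score >= threshold) or ``"relative"``
    (keep score >= threshold * max(score)).  An empty selection is returned
    with a warning flag rather than raising.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if rule == "absolute":
        cut = threshold
    elif rule == "relative":
        cut = threshold * scores.max() if scores.size else np.inf
    else:
        raise ValueError(f"unknown rule {rule!r}")
    indices = np.nonzero(scores >= cut)[0] if scores.max() > 0 else np.array([], int)
    warning = None
    if indices.size == 0:
        warning = f"no score passed the {rule} threshold {threshold}"
        warnings.warn(warning, stacklevel=2)
    wl = (np.asarray(wavelengths)[indices]
          if wavelengths is not None else np.full(indices.size, np.nan))
    return SelectionResult(
        method=method, indices=indices, wavelengths=wl, scores=scores,
        score_kind="score", diagnostics=diagnostics or
        {"rule": rule, "threshold": threshold}, warning=warning,
    )


def nca_select(
    table: SpectraTable, params: NcaParams = NcaParams()
) -> SelectionResult:
    """NCA weighting followed by the relative-threshold rule on w^2."""
    w, trace, converged = nca_fit(table, params)
    result = select_by_score(
        w ** 2,
        rule=params.threshold_rule,
        threshold=params.threshold,
        wavelengths=table.wavelengths,
        method="nca",
        diagnostics={**asdict(params), "objective_trace": trace,
                     "converged": converged},
    )
    result.score_kind = "weight_squared"
    return result
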