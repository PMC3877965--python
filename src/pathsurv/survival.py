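"""Survival-statistics primitives: median dichotomization, the two-group
log-rank test, univariate Cox coefficient signs, Kaplan–Meier summaries and
a multivariate Cox wrapper.

The log-rank statistic and the single-covariate Cox fit are implemented as
vectorized numpy routines that evaluate many genes against one survival
outcome in a single pass.  The screening, cross-validation and resampling
stages each perform thousands of per-gene tests, so these two primitives
carry essentially all of the pipeline's compute.  Breslow tie handling is
used throughout; only the coefficient's sign feeds the downstream scoring
rule, and the sign is insensitive to the tie convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupLabels",
    "LogRankResult",
    "CoxFit",
    "KMCurve",
    "dichotomize_at_median",
    "logrank_test",
    "cox_univariate_sign",
    "km_curve",
    "cox_multivariate",
]

HIGH, LOW = "High", "Low"


@dataclass
class GroupLabels:
    """Per-sample High/Low assignment and the cut value that produced it.

    ``high`` is a boolean array, True where the sample is in the High
    (at-or-above-cut) group.
    """

    high: np.ndarray
    cut: float
    degenerate: bool = False

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.high, HIGH, LOW)

    def counts(self) -> tuple[int, int]:
        n_high = int(self.high.sum())
        return n_high, int(self.high.size - n_high)


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    n_high: int
    n_low: int
    events_high: int
    events_low: int


@dataclass
class CoxFit:
    """A (possibly multivariate) Cox proportional-hazards fit.

    ``sign`` is +1/-1 for the leading coefficient, 0 for degenerate fits
    (constant covariate, or no usable information).
    """

    coef: np.ndarray
    p_values: np.ndarray
    converged: bool
    degenerate: bool = False
    names: list[str] = field(default_factory=list)

    @property
    def coefficient(self) -> float:
        return float(self.coef[0])

    @property
    def sign(self) -> int:
        if self.degenerate:
            return 0
        return int(np.sign(self.coef[0]))

    @property
    def p_value(self) -> float:
        return float(self.p_values[0])


@dataclass
class KMCurve:
    """Per-group Kaplan–Meier product-limit estimates and median survival.

    ``tables`` maps group label -> DataFrame(time, survival, at_risk);
    ``medians`` maps group label -> median survival time (inf if the curve
    never reaches 0.5).
    """

    tables: dict[str, pd.DataFrame]
    medians: dict[str, float]


def _as_array(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D vector of per-sample values")
    return a


def dichotomize_at_median(values) -> GroupLabels:
    """Split samples at the sample median; High means value >= median.

    For even n the cut is the mean of the two middle order statistics.
    All-identical input puts every sample in High (the >= rule applied
    literally) and sets the degeneracy flag.
    """
    a = _as_array(values)
    if a.size < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite values")
    cut = float(np.median(a))
    high = a >= cut
    degenerate = bool(high.all() or (~high).all())
    if degenerate:
        warnings.warn("median dichotomization produced a single group", stacklevel=2)
    return GroupLabels(high=high, cut=cut, degenerate=degenerate)


# ---------------------------------------------------------------------------
# internal: shared risk-set geometry
# ---------------------------------------------------------------------------

class _RiskSetLayout:
    """Patients sorted by descending time with tie-block bookkeeping.

    In descending-time order the risk set at an event time is a prefix of
    the sorted patients; ``block_end[i]`` is the last index of the tie block
    containing position i, so prefix cumulative sums evaluated at
    ``block_end`` give risk-set totals that include all tied patients.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be matching 1-D vectors")
        if not np.all(time > 0):
            raise ValueError("survival times must be positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        self.n = time.size
        self.order = np.argsort(-time, kind="stable")
        self.t = time[self.order]
        self.d = event[self.order].astype(bool)
        # last index of each tie block
        n = self.n
        block_end = np.empty(n, dtype=np.intp)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and self.t[k + 1] == self.t[i]:
                k += 1
            block_end[i : k + 1] = k
            i = k + 1
        self.block_end = block_end
        self.event_idx = np.flatnonzero(self.d)          # positions of events
        self.event_risk = block_end[self.event_idx]       # risk-set prefix end per event
        self.n_events = int(self.d.sum())


def _logrank_batch(
    time: np.ndarray, event: np.ndarray, membership: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank chi-square (1 df) for G group assignments against one outcome.

    ``membership`` is a (G, n) boolean matrix, True = High group.  Returns
    (statistic, p_value) arrays of length G; rows whose High or Low group is
    empty, or with zero log-rank variance, come back as NaN.
    """
    layout = _RiskSetLayout(time, event)
    M = np.atleast_2d(np.asarray(membership, dtype=float))[:, layout.order]
    if M.shape[1] != layout.n:
        raise ValueError("membership matrix does not match sample count")
    if layout.n_events == 0:
        raise ValueError("log-rank test requires at least one observed event")

    # distinct event-time blocks
    blocks = np.unique(layout.event_risk)          # prefix-end index per block
    csM = np.cumsum(M, axis=1)                     # (G, n)
    n_at_risk = blocks + 1.0                       # total at risk per block
    n1 = csM[:, blocks]                            # High at risk per block (G, B)

    # events per block, and High events per block; event positions are sorted
    # by time, so block_of_event is non-decreasing and reduceat applies
    block_of_event = np.searchsorted(blocks, layout.event_risk)
    d_total = np.bincount(block_of_event, minlength=blocks.size).astype(float)
    ev_M = M[:, layout.event_idx]                  # (G, E)
    starts = np.flatnonzero(np.r_[True, np.diff(block_of_event) != 0])
    d1 = np.add.reduceat(ev_M, starts, axis=1)     # (G, B): one run per block

    frac = n1 / n_at_risk
    oe = (d1 - d_total * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_term = d_total * frac * (1.0 - frac) * (n_at_risk - d_total) / (n_at_risk - 1.0)
    var_term = np.where(n_at_risk > 1, var_term, 0.0)
    variance = var_term.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = np.where(variance > 0, oe**2 / variance, np.nan)
    p = stats.chi2.sf(statistic, df=1)

    n_high = M.sum(axis=1)
    bad = (n_high == 0) | (n_high == layout.n)
    statistic = np.where(bad, np.nan, statistic)
    p = np.where(bad | ~np.isfinite(statistic), np.nan, p)
    return statistic, p


def logrank_test(surv: pd.DataFrame, labels: GroupLabels) -> LogRankResult:
    """Two-group log-rank test (chi-square, 1 df) of High vs Low survival.

    At each distinct event time the observed High-group events are compared
    with their hypergeometric expectation given the at-risk counts; the
    squared sum of differences over the summed hypergeometric variance is
    referred to the upper tail of chi-square(1).  Patients censored at an
    event time count as at risk through that time.
    """
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy()
    high = np.asarray(labels.high, dtype=bool)
    if high.shape[0] != time.shape[0]:
        raise ValueError("labels do not match the survival table")
    n_high = int(high.sum())
    if n_high == 0 or n_high == high.size:
        raise ValueError("log-rank test requires both groups non-empty")
    if int(np.sum(event)) == 0:
        raise ValueError("log-rank test requires at least one observed event")

    stat, p = _logrank_batch(time, event, high[None, :])
    statistic = float(stat[0])
    if not np.isfinite(statistic):
        # zero variance (e.g. single event pattern); O == E everywhere
        statistic, pval = 0.0, 1.0
    else:
        pval = float(p[0])
    return LogRankResult(
        statistic=statistic,
        p_value=pval,
        n_high=n_high,
        n_low=int(high.size - n_high),
        events_high=int(event[high].sum()),
        events_low=int(event[~high].sum()),
    )


# ---------------------------------------------------------------------------
# univariate Cox (batched Newton–Raphson, Breslow ties)
# ---------------------------------------------------------------------------

_MAX_BETA = 20.0


def _cox_batch(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single-covariate Cox partial-likelihood fits for G covariates at once.

    ``X`` is (G, n).  Returns (beta, p_wald, converged, degenerate).  A
    covariate that is constant (or carries no score information at beta=0)
    is flagged degenerate with beta 0.  Separation / non-convergence falls
    back to the sign of the score statistic at beta=0: beta is set to
    sign(U0) * _MAX_BETA so downstream sign logic still works, with the
    convergence flag False.
    """
    layout = _RiskSetLayout(time, event)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = X[:, layout.order]
    G, n = Xs.shape
    if layout.n_events < 2:
        raise ValueError("Cox fit requires at least 2 observed events")

    ev, rk = layout.event_idx, layout.event_risk

    def score_info(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        eta = beta[:, None] * Xs
        eta -= eta.max(axis=1, keepdims=True)  # scale cancels in the ratios
        W = np.exp(eta)
        S0 = np.cumsum(W, axis=1)[:, rk]
        S1 = np.cumsum(W * Xs, axis=1)[:, rk]
        S2 = np.cumsum(W * Xs * Xs, axis=1)[:, rk]
        mu = S1 / S0
        v = S2 / S0 - mu**2
        U = (Xs[:, ev] - mu).sum(axis=1)
        info = v.sum(axis=1)
        return U, info

    beta = np.zeros(G)
    U0, I0 = score_info(beta)
    degenerate = I0 <= 1e-12
    active = ~degenerate
    converged = np.zeros(G, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        U, info = score_info(beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 1e-12, U / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -1.0, 1.0)
        beta = np.where(active, np.clip(beta + step, -_MAX_BETA, _MAX_BETA), beta)
        done = active & (np.abs(step) < tol)
        converged |= done
        active &= ~done
        active &= np.abs(beta) < _MAX_BETA  # hit the cap: separation, stop iterating

    converged &= ~degenerate
    separated = ~converged & ~degenerate
    if separated.any():
        beta = np.where(separated, np.sign(U0) * _MAX_BETA, beta)

    _, info_hat = score_info(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info_hat > 0, 1.0 / np.sqrt(np.maximum(info_hat, 1e-300)), np.inf)
    z = np.where(np.isfinite(se), beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(degenerate, np.nan, p)
    beta = np.where(degenerate, 0.0, beta)
    return beta, p, converged, degenerate


def cox_univariate_sign(surv: pd.DataFrame, covariate) -> CoxFit:
    """Fit a single-covariate Cox model and report the coefficient's sign.

    The partial likelihood (Breslow ties) is maximized by Newton–Raphson.
    On non-convergence or separation the sign of the score statistic at
    beta = 0 is used and the convergence flag is False.  A constant
    covariate yields sign 0 with the degenerate flag set.
    """
    x = _as_array(covariate)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy()
    if x.shape[0] != time.shape[0]:
        raise ValueError("covariate does not match the survival table")
    beta, p, conv, degen = _cox_batch(time, event, x[None, :])
    return CoxFit(
        coef=np.array([beta[0]]),
        p_values=np.array([p[0]]),
        converged=bool(conv[0]),
        degenerate=bool(degen[0]),
        names=["covariate"],
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier and multivariate Cox (lifelines-backed)
# ---------------------------------------------------------------------------

def km_curve(surv: pd.DataFrame, labels: GroupLabels | None = None) -> KMCurve:
    """Kaplan–Meier product-limit curves per group, with median survival.

    With ``labels`` None the whole cohort forms a single "All" group.  The
    median is the earliest time the survival estimate drops to <= 0.5
    (``inf`` if it never does).
    """
    from lifelines import KaplanMeierFitter

    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy()
    if labels is None:
        groups = {"All": np.ones(time.size, dtype=bool)}
    else:
        groups = {HIGH: np.asarray(labels.high, bool), LOW: ~np.asarray(labels.high, bool)}

    tables: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for name, mask in groups.items():
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        tables[name] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": at_risk.to_numpy(dtype=float),
            }
        )
        medians[name] = float(kmf.median_survival_time_)
    return KMCurve(tables=tables, medians=medians)


def cox_multivariate(surv: pd.DataFrame, covariates: pd.DataFrame) -> CoxFit:
    """Multivariate Cox regression (Breslow ties) over named covariates.

    Thin wrapper around :class:`lifelines.CoxPHFitter`; returns the
    coefficient vector with per-coefficient Wald p-values.  Rank-deficient
    designs are rejected up front, naming the offending covariates.
    """
    from lifelines import CoxPHFitter

    covariates = pd.DataFrame(covariates)
    if covariates.index.shape[0] != surv.shape[0]:
        raise ValueError("covariates do not match the survival table")
    Xm = covariates.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        bad = [c for c in covariates.columns if covariates[c].nunique() <= 1]
        raise ValueError(
            f"rank-deficient design matrix; suspect covariates: {bad or list(covariates.columns)}"
        )
    n_events = int(np.sum(surv["event"].to_numpy()))
    if n_events < Xm.shape[1]:
        raise ValueError("fewer events than covariates")

    df = covariates.copy()
    df["time"] = surv["time"].to_numpy(dtype=float)
    df["event"] = surv["event"].to_numpy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    names = list(covariates.columns)
    coef = cph.params_.reindex(names).to_numpy()
    p = cph.summary["p"].reindex(names).to_numpy()
    return CoxFit(coef=coef, p_values=p, converged=True, names=names)
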