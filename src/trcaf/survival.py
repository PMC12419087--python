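"""Per-gene prognostic screening on a bulk survival cohort.

The screen dichotomizes each gene at the expression cutpoint that maximizes a
standardized two-group log-rank statistic (a maximally selected rank
statistic), attaches a selection-adjusted p-value (permutation by default),
estimates the hazard direction with the Pike O/E ratio, and classifies each
gene as high-risk (HR > 1, p < alpha), low-risk (HR < 1, p < alpha) or
neither.  A gene-set variant z-scores the member genes, averages them into a
per-sample signature and stratifies the cohort by the same machinery.

All standardized statistics use the Mantel-Cox hypergeometric variance, so
the squared standardized statistic at a fixed dichotomy equals the ordinary
log-rank chi-square for that dichotomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalCohort",
    "KMCurve",
    "LogrankResult",
    "DegenerateExpressionError",
    "km_estimate",
    "logrank_test",
    "estimate_hr",
    "maxstat_cutpoint",
    "screen_genes",
    "stratify_by_signature",
]


class DegenerateExpressionError(ValueError):
    """Raised when no admissible cutpoint exists (e.g. all values tied)."""


@dataclass
class SurvivalCohort:
    """Expression matrix (genes x samples) with right-censored follow-up.

    ``expr`` columns must be ordered like ``samples``; ``event`` is 1 for an
    observed event and 0 for censoring.
    """

    expr: pd.DataFrame
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = self.expr.shape[1]
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match expr columns")
        if np.any(np.isnan(self.time)) or np.any(self.time < 0):
            raise ValueError("times must be non-negative and non-missing")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass(frozen=True)
class LogrankResult:
    """Mantel-Cox log-rank test; group 1 first in observed/expected."""

    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    p_value: float


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimator; censored-only input yields a flat curve at 1."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0 or t.shape != e.shape:
        raise ValueError("time and event must be equal-length, non-empty")
    if np.any(t < 0):
        raise ValueError("negative times")
    if e.sum() == 0:
        empty = np.array([])
        return KMCurve(empty, empty, empty.astype(int), empty.astype(int))
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    obs = table[table["observed"] > 0]
    times = obs.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=obs["at_risk"].to_numpy(dtype=int),
        n_events=obs["observed"].to_numpy(dtype=int),
    )


def _risk_grid(t: np.ndarray, e: np.ndarray):
    """Distinct event times with event counts, at-risk counts and the
    sample-by-event-time at-risk indicator matrix."""
    et = np.unique(t[e == 1])
    if et.size == 0:
        return et, et, et, np.zeros((t.size, 0), dtype=bool)
    d = np.array([(t[e == 1] == tj).sum() for tj in et], dtype=float)
    R = t[:, None] >= et[None, :]
    return et, d, R.sum(axis=0).astype(float), R


def _group1_mask(group: Sequence, high_label=None) -> np.ndarray:
    g = np.asarray(group)
    if g.dtype == bool:
        return g
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("group must have exactly 2 levels")
    if high_label is None:
        high_label = sorted(map(str, labels))[-1]
    mask = np.asarray([str(x) == str(high_label) for x in g])
    return mask


def logrank_test(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence,
    high_label=None,
) -> LogrankResult:
    """Two-group Mantel-Cox log-rank test.

    ``group`` may be boolean (True = group 1) or any 2-level labels; with
    labels, ``high_label`` selects group 1 (default: lexicographically last).
    Ties in event times are aggregated into one hypergeometric table.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    mask1 = _group1_mask(group, high_label)
    if mask1.all() or not mask1.any():
        raise ValueError("both groups must be non-empty")
    et, d, nj, R = _risk_grid(t, e)
    if et.size == 0:
        zero = np.zeros(2)
        return LogrankResult(zero, zero, 0.0, 1.0)
    n1j = R[mask1].sum(axis=0).astype(float)
    O1 = float(e[mask1].sum())
    D = float(d.sum())
    E1 = float(np.sum(d * n1j / nj))
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = np.where(
            nj > 1,
            d * (n1j / nj) * (1.0 - n1j / nj) * (nj - d) / (nj - 1.0),
            0.0,
        )
    V = float(var_terms.sum())
    if V <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = (O1 - E1) ** 2 / V
        p = float(stats.chi2.sf(stat, df=1))
    return LogrankResult(
        observed=np.array([O1, D - O1]),
        expected=np.array([E1, D - E1]),
        statistic=float(stat),
        p_value=p,
    )


def estimate_hr(logrank: LogrankResult) -> float:
    """Pike hazard-ratio estimate (O1/E1)/(O2/E2); group 1 = high expression.

    Returns NaN when either expected count is zero (undefined).
    """
    O1, O2 = logrank.observed
    E1, E2 = logrank.expected
    if E1 <= 0 or E2 <= 0:
        return float("nan")
    with np.errstate(divide="ignore"):
        if O2 == 0:
            return float("inf") if O1 > 0 else float("nan")
        return float((O1 / E1) / (O2 / E2))


def _prefix_statistics(orders: np.ndarray, e: np.ndarray, d, nj, R,
                       dtype=np.float64) -> np.ndarray:
    """|standardized log-rank| for every prefix high-group of each ordering.

    ``orders`` has shape (B, n); entry (b, k-1) of the result is the
    standardized statistic when the high group is the first k samples of
    ordering b.  Hypergeometric variance throughout.  float32 is accurate
    enough for permutation maxima; the observed scan uses float64.
    """
    Rf = R.astype(dtype)
    Rb = Rf[orders]                      # (B, n, m)
    n1 = np.cumsum(Rb, axis=1)
    O1 = np.cumsum(e[orders], axis=1).astype(dtype)
    w = (d / nj).astype(dtype)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(nj > 1, d * (nj - d) / (nj * (nj - 1.0)), 0.0)
    beta = (alpha / nj).astype(dtype)
    alpha = alpha.astype(dtype)
    E1 = n1 @ w
    V = n1 @ alpha - (n1 * n1) @ beta
    U = O1 - E1
    Z = np.zeros_like(U)
    ok = V > 1e-9
    Z[ok] = np.abs(U[ok]) / np.sqrt(V[ok])
    return Z.astype(np.float64)


def _cutpoint_window(n: int, minprop: float, maxprop: float) -> tuple[int, int]:
    # prefix size k = high-group size; low-group proportion (n-k)/n must lie
    # in [minprop, maxprop]
    k_lo = max(1, int(np.ceil(n * (1.0 - maxprop) - 1e-9)))
    k_hi = min(n - 1, int(np.floor(n * (1.0 - minprop) + 1e-9)))
    return k_lo, k_hi


def _miller_siegmund_p(b: float, t1: float, t2: float) -> float:
    """Approximate p-value for the maximally selected standardized statistic
    (Brownian-bridge band-crossing approximation); conservative at small n."""
    if b <= 1.0:
        return 1.0
    phi = stats.norm.pdf(b)
    p = 4.0 * phi / b + phi * (b - 1.0 / b) * np.log(
        (t2 * (1.0 - t1)) / (t1 * (1.0 - t2))
    )
    return float(min(1.0, max(0.0, p)))


def maxstat_cutpoint(
    expr_g: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    minprop: float = 0.1,
    maxprop: float = 0.9,
    p_method: str = "permutation",
    n_perm: int = 1000,
    seed: int | None = None,
    _grid=None,
    _rng=None,
    _early_stop: int = 0,
) -> tuple[float, float, float]:
    """Maximally selected log-rank statistic over expression cutpoints.

    Every distinct expression value whose induced low-group proportion lies in
    ``[minprop, maxprop]`` is scanned as a dichotomizing threshold (high group
    = expression strictly above).  Returns ``(cutpoint, max_statistic,
    p_value)`` where the cutpoint is the midpoint between the two adjacent
    distinct values bracketing the best split (smallest such value on ties).

    ``p_method='permutation'`` computes an add-one-smoothed permutation
    p-value of the maximal statistic; ``'approx'`` uses the Brownian-bridge
    band-crossing approximation.
    """
    x = np.asarray(expr_g, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    n = x.size
    if t.shape != x.shape or e.shape != x.shape:
        raise ValueError("expr/time/event lengths differ")
    order = np.argsort(-x, kind="stable")
    xs = x[order]
    k_lo, k_hi = _cutpoint_window(n, minprop, maxprop)
    if k_hi < k_lo:
        raise DegenerateExpressionError("cutpoint window is empty")
    boundary = xs[:-1] > xs[1:]          # prefix size k valid iff xs[k-1] > xs[k]
    ks = np.arange(1, n)
    valid = boundary & (ks >= k_lo) & (ks <= k_hi)
    if not valid.any():
        raise DegenerateExpressionError(
            "fewer than 2 distinct expression values in the cutpoint window"
        )
    et, d, nj, R = _risk_grid(t, e)
    if et.size == 0:
        raise DegenerateExpressionError("no events in cohort")
    grid = (e, d, nj, R) if _grid is None else _grid
    Z = _prefix_statistics(order[None, :], *grid)[0][:-1]  # prefix sizes 1..n-1
    Zv = np.where(valid, Z, -np.inf)
    max_stat = float(Zv.max())
    # ties -> smallest cutpoint value -> largest admissible prefix
    best_k = int(np.max(np.flatnonzero(Zv >= max_stat - 1e-12))) + 1
    cutpoint = float((xs[best_k - 1] + xs[best_k]) / 2.0)

    if p_method == "approx":
        p = _miller_siegmund_p(max_stat, k_lo / n, k_hi / n)
    elif p_method == "permutation":
        rng = _rng if _rng is not None else np.random.default_rng(seed)
        exceed = 0
        base = np.arange(n)
        # permuting expression against (time, event) = scanning prefixes of a
        # random sample ordering; tie structure of expr is preserved, so the
        # same valid-k mask applies
        chunk = max(1, min(n_perm, int(2e7 // max(1, n * max(1, et.size)))))
        if _early_stop:
            chunk = min(chunk, max(25, 2 * _early_stop))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            orders = rng.permuted(np.tile(base, (b, 1)), axis=1)
            Zp = _prefix_statistics(orders, *grid, dtype=np.float32)[:, :-1]
            perm_max = np.where(valid, Zp, -np.inf).max(axis=1)
            exceed += int((perm_max >= max_stat - 1e-5).sum())
            done += b
            # sequential early stop: once the observed maximum has been beaten
            # many times the gene can never reach alpha; the truncated
            # estimate stays valid (and conservative) for such genes, while
            # small p-values always use the full permutation budget
            if _early_stop and exceed >= _early_stop and done < n_perm:
                break
        p = (1.0 + exceed) / (done + 1.0)
    else:
        raise ValueError(f"unknown p_method: {p_method!r}")
    return cutpoint, max_stat, float(p)


RISK_ALL_HR = "ALL_HR"
RISK_ALL_LR = "ALL_LR"
RISK_NONE = "NONE"


def screen_genes(
    cohort: SurvivalCohort,
    alpha: float = 0.05,
    minprop: float = 0.1,
    maxprop: float = 0.9,
    p_method: str = "permutation",
    n_perm: int = 1000,
    seed: int | None = None,
    early_stop: int = 25,
) -> pd.DataFrame:
    """Screen every gene of the cohort for prognostic impact.

    For each gene: maxstat cutpoint and selection-adjusted p-value, Pike HR of
    the high- vs low-expression groups at that cutpoint, and the risk class
    (ALL_HR iff HR > 1 and p < alpha; ALL_LR iff HR < 1 and p < alpha).
    Degenerate genes (no admissible cutpoint) are classified NONE and flagged.
    Returns a DataFrame sorted by p-value with BH q-values reported alongside
    (classification uses the nominal p, q is informational).
    """
    t, e = cohort.time, cohort.event
    et, d, nj, R = _risk_grid(t, e)
    if et.size == 0:
        raise ValueError("cohort has no events")
    grid = (e, d, nj, R)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort.genes))
    rows = []
    X = cohort.expr.to_numpy(dtype=float)
    for gi, gene in enumerate(cohort.genes):
        x = X[gi]
        try:
            cut, mstat, p = maxstat_cutpoint(
                x, t, e,
                minprop=minprop, maxprop=maxprop,
                p_method=p_method, n_perm=n_perm,
                _grid=grid, _rng=np.random.default_rng(children[gi]),
                _early_stop=early_stop,
            )
        except DegenerateExpressionError as err:
            rows.append(
                dict(gene=gene, cutpoint=np.nan, max_statistic=np.nan,
                     p_value=np.nan, hr=np.nan, risk_class=RISK_NONE,
                     note=str(err))
            )
            continue
        lr = logrank_test(t, e, x > cut)
        hr = estimate_hr(lr)
        if p < alpha and np.isfinite(hr) and hr > 1:
            cls = RISK_ALL_HR
        elif p < alpha and hr < 1:
            cls = RISK_ALL_LR
        else:
            cls = RISK_NONE
        rows.append(
            dict(gene=gene, cutpoint=cut, max_statistic=mstat, p_value=p,
                 hr=hr, risk_class=cls, note="")
        )
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["q_value"] = q
    out = out.sort_values(["p_value", "gene"], na_position="last").reset_index(drop=True)
    return out[["gene", "cutpoint", "max_statistic", "p_value", "q_value",
                "hr", "risk_class", "note"]]


def signature_values(cohort: SurvivalCohort, genes: Sequence[str]) -> pd.Series:
    """Per-sample signature = mean of z-scored member-gene expression."""
    present = [g for g in genes if g in cohort.expr.index]
    if not present:
        raise ValueError("gene set has empty intersection with cohort genes")
    sub = cohort.expr.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    return pd.Series(z.mean(axis=0), index=cohort.expr.columns, name="signature")


def stratify_by_signature(
    cohort: SurvivalCohort,
    geneset: Sequence[str],
    cut_method: str = "maxstat",
    minprop: float = 0.1,
    maxprop: float = 0.9,
    p_method: str = "permutation",
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[pd.Series, LogrankResult, tuple[KMCurve, KMCurve]]:
    """Dichotomize the cohort by a gene-set signature and test survival.

    Returns per-sample high/low labels, the log-rank result (group 1 = high
    signature) and the (high, low) Kaplan-Meier curves.
    """
    sig = signature_values(cohort, geneset)
    if cut_method == "median":
        cut = float(np.median(sig))
    elif cut_method == "maxstat":
        cut, _, _ = maxstat_cutpoint(
            sig.to_numpy(), cohort.time, cohort.event,
            minprop=minprop, maxprop=maxprop,
            p_method=p_method, n_perm=n_perm, seed=seed,
        )
    else:
        raise ValueError(f"unknown cut_method: {cut_method!r}")
    high = sig > cut
    if high.all() or not high.any():
        raise DegenerateExpressionError("signature cut left one group empty")
    labels = pd.Series(np.where(high, "high", "low"), index=sig.index, name="group")
    lr = logrank_test(cohort.time, cohort.event, high.to_numpy())
    km_high = km_estimate(cohort.time[high.to_numpy()], cohort.event[high.to_numpy()])
    km_low = km_estimate(cohort.time[~high.to_numpy()], cohort.event[~high.to_numpy()])
    return labels, lr, (km_high, km_low)
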