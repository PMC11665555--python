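"""Expression-versus-outcome survival screening.

Implements the estimators the screen is built from — Kaplan-Meier
product-limit curves, the two-group log-rank test (hypergeometric
variance at each distinct event time), and univariate Cox proportional
hazards by Newton-Raphson maximization of the Efron-corrected partial
likelihood — plus the two dichotomization analyses run on top of them:

* median split: high group = expression >= median (ties go high), with
  KM curves, log-rank p and Cox HR + 95% CI;
* optimal-cutoff scan: dichotomize at every candidate cutoff in a
  quantile window, trace HR and 95% CI across cutoffs, and choose the
  cutoff by minimum log-rank p (or maximum |log HR|).

The chosen-cutoff p is selection-biased (a minimum over many tests) and
is flagged as such in the scan output; no multiplicity correction is
applied because none is part of the screening procedure.

All times are treated as right-censored only.  The Cox solver fits on a
standardized covariate internally and maps the coefficient back, which
keeps Newton iterations well-conditioned for arbitrary expression units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

__all__ = [
    "km_estimate",
    "km_survival_at",
    "logrank_test",
    "cox_univariate",
    "CoxResult",
    "median_split",
    "MedianSplitResult",
    "cutpoint_scan",
    "CutpointScan",
]

_Z975 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a DataFrame (time, at_risk, n_events, survival) with one row
    per distinct event time; the curve is right-continuous,
    non-increasing and starts at 1.  A fully censored sample yields an
    empty table (a flat curve at 1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("empty cohort")
    if (time <= 0).any():
        raise ValueError("follow-up times must be positive")
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    event_times = np.unique(t_s[e_s])
    n = time.size
    at_risk = n - np.searchsorted(t_s, event_times, side="left")
    d = np.array([int(((t_s == t) & e_s).sum()) for t in event_times])
    surv = np.cumprod(1.0 - d / at_risk)
    return pd.DataFrame({
        "time": event_times,
        "at_risk": at_risk,
        "n_events": d,
        "survival": surv,
    })


def km_survival_at(curve: pd.DataFrame, t: float) -> float:
    """Evaluate a KM step function at time t (1 before the first event)."""
    below = curve.loc[curve["time"] <= t, "survival"]
    return float(below.iloc[-1]) if len(below) else 1.0


# ---------------------------------------------------------------------------
# Shared tied-risk-set bookkeeping (descending-time block structure)
# ---------------------------------------------------------------------------

@dataclass
class _RiskSets:
    """Precomputed block structure for one (time, event) sample."""

    order: np.ndarray          # descending-time permutation
    t_s: np.ndarray
    e_s: np.ndarray
    block_id: np.ndarray       # per observation, 0-based distinct-time block
    block_last: np.ndarray     # per block, last index (risk-set boundary)
    ev_pos: np.ndarray         # positions (desc order) of events
    blk_e: np.ndarray          # block id per event
    frac: np.ndarray           # Efron fraction l/d per event
    d_per_block: np.ndarray


def _risk_sets(time: np.ndarray, event: np.ndarray) -> _RiskSets:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(-time, kind="stable")
    t_s, e_s = time[order], event[order]
    if t_s.size == 1:
        block_id = np.zeros(1, dtype=int)
    else:
        block_id = np.concatenate([[0], np.cumsum(t_s[1:] != t_s[:-1])])
    counts = np.bincount(block_id)
    block_last = np.cumsum(counts) - 1
    ev_pos = np.flatnonzero(e_s)
    blk_e = block_id[ev_pos]
    d_per_block = np.bincount(blk_e, minlength=counts.size)
    starts = np.concatenate([[0], np.cumsum(d_per_block)[:-1]])
    l_rank = np.arange(ev_pos.size) - starts[blk_e]
    with np.errstate(invalid="ignore"):
        frac = l_rank / d_per_block[blk_e]
    return _RiskSets(order, t_s, e_s, block_id, block_last,
                     ev_pos, blk_e, frac, d_per_block)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

def logrank_test(time: np.ndarray, event: np.ndarray,
                 group_mask: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test.

    Ties are handled with the hypergeometric variance at each distinct
    event time.  Returns (chi-square statistic on 1 df, p-value).
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.all() or not group_mask.any():
        raise ValueError("both groups must be non-empty")
    rs = _risk_sets(time, event)
    if rs.ev_pos.size == 0:
        return 0.0, 1.0
    m_s = group_mask[rs.order].astype(float)
    cum_m = np.cumsum(m_s)
    blocks = np.flatnonzero(rs.d_per_block > 0)
    last = rs.block_last[blocks]
    n_at = last + 1.0
    n1_at = cum_m[last]
    d = rs.d_per_block[blocks].astype(float)
    d1 = np.bincount(rs.blk_e, weights=m_s[rs.ev_pos],
                     minlength=rs.d_per_block.size)[blocks]
    o_minus_e = d1 - d * n1_at / n_at
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(
            n_at > 1,
            d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1),
            0.0,
        )
    v = float(var.sum())
    if v <= 0:
        return 0.0, 1.0
    stat = float(o_minus_e.sum() ** 2 / v)
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Univariate Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Univariate Cox fit: hazard ratio with Wald 95% CI."""

    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    se: float
    converged: bool
    message: str = ""
    n_events: int = 0


def cox_univariate(time: np.ndarray, event: np.ndarray,
                   covariate: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-9) -> CoxResult:
    """Fit a single-covariate Cox model by Newton-Raphson.

    Maximizes the Efron-corrected partial likelihood; the hazard ratio
    is exp(coefficient) per unit of the covariate, with a Wald 95% CI
    from the observed information.  Monotone likelihoods (complete
    separation of events by the covariate) are flagged non-converged
    rather than silently reporting a divergent estimate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    if x.size != time.size or event.size != time.size:
        raise ValueError("time, event and covariate lengths differ")
    if int(event.sum()) == 0:
        raise ValueError("need at least one event")
    sd = float(x.std())
    if sd == 0.0:
        raise ValueError("constant covariate carries no information")
    z = (x - x.mean()) / sd

    rs = _risk_sets(time, event)
    z_s = z[rs.order]
    ev = rs.ev_pos
    blk_e = rs.blk_e
    frac = rs.frac
    nblk = rs.d_per_block.size
    last_e = rs.block_last[blk_e]
    z_ev_sum = float(z_s[ev].sum())

    beta = 0.0
    converged = False
    message = ""
    info = np.nan
    for _ in range(max_iter):
        w = np.exp(beta * z_s)
        wz = w * z_s
        wzz = wz * z_s
        c0, c1, c2 = np.cumsum(w), np.cumsum(wz), np.cumsum(wzz)
        s0d = np.bincount(blk_e, weights=w[ev], minlength=nblk)[blk_e]
        s1d = np.bincount(blk_e, weights=wz[ev], minlength=nblk)[blk_e]
        s2d = np.bincount(blk_e, weights=wzz[ev], minlength=nblk)[blk_e]
        a0 = c0[last_e] - frac * s0d
        a1 = c1[last_e] - frac * s1d
        a2 = c2[last_e] - frac * s2d
        r = a1 / a0
        grad = z_ev_sum - float(r.sum())
        info = float((a2 / a0 - r * r).sum())
        if not np.isfinite(grad) or not np.isfinite(info) or info <= 0:
            message = "singular information matrix"
            break
        delta = grad / info
        beta += delta
        if abs(beta) > 40.0:
            message = "monotone partial likelihood (separation)"
            break
        if abs(delta) < tol:
            converged = True
            break
    else:
        message = "maximum iterations reached"

    if not converged:
        logger.warning("Cox fit did not converge: %s", message)
        return CoxResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         False, message, int(event.sum()))
    coef = beta / sd
    se = (1.0 / np.sqrt(info)) / sd
    return CoxResult(
        coef=float(coef),
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - _Z975 * se)),
        ci_high=float(np.exp(coef + _Z975 * se)),
        p=float(2.0 * stats.norm.sf(abs(coef) / se)),
        se=float(se),
        converged=True,
        n_events=int(event.sum()),
    )


# ---------------------------------------------------------------------------
# Median split
# ---------------------------------------------------------------------------

@dataclass
class MedianSplitResult:
    high_mask: np.ndarray
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    logrank_stat: float
    logrank_p: float
    cox: CoxResult
    cutoff: float = np.nan


def median_split(cohort: pd.DataFrame) -> MedianSplitResult:
    """Dichotomize at the median expression (ties to the high group).

    Emits both groups' KM curves, the log-rank test and the Cox hazard
    ratio of high versus low expression.
    """
    if len(cohort) < 4:
        raise ValueError("median split needs at least 4 subjects")
    expr = cohort["expression"].to_numpy(dtype=float)
    if np.ptp(expr) == 0:
        raise ValueError("all expression values identical; cannot split")
    med = float(np.median(expr))
    mask = expr >= med
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=bool)
    stat, p = logrank_test(time, event, mask)
    cox = cox_univariate(time, event, mask.astype(float))
    return MedianSplitResult(
        high_mask=mask,
        km_high=km_estimate(time[mask], event[mask]),
        km_low=km_estimate(time[~mask], event[~mask]),
        logrank_stat=stat,
        logrank_p=p,
        cox=cox,
        cutoff=med,
    )


# ---------------------------------------------------------------------------
# Optimal-cutoff scan
# ---------------------------------------------------------------------------

@dataclass
class CutpointScan:
    """HR / CI / log-rank trace across candidate dichotomization cutoffs."""

    table: pd.DataFrame
    chosen_cutoff: float
    chosen_rule: str
    notes: dict = field(default_factory=dict)


def _candidate_cutoffs(expr: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    q_lo, q_hi = config.cutoff_grid_quantiles
    lo = np.quantile(expr, q_lo, method="higher")
    hi = np.quantile(expr, q_hi, method="higher")
    if config.n_cutoffs is None:
        vals = np.unique(expr)
        return vals[(vals >= lo) & (vals <= hi)]
    qs = np.linspace(q_lo, q_hi, int(config.n_cutoffs))
    return np.unique(np.quantile(expr, qs, method="higher"))


def cutpoint_scan(cohort: pd.DataFrame,
                  config: AnalysisConfig | None = None) -> CutpointScan:
    """Trace HR, 95% CI and log-rank p across candidate cutoffs.

    Candidates are quantile-spaced observed expression values inside the
    configured window (default 41 points over the 10%-90% quantiles,
    which includes the exact median-split cutoff); ``n_cutoffs=None``
    scans every distinct value in the window.  The chosen cutoff follows
    ``config.cutpoint_rule`` — minimum log-rank p (ties broken by larger
    |log HR|, then lower cutoff) or maximum |log HR| (ties by smaller p,
    then lower cutoff).  Per-cutoff non-convergence is recorded as
    missing, not fatal.
    """
    config = config or AnalysisConfig()
    if len(cohort) < 10:
        raise ValueError("cutpoint scan needs at least 10 subjects")
    expr = cohort["expression"].to_numpy(dtype=float)
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=bool)
    cutoffs = _candidate_cutoffs(expr, config)
    if cutoffs.size < 2:
        raise ValueError("fewer than 2 distinct cutoffs in the quantile window")

    rows = []
    for c in cutoffs:
        mask = expr >= c
        if mask.all() or not mask.any():
            continue
        stat, p = logrank_test(time, event, mask)
        try:
            cox = cox_univariate(time, event, mask.astype(float))
        except ValueError:
            cox = CoxResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                            False, "unfittable", int(event.sum()))
        rows.append({
            "cutoff": float(c),
            "n_high": int(mask.sum()),
            "hr": cox.hr,
            "ci_low": cox.ci_low,
            "ci_high": cox.ci_high,
            "logrank_stat": stat,
            "logrank_p": p,
            "converged": cox.converged,
        })
    if not rows:
        raise ValueError("no valid cutoff in the quantile window")
    table = pd.DataFrame(rows)

    valid = table.loc[table["converged"] & table["logrank_p"].notna()].copy()
    if valid.empty:
        raise ValueError("no converged cutoff fit in the scan")
    valid["abs_loghr"] = np.abs(np.log(valid["hr"]))
    if config.cutpoint_rule == "min_p":
        valid = valid.sort_values(
            ["logrank_p", "abs_loghr", "cutoff"],
            ascending=[True, False, True], kind="mergesort")
    else:
        valid = valid.sort_values(
            ["abs_loghr", "logrank_p", "cutoff"],
            ascending=[False, True, True], kind="mergesort")
    chosen = float(valid.iloc[0]["cutoff"])
    return CutpointScan(
        table=table,
        chosen_cutoff=chosen,
        chosen_rule=config.cutpoint_rule,
        notes={
            "selection_bias": (
                "chosen-cutoff p is the minimum over the scanned grid and is "
                "uncorrected for cutoff multiplicity; interpret as "
                "selection-biased"
            ),
            "n_cutoffs_scanned": int(len(table)),
        },
    )
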