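"""Kaplan–Meier estimation and Cox proportional-hazards regression.

Both estimators are implemented directly (product-limit; Newton–Raphson
maximization of the partial likelihood with Efron or Breslow tie
handling) so they can be verified against brute-force oracles rather
than delegating to a single library call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxResult",
    "km_estimate",
    "km_median",
    "cox_ph",
    "compare_groups",
    "age_stratified_analysis",
    "merged_subtype_model",
]


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size at each event time
    n_events: np.ndarray  # events at each event time
    median_os: float  # NaN when S never reaches 0.5

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    ``median_os`` is the smallest event time t with S(t) ≤ 0.5 (NaN if
    the curve never drops to 0.5).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no survival records")
    if np.any(~np.isfinite(times)) or np.any(times < 0):
        raise ValueError("times must be finite and non-negative")

    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    event_times = np.unique(t[e == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    n_ev = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, et in enumerate(event_times):
        n_i = int(np.sum(t >= et))
        d_i = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv[i], at_risk[i], n_ev[i] = s, n_i, d_i
    median = float("nan")
    for et, s_val in zip(event_times, surv):
        if s_val <= 0.5 + 1e-12:
            median = float(et)
            break
    return KMCurve(event_times, surv, at_risk, n_ev, median)


def km_median(times: np.ndarray, events: np.ndarray) -> float:
    return km_estimate(times, events).median_os


@dataclass
class CoxResult:
    """Fitted Cox model: one row of statistics per covariate."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    n: int
    n_events: int
    ties: str
    loglik: float
    loglik_null: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def p(self) -> np.ndarray:
        z = np.divide(self.coef, self.se, out=np.zeros_like(self.coef), where=self.se > 0)
        return 2.0 * stats.norm.sf(np.abs(z))

    def lr_test(self) -> tuple[float, int, float]:
        """Likelihood-ratio test of the full model vs null."""
        chi2 = 2.0 * (self.loglik - self.loglik_null)
        df = len(self.covariates)
        return chi2, df, float(stats.chi2.sf(max(chi2, 0.0), df))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coef,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
                "se": self.se,
            }
        )


def _cox_ll_grad_info(
    beta: np.ndarray, x: np.ndarray, t: np.ndarray, d: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score vector and information matrix."""
    n, p = x.shape
    # sort descending by time so cumulative sums are risk-set sums
    order = np.argsort(-t, kind="mergesort")
    ts, ds, xs = t[order], d[order], x[order]
    eta = xs @ beta
    eta -= eta.max()  # stabilization; the shift cancels term-by-term
    w = np.exp(eta)
    wx = w[:, None] * xs
    wxx = wx[:, :, None] * xs[:, None, :]
    cum0 = np.cumsum(w)
    cum1 = np.cumsum(wx, axis=0)
    cum2 = np.cumsum(wxx, axis=0)

    # block structure of tied times
    new_block = np.append(False, ts[:-1] != ts[1:])
    block_id = np.cumsum(new_block)
    n_blocks = int(block_id[-1]) + 1
    ends = np.flatnonzero(np.append(ts[:-1] != ts[1:], True))
    m_per_block = np.bincount(block_id[ds == 1], minlength=n_blocks)

    dead_all = np.flatnonzero(ds == 1)
    ll = float(eta[dead_all].sum())
    grad = xs[dead_all].sum(axis=0) if dead_all.size else np.zeros(p)
    info = np.zeros((p, p))

    # vectorized path: Breslow (any multiplicity) and Efron singletons
    if ties == "breslow":
        vec_blocks = np.flatnonzero(m_per_block > 0)
        weights = m_per_block[vec_blocks].astype(float)
        loop_blocks = np.array([], dtype=int)
    else:
        vec_blocks = np.flatnonzero(m_per_block == 1)
        weights = np.ones(vec_blocks.size)
        loop_blocks = np.flatnonzero(m_per_block > 1)
    if vec_blocks.size:
        e = ends[vec_blocks]
        denom = cum0[e]
        z1 = cum1[e]
        z2 = cum2[e]
        ll -= float(weights @ np.log(denom))
        grad -= (weights / denom) @ z1
        info += np.einsum("e,eij->ij", weights / denom, z2)
        info -= np.einsum("e,ei,ej->ij", weights / denom**2, z1, z1)

    # Efron correction for tied event blocks
    for b in loop_blocks:
        end = ends[b]
        start = end - np.flatnonzero(block_id == b).size + 1
        dead = np.flatnonzero(ds[start : end + 1] == 1) + start
        m_d = dead.size
        s0, s1, s2 = cum0[end], cum1[end], cum2[end]
        s0d = w[dead].sum()
        s1d = wx[dead].sum(axis=0)
        s2d = wxx[dead].sum(axis=0)
        for ell in range(m_d):
            f = ell / m_d
            denom = s0 - f * s0d
            z1 = s1 - f * s1d
            z2 = s2 - f * s2d
            ll -= math.log(denom)
            grad -= z1 / denom
            info += z2 / denom - np.outer(z1, z1) / denom**2
    return ll, grad, info


def cox_ph(
    data: pd.DataFrame,
    duration_col: str = "os_months",
    event_col: str = "event",
    covariate_cols: list[str] | None = None,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Convergence: max |score| < ``tol`` or ``max_iter`` iterations.
    Monotone likelihood (complete separation) is flagged via an
    infinite-HR warning rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if covariate_cols is None:
        covariate_cols = [c for c in data.columns if c not in (duration_col, event_col)]
    if not covariate_cols:
        raise ValueError("no covariates specified")
    df = data[[duration_col, event_col, *covariate_cols]].dropna()
    t = df[duration_col].to_numpy(dtype=float)
    d = df[event_col].to_numpy(dtype=int)
    x = df[covariate_cols].to_numpy(dtype=float)
    n = len(df)
    if n == 0:
        raise ValueError("no complete records")
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no events observed; cannot fit Cox model")
    for j, c in enumerate(covariate_cols):
        if np.ptp(x[:, j]) == 0:
            raise ValueError(f"covariate {c!r} is constant")
    # center covariates for conditioning (does not change coef or se)
    x = x - x.mean(axis=0)

    p = x.shape[1]
    beta = np.zeros(p)
    warnings_list: list[str] = []
    ll_null, _, _ = _cox_ll_grad_info(np.zeros(p), x, t, d, ties)
    ll, grad, info = ll_null, None, None
    converged = False
    for _ in range(max_iter):
        ll, grad, info = _cox_ll_grad_info(beta, x, t, d, ties)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            warnings_list.append("singular information matrix")
            break
        # step-halving to guarantee likelihood ascent
        new_beta = beta + step
        new_ll, _, _ = _cox_ll_grad_info(new_beta, x, t, d, ties)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, _, _ = _cox_ll_grad_info(new_beta, x, t, d, ties)
            halvings += 1
        beta = new_beta
    else:
        ll, grad, info = _cox_ll_grad_info(beta, x, t, d, ties)
        if np.max(np.abs(grad)) < tol:
            converged = True

    if np.max(np.abs(beta)) > 15:
        warnings_list.append(
            "monotone likelihood suspected (|coef| > 15): hazard ratio effectively infinite"
        )
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
        warnings_list.append("variance not estimable (singular information)")
    return CoxResult(
        covariates=list(covariate_cols),
        coef=beta,
        se=se,
        n=n,
        n_events=n_events,
        ties=ties,
        loglik=float(ll),
        loglik_null=float(ll_null),
        converged=converged,
        warnings=warnings_list,
    )


def _group_summary(df: pd.DataFrame, group_col: str, duration_col: str, event_col: str) -> pd.DataFrame:
    rows = []
    for g, sub in df.groupby(group_col, sort=True):
        curve = km_estimate(sub[duration_col].to_numpy(), sub[event_col].to_numpy())
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "events": int(sub[event_col].sum()),
                "median_os": curve.median_os,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    data: pd.DataFrame,
    group_col: str,
    duration_col: str = "os_months",
    event_col: str = "event",
    ties: str = "efron",
) -> dict:
    """Group summaries plus pairwise and global Cox results.

    Returns ``{"summary": frame, "pairwise": frame, "global": CoxResult}``.
    Pairwise HRs are for the second group vs the first (alphabetical).
    The global model codes the grouping as k−1 indicators against the
    first group and reports a likelihood-ratio test.
    """
    df = data[[group_col, duration_col, event_col]].dropna()
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (df[group_col] == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    summary = _group_summary(df, group_col, duration_col, event_col)

    pair_rows = []
    for ga, gb in combinations(groups, 2):
        sub = df[df[group_col].isin([ga, gb])].copy()
        sub["_ind"] = (sub[group_col] == gb).astype(float)
        try:
            res = cox_ph(sub, duration_col, event_col, ["_ind"], ties=ties)
            pair_rows.append(
                {
                    "group_a": ga, "group_b": gb,
                    "hr": res.hr[0], "ci_low": res.ci_low[0], "ci_high": res.ci_high[0],
                    "p": res.p[0],
                }
            )
        except ValueError as exc:
            pair_rows.append(
                {"group_a": ga, "group_b": gb, "hr": float("nan"),
                 "ci_low": float("nan"), "ci_high": float("nan"), "p": float("nan"),
                 "note": str(exc)}
            )
    pairwise = pd.DataFrame(pair_rows)

    dummies = pd.get_dummies(df[group_col], prefix="g", dtype=float).iloc[:, 1:]
    glob_df = pd.concat([df[[duration_col, event_col]], dummies], axis=1)
    global_res = cox_ph(glob_df, duration_col, event_col, list(dummies.columns), ties=ties)
    return {"summary": summary, "pairwise": pairwise, "global": global_res}


def age_stratified_analysis(
    data: pd.DataFrame,
    cutoff_years: float = 45.0,
    duration_col: str = "os_months",
    event_col: str = "event",
    adjust: bool = False,
    ties: str = "efron",
) -> dict:
    """Dichotomized survival comparison at an age cut-off (≥cutoff inclusive).

    With ``adjust=True`` also fits the multivariate model with
    age<cutoff, grade II (vs III/IV) and KPS ≥90 (vs <90) indicators.
    """
    df = data.dropna(subset=["age_years", duration_col, event_col]).copy()
    if df.empty:
        raise ValueError("no records with age and survival")
    df["age_group"] = np.where(df["age_years"] >= cutoff_years, f"ge{cutoff_years:g}", f"lt{cutoff_years:g}")
    if df["age_group"].nunique() < 2:
        raise ValueError(f"all ages on one side of the {cutoff_years}-year cut-off")
    out = compare_groups(df, "age_group", duration_col, event_col, ties=ties)
    if adjust:
        mv = df.copy()
        mv["age_lt_cutoff"] = (mv["age_years"] < cutoff_years).astype(float)
        mv["grade_II"] = (mv["who_grade"] == "II").astype(float)
        mv["kps_ge_90"] = (mv["kps"] >= 90).astype(float)
        covs = [c for c in ("age_lt_cutoff", "grade_II", "kps_ge_90") if mv[c].nunique() > 1]
        out["multivariate"] = cox_ph(mv, duration_col, event_col, covs, ties=ties)
    return out


def merged_subtype_model(
    data: pd.DataFrame,
    merge: dict[str, str] | None = None,
    reference: str = "M3",
    subtype_col: str = "subtype",
    duration_col: str = "os_months",
    event_col: str = "event",
    adjust_grade: bool = False,
    ties: str = "efron",
) -> CoxResult:
    """Cox model of a merged subtype class against a reference class.

    ``merge`` maps original labels to a merged label (default
    {"M1": "M1/2", "M2": "M1/2"}); records outside merged ∪ reference are
    dropped.  With ``adjust_grade`` a WHO grade III/IV-vs-II indicator is
    added.
    """
    merge = merge if merge is not None else {"M1": "M1/2", "M2": "M1/2"}
    df = data.dropna(subset=[duration_col, event_col]).copy()
    df["_merged"] = df[subtype_col].map(lambda s: merge.get(s, s))
    merged_labels = sorted(set(merge.values()))
    if len(merged_labels) != 1:
        raise ValueError("merge map must target exactly one merged label")
    merged_label = merged_labels[0]
    df = df[df["_merged"].isin([merged_label, reference])]
    for lab in (merged_label, reference):
        if (df["_merged"] == lab).sum() == 0:
            raise ValueError(f"class {lab!r} is empty")
    df["_ind"] = (df["_merged"] == merged_label).astype(float)
    covs = ["_ind"]
    names = [f"{merged_label}_vs_{reference}"]
    if adjust_grade:
        df["_grade_hi"] = df["who_grade"].isin(["III", "IV"]).astype(float)
        covs.append("_grade_hi")
        names.append("grade_III_IV_vs_II")
    res = cox_ph(df, duration_col, event_col, covs, ties=ties)
    res.covariates = names
    return res
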