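"""Survival stratification by the piSNV ratio.

Kaplan-Meier estimation, the two-group log-rank test, the maximally
selected rank statistic for choosing an optimal ratio cutpoint, and a Cox
proportional-hazards fitter (Efron tie handling, Newton-Raphson with step
halving).  The cutpoint-selected log-rank p is exploratory: the maximum of
many correlated tests is anti-conservative, and the report labels it so
rather than correcting it.

scipy supplies the chi-square and normal distributions; lifelines is used
in the test suite as an independent cross-check, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t); 1.0 before the first event time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored subjects leave the risk set without producing a step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if ((e != 0) & (e != 1)).any():
        raise ValueError("events must be 0/1")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for et in event_times:
        n_i = int((t >= et).sum())
        d_i = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_ev.append(d_i)
    return KMCurve(event_times, np.array(surv), np.array(at_risk, dtype=int),
                   np.array(n_ev, dtype=int))


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_oe(group: np.ndarray, t: np.ndarray, e: np.ndarray
                ) -> tuple[float, float, float]:
    """(O1 - E1, V, O1) of group 1 summed over distinct event times.

    Vectorized over event times via sorted suffix sums (the cutpoint scan
    calls this once per candidate split).
    """
    order = np.argsort(t, kind="stable")
    ts, es, gs = t[order], e[order].astype(bool), group[order].astype(float)
    n = ts.size
    te, ge = ts[es], gs[es]
    times = np.unique(te)
    if times.size == 0:
        return 0.0, 0.0, 0.0
    first = np.searchsorted(ts, times, side="left")
    at_risk = n - first
    suffix_g = np.concatenate([np.cumsum(gs[::-1])[::-1], [0.0]])
    n1 = suffix_g[first]
    lo = np.searchsorted(te, times, side="left")
    hi = np.searchsorted(te, times, side="right")
    d = (hi - lo).astype(float)
    cum_ge = np.concatenate([[0.0], np.cumsum(ge)])
    d1 = cum_ge[hi] - cum_ge[lo]
    oe = float((d1 - d * n1 / at_risk).sum())
    ok = at_risk > 1
    frac = n1[ok] / at_risk[ok]
    var = float((d[ok] * frac * (1 - frac)
                 * (at_risk[ok] - d[ok]) / (at_risk[ok] - 1)).sum())
    return oe, var, float(d1.sum())


def logrank_test(group_labels: Sequence[int], times: Sequence[float],
                 events: Sequence[int]) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with df = 1."""
    g = np.asarray(group_labels)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.size}")
    g01 = (g == labels[1]).astype(int)
    oe, var, _ = _logrank_oe(g01, t, e)
    if var <= 0:
        return 0.0, 1.0
    chi2 = oe * oe / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# maximally selected rank statistic
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    """Outcome of the standardized log-rank scan over admissible cutpoints."""

    cutpoint: float
    max_standardized_statistic: float
    group_sizes: tuple[int, int]  # (n_low, n_high)
    logrank_chi2: float
    logrank_p: float
    scanned: pd.DataFrame = field(repr=False, default=None)


def optimal_cutpoint(values: Sequence[float], times: Sequence[float],
                     events: Sequence[int], minprop: float = 0.1
                     ) -> CutpointResult:
    """Cutpoint maximizing the standardized two-group log-rank statistic.

    Every distinct value v splitting the cohort into {<= v} and {> v} with
    both groups of size >= minprop * n is scanned; the selected split's own
    log-rank test is reported (exploratory: selection inflates it).
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = x.size
    if not (0 < minprop < 0.5):
        raise ValueError("minprop must be in (0, 0.5)")
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct values to scan")
    min_n = minprop * n
    rows = []
    for v in np.unique(x)[:-1]:
        high = (x > v).astype(int)
        n_high = int(high.sum())
        n_low = n - n_high
        if n_low < min_n or n_high < min_n:
            continue
        oe, var, _ = _logrank_oe(high, t, e)
        z = abs(oe) / math.sqrt(var) if var > 0 else 0.0
        rows.append((float(v), z, n_low, n_high))
    if not rows:
        raise ValueError("no cutpoint satisfies the minprop constraint")
    scanned = pd.DataFrame(rows, columns=["cutpoint", "abs_z", "n_low", "n_high"])
    best = scanned.loc[scanned["abs_z"].idxmax()]
    high = (x > best["cutpoint"]).astype(int)
    chi2, p = logrank_test(high, t, e)
    return CutpointResult(float(best["cutpoint"]), float(best["abs_z"]),
                          (int(best["n_low"]), int(best["n_high"])),
                          chi2, p, scanned)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxCovariate:
    name: str
    coef: float
    hazard_ratio: float
    se: float
    ci95: tuple[float, float]
    p_value: float


@dataclass
class CoxResult:
    """Fit of the Cox partial likelihood; ``flagged`` marks failed fits."""

    covariates: list[CoxCovariate]
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    flagged: bool = False
    message: str = ""

    def __getitem__(self, name: str) -> CoxCovariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.name, c.coef, c.hazard_ratio, c.se, c.ci95[0], c.ci95[1],
              c.p_value) for c in self.covariates],
            columns=["covariate", "coef", "hazard_ratio", "se",
                     "ci95_low", "ci95_high", "p_value"])


def _efron_loglik(beta: np.ndarray, X: np.ndarray, t: np.ndarray,
                  e: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron-tied log partial likelihood with gradient and Hessian.

    Single pass from the largest time down, accumulating the risk-set sums
    S0 = sum w, S1 = sum w x, S2 = sum w x x^T incrementally.
    """
    n, p = X.shape
    order = np.argsort(t, kind="stable")
    ts, es, Xs = t[order], e[order], X[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # numeric guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    wX = w[:, None] * Xs
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        ti = ts[i]
        j = i
        while j >= 0 and ts[j] == ti:
            S0 += w[j]
            S1 += wX[j]
            S2 += np.outer(wX[j], Xs[j])
            j -= 1
        dead = np.nonzero(es[j + 1 : i + 1] == 1)[0] + (j + 1)
        d = dead.size
        if d:
            s0d = float(w[dead].sum())
            s1d = wX[dead].sum(axis=0)
            s2d = wX[dead].T @ Xs[dead]
            ll += float(eta[dead].sum())
            grad += Xs[dead].sum(axis=0)
            for l in range(d):
                f = l / d
                s0 = S0 - f * s0d
                s1 = S1 - f * s1d
                s2 = S2 - f * s2d
                ll -= math.log(s0)
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / (s0 * s0)
        i = j
    return ll, grad, hess


def cox_fit(covariates: pd.DataFrame | np.ndarray, times: Sequence[float],
            events: Sequence[int], max_iter: int = 50,
            tol: float = 1e-8) -> CoxResult:
    """Maximize the Cox partial likelihood (Efron ties) by Newton-Raphson.

    Iterates until the gradient norm falls below ``tol``; step halving keeps
    the likelihood non-decreasing.  Non-convergence or a coefficient running
    away (monotone likelihood / perfect separation) yields a flagged result.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more subjects than covariates")
    if any(np.ptp(X[:, j]) == 0 for j in range(p)):
        raise ValueError("constant covariate in the design")

    beta = np.zeros(p)
    ll, grad, hess = _efron_loglik(beta, X, t, e)
    converged = False
    it = 0
    message = ""
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _efron_loglik(cand, X, t, e)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(beta).max() > 20:
            # a log hazard ratio beyond +-20 is numerically a divergence
            message = "monotone likelihood (perfect separation?)"
            break
        if np.linalg.norm(grad) < tol:
            converged = True
            break
    flagged = not converged or np.abs(beta).max() > 20

    if flagged:
        covs = [CoxCovariate(name, math.nan, math.nan, math.nan,
                             (math.nan, math.nan), math.nan)
                for name in names]
        return CoxResult(covs, float(ll), n, int(e.sum()), False, it,
                         flagged=True,
                         message=message or f"no convergence in {max_iter} iterations")

    cov_mat = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov_mat))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    zc = sps.norm.ppf(0.975)
    covs = [
        CoxCovariate(name, float(b), float(math.exp(b)), float(s),
                     (float(math.exp(b - zc * s)), float(math.exp(b + zc * s))),
                     float(pv))
        for name, b, s, pv in zip(names, beta, se, pvals)
    ]
    return CoxResult(covs, float(ll), n, int(e.sum()), True, it)


# ---------------------------------------------------------------------------
# clinical design matrix
# ---------------------------------------------------------------------------

def clinical_design(clinical: pd.DataFrame, ratios: Mapping[str, float],
                    cutpoint: float | None = None,
                    continuous: bool = False,
                    stage_ordinal: bool = False) -> pd.DataFrame:
    """Cox design matrix: ratio term plus age, sex and TNM stage.

    The ratio enters as a high/low indicator at ``cutpoint`` (default: its
    median) unless ``continuous``.  Sex and stage are dummy coded; stage
    can instead enter as an ordinal score 1-4.  Indexed by sample id.
    """
    df = clinical.set_index("sample_id")
    r = pd.Series({s: ratios[s] for s in df.index if s in ratios}, dtype=float)
    df = df.loc[r.index]
    if continuous:
        ratio_col = r
        ratio_name = "ratio"
    else:
        cut = float(np.median(r)) if cutpoint is None else cutpoint
        ratio_col = (r > cut).astype(float)
        ratio_name = "high_ratio"
    design = pd.DataFrame({ratio_name: ratio_col, "age": df["age"].astype(float)})
    design["sex_male"] = (df["sex"].astype(str).str.lower() == "male").astype(float)
    stages = ["I", "II", "III", "IV"]
    if stage_ordinal:
        design["stage"] = df["stage"].map({s: i + 1 for i, s in enumerate(stages)})
    else:
        for s in stages[1:]:
            design[f"stage_{s}"] = (df["stage"] == s).astype(float)
    return design
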