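"""Survival validation: Kaplan-Meier/log-rank, Cox models, optimal
cutpoints, tertiles, and cluster-versus-parameter comparisons.

Progression-free survival is time from diagnosis to relapse, progression
or any-cause death, right-censored at last follow-up.  Cox models are fit
by partial likelihood (lifelines, Efron tie handling) with Wald confidence
intervals; in multivariate mode at most one imaging-derived variable
(unsupervised cluster, supervised cluster, or MTV group) may enter a model,
because the three are near-collinear readouts of the same burden.  MTV
strata come from a maximally selected log-rank cutpoint search; age-style
covariates from tertiles.  Two-sided alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxFit", "CutpointResult", "KMResult",
    "fit_km_logrank", "fit_cox", "find_cutpoints", "tertile_bins",
    "cluster_param_stats", "univariate_cox_coefficients",
    "IMAGING_VARIABLES", "categorize_by_cutpoints",
]

IMAGING_VARIABLES = frozenset({"unsupervised_cluster", "supervised_cluster", "mtv_group"})


# --------------------------------------------------------------------------
# Fast univariate Cox across many features
# --------------------------------------------------------------------------

def univariate_cox_coefficients(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_iter: int = 6,
    max_abs: float = 20.0,
    return_se: bool = False,
):
    """Univariate Cox log-hazard coefficient for every column of ``X``.

    Newton-Raphson on the Breslow partial likelihood, vectorized across
    features so thousands of univariate fits cost a handful of array
    passes.  Constant columns get coefficient 0.  Estimates are clipped to
    ``max_abs`` (separation guard).  With ``return_se=True`` also returns
    the Wald standard error ``1/sqrt(I(beta_hat))`` per feature.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if event.sum() == 0:
        raise ValueError("no observed events; coefficients undefined")

    # descending time order makes risk sets prefix sums
    order = np.argsort(-time, kind="stable")
    t_s, e_s, X_s = time[order], event[order], X[order]
    # risk set at a death time t includes all with time >= t; with ties we
    # need the cumulative sum taken at the *last* subject sharing that time
    _, inv, counts = np.unique(-t_s, return_inverse=True, return_counts=True)
    last_idx = np.cumsum(counts) - 1          # per unique time, last position
    group_end = last_idx[inv]                 # per subject, last position of its tie group

    beta = np.zeros(p)
    const = X_s.std(axis=0) == 0
    ev = e_s[:, None]
    I = np.ones(p)
    for _ in range(n_iter):
        eta = np.clip(X_s * beta, -500, 500)
        w = np.exp(eta)
        S0 = np.cumsum(w, axis=0)[group_end]
        S1 = np.cumsum(w * X_s, axis=0)[group_end]
        S2 = np.cumsum(w * X_s * X_s, axis=0)[group_end]
        mu = S1 / S0
        U = (ev * (X_s - mu)).sum(axis=0)
        I = (ev * (S2 / S0 - mu * mu)).sum(axis=0)
        step = np.where(I > 1e-12, U / np.maximum(I, 1e-12), 0.0)
        beta = np.clip(beta + step, -max_abs, max_abs)
    beta[const] = 0.0
    if return_se:
        se = np.where(I > 1e-12, 1.0 / np.sqrt(np.maximum(I, 1e-12)), np.inf)
        se[const] = np.inf
        return beta, se
    return beta


# --------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# --------------------------------------------------------------------------

@dataclass
class KMResult:
    """Per-group KM curves with overall and pairwise log-rank tests."""

    curves: dict[str, pd.DataFrame]        # group -> columns: timeline, survival
    overall_statistic: float
    overall_p: float
    pairwise: pd.DataFrame                 # columns: group_a, group_b, statistic, p
    group_sizes: dict[str, int]


def fit_km_logrank(groups, time, event) -> KMResult:
    """Kaplan-Meier estimate per group plus overall and pairwise log-rank.

    Curves start at survival 1 and are nonincreasing right-continuous step
    functions.  Requires at least two nonempty groups.
    """
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError(f"need >= 2 groups for a log-rank comparison, got {labels}")
    curves, sizes = {}, {}
    for g in labels:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=str(g))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["timeline", "survival"]
        curves[str(g)] = sf
        sizes[str(g)] = int(sel.sum())
    overall = multivariate_logrank_test(time, groups, event)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sa, sb = groups == a, groups == b
            res = logrank_test(time[sa], time[sb], event[sa], event[sb])
            rows.append((str(a), str(b), float(res.test_statistic), float(res.p_value)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    return KMResult(
        curves=curves,
        overall_statistic=float(overall.test_statistic),
        overall_p=float(overall.p_value),
        pairwise=pairwise,
        group_sizes=sizes,
    )


# --------------------------------------------------------------------------
# Cox regression
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Tidy Cox model summary.

    ``summary`` has one row per non-reference level/term with columns
    variable, category, hr, ci_low, ci_high, p.  Reference levels of
    categorical variables are listed in ``references``.
    """

    summary: pd.DataFrame
    mode: str
    references: dict[str, str] = field(default_factory=dict)
    log_likelihood: float = np.nan


def _design(df: pd.DataFrame, covariates: list[str], references: dict[str, str]):
    """Dummy-encode categoricals against declared/first reference levels."""
    cols, meta, refs = [], [], {}
    for var in covariates:
        s = df[var]
        if s.nunique(dropna=False) < 2:
            raise ValueError(f"covariate {var!r} is constant")
        if s.dtype == bool:
            cols.append(s.astype(float).rename(var))
            meta.append((var, "yes"))
            refs[var] = "no"
        elif s.dtype.kind in "ifu":
            cols.append(s.astype(float).rename(var))
            meta.append((var, ""))
        else:
            levels = sorted(s.astype(str).unique().tolist())
            ref = references.get(var, levels[0])
            if ref not in levels:
                raise ValueError(f"reference {ref!r} not a level of {var!r}")
            refs[var] = ref
            for lv in levels:
                if lv == ref:
                    continue
                name = f"{var}[{lv}]"
                cols.append((s.astype(str) == lv).astype(float).rename(name))
                meta.append((var, lv))
    return pd.concat(cols, axis=1), meta, refs


def fit_cox(
    df: pd.DataFrame,
    covariates: list[str] | str,
    duration_col: str = "pfs_days",
    event_col: str = "event",
    mode: str = "univariate",
    references: dict[str, str] | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit(s) with Wald 95% CIs.

    ``mode='univariate'`` fits one single-covariate model per entry of
    ``covariates`` and stacks the summaries; ``mode='multivariate'`` fits
    one joint model and refuses more than one imaging-derived variable
    (unsupervised cluster / supervised cluster / MTV group), which are
    mutually collinear burden readouts.
    """
    if isinstance(covariates, str):
        covariates = [covariates]
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    references = references or {}
    if mode == "multivariate":
        imaging = sorted(set(covariates) & IMAGING_VARIABLES)
        if len(imaging) > 1:
            raise ValueError(
                f"multivariate model may include at most one of {sorted(IMAGING_VARIABLES)} "
                f"(got {imaging}): these are collinear burden measures"
            )
        groups = [covariates]
    else:
        groups = [[v] for v in covariates]

    if not np.asarray(df[event_col], dtype=bool).any():
        raise ValueError("no observed events")

    rows, refs_all, ll = [], {}, np.nan
    for group in groups:
        X, meta, refs = _design(df, group, references)
        refs_all.update(refs)
        data = X.copy()
        data[duration_col] = df[duration_col].to_numpy(dtype=float)
        data[event_col] = df[event_col].to_numpy(dtype=bool)
        cph = CoxPHFitter()
        cph.fit(data, duration_col=duration_col, event_col=event_col)
        ll = float(cph.log_likelihood_)
        summ = cph.summary
        for col, (var, cat) in zip(X.columns, meta):
            r = summ.loc[col]
            rows.append(
                (var, cat, float(np.exp(r["coef"])),
                 float(np.exp(r["coef lower 95%"])), float(np.exp(r["coef upper 95%"])),
                 float(r["p"]))
            )
    summary = pd.DataFrame(rows, columns=["variable", "category", "hr", "ci_low", "ci_high", "p"])
    return CoxFit(summary=summary, mode=mode, references=refs_all, log_likelihood=ll)


# --------------------------------------------------------------------------
# Maximally selected log-rank cutpoints
# --------------------------------------------------------------------------

@dataclass
class CutpointResult:
    """Cutpoints splitting a marker into low / moderate / high strata."""

    cutpoints: tuple[float, ...]
    statistic: float                    # |standardized log-rank| at the primary cut
    trace: pd.DataFrame                 # columns: candidate, statistic (primary search)
    strategy: str

    @property
    def labels(self):
        return ("low", "moderate", "high") if len(self.cutpoints) == 2 else ("low", "high")


def _logrank_z(is_high: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Standardized two-group log-rank statistic U / sqrt(V).

    Direct implementation over the distinct event times (hypergeometric
    mean/variance per time); sign is positive when the high group has more
    events than expected.
    """
    t_evt = np.unique(time[event])
    U = 0.0
    V = 0.0
    for t in t_evt:
        at_risk = time >= t
        n_tot = at_risk.sum()
        n_high = (at_risk & is_high).sum()
        d_tot = (event & (time == t)).sum()
        d_high = (event & (time == t) & is_high).sum()
        U += d_high - d_tot * n_high / n_tot
        if n_tot > 1:
            V += (d_tot * (n_high / n_tot) * (1 - n_high / n_tot)
                  * (n_tot - d_tot) / (n_tot - 1))
    return U / np.sqrt(V) if V > 0 else 0.0


def _best_single_cut(values, time, event, min_prop):
    n = len(values)
    uniq = np.unique(values)
    if len(uniq) < 2:
        return None, pd.DataFrame(columns=["candidate", "statistic"])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    min_n = max(1, int(np.ceil(min_prop * n)))
    rows = []
    for c in candidates:
        high = values > c
        if high.sum() < min_n or (~high).sum() < min_n:
            continue
        rows.append((float(c), abs(_logrank_z(high, time, event))))
    trace = pd.DataFrame(rows, columns=["candidate", "statistic"])
    if trace.empty:
        return None, trace
    best = trace.loc[trace["statistic"].idxmax()]
    return float(best["candidate"]), trace


def find_cutpoints(
    values,
    time,
    event,
    min_prop: float = 0.1,
    n_cuts: int = 2,
    strategy: str = "sequential",
) -> CutpointResult:
    """Cutpoint(s) maximizing the standardized log-rank statistic.

    The primary cut maximizes |U/sqrt(V)| over midpoints between adjacent
    distinct marker values, subject to each side holding at least
    ``min_prop`` of the cohort.  With ``n_cuts=2`` and
    ``strategy='sequential'`` the larger stratum is then split by the same
    search (min_prop relative to the stratum); ``strategy='joint'``
    exhaustively scores all cut pairs by the three-group log-rank
    chi-square.  Cutpoints are returned ascending.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(values) < 10:
        raise ValueError("need >= 10 subjects for a cutpoint search")
    if np.unique(values).size < 2:
        raise ValueError("marker values are constant; no cutpoint exists")
    if not 0 < min_prop < 0.5:
        raise ValueError("min_prop must lie in (0, 0.5)")
    if n_cuts not in (1, 2):
        raise ValueError("n_cuts must be 1 or 2")
    if strategy not in ("sequential", "joint"):
        raise ValueError(f"unknown strategy {strategy!r}")

    primary, trace = _best_single_cut(values, time, event, min_prop)
    if primary is None:
        raise ValueError("no candidate cut respects the min_prop constraint")
    stat = float(trace["statistic"].max())
    if n_cuts == 1:
        return CutpointResult((primary,), stat, trace, strategy)

    if strategy == "sequential":
        high = values > primary
        larger = high if high.sum() >= (~high).sum() else ~high
        sub = np.flatnonzero(larger)
        secondary, _ = _best_single_cut(values[sub], time[sub], event[sub], min_prop)
        if secondary is None:
            cuts = (primary,)
        else:
            cuts = tuple(sorted((primary, secondary)))
        return CutpointResult(cuts, stat, trace, strategy)

    # joint: exhaustive pairs scored by 3-group log-rank chi-square
    uniq = np.unique(values)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    min_n = max(1, int(np.ceil(min_prop * len(values))))
    best_pair, best_chi2 = None, -np.inf
    for i, c1 in enumerate(candidates):
        for c2 in candidates[i + 1:]:
            g = np.digitize(values, [c1, c2])
            if np.bincount(g, minlength=3).min() < min_n:
                continue
            res = multivariate_logrank_test(time, g, event)
            if res.test_statistic > best_chi2:
                best_chi2, best_pair = float(res.test_statistic), (float(c1), float(c2))
    if best_pair is None:
        raise ValueError("no cut pair respects the min_prop constraint")
    return CutpointResult(best_pair, best_chi2, trace, strategy)


def categorize_by_cutpoints(values, cutpoints) -> np.ndarray:
    """Label marker values low / moderate / high (or low / high) by cuts."""
    values = np.asarray(values, dtype=float)
    cuts = sorted(cutpoints)
    names = ["low", "moderate", "high"] if len(cuts) == 2 else ["low", "high"]
    idx = np.digitize(values, cuts)
    return np.asarray(names, dtype=object)[idx]


def tertile_bins(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Split values at the 33.3rd / 66.7th percentiles into low/mid/high.

    Group rule: low is ``v < c1``, mid is ``c1 <= v < c2``, high is
    ``v >= c2`` (the convention of age strata like "<58, 58-67, 67<=").
    With heavy ties the groups follow the percentile rule and may be
    unequal.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need >= 3 subjects for tertiles")
    if np.unique(values).size < 3:
        raise ValueError("need >= 3 distinct values for tertiles")
    c1, c2 = np.percentile(values, [100.0 / 3.0, 200.0 / 3.0])
    labels = np.where(values < c1, "low", np.where(values < c2, "mid", "high"))
    return labels.astype(object), (float(c1), float(c2))


# --------------------------------------------------------------------------
# Cluster vs conventional-parameter comparisons
# --------------------------------------------------------------------------

def cluster_param_stats(
    params: pd.DataFrame,
    labels,
    log_transform: bool = True,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Kruskal-Wallis per parameter across cluster groups, plus pairwise
    Mann-Whitney tests with Benjamini-Hochberg correction.

    ``log_transform`` applies log1p first (MTV/TLG may be exactly 0); the
    Kruskal-Wallis test is rank-based, so this changes nothing about H and
    p but matches how the distributions are usually displayed.
    """
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if (labels == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")
    out = {}
    for col in params.columns:
        x = params[col].to_numpy(dtype=float)
        if log_transform:
            x = np.log1p(x)
        samples = [x[labels == g] for g in groups]
        try:
            H, p = stats.kruskal(*samples)
        except ValueError:
            H, p = 0.0, 1.0
        if not np.isfinite(H):  # all values identical: no rank variation
            H, p = 0.0, 1.0
        pair_rows = []
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                xa, xb = x[labels == a], x[labels == b]
                if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
                    u, pp = np.nan, 1.0
                else:
                    u, pp = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                pair_rows.append((str(a), str(b), float(u), float(pp)))
        pairs = pd.DataFrame(pair_rows, columns=["group_a", "group_b", "u", "p"])
        # Benjamini-Hochberg within each parameter's set of pairwise tests
        pairs["p_adj"] = multipletests(pairs["p"].to_numpy(), method="fdr_bh")[1]
        out[col] = {
            "H": float(H),
            "p": float(p),
            "significant": bool(p < alpha),
            "pairwise": pairs,
        }
    return out
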