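"""Cohort statistics for mutation prediction and survival.

Implements the analysis toolkit used on the nodule/parenchyma features:
exact and asymptotic contingency tests, rank tests, logistic regression with
classical stepwise selection (score-test entry, Wald-test stay), odds-ratio
rescaling, ROC analysis with a sensitivity-targeted cutoff, Pearson
correlation, a single CART-style recursive-partition split, and Kaplan-Meier
/ Cox (Breslow ties) survival.  p-values are two-sided throughout and no
multiplicity adjustment is applied.

Exact tests are implemented by enumeration so they can be validated against
brute-force oracles: Fisher's test enumerates all r x c tables with the
observed margins, and the rank-sum test enumerates all group assignments
when the pooled sample is small.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "LogisticFit",
    "ROCResult",
    "fisher_exact",
    "chi_square_test",
    "wilcoxon_rank_sum",
    "fit_logistic",
    "stepwise_select",
    "rescale_odds_ratio",
    "roc_curve",
    "threshold_at_sensitivity",
    "pearson_correlation",
    "recursive_partition_split",
    "km_estimator",
    "cox_lrt",
    "table_percentages",
]


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table needs non-negative integer counts")
    return np.round(arr).astype(int)


ContingencyTable = "pd.DataFrame | np.ndarray"  # counts with row/column labels


def _log_table_prob(cells: np.ndarray, row_tot: np.ndarray, col_tot: np.ndarray) -> float:
    n = row_tot.sum()
    return float(
        gammaln(row_tot + 1).sum() + gammaln(col_tot + 1).sum()
        - gammaln(n + 1) - gammaln(cells + 1).sum()
    )


def _enumerate_tables(row_tot, col_tot):
    """Yield every non-negative integer table with the given margins."""
    r = len(row_tot)

    def rows(remaining_cols, i):
        if i == r - 1:
            yield [tuple(remaining_cols)]
            return
        for row in _compositions(row_tot[i], remaining_cols):
            rest = remaining_cols - np.array(row)
            for tail in rows(rest, i + 1):
                yield [row] + tail

    yield from rows(np.array(col_tot, dtype=int), 0)


def _compositions(total, caps):
    """All ways to write ``total`` as a sum over cells with per-cell caps."""
    caps = list(caps)
    if len(caps) == 1:
        if 0 <= total <= caps[0]:
            yield (int(total),)
        return
    head_max = min(total, caps[0])
    head_min = max(0, total - sum(caps[1:]))
    for h in range(head_min, head_max + 1):
        for tail in _compositions(total - h, caps[1:]):
            yield (h,) + tail


def fisher_exact(table, enumeration_budget: int = 2_000_000) -> float:
    """Two-sided Fisher exact p for an r x c table by full enumeration.

    All tables sharing the observed margins are enumerated; the p-value is
    the total probability (multivariate hypergeometric) of tables no more
    probable than the observed one — the probability-ordering convention.

    Raises
    ------
    ValueError
        When the enumeration budget would be exceeded; use
        :func:`chi_square_test` for large tables.
    """
    obs = _as_table(table)
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    # quick upper bound on the number of tables: product of per-free-cell ranges
    bound = 1
    for i in range(obs.shape[0] - 1):
        for j in range(obs.shape[1] - 1):
            bound *= min(row_tot[i], col_tot[j]) + 1
            if bound > enumeration_budget:
                raise ValueError(
                    "table too large for exact enumeration; use chi_square_test"
                )
    logp_obs = _log_table_prob(obs, row_tot, col_tot)
    tol = 1e-7 * abs(logp_obs)  # tie tolerance, as in standard implementations
    total = 0.0
    for rows in _enumerate_tables(row_tot, col_tot):
        cells = np.array(rows, dtype=int)
        lp = _log_table_prob(cells, row_tot, col_tot)
        if lp <= logp_obs + max(tol, 1e-10):
            total += np.exp(lp)
    return float(min(total, 1.0))


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square statistic and p for an r x c table (no continuity
    correction); raises on a zero expected cell."""
    obs = _as_table(table)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected cell count")
    stat, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def wilcoxon_rank_sum(x, y, exact_limit: int = 12) -> float:
    """Two-sided rank-sum p with midranks for ties.

    Exact by enumeration of all group assignments when the pooled sample has
    at most ``exact_limit`` observations; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    if n + m <= exact_limit:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)  # midranks
        w_obs = ranks[:n].sum()
        mu = ranks.sum() * n / (n + m)
        dev = abs(w_obs - mu)
        count = 0
        total = 0
        for comb in itertools.combinations(range(n + m), n):
            total += 1
            if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-12:
                count += 1
        return count / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass
class LogisticFit:
    """A fitted logistic model: names, log-odds coefficients, Wald inference."""

    variables: list[str]
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    llf: float
    converged: bool
    separation: bool = False
    selection_trace: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return self.params[name]

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        z = sps.norm.ppf(0.5 + level / 2)
        b, se = self.params[name], self.bse[name]
        return (b - z * se, b + z * se)


def _design(X, names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def fit_logistic(design, y, names=None) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS via statsmodels).

    An intercept is always included.  Complete or quasi-complete separation
    is detected (perfect prediction or exploding coefficients) and flagged
    rather than raised.

    Raises
    ------
    ValueError
        If the outcome is constant or there are more parameters than
        observations.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    X, names = _design(design, names)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; no information to fit")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    exog = sm.add_constant(X, has_constant="add")
    cols = ["Intercept"] + names
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        except Exception:
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, exog).fit(disp=0, maxiter=50, method="bfgs")
    if np.abs(res.params).max() > 50:
        separation = True
    return LogisticFit(
        variables=names,
        params=dict(zip(cols, map(float, res.params))),
        bse=dict(zip(cols, map(float, res.bse))),
        pvalues=dict(zip(cols, map(float, res.pvalues))),
        llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)) and not separation,
        separation=separation,
    )


def _score_test_p(Xcur: np.ndarray, y: np.ndarray, p_hat: np.ndarray,
                  x_new: np.ndarray) -> float:
    """Rao score test for adding one column to a fitted logistic model."""
    w = p_hat * (1.0 - p_hat)
    U = float(x_new @ (y - p_hat))
    XtW = Xcur.T * w
    A = XtW @ Xcur
    b = XtW @ x_new
    try:
        v = float(x_new @ (w * x_new) - b @ np.linalg.solve(A, b))
    except np.linalg.LinAlgError:
        return 1.0
    if v <= 1e-12:
        return 1.0
    return float(sps.chi2.sf(U * U / v, df=1))


def stepwise_select(
    candidates: pd.DataFrame,
    y,
    entry_p: float = 0.05,
    stay_p: float = 0.05,
    max_steps: int = 100,
) -> LogisticFit:
    """Classical stepwise logistic selection.

    Repeatedly adds the candidate with the smallest score-test p-value below
    ``entry_p``, then drops any included variable whose Wald p-value exceeds
    ``stay_p``.  Collinear candidates (score-test variance ~ 0 given the
    current model) never enter.  A visited-set guard prevents add/drop
    cycles.  An empty selection returns the intercept-only fit.  The
    selection history is recorded on ``selection_trace``.
    """
    if not isinstance(candidates, pd.DataFrame):
        raise TypeError("candidates must be a named-column DataFrame")
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    y = np.asarray(y, dtype=float)
    Xall = candidates.to_numpy(dtype=float)
    names = list(candidates.columns)
    included: list[str] = []
    trace: list[str] = []
    seen: set[frozenset] = {frozenset()}

    def fit_current() -> LogisticFit:
        if included:
            return fit_logistic(candidates[included], y)
        # intercept-only
        p = y.mean()
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))) if 0 < p < 1 else 0.0
        return LogisticFit(["__none__"], {"Intercept": float(np.log(p / (1 - p)))}
                           if 0 < p < 1 else {"Intercept": np.nan},
                           {}, {}, llf, True)

    for _ in range(max_steps):
        changed = False
        # forward: score test for each excluded candidate
        cur_fit = fit_current()
        Xcur = np.column_stack([np.ones_like(y)] +
                               [Xall[:, names.index(v)] for v in included])
        eta = Xcur @ np.array([cur_fit.params.get("Intercept", 0.0)] +
                              [cur_fit.params[v] for v in included])
        p_hat = 1.0 / (1.0 + np.exp(-eta))
        best_name, best_p = None, np.inf
        for name in names:
            if name in included:
                continue
            pv = _score_test_p(Xcur, y, p_hat, Xall[:, names.index(name)])
            if pv < best_p:
                best_name, best_p = name, pv
        if best_name is not None and best_p < entry_p:
            cand_set = frozenset(included + [best_name])
            if cand_set not in seen:
                included.append(best_name)
                seen.add(cand_set)
                trace.append(f"add {best_name} (score p={best_p:.3g})")
                changed = True
        # backward: worst Wald p among included
        if included:
            fit = fit_logistic(candidates[included], y)
            worst = max(included, key=lambda v: fit.pvalues[v])
            if fit.pvalues[worst] > stay_p:
                new_set = frozenset(v for v in included if v != worst)
                if new_set not in seen:
                    seen.add(new_set)
                included.remove(worst)
                trace.append(f"drop {worst} (Wald p={fit.pvalues[worst]:.3g})")
                changed = True
        if not changed:
            break

    final = fit_logistic(candidates[included], y) if included else fit_current()
    if not included:
        final.variables = []
    final.selection_trace = trace
    return final


def rescale_odds_ratio(beta_per_unit: float, delta_units: float) -> float:
    """Odds ratio for a ``delta_units`` change: exp(beta * delta).

    A negative delta expresses e.g. "per 10-point decrease".
    """
    if not np.isfinite(beta_per_unit):
        raise ValueError("beta must be finite")
    return float(np.exp(beta_per_unit * delta_units))


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str  # "higher" or "lower" scores indicate the positive class


def roc_curve(scores, labels, direction: str = "higher") -> ROCResult:
    """ROC over all distinct score thresholds; trapezoidal AUC.

    The AUC equals the pairwise concordance probability with ties counted
    half.  ``direction="higher"`` means larger scores indicate the positive
    class; a case is called positive at threshold t when its (oriented)
    score is >= t.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    s = scores if direction == "higher" else -scores
    thr_oriented = np.unique(s)[::-1]  # strictest first
    sens, spec = [], []
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    for t in thr_oriented:
        called = s >= t
        sens.append((called & labels).sum() / n_pos)
        spec.append((~called & ~labels).sum() / n_neg)
    sens = np.array(sens)
    spec = np.array(spec)
    fpr = np.concatenate([[0.0], 1.0 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = thr_oriented if direction == "higher" else -thr_oriented
    return ROCResult(thresholds, sens, spec, auc, direction)


def threshold_at_sensitivity(roc: ROCResult, target: float = 0.80):
    """The cutoff achieving sensitivity >= target with maximal specificity.

    Among thresholds meeting the sensitivity floor the most specific is
    chosen; exact ties in (sensitivity, specificity) go to the less extreme
    threshold, i.e. the least strict cut that yields the same classification.
    Returns ``(threshold, sensitivity, specificity)``.
    """
    ok = roc.sensitivity >= target
    if not ok.any():  # cannot happen for target <= 1 with the full scan
        raise ValueError("sensitivity target unreachable")
    idx = np.flatnonzero(ok)
    best_spec = roc.specificity[idx].max()
    tied = idx[roc.specificity[idx] == best_spec]
    # ties share sens/spec; thresholds are sorted strictest-first, so the
    # last tied index is the least strict (least extreme) cut
    tied = tied[roc.sensitivity[tied] == roc.sensitivity[tied].max()]
    i = int(tied[-1])
    return float(roc.thresholds[i]), float(roc.sensitivity[i]), float(roc.specificity[i])


def pearson_correlation(x, y) -> float:
    """Sample Pearson r; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("need two same-length samples with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    return float(sps.pearsonr(x, y).statistic)


def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = y.mean()
    return 2.0 * p * (1.0 - p)


def recursive_partition_split(features: pd.DataFrame, y):
    """The single best CART-style split by exhaustive Gini search.

    Every feature and every midpoint of its sorted distinct values is
    scored by the weighted Gini impurity of the induced partition; returns
    ``(feature_name, cutpoint, impurity)``.  Ties keep the earlier feature
    column and the lower cutpoint.
    """
    if not isinstance(features, pd.DataFrame):
        raise TypeError("features must be a named-column DataFrame")
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if y.min() == y.max():
        raise ValueError("single-class outcome cannot be split")
    best = (None, np.nan, np.inf)
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        vals = np.unique(x)
        for cut in (vals[:-1] + vals[1:]) / 2.0:
            left = y[x <= cut]
            right = y[x > cut]
            imp = (left.size * _gini(left) + right.size * _gini(right)) / y.size
            if imp < best[2] - 1e-12:
                best = (name, float(cut), float(imp))
    if best[0] is None:
        # no feature varies; report the first with no split possible
        raise ValueError("no splittable feature (all features constant)")
    return best


def km_estimator(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a DataFrame with columns ``time`` and ``survival`` (the step
    function evaluated at the distinct event/censoring times).
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def cox_partial_loglik(beta, times, events, X) -> float:
    """Breslow partial log-likelihood for a p-column design matrix."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    ll = 0.0
    for t in np.unique(times[events]):
        d = events & (times == t)
        risk = times >= t
        ll += eta[d].sum() - d.sum() * np.log(np.exp(eta[risk]).sum())
    return float(ll)


def cox_lrt(times, events, covariate) -> dict:
    """Cox proportional-hazards fit (Breslow ties) with a likelihood-ratio test.

    Newton-Raphson on the Breslow partial likelihood; returns a dict with
    ``beta`` (array), ``hazard_ratio`` (of the first covariate), ``loglik``,
    ``loglik_null``, ``lrt_stat`` and ``p_value`` (chi-square, df = number of
    covariates).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    X = np.asarray(covariate, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not events.any():
        raise ValueError("need at least one event")
    if any(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
        raise ValueError("constant covariate")
    X = X - X.mean(axis=0)  # centring stabilises the exponentials
    p = X.shape[1]
    beta = np.zeros(p)
    ll0 = cox_partial_loglik(beta, times, events, X)
    ll = ll0
    for _ in range(50):
        grad = np.zeros(p)
        info = np.zeros((p, p))
        eta = X @ beta
        w = np.exp(eta)
        for t in np.unique(times[events]):
            d = events & (times == t)
            risk = times >= t
            wr = w[risk]
            xr = X[risk]
            s0 = wr.sum()
            s1 = wr @ xr
            s2 = xr.T @ (wr[:, None] * xr)
            nb = d.sum()
            grad += X[d].sum(axis=0) - nb * s1 / s0
            info += nb * (s2 / s0 - np.outer(s1, s1) / s0**2)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        new = beta + step
        ll_new = cox_partial_loglik(new, times, events, X)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new = beta + step
            ll_new = cox_partial_loglik(new, times, events, X)
            halvings += 1
        beta, ll = new, ll_new
        if np.abs(step).max() < 1e-10:
            break
    lrt = 2.0 * (ll - ll0)
    return {
        "beta": beta,
        "hazard_ratio": float(np.exp(beta[0])),
        "loglik": float(ll),
        "loglik_null": float(ll0),
        "lrt_stat": float(max(lrt, 0.0)),
        "p_value": float(sps.chi2.sf(max(lrt, 0.0), df=p)),
    }


def table_percentages(table, decimals: int | None = None):
    """Column-wise percentages of a contingency table (100 * count / column
    total), optionally rounded to the printed precision."""
    if isinstance(table, pd.DataFrame):
        counts = table.to_numpy(dtype=float)
        out_frame = True
    else:
        counts = np.asarray(table, dtype=float)
        out_frame = False
    col_tot = counts.sum(axis=0)
    if (col_tot <= 0).any():
        raise ValueError("zero column total")
    pct = 100.0 * counts / col_tot
    if decimals is not None:
        pct = np.round(pct, decimals)
    if out_frame:
        return pd.DataFrame(pct, index=table.index, columns=table.columns)
    return pct
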