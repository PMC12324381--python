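"""Group statistics and logistic feature selection for pattern cohorts.

The analysis stack mirrors how a phenotype screen interrogates the
feature table: a Kruskal–Wallis test asks whether a feature differs
anywhere across groups; pairwise Mann–Whitney U tests compare each
mutant group with its paired control; nested logistic-regression models
(control = 0, mutant = 1) compared by likelihood-ratio tests identify
which feature combination carries the discriminative signal, with a
multiple-regression fit giving per-feature Wald p-values.

All tests are two-sided and reported at α = 0.05 by default; raw
p-values are reported per feature and mutant (Benjamini–Hochberg
adjustment is available but off by default). Tissues are treated as
independent patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

__all__ = [
    "Cohort",
    "RegressionResult",
    "LRTResult",
    "FeatureSelectionReport",
    "kruskal_wallis",
    "mann_whitney_u",
    "IRLSLogisticRegression",
    "fit_logistic",
    "likelihood_ratio_test",
    "feature_selection_report",
    "LRT_MODEL_SEQUENCE",
]

#: Augmented-model sequence for the LRT grid, all on the RSA base model.
#: Three-feature models additionally report a test against their
#: two-feature parent (RSA+CSV).
LRT_MODEL_SEQUENCE = [
    ("RSA + CQ", ["RSA", "CQ"], ["RSA"]),
    ("RSA + CSV", ["RSA", "CSV"], ["RSA"]),
    ("RSA + OP", ["RSA", "OP"], ["RSA"]),
    ("RSA + CSV + OP", ["RSA", "CSV", "OP"], ["RSA", "CSV"]),
    ("RSA + CSV + CQ", ["RSA", "CSV", "CQ"], ["RSA", "CSV"]),
]


@dataclass
class Cohort:
    """Feature table plus the mutant→control pairing.

    ``features`` carries one row per pattern with at least the columns
    pattern_id, group, and the five feature columns; ``pairing`` maps
    each mutant group label to its paired control group.
    """

    features: pd.DataFrame
    pairing: dict[str, str] = field(default_factory=dict)

    def group(self, label: str) -> pd.DataFrame:
        sub = self.features[self.features["group"] == label]
        if len(sub) == 0:
            raise KeyError(f"group {label!r} not present in the cohort")
        return sub

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.features["group"]))


@dataclass
class RegressionResult:
    """A fitted logistic regression (intercept first)."""

    feature_names: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_obs: int
    converged: bool


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    warning: str | None = None


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H across ≥ 2 groups, tie-corrected, χ² p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # no rank variation at all
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U between two samples.

    The p-value is exact (full enumeration of rank arrangements) when
    the smaller sample has ≤ 8 observations and the pooled data are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections is used. Returns U for the first sample.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


class IRLSLogisticRegression:
    """Binary logistic regression fit by iteratively reweighted least squares.

    Newton/IRLS with convergence declared when the relative change in
    log-likelihood drops below ``tol`` (default 1e-10) or after
    ``max_iter`` (default 100) steps. Complete separation — the
    optimiser pushing coefficients without bound while the likelihood
    approaches its supremum — is detected via a diverging linear
    predictor on a perfectly classified sample and reported through
    ``converged_ = False`` rather than an exception.

    Fitted attributes: ``coef_`` (slopes), ``intercept_``,
    ``params_`` (intercept first), ``bse_`` (Wald standard errors),
    ``p_values_``, ``llf_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, include_intercept: bool = True, tol: float = 1e-10, max_iter: int = 100):
        self.include_intercept = include_intercept
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "include_intercept": self.include_intercept,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "IRLSLogisticRegression":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: Sequence[int]):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        if classes.size < 2:
            raise ValueError("response contains a single class; model undefined")
        if not np.isfinite(X).all():
            raise ValueError("design matrix must be finite")

        n = X.shape[0]
        design = np.column_stack([np.ones(n), X]) if self.include_intercept else X
        p_dim = design.shape[1]
        beta = np.zeros(p_dim)
        ll_old = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = design @ beta
            # clip only inside the likelihood to avoid log(0)
            mu = 1.0 / (1.0 + np.exp(-eta))
            mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
            ll = float(np.sum(y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)))
            if np.isfinite(ll_old):
                rel = abs(ll - ll_old) / max(abs(ll_old), 1e-30)
                if rel < self.tol:
                    converged = True
                    break
            ll_old = ll
            w = mu * (1 - mu)
            # damp the weights so the normal equations stay solvable as
            # probabilities saturate
            w = np.maximum(w, 1e-10)
            xtw = design.T * w
            hess = xtw @ design
            grad = design.T @ (y - mu)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            beta = beta + step

        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)))

        # complete separation: perfect classification with a runaway
        # linear predictor means the MLE does not exist
        perfect = np.all((mu > 0.5) == (y > 0.5)) and np.max(np.abs(eta)) > 15
        if perfect:
            converged = False

        w = np.maximum(mu * (1 - mu), 1e-12)
        hess = (design.T * w) @ design
        try:
            cov = np.linalg.inv(hess)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(p_dim, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / bse
        pvals = 2.0 * sps.norm.sf(np.abs(z))

        self.params_ = beta
        self.intercept_ = float(beta[0]) if self.include_intercept else 0.0
        self.coef_ = beta[1:] if self.include_intercept else beta
        self.bse_ = bse
        self.p_values_ = pvals
        self.llf_ = llf
        self.converged_ = bool(converged)
        self.n_iter_ = it
        self.n_obs_ = n
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = (
            np.column_stack([np.ones(X.shape[0]), X])
            if self.include_intercept
            else X
        )
        p1 = 1.0 / (1.0 + np.exp(-(design @ self.params_)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    response: Sequence[int],
    include_intercept: bool = True,
) -> RegressionResult:
    """Fit a binary logistic regression and return its summary.

    *design* may be a DataFrame (column names become feature names) or
    an array. The intercept, when included, is the first coefficient.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    est = IRLSLogisticRegression(include_intercept=include_intercept).fit(
        X, response
    )
    all_names = (["intercept"] if include_intercept else []) + names
    return RegressionResult(
        feature_names=all_names,
        coefficients=est.params_,
        std_errors=est.bse_,
        p_values=est.p_values_,
        log_likelihood=est.llf_,
        n_obs=est.n_obs_,
        converged=est.converged_,
    )


def likelihood_ratio_test(
    nested: RegressionResult, full: RegressionResult
) -> LRTResult:
    """Likelihood-ratio test of a nested logistic model against a fuller one.

    The statistic 2(ℓ_full − ℓ_nested) is clamped at zero (numerical
    slack can make it marginally negative) and referred to a χ²
    distribution with df = added parameter count. Non-nested feature
    sets are an error; a non-converged member yields a warning flag on
    the result, not an exception.
    """
    if not set(nested.feature_names) <= set(full.feature_names):
        raise ValueError(
            "models are not nested: "
            f"{nested.feature_names} vs {full.feature_names}"
        )
    if nested.n_obs != full.n_obs:
        raise ValueError("models were fit on different numbers of observations")
    df = len(full.feature_names) - len(nested.feature_names)
    stat = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    if df == 0:  # identical feature sets: no test, likelihood gap is slack
        p = 1.0 if stat < 1e-8 else 0.0
    else:
        p = float(sps.chi2.sf(stat, df))
    warning = None
    if not (nested.converged and full.converged):
        warning = "at least one model did not converge (possible separation)"
    return LRTResult(statistic=float(stat), df=df, p_value=p, warning=warning)


@dataclass
class FeatureSelectionReport:
    """Per-mutant analysis bundle: univariate, LRT grid, multiple regression."""

    mutant_group: str
    control_group: str
    univariate: pd.DataFrame  # feature, U, p_value, n_mutant, n_control
    lrt: pd.DataFrame  # model, p_vs_base, p_vs_parent, converged
    multiple_regression: pd.DataFrame  # feature, coefficient, p_value
    n_dropped: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mutant_group": self.mutant_group,
            "control_group": self.control_group,
            "univariate": self.univariate.to_dict(orient="records"),
            "lrt": self.lrt.to_dict(orient="records"),
            "multiple_regression": self.multiple_regression.to_dict(
                orient="records"
            ),
            "n_dropped": self.n_dropped,
            "warnings": self.warnings,
        }


def _complete_rows(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return df.dropna(subset=cols)


def feature_selection_report(
    cohort: Cohort,
    mutant_group: str,
    *,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> FeatureSelectionReport:
    """Compare one mutant group with its paired control.

    Emits (i) per-feature two-sided Mann–Whitney p-values, (ii) the LRT
    grid over the standard augmented-model sequence on the RSA base
    model — each model tested against the base and, for three-feature
    models, also against its two-feature parent — and (iii) Wald
    p-values from the multiple logistic regression on all five features.
    Patterns with a missing CQ are dropped pairwise per analysis, with
    the dropped counts recorded on the report. Degenerate (separated)
    fits propagate as warnings rather than aborting.
    """
    if mutant_group not in cohort.pairing:
        raise KeyError(f"{mutant_group!r} has no paired control in the cohort")
    control_group = cohort.pairing[mutant_group]
    mut = cohort.group(mutant_group)
    ctl = cohort.group(control_group)
    if len(mut) < 3 or len(ctl) < 3:
        raise ValueError(
            "need at least 3 patterns per group "
            f"(got {len(mut)} mutant, {len(ctl)} control)"
        )
    warnings: list[str] = []
    n_dropped: dict[str, int] = {}

    # (i) univariate Mann-Whitney per feature
    uni_rows = []
    for feat in FEATURE_NAMES:
        m = mut[feat].dropna().to_numpy(dtype=float)
        c = ctl[feat].dropna().to_numpy(dtype=float)
        dropped = (len(mut) - m.size) + (len(ctl) - c.size)
        if dropped:
            n_dropped[f"univariate:{feat}"] = int(dropped)
        u, p = mann_whitney_u(m, c)
        uni_rows.append(
            {
                "feature": feat,
                "U": u,
                "p_value": p,
                "n_mutant": int(m.size),
                "n_control": int(c.size),
            }
        )
    univariate = pd.DataFrame(uni_rows)
    if bh_correction:
        univariate["p_adjusted"] = _benjamini_hochberg(
            univariate["p_value"].to_numpy()
        )
    decisive = univariate["p_adjusted" if bh_correction else "p_value"]
    univariate["significant"] = decisive < alpha

    # shared binary-class table (control = 0, mutant = 1)
    both = pd.concat([ctl, mut], ignore_index=True)
    both["_y"] = (both["group"] == mutant_group).astype(int)

    def _fit(cols: list[str]) -> tuple[RegressionResult, int]:
        sub = _complete_rows(both, cols)
        res = fit_logistic(sub[cols], sub["_y"].to_numpy())
        return res, len(both) - len(sub)

    # (ii) LRT grid on the RSA base model
    lrt_rows = []
    for label, feats, parent_feats in LRT_MODEL_SEQUENCE:
        needed = sorted(set(feats) | set(parent_feats) | {"RSA"})
        sub = _complete_rows(both, needed)
        dropped = len(both) - len(sub)
        if dropped:
            n_dropped[f"lrt:{label}"] = int(dropped)
        y = sub["_y"].to_numpy()
        base = fit_logistic(sub[["RSA"]], y)
        full = fit_logistic(sub[feats], y)
        vs_base = likelihood_ratio_test(base, full)
        if len(parent_feats) > 1:
            parent = fit_logistic(sub[parent_feats], y)
            vs_parent = likelihood_ratio_test(parent, full)
            p_parent = vs_parent.p_value
        else:
            p_parent = vs_base.p_value
        if vs_base.warning:
            warnings.append(f"{label}: {vs_base.warning}")
        lrt_rows.append(
            {
                "model": label,
                "p_vs_base": vs_base.p_value,
                "p_vs_parent": p_parent,
                "converged": full.converged,
            }
        )
    lrt = pd.DataFrame(lrt_rows)

    # (iii) multiple logistic regression on all five features
    multi_feats = ["RSA", "OP", "CQ", "CSV"]
    res, dropped = _fit(multi_feats)
    if dropped:
        n_dropped["multiple_regression"] = int(dropped)
    if not res.converged:
        warnings.append("multiple regression did not converge (possible separation)")
    multiple = pd.DataFrame(
        {
            "feature": res.feature_names,
            "coefficient": res.coefficients,
            "p_value": res.p_values,
        }
    )
    multiple = multiple[multiple["feature"] != "intercept"].reset_index(drop=True)

    return FeatureSelectionReport(
        mutant_group=mutant_group,
        control_group=control_group,
        univariate=univariate,
        lrt=lrt,
        multiple_regression=multiple,
        n_dropped=n_dropped,
        warnings=warnings,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out
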