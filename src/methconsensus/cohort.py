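"""Validation-stage statistics on the clinical cohort table.

The cohort carries 19 analysis variables (age, sex, three vascular risk
factors, 13 blood tests, a percent-methylation marker) plus three MRI
imaging-feature flags (white matter hyperintensities, lacunes,
microbleeds). The stage: impute missing cells, compare no-SVD vs any-SVD
groups, build isolated/coexistence subgroups, test whether adding the
methylation marker to a backward-selected risk-factor model improves AUC,
and fit multinomial models contrasting isolated and coexistence phenotypes
against no-SVD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

import statsmodels.api as sm

from .simulate import ANALYSIS_COLUMNS, BLOOD_TEST_COLUMNS

log = logging.getLogger(__name__)

FLAG_COLUMNS = ("wmh", "lacune", "microbleed")


# ---------------------------------------------------------------- imputation

def impute_missing(
    cohort: pd.DataFrame,
    seed: int = 0,
    mode: str = "forest",
    max_rounds: int = 10,
    n_estimators: int = 20,
) -> tuple[pd.DataFrame, pd.Series]:
    """Iterative conditional-model imputation of the analysis variables.

    Each incomplete column is regressed on all other variables (imaging
    flags included as predictors, never imputed), cycling until
    convergence or ``max_rounds``. ``mode`` selects the conditional model:
    "forest" (tree ensemble) or "linear". Deterministic given ``seed``.
    Returns the completed table and a per-column count of imputed cells.
    """
    cols = [c for c in ANALYSIS_COLUMNS if c in cohort.columns]
    fully_missing = [c for c in cols if cohort[c].isna().all()]
    if fully_missing:
        raise ValueError(f"fully missing columns cannot be imputed: {fully_missing}")

    work = cohort.copy()
    sex_numeric = None
    if "sex" in work.columns and work["sex"].dtype == object:
        sex_numeric = work["sex"].map({"M": 0.0, "F": 1.0})
        work["sex"] = sex_numeric
    feature_cols = cols + [c for c in FLAG_COLUMNS if c in work.columns]
    x = work[feature_cols].astype(float)
    report = x[cols].isna().sum()

    if report.sum() > 0:
        if mode == "forest":
            estimator = RandomForestRegressor(
                n_estimators=n_estimators, random_state=seed, n_jobs=1)
        elif mode == "linear":
            # regularised so junk predictors do not inflate prediction noise
            estimator = BayesianRidge()
        else:
            raise ValueError(f"unknown imputation mode {mode!r}")
        # standardise so the shared ridge penalty treats columns on very
        # different scales (platelets vs binary flags) evenly
        centre = x.mean()
        scale = x.std(ddof=0).replace(0.0, 1.0)
        z = (x - centre) / scale
        imputer = IterativeImputer(
            estimator=estimator, max_iter=max_rounds, random_state=seed,
            sample_posterior=False, skip_complete=True)
        filled = pd.DataFrame(imputer.fit_transform(z), index=x.index,
                              columns=feature_cols) * scale + centre
    else:
        filled = x

    out = cohort.copy()
    for c in cols:
        out[c] = filled[c]
    if sex_numeric is not None:
        out["sex"] = np.where(filled["sex"] >= 0.5, "F", "M")
    for c in ("hypertension", "diabetes", "smoking"):
        if c in out.columns:
            out[c] = np.clip(np.round(out[c].astype(float)), 0, 1).astype(int)
    return out, report


# --------------------------------------------------------- group comparisons

def compare_groups(
    cohort: pd.DataFrame,
    group: pd.Series,
    categorical_test: str = "auto",
) -> pd.DataFrame:
    """Two-group comparison table over the 19 analysis variables.

    Continuous variables: two-sided independent t-test (pooled reported,
    Welch also computed). Categorical variables: Pearson chi-squared on
    the contingency table; ``categorical_test`` = "exact" forces Fisher's
    exact test, "auto" falls back to it when an expected count is < 5.
    Zero-variance continuous variables in both groups get p = 1, flagged.
    """
    g = group.loc[cohort.index].astype(int)
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in ANALYSIS_COLUMNS:
        if col not in cohort.columns:
            continue
        s = cohort[col]
        if pd.api.types.is_numeric_dtype(s) and col not in (
                "hypertension", "diabetes", "smoking"):
            a = s[g == 0].dropna().astype(float)
            b = s[g == 1].dropna().astype(float)
            flag = ""
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                p_pooled = p_welch = 1.0
                t_stat = 0.0
                flag = "zero_variance"
            else:
                t_stat, p_pooled = stats.ttest_ind(a, b, equal_var=True)
                _, p_welch = stats.ttest_ind(a, b, equal_var=False)
            rows.append({
                "variable": col, "kind": "continuous",
                "group0_summary": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                "group1_summary": f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                "statistic": float(t_stat), "p": float(p_pooled),
                "p_welch": float(p_welch), "flag": flag})
        else:
            tab = pd.crosstab(s, g)
            if tab.shape[0] < 2:
                rows.append({"variable": col, "kind": "categorical",
                             "group0_summary": _cat_summary(s[g == 0]),
                             "group1_summary": _cat_summary(s[g == 1]),
                             "statistic": 0.0, "p": 1.0, "p_welch": np.nan,
                             "flag": "single_level"})
                continue
            chi2, p_chi, _, expected = stats.chi2_contingency(tab, correction=False)
            method = categorical_test
            if method == "auto":
                method = "exact" if (expected < 5).any() and tab.shape == (2, 2) \
                    else "chi2"
            if method == "exact" and tab.shape == (2, 2):
                _, p_val = stats.fisher_exact(tab)
                stat = np.nan
            else:
                p_val, stat = p_chi, chi2
            rows.append({"variable": col, "kind": "categorical",
                         "group0_summary": _cat_summary(s[g == 0]),
                         "group1_summary": _cat_summary(s[g == 1]),
                         "statistic": float(stat) if stat == stat else np.nan,
                         "p": float(p_val), "p_welch": np.nan,
                         "flag": method})
    return pd.DataFrame(rows).set_index("variable")


def _cat_summary(s: pd.Series) -> str:
    counts = s.value_counts()
    total = counts.sum()
    return ":".join(f"{lev} {c} ({100.0 * c / total:.1f}%)"
                    for lev, c in counts.sort_index().items())


# ------------------------------------------------------------------ subgroups

@dataclass
class SubgroupCensus:
    combo_counts: dict
    subgroup_counts: dict
    percentages: dict
    n_total: int
    flags: dict = field(default_factory=dict)


def build_subgroups(flags: pd.DataFrame) -> tuple[pd.DataFrame, SubgroupCensus]:
    """Label each patient and produce the cohort census.

    For each imaging feature X: isolated-X = X present, other two absent;
    coexistence-X = X present with >= 1 other feature; any-SVD = >= 1
    feature. Percentages are of the total cohort, one decimal.
    """
    for c in FLAG_COLUMNS:
        if c not in flags.columns:
            raise ValueError(f"missing imaging-feature flag column {c!r}")
        bad = flags[flags[c].isna()]
        if len(bad):
            raise ValueError(f"missing {c} flag for patient {bad.index[0]}")
    f = flags[list(FLAG_COLUMNS)].astype(int)
    total = f.sum(axis=1)

    labels = pd.DataFrame(index=f.index)
    labels["any_svd"] = total > 0
    for c in FLAG_COLUMNS:
        others = total - f[c]
        labels[f"{c}_label"] = np.select(
            [f[c] == 0, (f[c] == 1) & (others == 0)],
            ["absent", "isolated"], default="coexistence")

    combo_names = {
        (0, 0, 0): "none", (1, 0, 0): "wmh", (0, 1, 0): "lacune",
        (0, 0, 1): "microbleed", (1, 1, 0): "wmh_lacune",
        (1, 0, 1): "wmh_microbleed", (0, 1, 1): "lacune_microbleed",
        (1, 1, 1): "all"}
    combos = {name: 0 for name in combo_names.values()}
    for _, row in f.iterrows():
        combos[combo_names[tuple(row)]] += 1

    n = len(f)
    sub = {
        "no_svd": int((~labels["any_svd"]).sum()),
        "any_svd": int(labels["any_svd"].sum()),
        "isolated_total": int((total == 1).sum()),
        "multi_feature": int((total >= 2).sum()),
    }
    for c in FLAG_COLUMNS:
        sub[f"isolated_{c}"] = int((labels[f"{c}_label"] == "isolated").sum())
        sub[f"coexistence_{c}"] = int((labels[f"{c}_label"] == "coexistence").sum())
        sub[f"{c}_subgroup"] = int((f[c] == 1).sum())
    pct = {k: round(100.0 * v / n, 1) for k, v in {**combos, **sub}.items()}
    flags_out = {
        # computed identities a reader may want to cross-check; the census
        # always reports arithmetic from the flags themselves
        "isolated_plus_multi_equals_any_svd":
            sub["isolated_total"] + sub["multi_feature"] == sub["any_svd"],
    }
    census = SubgroupCensus(combo_counts=combos, subgroup_counts=sub,
                            percentages=pct, n_total=n, flags=flags_out)
    return labels, census


# --------------------------------------------------------------- logistic fit

@dataclass
class LogisticFit:
    model_label: str
    terms: pd.DataFrame       # index term, columns B, exp_b, se, p
    auc: float
    auc_ci: tuple
    converged: bool
    separation_flag: bool
    log_likelihood: float
    ll_history: list = field(default_factory=list)

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        b = self.terms["B"].reindex(["const"] + list(x.columns)).to_numpy()
        xm = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
        return 1.0 / (1.0 + np.exp(-xm @ b))


def logistic_irls(
    x: pd.DataFrame, y: np.ndarray,
    max_iter: int = 100, tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS with step halving.

    The log-likelihood is non-decreasing across iterations by
    construction (a Newton step is halved until it improves). Quasi-
    perfect separation is detected (fitted probabilities saturating at the
    class labels with diverging coefficients) and flagged rather than
    raised.
    """
    xm = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    names = ["const"] + list(x.columns)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    beta = np.zeros(xm.shape[1])

    def loglik(b):
        eta = np.clip(xm @ b, -500, 500)
        return float(np.sum(y * eta - np.log1p(np.exp(eta))))

    ll = loglik(beta)
    history = [ll]
    converged = False
    separation = False
    for _ in range(max_iter):
        eta = np.clip(xm @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        info = xm.T @ (xm * w[:, None])
        score = xm.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        factor = 1.0
        new_ll = loglik(beta + step)
        while new_ll < ll and factor > 1e-8:
            factor /= 2.0
            new_ll = loglik(beta + factor * step)
        beta = beta + factor * step
        history.append(new_ll)
        if new_ll - ll < tol:
            converged = True
            ll = new_ll
            break
        ll = new_ll
        if np.abs(beta).max() > 25 and np.all((mu > 0.999) == (y == 1)):
            separation = True
            break

    eta = np.clip(xm @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    cov = np.linalg.pinv(xm.T @ (xm * w[:, None]))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {"B": beta, "exp_b": np.exp(beta), "se": se, "p": pvals}, index=names)
    auc, ci = roc_auc(mu, y)
    return LogisticFit(
        model_label="", terms=terms, auc=auc, auc_ci=ci,
        converged=converged and not separation, separation_flag=separation,
        log_likelihood=history[-1], ll_history=history)


def roc_auc(scores, labels) -> tuple[float, tuple]:
    """AUC as the Mann-Whitney concordance probability (ties 0.5) with a
    DeLong-style asymptotic 95% CI from placement values."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    # placement of each positive among negatives and vice versa
    order = np.argsort(neg, kind="mergesort")
    neg_sorted = neg[order]
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / len(neg)
    auc = float(v10.mean())
    order = np.argsort(pos, kind="mergesort")
    pos_sorted = pos[order]
    lo = np.searchsorted(pos_sorted, neg, side="left")
    hi = np.searchsorted(pos_sorted, neg, side="right")
    v01 = 1.0 - (lo + 0.5 * (hi - lo)) / len(pos)
    var = (np.var(v10, ddof=1) / len(pos) if len(pos) > 1 else 0.0) \
        + (np.var(v01, ddof=1) / len(neg) if len(neg) > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def _encode_terms(cohort: pd.DataFrame, terms) -> pd.DataFrame:
    x = pd.DataFrame(index=cohort.index)
    for t in terms:
        s = cohort[t]
        if t == "sex" and s.dtype == object:
            x[t] = (s == "F").astype(float)  # reference level: men
        else:
            x[t] = s.astype(float)
    return x


DEFAULT_BASE_TERMS = ("age", "sex", "hypertension", "diabetes", "smoking") \
    + BLOOD_TEST_COLUMNS


def hierarchical_logistic(
    cohort: pd.DataFrame,
    outcome: pd.Series,
    base_terms=DEFAULT_BASE_TERMS,
    added_term: str = "cdh7_methylation",
    select_p: float = 0.05,
) -> tuple[LogisticFit, LogisticFit, float]:
    """Backward-selected base model vs marker-augmented model.

    The base model starts from all ``base_terms`` and drops the weakest
    term while any term's Wald p exceeds ``select_p``; the augmented model
    adds ``added_term`` to the retained set. Returns both fits and the AUC
    difference (augmented minus base) from in-sample predicted
    probabilities.
    """
    y = outcome.loc[cohort.index].astype(int).to_numpy()
    terms = [t for t in base_terms if t in cohort.columns]
    while True:
        fit = logistic_irls(_encode_terms(cohort, terms), y)
        pv = fit.terms.drop(index="const")["p"]
        worst = pv.idxmax()
        if pv.loc[worst] > select_p and len(terms) > 1:
            terms.remove(worst)
        else:
            break
    base_fit = fit
    base_fit.model_label = "base"
    aug_fit = logistic_irls(_encode_terms(cohort, terms + [added_term]), y)
    aug_fit.model_label = "base+methylation"
    return base_fit, aug_fit, aug_fit.auc - base_fit.auc


# ------------------------------------------------------------- multinomial

def multinomial_fit(
    cohort: pd.DataFrame,
    category: pd.Series,
    reference: str = "no_svd",
    terms=("age", "homocysteine", "cdh7_methylation"),
    min_category_n: int = 10,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Multinomial logit contrasting phenotype categories against a
    reference category.

    Categories with fewer than ``min_category_n`` patients are skipped
    with a report line. With exactly two categories the fit reduces to
    binary logistic regression. Returns per-category coefficient tables
    (B, exp(B), Wald p) and the skip notes.
    """
    cat = category.loc[cohort.index]
    counts = cat.value_counts()
    if reference not in counts or counts[reference] == 0:
        raise ValueError(f"reference category {reference!r} is empty")
    notes = []
    keep = [reference]
    for lev, c in counts.items():
        if lev == reference:
            continue
        if c < min_category_n:
            notes.append(f"category {lev!r} skipped: only {c} patients")
        else:
            keep.append(lev)
    if len(keep) < 2:
        raise ValueError("no non-reference category large enough to fit")

    mask = cat.isin(keep)
    sub = cohort.loc[mask]
    x = sm.add_constant(_encode_terms(sub, [t for t in terms if t in sub.columns]))
    levels = [reference] + [lev for lev in keep if lev != reference]
    code = pd.Categorical(cat.loc[mask], categories=levels)
    model = sm.MNLogit(code.codes, x)
    res = model.fit(method="newton", maxiter=200, disp=False, tol=1e-10)

    out = {}
    for j, lev in enumerate(levels[1:]):
        b = res.params.iloc[:, j]
        se = res.bse.iloc[:, j]
        p = res.pvalues.iloc[:, j]
        out[lev] = pd.DataFrame(
            {"B": b.to_numpy(), "exp_b": np.exp(b.to_numpy()),
             "se": se.to_numpy(), "p": p.to_numpy()}, index=x.columns)
    return out, notes


# ------------------------------------------------- marker utilities

def select_validation_targets(
    group_means: pd.DataFrame, threshold: float = 5.0
) -> pd.DataFrame:
    """Pyrosequencing positivity screen.

    ``group_means`` is genes x groups percent methylation. A gene is
    selected iff its minimum group mean is strictly greater than
    ``threshold``; genes with a missing group mean are non-evaluable.
    """
    out = group_means.copy()
    mins = group_means.min(axis=1)
    evaluable = group_means.notna().all(axis=1)
    out["evaluable"] = evaluable
    out["selected"] = evaluable & (mins > threshold)
    return out


@dataclass(frozen=True)
class ExpressionRecord:
    ct_target: float
    ct_reference: float
    delta_ct: float


def delta_ct(ct_target: float, ct_reference: float) -> ExpressionRecord:
    """qPCR threshold-cycle difference, target minus reference gene.

    Higher delta-Ct means lower relative expression of the target.
    """
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("cycle numbers must be finite")
    if ct_target <= 0 or ct_reference <= 0:
        raise ValueError("cycle numbers must be positive")
    return ExpressionRecord(ct_target=float(ct_target),
                            ct_reference=float(ct_reference),
                            delta_ct=float(ct_target - ct_reference))


def methylation_expression_correlation(methylation, delta_ct_values):
    """Pearson correlation between percent methylation and delta-Ct."""
    r, p = stats.pearsonr(np.asarray(methylation, dtype=float),
                          np.asarray(delta_ct_values, dtype=float))
    return float(r), float(p)
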