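"""Per-arm differential methylation and dual-arm consensus calling.

Testing runs on M-values with ordinary least squares per probe and
empirical-Bayes variance moderation: per-probe residual variances are
shrunk toward a prior variance s0^2 with prior degrees of freedom d0, both
estimated in closed form by matching the moments of log residual variances
to a scaled-F prior (trigamma inversion). Effect sizes are reported on the
beta scale as the difference in group means (delta beta, test minus
control). Multiple testing uses Benjamini-Hochberg; calibration is
summarised by the genomic inflation factor lambda; candidate screening
intersects the two arms (nominal p below threshold in both, concordant
direction) with effect-size and promoter filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import BetaMatrix, MValueMatrix, ProbeAnnotation

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

P_CONSENSUS_DEFAULT = 0.05
DELTA_BETA_MIN_DEFAULT = 0.10
FDR_ALPHA_DEFAULT = 0.05


@dataclass
class EBayesParams:
    d0: float        # prior degrees of freedom, may be inf
    s0_sq: float     # prior variance
    d_resid: float   # residual df per probe


@dataclass
class InflationReport:
    lam: float
    n_tests: int


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_ebayes_params(s2: np.ndarray, d_resid: float) -> EBayesParams:
    """Moment-matching estimate of (d0, s0^2) from per-probe residual
    variances with ``d_resid`` degrees of freedom each."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return EBayesParams(d0=np.inf, s0_sq=float(s2[ok].mean() if ok.any() else 1.0),
                            d_resid=d_resid)
    z = np.log(s2[ok])
    e = z - special.digamma(d_resid / 2.0) + np.log(d_resid / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d_resid / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return EBayesParams(d0=d0, s0_sq=s0_sq, d_resid=d_resid)


def moderated_fit(
    m: MValueMatrix,
    design: pd.DataFrame,
    contrast: np.ndarray | str = "group",
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, EBayesParams]:
    """Per-probe OLS on M-values with empirical-Bayes moderated t.

    ``design`` is the numeric model matrix (samples x terms); ``contrast``
    is a term name or a coefficient vector. ``prior_df`` forces d0 (0
    recovers the ordinary t; inf gives the fully pooled prior variance).
    Returns a per-probe table (estimate on the M scale, moderated t,
    two-sided p with d0 + d residual df) plus the estimated prior.
    """
    x = design.to_numpy(dtype=float)
    n, p_terms = x.shape
    d = n - p_terms
    if d < 1:
        raise ValueError("zero residual degrees of freedom")
    if np.linalg.matrix_rank(x) < p_terms:
        raise ValueError("design matrix is rank deficient")
    if isinstance(contrast, str):
        c = np.zeros(p_terms)
        c[list(design.columns).index(contrast)] = 1.0
    else:
        c = np.asarray(contrast, dtype=float)

    y = m.values.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = y @ (xtx_inv @ x.T).T               # probes x terms
    resid = y - coefs @ x.T
    s2 = (resid ** 2).sum(axis=1) / d
    unscaled_se = float(np.sqrt(c @ xtx_inv @ c))
    est = coefs @ c

    params = estimate_ebayes_params(s2, d)
    if prior_df is not None:
        params = EBayesParams(d0=float(prior_df), s0_sq=params.s0_sq, d_resid=d)
    d0, s0_sq = params.d0, params.s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(d)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = float(d0 + d)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / (np.sqrt(s2_post) * unscaled_se)
    degenerate = (s2_post == 0) | ~np.isfinite(t)
    t[degenerate] = 0.0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[degenerate] = 1.0

    table = pd.DataFrame(
        {"log_fc_m": est, "s2": s2, "s2_post": s2_post,
         "t_moderated": t, "p": p},
        index=m.values.index)
    return table, params


def delta_beta(beta: BetaMatrix, group: pd.Series) -> pd.Series:
    """Per-probe difference in mean beta, test minus control.

    ``group`` maps sample id to 0 (control) or 1 (test); both groups must
    be non-empty. The difference is computed on the beta scale.
    """
    g = group.loc[beta.sample_ids].to_numpy(dtype=float)
    if (g == 1).sum() == 0 or (g == 0).sum() == 0:
        raise ValueError("both groups must be non-empty")
    vals = beta.values.to_numpy(dtype=float)
    diff = vals[:, g == 1].mean(axis=1) - vals[:, g == 0].mean(axis=1)
    return pd.Series(diff, index=beta.values.index, name="delta_beta")


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, stable for ties."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def genomic_lambda(p) -> InflationReport:
    """Genomic inflation factor from a vector of p-values.

    Each p is converted to its 1-df chi-square quantile; lambda is the
    median of those statistics over the null median 0.4549.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError(
            "p-values must lie in (0, 1]; floor zero p-values before "
            "computing the inflation factor")
    chi2 = stats.chi2.isf(p, 1)
    return InflationReport(lam=float(np.median(chi2) / CHI2_1DF_MEDIAN),
                           n_tests=int(p.size))


def build_dmp_table(
    fit: pd.DataFrame, dbeta: pd.Series
) -> pd.DataFrame:
    """Assemble one arm's DMP table: moderated stats + beta-scale effect."""
    tab = fit.copy()
    tab["delta_beta"] = dbeta.loc[tab.index]
    tab["q_fdr"] = bh_fdr(tab["p"].to_numpy())
    tab["direction"] = np.where(tab["delta_beta"] >= 0, "+", "-")
    return tab


def strict_fdr_significance(
    arm: pd.DataFrame,
    fdr_alpha: float = FDR_ALPHA_DEFAULT,
    delta_beta_min: float = DELTA_BETA_MIN_DEFAULT,
) -> pd.DataFrame:
    """Probes passing the strict rule FDR < alpha AND |delta beta| > min.

    An empty result is a valid outcome.
    """
    mask = (arm["q_fdr"] < fdr_alpha) & (arm["delta_beta"].abs() > delta_beta_min)
    return arm.loc[mask]


def call_consensus(
    arm_a: pd.DataFrame,
    arm_b: pd.DataFrame,
    annot: ProbeAnnotation,
    p_max: float = P_CONSENSUS_DEFAULT,
    delta_beta_min: float = DELTA_BETA_MIN_DEFAULT,
) -> pd.DataFrame:
    """Dual-arm consensus DMP calling.

    A probe is a consensus DMP iff p < ``p_max`` in both arms, the two
    arms' delta betas share a non-zero sign, |delta beta| > ``delta_beta_min``
    in both arms, and the probe is promoter-proximal (TSS200/TSS1500).
    Probes present in only one arm are reported with evaluable=False.
    Output is sorted by min(p_a, p_b).
    """
    all_probes = arm_a.index.union(arm_b.index, sort=False)
    shared = arm_a.index.intersection(arm_b.index)
    annot.require_probes(list(shared))

    rec = pd.DataFrame(index=all_probes)
    rec.index.name = "probe_id"
    rec["evaluable"] = rec.index.isin(shared)
    rec["p_arm_a"] = arm_a["p"].reindex(all_probes)
    rec["p_arm_b"] = arm_b["p"].reindex(all_probes)
    rec["delta_beta_arm_a"] = arm_a["delta_beta"].reindex(all_probes)
    rec["delta_beta_arm_b"] = arm_b["delta_beta"].reindex(all_probes)

    sign_a = np.sign(rec["delta_beta_arm_a"])
    sign_b = np.sign(rec["delta_beta_arm_b"])
    rec["concordant"] = (sign_a == sign_b) & (sign_a != 0)
    rec["passes_effect"] = (
        (rec["delta_beta_arm_a"].abs() > delta_beta_min)
        & (rec["delta_beta_arm_b"].abs() > delta_beta_min))
    region = annot.table["region_class"].reindex(all_probes)
    rec["passes_promoter"] = region.isin(["TSS200", "TSS1500"]).to_numpy()
    rec["is_consensus_dmp"] = (
        rec["evaluable"]
        & (rec["p_arm_a"] < p_max) & (rec["p_arm_b"] < p_max)
        & rec["concordant"] & rec["passes_effect"] & rec["passes_promoter"])

    if annot.nearest_gene is not None:
        rec.insert(0, "nearest_gene", annot.nearest_gene.reindex(all_probes))
    rec["chrom"] = annot.table["chrom"].reindex(all_probes)
    rec["dist_to_tss"] = annot.table["dist_to_tss"].reindex(all_probes)
    rec["min_p"] = rec[["p_arm_a", "p_arm_b"]].min(axis=1)
    return rec.sort_values("min_p", kind="mergesort")


def variance_partition(
    m: MValueMatrix,
    design: pd.DataFrame,
    factor_groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Marginal delta-R^2 variance partition, averaged over probes.

    For each factor group g (a named set of design-matrix columns), the
    per-probe fraction is R^2(full) - R^2(without g), clipped at 0; the
    residual fraction is 1 - R^2(full). Probes whose reduced model is
    singular beyond repair are skipped and counted.
    """
    x = design.to_numpy(dtype=float)
    y = m.values.to_numpy(dtype=float)
    yc = y - y.mean(axis=1, keepdims=True)
    tss = (yc ** 2).sum(axis=1)
    ok = tss > 0

    def r2_matrix(cols_mask):
        xs = x[:, cols_mask]
        coef, *_ = np.linalg.lstsq(xs, y.T, rcond=None)
        resid = y - (xs @ coef).T
        rss = (resid ** 2).sum(axis=1)
        r2 = np.zeros_like(tss)
        r2[ok] = 1.0 - rss[ok] / tss[ok]
        return np.clip(r2, 0.0, 1.0)

    full_mask = np.ones(x.shape[1], dtype=bool)
    r2_full = r2_matrix(full_mask)
    cols = list(design.columns)
    rows = {}
    for name, members in factor_groups.items():
        missing = set(members) - set(cols)
        if missing:
            raise KeyError(f"factor group {name} references unknown columns "
                           f"{sorted(missing)}")
        mask = np.array([c not in members for c in cols])
        r2_red = r2_matrix(mask)
        rows[name] = np.clip(r2_full - r2_red, 0.0, 1.0)
    rows["residual"] = 1.0 - r2_full

    per_probe = pd.DataFrame(rows, index=m.values.index)
    summary = per_probe[ok].mean(axis=0).to_frame("fraction_explained")
    summary["n_probes"] = int(ok.sum())
    summary["n_skipped"] = int((~ok).sum())
    return summary
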