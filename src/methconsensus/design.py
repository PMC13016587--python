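"""Model-matrix construction for one analysis arm.

Workflow: PCA of the M-value matrix over samples, screening of sample
metadata against the top principal components (a variable enters the
design when it associates with any screened PC at the chosen alpha),
surrogate-variable construction from the residual matrix with a
permutation (parallel-analysis) dimension cut-off, exclusion of surrogate
variables confounded with case-control status (p < 1e-6 or eta-squared
> 0.5 against the group), and a cap of adjustment terms at a fraction of
the sample size (default 25%) as an overfitting safeguard. The group term
never counts against the cap and is never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MValueMatrix

log = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.01
MAX_PCS_DEFAULT = 5
SV_P_EXCLUDE = 1e-6
SV_ETA2_EXCLUDE = 0.5
CAP_FRACTION_DEFAULT = 0.25


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    explained_variance: np.ndarray  # fractions, non-increasing


@dataclass
class SurrogateVariableRecord:
    sv_id: str
    eta_squared: float
    p_vs_group: float
    eigenvalue_rank: int
    retained: bool


@dataclass
class AnalysisDesign:
    """The model matrix of one arm: group + capped adjustment terms."""

    group: pd.Series               # 0/1 per sample
    covariates: pd.DataFrame       # numeric/categorical columns
    svs: pd.DataFrame              # numeric columns
    cap: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_adjustment_terms(self) -> int:
        return self._n_cov_terms() + self.svs.shape[1]

    def _n_cov_terms(self) -> int:
        n = 0
        for col in self.covariates.columns:
            s = self.covariates[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                n += max(s.nunique() - 1, 1)
            else:
                n += 1
        return n

    def matrix(self) -> pd.DataFrame:
        """Numeric design matrix: intercept, group, covariates (categorical
        columns dummy-coded, first level reference), surrogate variables."""
        parts = [pd.DataFrame({"const": 1.0, "group": self.group.astype(float)},
                              index=self.group.index)]
        if self.covariates.shape[1]:
            num = self.covariates.select_dtypes(include=[np.number])
            cat = self.covariates.drop(columns=num.columns)
            if num.shape[1]:
                parts.append(num.astype(float))
            if cat.shape[1]:
                parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
        if self.svs.shape[1]:
            parts.append(self.svs.astype(float))
        x = pd.concat(parts, axis=1)
        if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return x

    def term_groups(self) -> dict[str, list[str]]:
        """Design-matrix columns grouped by originating term."""
        x = self.matrix()
        groups: dict[str, list[str]] = {"group": ["group"]}
        for col in self.covariates.columns:
            groups[col] = [c for c in x.columns
                           if c == col or c.startswith(f"{col}_")]
        for col in self.svs.columns:
            groups[col] = [col]
        return groups


def pca_samples(m: MValueMatrix, n_components: int) -> PcaResult:
    """Sample-space PCA of the per-probe-centred M matrix.

    Explained-variance fractions are relative to the total (centred)
    variance, so they sum to at most 1 and are non-increasing.
    """
    y = m.values.to_numpy(dtype=float)
    if n_components > min(y.shape):
        raise ValueError("n_components exceeds matrix dimensions")
    yc = y - y.mean(axis=1, keepdims=True)
    total = float((yc ** 2).sum())
    if total == 0.0:
        raise ValueError("matrix has zero variance; PCA undefined")
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    scores = (vt[:n_components] * s[:n_components, None]).T
    explained = (s[:n_components] ** 2) / total
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=cols),
        explained_variance=explained,
    )


def discover_covariates(
    pc_scores: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    max_pcs: int = MAX_PCS_DEFAULT,
    group_col: str = "group",
) -> tuple[list[str], pd.DataFrame]:
    """Select metadata variables associated with any of the top PCs.

    Numeric variables are tested by the simple-regression F test (on each
    PC's scores), categorical ones by one-way ANOVA. A variable is
    selected iff min-p over the screened PCs is below ``alpha``. The group
    variable itself is never selectable; constant or all-missing columns
    are skipped with a logged reason.
    """
    if not pc_scores.index.equals(metadata.index):
        raise ValueError("metadata and PC scores index different samples")
    pcs = pc_scores.columns[: max_pcs]
    rows = []
    selected = []
    for col in metadata.columns:
        if col == group_col:
            continue
        s = metadata[col]
        if s.isna().all():
            log.info("skipping %s: all missing", col)
            continue
        if s.nunique(dropna=True) <= 1:
            log.info("skipping %s: zero variance", col)
            continue
        pvals = {}
        for pc in pcs:
            y = pc_scores[pc]
            if pd.api.types.is_numeric_dtype(s):
                mask = s.notna()
                res = stats.linregress(s[mask].astype(float), y[mask])
                pvals[pc] = float(res.pvalue)
            else:
                groups = [y[s == lev].to_numpy() for lev in s.dropna().unique()]
                groups = [g for g in groups if len(g) > 0]
                pvals[pc] = float(stats.f_oneway(*groups).pvalue) \
                    if len(groups) > 1 else 1.0
        min_p = min(pvals.values())
        rows.append({"variable": col, **pvals, "min_p": min_p,
                     "selected": min_p < alpha})
        if min_p < alpha:
            selected.append(col)
    table = pd.DataFrame(rows)
    return selected, table


def build_surrogate_variables(
    m: MValueMatrix,
    design: pd.DataFrame,
    n_sv_max: int = 5,
    seed: int = 0,
    n_permutations: int = 20,
) -> pd.DataFrame:
    """Candidate surrogate variables from the residual matrix.

    Each probe is regressed on the known design (group included); the
    right singular vectors of the residual matrix, ordered by singular
    value, are candidate SVs. The count is limited by ``n_sv_max`` and by
    parallel analysis: an SV is kept while its singular value exceeds the
    95th percentile of the matching singular values from row-permuted
    residual matrices (``n_permutations`` permutations, seeded).
    """
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("known design is rank deficient")
    y = m.values.to_numpy(dtype=float)
    beta_hat, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y - (x @ beta_hat).T
    if not np.any(np.abs(resid) > 1e-12):
        log.info("residual matrix is numerically zero; no SVs")
        return pd.DataFrame(index=m.sample_ids)

    s_obs = np.linalg.svd(resid, compute_uv=False)
    f_obs = s_obs ** 2 / (s_obs ** 2).sum()
    # row-permute, re-project through the same residual operator, and
    # compare variance *fractions*: re-projection shrinks the permuted
    # matrix's total variance, so raw singular values are not comparable
    proj = np.eye(x.shape[0]) - x @ np.linalg.pinv(x)
    rng = np.random.default_rng(seed)
    f_perm = np.empty((n_permutations, len(s_obs)))
    for b in range(n_permutations):
        s_b = np.linalg.svd(rng.permuted(resid, axis=1) @ proj,
                            compute_uv=False)
        f_perm[b] = s_b ** 2 / (s_b ** 2).sum()
    thresholds = np.percentile(f_perm, 95, axis=0)

    n_keep = 0
    for i in range(min(n_sv_max, len(s_obs))):
        if f_obs[i] > thresholds[i]:
            n_keep += 1
        else:
            break
    if n_keep == 0:
        return pd.DataFrame(index=m.sample_ids)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    svs = vt[:n_keep].T
    return pd.DataFrame(svs, index=m.sample_ids,
                        columns=[f"SV{i+1}" for i in range(n_keep)])


def exclude_confounded_svs(
    svs: pd.DataFrame,
    group: pd.Series,
    p_exclude: float = SV_P_EXCLUDE,
    eta2_exclude: float = SV_ETA2_EXCLUDE,
) -> list[SurrogateVariableRecord]:
    """Screen SVs against case-control status.

    For each SV the regression SV ~ group yields eta-squared (the R^2 of
    that fit, i.e. the variance fraction explained by group) and an
    F-test p-value. An SV is excluded when p < ``p_exclude`` OR
    eta-squared > ``eta2_exclude``.
    """
    g = group.to_numpy(dtype=float)
    classes = np.unique(g)
    if len(classes) < 2:
        raise ValueError("group must contain both classes")
    n = len(g)
    records = []
    for rank, col in enumerate(svs.columns, start=1):
        v = svs[col].to_numpy(dtype=float)
        vc = v - v.mean()
        gc = g - g.mean()
        denom = float((vc ** 2).sum() * (gc ** 2).sum())
        r2 = float((vc @ gc) ** 2 / denom) if denom > 0 else 0.0
        if r2 >= 1.0:
            p = 0.0
        else:
            f_stat = r2 / (1.0 - r2) * (n - 2)
            p = float(stats.f.sf(f_stat, 1, n - 2))
        records.append(SurrogateVariableRecord(
            sv_id=col, eta_squared=r2, p_vs_group=p, eigenvalue_rank=rank,
            retained=not (p < p_exclude or r2 > eta2_exclude)))
    return records


def cap_design(
    group: pd.Series,
    covariates: pd.DataFrame,
    svs: pd.DataFrame,
    n_samples: int,
    cap_fraction: float = CAP_FRACTION_DEFAULT,
    covariate_priority: list[str] | None = None,
) -> AnalysisDesign:
    """Assemble the arm design, capping adjustment terms at
    floor(cap_fraction * n_samples).

    When candidates exceed the cap, covariates are kept first in priority
    order (the given list order, e.g. ranked by strength of PC
    association; ties broken lexicographically), then SVs by eigenvalue
    rank. The group term never counts against the cap.
    """
    cap = int(np.floor(cap_fraction * n_samples))
    if cap < 1:
        raise ValueError("cap < 1: design would have no adjustment capacity")

    if covariate_priority is None:
        covariate_priority = list(covariates.columns)
    order = sorted(covariates.columns,
                   key=lambda c: (covariate_priority.index(c)
                                  if c in covariate_priority else len(covariate_priority), c))

    def n_terms(col):
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            return max(s.nunique() - 1, 1)
        return 1

    kept_cov, kept_sv, dropped = [], [], []
    used = 0
    for col in order:
        t = n_terms(col)
        if used + t <= cap:
            kept_cov.append(col)
            used += t
        else:
            dropped.append(("covariate", col))
    for col in svs.columns:  # already in eigenvalue-rank order
        if used + 1 <= cap:
            kept_sv.append(col)
            used += 1
        else:
            dropped.append(("sv", col))
    for kind, name in dropped:
        log.info("cap %d: dropped %s %s", cap, kind, name)

    return AnalysisDesign(
        group=group,
        covariates=covariates[kept_cov],
        svs=svs[kept_sv],
        cap=cap,
        provenance={"priority": order, "dropped": dropped,
                    "cap_fraction": cap_fraction},
    )
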