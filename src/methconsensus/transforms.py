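"""Beta <-> M-value transforms and amplicon-level summaries.

M = log2((beta + eps) / (1 - beta + eps)) with a small positive offset eps
keeps the statistic finite at the boundaries and stabilises variance for
linear modelling; differential testing runs on M, effect sizes are reported
on the beta scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BetaMatrix, MValueMatrix

DEFAULT_M_OFFSET = 1e-4


def beta_to_m(beta: BetaMatrix, offset: float = DEFAULT_M_OFFSET) -> MValueMatrix:
    """Transform a beta matrix to M-values with a logit offset."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    b = beta.values.to_numpy(dtype=float)
    m = np.log2((b + offset) / (1.0 - b + offset))
    return MValueMatrix(
        pd.DataFrame(m, index=beta.values.index, columns=beta.values.columns),
        offset=offset,
    )


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Exact inverse of :func:`beta_to_m` for betas in [offset, 1-offset]."""
    eps = m.offset
    x = np.exp2(m.values.to_numpy(dtype=float))
    b = (x * (1.0 + eps) - eps) / (1.0 + x)
    b = np.clip(b, 1e-12, 1.0 - 1e-12)
    return BetaMatrix(
        pd.DataFrame(b, index=m.values.index, columns=m.values.columns))


def beta_to_m_scalar(beta, offset: float = DEFAULT_M_OFFSET):
    """Elementwise M-value of a scalar/array of beta fractions."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    b = np.asarray(beta, dtype=float)
    return np.log2((b + offset) / (1.0 - b + offset))


def amplicon_mean_methylation(per_cpg_percents) -> float:
    """Mean percent methylation across the successfully analysed CpG sites
    of one bisulfite-PCR amplicon.

    Raises
    ------
    ValueError
        If the list is empty (no successfully analysed CpG sites) or a
        value falls outside [0, 100].
    """
    vals = np.asarray(list(per_cpg_percents), dtype=float)
    if vals.size == 0:
        raise ValueError("no successfully analyzed CpG sites in amplicon")
    if ((vals < 0) | (vals > 100)).any() or not np.isfinite(vals).all():
        raise ValueError("percent methylation values must lie in [0, 100]")
    return float(vals.mean())
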