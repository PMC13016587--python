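"""Cell-composition estimation, the pipeline's two arms.

Reference-free mode factorises the beta matrix into K latent cell-type
profiles (probes x K, values in [0,1]) and non-negative per-sample
loadings by alternating constrained least squares, initialised from the
top-K singular vectors so the result is deterministic. Reference-based
mode projects each sample onto known leukocyte profiles by non-negative
least squares and renormalises the fractions to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import BetaMatrix

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


@dataclass
class DeconvResult:
    method: str  # "reference_free" | "reference_based"
    k: int
    loadings: pd.DataFrame  # samples x k
    profiles: pd.DataFrame | None = None  # probes x k, reference-free only
    n_iter: int = 0
    converged: bool = True
    rmse: float = float("nan")
    rmse_history: list = field(default_factory=list)


def _rmse(y, p, w):
    return float(np.sqrt(np.mean((y - p @ w) ** 2)))


def reference_free_decompose(
    beta: BetaMatrix,
    k: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> DeconvResult:
    """Latent cell-composition decomposition with box/non-negativity
    constraints.

    Profiles are clipped to [0,1]; loadings are non-negative (NNLS per
    sample). Iterates until the RMS change in reconstruction drops below
    ``tol`` or ``max_iter`` is reached; a step that would increase the
    reconstruction RMSE is rejected, so the recorded RMSE sequence is
    non-increasing. ``seed`` is accepted for interface stability; the
    SVD-based initialisation is itself deterministic.
    """
    y = beta.values.to_numpy(dtype=float)
    n_probes, n_samples = y.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n_samples:
        raise ValueError("k must be smaller than the number of samples")
    if k > n_probes:
        raise ValueError("k must not exceed the number of probes")

    u, s, vt = np.linalg.svd(y, full_matrices=False)
    w = np.abs(vt[:k] * s[:k, None])  # k x samples, non-negative start
    w[w.sum(axis=1) == 0] = 1.0
    p = _solve_profiles(y, w)
    prev = _rmse(y, p, w)
    history = [prev]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w_new = _solve_loadings(y, p)
        p_new = _solve_profiles(y, w_new)
        cur = _rmse(y, p_new, w_new)
        if cur > prev + 1e-12:
            # constrained step increased the objective: keep previous iterate
            converged = True
            break
        p, w = p_new, w_new
        history.append(cur)
        if prev - cur < tol:
            converged = True
            prev = cur
            break
        prev = cur
    if not converged:
        log.warning("reference-free decomposition did not converge in %d "
                    "iterations (last RMSE %.3g)", max_iter, prev)

    comp = [f"LC{i+1}" for i in range(k)]
    return DeconvResult(
        method="reference_free",
        k=k,
        loadings=pd.DataFrame(w.T, index=beta.sample_ids, columns=comp),
        profiles=pd.DataFrame(p, index=beta.probe_ids, columns=comp),
        n_iter=n_iter,
        converged=converged,
        rmse=history[-1],
        rmse_history=history,
    )


def _solve_profiles(y, w):
    """Least squares for profiles given loadings, clipped to [0,1]."""
    p, *_ = np.linalg.lstsq(w.T, y.T, rcond=None)
    return np.clip(p.T, 0.0, 1.0)


def _solve_loadings(y, p):
    """Per-sample NNLS for loadings given profiles."""
    k = p.shape[1]
    w = np.empty((k, y.shape[1]))
    for j in range(y.shape[1]):
        w[:, j], _ = nnls(p, y[:, j])
    return w


def reference_based_project(
    beta: BetaMatrix, reference: pd.DataFrame
) -> DeconvResult:
    """Project each sample onto labelled cell-type reference profiles.

    ``reference`` is probes x compartments with fractions in (0,1); its
    probes must be a subset of the beta matrix's. Per sample the NNLS
    solution against the reference columns is renormalised to sum to one.
    """
    k = reference.shape[1]
    if k < 2:
        raise ValueError("reference must carry at least 2 compartments")
    overlap = [p for p in reference.index if p in beta.values.index]
    if len(overlap) < k + 1:
        raise ValueError(
            f"only {len(overlap)} probes overlap the reference; "
            f"need at least {k + 1} to determine {k} fractions")
    r = reference.loc[overlap].to_numpy(dtype=float)
    y = beta.values.loc[overlap].to_numpy(dtype=float)

    fracs = np.empty((y.shape[1], k))
    for j in range(y.shape[1]):
        coef, _ = nnls(r, y[:, j])
        total = coef.sum()
        fracs[j] = coef / total if total > 0 else np.full(k, 1.0 / k)
    loadings = pd.DataFrame(fracs, index=beta.sample_ids,
                            columns=list(reference.columns))
    return DeconvResult(method="reference_based", k=k, loadings=loadings,
                        rmse=float(np.sqrt(np.mean((y - r @ fracs.T) ** 2))))
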