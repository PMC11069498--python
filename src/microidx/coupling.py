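"""Shared-variation test between two omics blocks.

Given two blocks measured on the same samples (e.g. metabolite abundances and
transcriptomics module eigengenes), the first latent component of each block
is extracted with a two-block partial least squares (PLS) fit -- the pair of
weight vectors maximizing cross-block covariance, computed by power iteration
on the cross-covariance matrix, with optional soft-threshold sparsity on the
loadings.  The strength of shared variation is the Spearman correlation of
the two component score vectors; its significance comes from refitting on
sample-permuted copies of one block and counting permutations whose
correlation exceeds the observed one (p = count / n_permutations, the literal
counting rule; an add-one variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

__all__ = ["CouplingResult", "first_components", "coupling_significance"]


@dataclass(frozen=True)
class CouplingResult:
    """Observed first-component correlation plus its permutation null."""

    rho_observed: float
    null_rhos: tuple[float, ...]
    p: float
    n_permutations: int


def _standardize(block: np.ndarray, scale: bool) -> np.ndarray:
    x = np.asarray(block, dtype=float)
    if x.ndim != 2 or min(x.shape) < 1:
        raise ValueError("blocks must be 2-D samples x features matrices")
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        if (sd == 0).all():
            raise ValueError("block has no variance (all columns constant)")
        sd[sd == 0] = 1.0
        x = x / sd
    if not np.any(x):
        raise ValueError("block has no variance (all columns constant)")
    return x


def _soft_threshold(w: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Soft-threshold so only the top keep_fraction of |loadings| stay nonzero."""
    if keep_fraction >= 1.0:
        return w
    k = max(1, int(np.ceil(keep_fraction * w.size)))
    # subtract the largest excluded magnitude so exactly the top-k survive
    excluded = np.sort(np.abs(w))[: w.size - k]
    lam = excluded.max() if excluded.size else 0.0
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def first_components(
    x: np.ndarray,
    y: np.ndarray,
    keep_fraction_x: float = 1.0,
    keep_fraction_y: float = 1.0,
    scale: bool = True,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """First latent component scores of each block (two-block PLS, power steps).

    Blocks are column-centered (and unit-scaled unless ``scale=False``).
    With ``keep_fraction_* = 1`` this converges to the leading singular pair
    of X'Y.  Sign convention: the X weight with the largest magnitude is made
    positive, and the Y weight's sign is chosen so the cross-block covariance
    of the components is non-negative (the PLS objective's optimum).
    Deterministic given data and settings.
    """
    xs = _standardize(x, scale)
    ys = _standardize(y, scale)
    if xs.shape[0] != ys.shape[0]:
        raise ValueError("blocks must share the same samples")
    if xs.shape[0] < 3:
        raise ValueError("need at least 3 samples")

    cross = xs.T @ ys  # p_x x p_y
    w = cross.sum(axis=1)
    if not np.any(w):
        w = np.ones(xs.shape[1])
    w /= np.linalg.norm(w)
    c = np.zeros(ys.shape[1])
    for _ in range(max_iter):
        c_new = cross.T @ w
        c_new = _soft_threshold(c_new, keep_fraction_y)
        norm_c = np.linalg.norm(c_new)
        if norm_c == 0:
            raise ValueError("sparsity removed every Y loading; raise keep_fraction_y")
        c_new /= norm_c
        w_new = cross @ c_new
        w_new = _soft_threshold(w_new, keep_fraction_x)
        norm_w = np.linalg.norm(w_new)
        if norm_w == 0:
            raise ValueError("sparsity removed every X loading; raise keep_fraction_x")
        w_new /= norm_w
        if np.linalg.norm(w_new - w) < tol and np.linalg.norm(c_new - c) < tol:
            w, c = w_new, c_new
            break
        w, c = w_new, c_new

    # canonical signs: dominant X loading positive; covariance non-negative
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    if float(w @ cross @ c) < 0:
        c = -c
    return xs @ w, ys @ c


def coupling_significance(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
    permute_block: str = "y",
    add_one: bool = False,
    **fit_kwargs: object,
) -> CouplingResult:
    """Permutation significance of the first-component Spearman correlation.

    The sample order of one block (``permute_block``: "x" or "y") is shuffled
    ``n_permutations`` times, components are refit per permutation, and
    p = #(null rho > observed rho) / n_permutations (strict inequality, the
    literal counting rule; ``add_one=True`` uses (1+hits)/(1+n) instead).
    Deterministic given data and seed.
    """
    if permute_block not in ("x", "y"):
        raise ValueError("permute_block must be 'x' or 'y'")
    sx, sy = first_components(x, y, **fit_kwargs)
    rho_obs = float(spearmanr(sx, sy).statistic)

    rng = np.random.default_rng(seed)
    n = np.asarray(x).shape[0]
    null = []
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if permute_block == "y":
            psx, psy = first_components(x, np.asarray(y)[perm], **fit_kwargs)
        else:
            psx, psy = first_components(np.asarray(x)[perm], y, **fit_kwargs)
        null.append(float(spearmanr(psx, psy).statistic))
    hits = sum(r > rho_obs for r in null)
    p = (1 + hits) / (1 + n_permutations) if add_one else hits / n_permutations
    return CouplingResult(
        rho_observed=rho_obs,
        null_rhos=tuple(null),
        p=float(p),
        n_permutations=n_permutations,
    )
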