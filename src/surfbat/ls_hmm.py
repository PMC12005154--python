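"""Li-Stephens haplotype-copying HMM over a phased reference panel.

The hidden state at typed site j is the reference haplotype the target is
copying from; transitions depend on the genetic distance between adjacent
typed sites and the panel size, emissions allow the mosaic to be imperfect
(recent mutation or genotyping error).  Posteriors come from the scaled
forward-backward recursion; a brute-force path-enumeration oracle is
provided for tiny instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HmmParams:
    """Copying-model parameters.

    ne
        Effective population size in the classic Li-Stephens recombination
        scaling (dimensionless, default 20 000 — the common imputation
        default).
    eps
        Per-site allele mismatch probability (symmetric), default 1e-4.
    min_switch
        Floor on the per-interval switch probability for strictly positive
        genetic distances, so long maps never produce an exactly absorbing
        chain.
    """

    ne: float = 20_000.0
    eps: float = 1e-4
    min_switch: float = 1e-12

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("ne must be positive")
        if not (0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")


def switch_prob(d_cm, n_haplotypes: int, params: HmmParams):
    """Per-interval switch probability r = 1 - exp(-0.04 * ne * d_cM / H).

    This is the classic r_j = 1 - exp(-4 Ne g_j / H) with g_j in Morgans.
    The full transition kernel k -> l is ``r/H + (1-r)*[k == l]``.  Zero
    distance gives r = 0 (identity kernel); positive distances are floored
    at ``params.min_switch``.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 reference haplotypes")
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distances must be non-negative")
    r = 1.0 - np.exp(-0.04 * params.ne * d / n_haplotypes)
    r = np.where(d > 0, np.maximum(r, params.min_switch), 0.0)
    return float(r) if r.ndim == 0 else r


def emission_prob(target_allele: int, panel_allele: int, params: HmmParams) -> float:
    """1 - eps on allele match, eps on mismatch."""
    return 1.0 - params.eps if target_allele == panel_allele else params.eps


def forward_backward_batch(
    targets: np.ndarray,
    panel: np.ndarray,
    cm: np.ndarray,
    params: HmmParams,
) -> np.ndarray:
    """Scaled forward-backward posteriors for a batch of target haplotypes.

    Parameters
    ----------
    targets
        (M, T) binary alleles of M target haplotypes at T typed sites.
    panel
        (T, K) binary reference alleles at the same sites.
    cm
        (T,) cumulative genetic positions; must be non-decreasing.
    params
        :class:`HmmParams`.

    Returns
    -------
    (M, T, K) array of posterior copying probabilities, each row over K
    summing to one.  Per-site rescaling keeps the recursion in the
    normalized domain, so instances with very many sites do not underflow.
    """
    targets = np.asarray(targets, dtype=np.uint8)
    if targets.ndim == 1:
        targets = targets[None, :]
    panel = np.asarray(panel, dtype=np.uint8)
    cm = np.asarray(cm, dtype=float)
    M, T = targets.shape
    K = panel.shape[1]
    if T < 1:
        raise ValueError("need at least one typed site")
    if K < 2:
        raise ValueError("need at least 2 reference haplotypes")
    if panel.shape[0] != T or cm.shape[0] != T:
        raise ValueError("panel/cm shapes disagree with targets")
    d = np.diff(cm)
    if np.any(d < -1e-12):
        raise ValueError("cm must be non-decreasing")
    r = switch_prob(np.maximum(d, 0.0), K, params)
    r = np.atleast_1d(r)

    eps = params.eps
    match = targets[:, :, None] == panel[None, :, :]  # (M, T, K) bool

    def emis(t: int) -> np.ndarray:
        return np.where(match[:, t, :], 1.0 - eps, eps)

    fwd = np.empty((T, M, K))
    f = emis(0) / K
    c = f.sum(axis=1, keepdims=True)
    if np.any(c <= 0):
        raise FloatingPointError("zero forward likelihood")
    f = f / c
    fwd[0] = f
    for t in range(1, T):
        rt = r[t - 1]
        # uniform-copying kernel applied to a normalized row: (1-r) f + r/K
        f = ((1.0 - rt) * f + rt / K) * emis(t)
        c = f.sum(axis=1, keepdims=True)
        if np.any(c <= 0):
            raise FloatingPointError("zero forward likelihood")
        f = f / c
        fwd[t] = f

    post = np.empty((M, T, K))
    b = np.ones((M, K))
    post[:, T - 1, :] = fwd[T - 1]
    for t in range(T - 2, -1, -1):
        w = emis(t + 1) * b
        rt = r[t]
        b = (1.0 - rt) * w + (rt / K) * w.sum(axis=1, keepdims=True)
        b = b / b.sum(axis=1, keepdims=True)
        p = fwd[t] * b
        post[:, t, :] = p / p.sum(axis=1, keepdims=True)
    return post


def forward_backward(
    target_hap: np.ndarray,
    panel: np.ndarray,
    cm: np.ndarray,
    params: HmmParams,
) -> np.ndarray:
    """Posterior copying probabilities (T, K) for one target haplotype."""
    return forward_backward_batch(np.asarray(target_hap)[None, :], panel, cm, params)[0]


def brute_force_posteriors(
    target_hap: np.ndarray,
    panel: np.ndarray,
    cm: np.ndarray,
    params: HmmParams,
    max_paths: int = 1_000_000,
) -> np.ndarray:
    """Posteriors by explicit enumeration of all K**T hidden-state paths.

    Test oracle only; refuses instances with more than ``max_paths`` paths.
    """
    target = np.asarray(target_hap, dtype=np.uint8)
    panel = np.asarray(panel, dtype=np.uint8)
    cm = np.asarray(cm, dtype=float)
    T = target.shape[0]
    K = panel.shape[1]
    if K < 2:
        raise ValueError("need at least 2 reference haplotypes")
    if K**T > max_paths:
        raise ValueError(f"instance too large for enumeration ({K}**{T} paths)")
    r = np.atleast_1d(switch_prob(np.maximum(np.diff(cm), 0.0), K, params))
    eps = params.eps

    def emit(t: int, k: int) -> float:
        return 1.0 - eps if target[t] == panel[t, k] else eps

    marg = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        w = (1.0 / K) * emit(0, path[0])
        for t in range(1, T):
            rt = r[t - 1]
            trans = rt / K + (1.0 - rt) * (path[t] == path[t - 1])
            w *= trans * emit(t, path[t])
        total += w
        for t in range(T):
            marg[t, path[t]] += w
    if total <= 0:
        raise FloatingPointError("zero total likelihood")
    return marg / total
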