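"""Block analysis with weighted bootstrap for correlated, reweighted data.

MD snapshots are strongly autocorrelated, so the naive standard error of a
(weighted) average underestimates the true uncertainty.  The series is
partitioned into consecutive blocks; for each block size a bootstrap draws
blocks with replacement with probability proportional to the block's summed
FEP weight and recomputes the weighted statistic; the spread over replicates
is the error at that block size.  Once blocks are longer than the
correlation time the curve plateaus; the reported error averages the largest
block sizes of the scan.

Grid convention: every integer block size from 1 to n/50, uniformly
subsampled to at most 400 sizes; the "last 200" average then refers to the
200 largest grid entries (all of them, with a log note, if fewer exist).
The n/50 cap keeps at least 50 blocks at every size: with fewer blocks the
empirical variance of the block means carries chi^2 noise of tens of
percent (and the (m-1)/m bootstrap factor), which would dominate the
plateau average; it presumes the correlation time is well below n/500
frames, comfortably true for typical snapshot strides.  The trailing
partial block is discarded so that weight-proportional block sampling is
not distorted by unequal block lengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .reweight import WeightedEnsemble

__all__ = ["BlockErrorCurve", "block_bootstrap_error", "combine_fit_errors"]

log = logging.getLogger(__name__)

_STATS = ("mean", "variance", "covariance")


@dataclass
class BlockErrorCurve:
    """Bootstrap error of a weighted statistic as a function of block size."""

    block_sizes: np.ndarray
    error: np.ndarray
    final_error: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.block_sizes) <= 0):
            raise ValueError("block sizes must be strictly increasing")
        if self.final_error < 0:
            raise ValueError("final_error must be >= 0")


def _block_size_grid(n: int, max_sizes: int) -> np.ndarray:
    bmax = max(n // 50, 1)
    if n < 8:
        raise ValueError(f"need at least 8 frames for block analysis, got {n}")
    grid = np.unique(np.round(np.linspace(1, bmax, min(max_sizes, bmax))).astype(int))
    return grid


def _replicate_stats(counts: np.ndarray, bsums: dict[str, np.ndarray],
                     statistic: str) -> np.ndarray:
    """Statistic per bootstrap replicate from block-sum linear combinations."""
    sw = counts @ bsums["w"]
    swx = counts @ bsums["wx"]
    mx = swx / sw
    if statistic == "mean":
        return mx
    swy = counts @ bsums["wy"]
    my = swy / sw
    sxy = counts @ bsums["wxy"]
    return sxy / sw - mx * my


def block_bootstrap_error(values: np.ndarray,
                          ensemble: WeightedEnsemble | np.ndarray,
                          statistic: str = "mean",
                          second: np.ndarray | None = None,
                          n_boot: int = 1000,
                          seed: int = 0,
                          max_sizes: int = 400,
                          last_sizes: int = 200) -> BlockErrorCurve:
    """Weighted block-bootstrap error of a statistic of a per-frame series.

    Parameters
    ----------
    values : per-frame series.
    ensemble : a :class:`WeightedEnsemble` or a bare weight vector.
    statistic : "mean", "variance" or "covariance" (then ``second`` is the
        partner series; "variance" is covariance of a series with itself).
    n_boot : bootstrap replicates per block size.
    seed : seeds all resampling; runs are bit-reproducible.
    """
    x = np.asarray(values, dtype=float)
    w = ensemble.weights if isinstance(ensemble, WeightedEnsemble) else np.asarray(ensemble, float)
    n = len(x)
    if len(w) != n:
        raise ValueError("values and weights length mismatch")
    if n < 8:
        raise ValueError(f"need at least 8 frames, got {n}")
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {_STATS}")
    if statistic == "covariance":
        if second is None:
            raise ValueError("covariance statistic needs the second series")
        y = np.asarray(second, dtype=float)
        if len(y) != n:
            raise ValueError("second series length mismatch")
    else:
        y = x
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")

    sizes = _block_size_grid(n, max_sizes)
    if len(sizes) < last_sizes:
        log.info("only %d block sizes available; final error averages all of them",
                 len(sizes))
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    errors = np.empty(len(sizes))
    for i, b in enumerate(sizes):
        nblk = n // b
        m = nblk * b
        shape = (nblk, b)
        bw = w[:m].reshape(shape).sum(axis=1)
        bsums = {
            "w": bw,
            "wx": (w[:m] * x[:m]).reshape(shape).sum(axis=1),
            "wy": (w[:m] * y[:m]).reshape(shape).sum(axis=1),
            "wxy": (w[:m] * x[:m] * y[:m]).reshape(shape).sum(axis=1),
        }
        p = bw / bw.sum()
        rng = np.random.default_rng(children[i])
        stats = np.empty(n_boot)
        # multinomial counts instead of index lists: the statistic is linear
        # in the block sums, so only how often each block is drawn matters
        chunk = max(1, min(n_boot, int(2e7 // max(nblk, 1))))
        done = 0
        while done < n_boot:
            k = min(chunk, n_boot - done)
            counts = rng.multinomial(nblk, p, size=k)
            stats[done:done + k] = _replicate_stats(counts, bsums, statistic)
            done += k
        errors[i] = stats.std()
    final = float(errors[-last_sizes:].mean())
    return BlockErrorCurve(block_sizes=sizes, error=errors, final_error=final,
                           n_boot=n_boot, seed=seed)


def combine_fit_errors(delta_ave: float, delta_ind: float) -> float:
    """Quadrature combination of the least-squares and point-indeterminacy
    error channels of a fit: sqrt(delta_ave^2 + delta_ind^2)."""
    if delta_ave < 0 or delta_ind < 0:
        raise ValueError("error components must be non-negative")
    return math.hypot(delta_ave, delta_ind)
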