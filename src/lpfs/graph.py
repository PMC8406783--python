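"""Sample-similarity graph construction.

Samples are nodes of a fully connected undirected graph whose edge weights
come from a Gaussian (RBF) kernel on the expression profiles,

    w_ij = exp(-||x_i - x_j||^2 / (2 delta^2))   for i != j,   w_ii = 0.

The propagation step operates on the symmetrically normalized matrix
Z = D^{-1/2} W D^{-1/2} with D = diag(row sums of W); the spectral radius of
Z is at most 1, which makes the propagation system ((1+mu)I - Z) positive
definite for every mu > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datamodel import ExpressionMatrix, LPFSConfig, ValidationError


class IsolatedSampleError(ValueError):
    """A sample has zero total edge weight, so normalization is undefined."""


@dataclass(frozen=True)
class SampleGraph:
    """Gaussian-kernel sample graph with its normalized weight matrix."""

    W: np.ndarray        # (n, n) symmetric, zero diagonal, entries in [0, 1]
    degrees: np.ndarray  # (n,) positive row sums of W
    Z: np.ndarray        # D^{-1/2} W D^{-1/2}

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]


def compute_weights(xm: ExpressionMatrix, delta: float) -> np.ndarray:
    """Gaussian-kernel weight matrix over samples with zero self-weights."""
    if not delta > 0:
        raise ValidationError(f"delta must be > 0, got {delta}")
    sq = squareform(pdist(xm.values, metric="sqeuclidean"))
    W = np.exp(-sq / (2.0 * delta * delta))
    np.fill_diagonal(W, 0.0)
    # pdist guarantees symmetry up to representation; enforce it exactly
    return (W + W.T) / 2.0


def normalize_weights(W: np.ndarray, sample_ids: tuple[str, ...] | None = None) -> SampleGraph:
    """Symmetric normalization Z = D^{-1/2} W D^{-1/2}.

    Raises
    ------
    IsolatedSampleError
        If a sample has zero degree (all its kernel weights underflowed).
        Increasing the bandwidth ``delta`` reconnects such samples.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError(f"W must be square, got shape {W.shape}")
    if not np.allclose(W, W.T):
        raise ValidationError("W must be symmetric")
    if np.any(W < 0):
        raise ValidationError("W must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValidationError("W must have a zero diagonal")
    degrees = W.sum(axis=1)
    if np.any(degrees <= 0):
        i = int(np.argmax(degrees <= 0))
        name = sample_ids[i] if sample_ids is not None else f"index {i}"
        raise IsolatedSampleError(
            f"sample {name} is isolated (zero total edge weight); "
            f"increase the kernel bandwidth delta to reconnect it"
        )
    inv_sqrt_d = 1.0 / np.sqrt(degrees)
    Z = W * np.outer(inv_sqrt_d, inv_sqrt_d)
    return SampleGraph(W=W, degrees=degrees, Z=Z)


def suggest_delta(xm: ExpressionMatrix) -> float:
    """Median pairwise Euclidean distance between distinct sample profiles.

    With this bandwidth the kernel exponents are O(1), giving informative
    (neither saturated nor underflowed) edge weights on any data scale.
    Zero-distance pairs (replicate profiles) are excluded so duplicating
    samples does not shrink the bandwidth; a fully degenerate dataset
    (all samples identical) falls back to 1.0.  Advisory only; any positive
    value may be passed explicitly.
    """
    dists = pdist(xm.values, metric="euclidean")
    dists = dists[dists > 0]
    if dists.size == 0:
        return 1.0
    return float(np.median(dists))


def resolve_delta(xm: ExpressionMatrix, delta: float | str) -> float:
    """Turn a config bandwidth (number or ``"auto"``) into a number."""
    if isinstance(delta, str):
        return suggest_delta(xm)
    return float(delta)


def build_sample_graph(xm: ExpressionMatrix, delta: float | str) -> SampleGraph:
    """Convenience: kernel weights plus normalization in one call."""
    W = compute_weights(xm, resolve_delta(xm, delta))
    return normalize_weights(W, xm.sample_ids)
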