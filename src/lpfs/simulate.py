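"""Synthetic multi-class expression data with planted marker genes.

Emulates a factorial bulk-RNA-seq design in which every sample belongs to
one of ``c`` exchangeable categories (e.g. genotype x age groups) and each
category owns a disjoint block of marker genes whose mean is shifted by
``effect`` noise standard deviations above the shared background.  All
other genes are pure noise.  Values are Gaussian around the background
mean, truncated at zero so matrices are valid non-negative expression.

The generator is deliberately simpler than real RNA-seq: no library-size
variation, no count overdispersion, no correlated gene modules.  It tests
the algorithm's recovery behavior, not an RNA-seq noise model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionMatrix, LabelSpec, ValidationError


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    labels: np.ndarray                      # (n,) categories 1..c
    markers: tuple[tuple[str, ...], ...]    # disjoint marker gene ids per category
    effect: float                           # mean shift in noise-SD units
    base_mean: float
    noise_sd: float

    def marker_indicator(self, gene_ids: tuple[str, ...]) -> np.ndarray:
        """Binary vector over ``gene_ids``: 1 iff the gene is any category's marker."""
        all_markers = {g for cat in self.markers for g in cat}
        return np.array([1 if g in all_markers else 0 for g in gene_ids], dtype=int)


def simulate_dataset(
    n_per_category: int = 8,
    c: int = 6,
    m: int = 300,
    markers_per_category: int = 10,
    effect: float = 2.0,
    base_mean: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a balanced ``c``-category design with planted markers.

    Gene ``g`` in a sample of category ``k`` is drawn from
    ``Normal(base_mean + effect * noise_sd * 1{g in markers_k}, noise_sd)``
    truncated at 0.  Marker blocks are the leading ``c * markers_per_category``
    gene columns, one disjoint block per category.  Identifiers and values
    are fully determined by ``seed``.
    """
    if n_per_category < 1 or c < 1 or m < 1:
        raise ValidationError("n_per_category, c and m must all be >= 1")
    if markers_per_category < 0:
        raise ValidationError("markers_per_category must be >= 0")
    if c * markers_per_category > m:
        raise ValidationError(
            f"{c} x {markers_per_category} marker genes do not fit into m={m}"
        )
    if not noise_sd > 0:
        raise ValidationError(f"noise_sd must be > 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    n = n_per_category * c
    labels = np.repeat(np.arange(1, c + 1), n_per_category)
    gene_ids = tuple(f"gene{j:05d}" for j in range(m))
    sample_ids = tuple(
        f"cat{k}_rep{r}" for k in range(1, c + 1) for r in range(1, n_per_category + 1)
    )
    means = np.full((n, m), float(base_mean))
    markers: list[tuple[str, ...]] = []
    for k in range(c):
        cols = np.arange(k * markers_per_category, (k + 1) * markers_per_category)
        markers.append(tuple(gene_ids[j] for j in cols))
        rows = np.flatnonzero(labels == k + 1)
        means[np.ix_(rows, cols)] += effect * noise_sd
    values = np.maximum(rng.normal(means, noise_sd), 0.0)
    xm = ExpressionMatrix(values=values, sample_ids=sample_ids, gene_ids=gene_ids)
    truth = SyntheticTruth(
        labels=labels,
        markers=tuple(markers),
        effect=float(effect),
        base_mean=float(base_mean),
        noise_sd=float(noise_sd),
    )
    return xm, truth


def full_labels(truth: SyntheticTruth) -> LabelSpec:
    """LabelSpec carrying every true category label."""
    return LabelSpec(labels=truth.labels, c=int(truth.labels.max()))


def make_partial_labels(
    truth: SyntheticTruth,
    labeled_fraction: float,
    seed: int = 0,
) -> LabelSpec:
    """Mask labels uniformly at random, stratified per category.

    Exactly ``floor(labeled_fraction * n_k)`` samples stay labeled in each
    category ``k``; a fraction too small to keep one label per category is
    an error.
    """
    if not 0.0 < labeled_fraction <= 1.0:
        raise ValidationError(f"labeled_fraction must lie in (0, 1], got {labeled_fraction}")
    rng = np.random.default_rng(seed)
    labels = truth.labels.copy()
    c = int(labels.max())
    masked = labels.copy()
    for k in range(1, c + 1):
        rows = np.flatnonzero(labels == k)
        n_keep = int(np.floor(labeled_fraction * rows.size))
        if n_keep < 1:
            raise ValidationError(
                f"labeled_fraction={labeled_fraction} keeps no label in category {k}"
            )
        keep = rng.choice(rows, size=n_keep, replace=False)
        drop = np.setdiff1d(rows, keep)
        masked[drop] = 0
    return LabelSpec(labels=masked, c=c)
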