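"""Core domain types for LPFS: expression matrices, sample labels, configuration.

The canonical in-memory layout is samples x genes: ``values[i, j]`` is the
expression level of gene ``j`` in sample ``i``.  Readers accept transposed
files and re-orient on load (see :mod:`lpfs.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

#: Sentinel used in label files for samples without a known category.
UNLABELED = "unlabeled"


class ValidationError(ValueError):
    """Raised when an input object violates a structural contract."""


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(x) for x in ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if x in seen or seen.add(x))
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated samples-by-genes non-negative expression matrix.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_genes)``; finite, non-negative.
    sample_ids, gene_ids
        Unique string identifiers for rows and columns respectively.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError(f"expression matrix must be 2-D, got shape {values.shape}")
        n, m = values.shape
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise ValidationError("need at least 1 gene")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"missing or non-finite value at sample index {i}, gene index {j}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression value at sample index {i}, gene index {j}"
            )
        sample_ids = _check_unique(self.sample_ids, "sample")
        gene_ids = _check_unique(self.gene_ids, "gene")
        if len(sample_ids) != n:
            raise ValidationError(f"{len(sample_ids)} sample ids for {n} rows")
        if len(gene_ids) != m:
            raise ValidationError(f"{len(gene_ids)} gene ids for {m} columns")
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "gene_ids", gene_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene column indices."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, idx],
            sample_ids=self.sample_ids,
            gene_ids=tuple(self.gene_ids[i] for i in idx),
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[idx, :],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            gene_ids=self.gene_ids,
        )


@dataclass(frozen=True)
class LabelSpec:
    """Per-sample category assignments over ``{1..c}``, with 0 meaning unlabeled.

    ``labels[i]`` is the category of sample ``i`` or 0 for an unlabeled sample.
    At least one sample must carry a label, otherwise propagation has no
    anchor and the problem is vacuous.
    """

    labels: np.ndarray
    c: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1:
            raise ValidationError("labels must be a 1-D vector")
        if self.c < 1:
            raise ValidationError(f"number of categories must be >= 1, got {self.c}")
        bad = (labels < 0) | (labels > self.c)
        if np.any(bad):
            i = int(np.argwhere(bad)[0][0])
            raise ValidationError(
                f"label {labels[i]} of sample index {i} outside 1..{self.c}"
            )
        if not np.any(labels > 0):
            raise ValidationError("at least one sample must be labeled")
        labels = labels.copy()
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_labeled(self) -> int:
        return int(np.sum(self.labels > 0))


def build_initial_label_matrix(spec: LabelSpec) -> np.ndarray:
    """Build the n x c one-hot initial label matrix Y.

    ``Y[i, j-1] = 1`` iff sample ``i`` carries label ``j``; unlabeled samples
    produce an all-zero row, which removes their anchoring term from the
    propagation step (the semi-supervised reading).
    """
    n, c = spec.n_samples, spec.c
    Y = np.zeros((n, c), dtype=float)
    labeled = spec.labels > 0
    Y[np.flatnonzero(labeled), spec.labels[labeled] - 1] = 1.0
    return Y


def prefilter_genes(xm: ExpressionMatrix, k: int, criterion: str = "variance") -> ExpressionMatrix:
    """Keep the ``k`` genes with the largest mean or sample variance.

    Robustly high-expressed housekeeping genes carry little class signal, so
    upstream pipelines commonly restrict to the few thousand most variable
    (or most expressed) genes before model fitting.  Retained genes keep
    their input order; ties are broken toward the earlier column.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if criterion not in ("mean", "variance"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    if k >= xm.n_genes:
        return xm
    if criterion == "mean":
        stat = xm.values.mean(axis=0)
    else:
        stat = xm.values.var(axis=0, ddof=1)
    top = np.argsort(-stat, kind="stable")[:k]
    return xm.subset_genes(np.sort(top))


_AUTO_DELTA = "auto"


@dataclass(frozen=True)
class LPFSConfig:
    """Hyper-parameters of the full LPFS procedure.

    Attributes
    ----------
    mu : float
        Anchor weight in (0, 1) balancing propagated labels against initial
        labels.
    beta : float
        Sparsity weight in (0, 1) on the l2,1 penalty of the feature
        selection matrix.
    delta : float or "auto"
        Gaussian kernel bandwidth for the sample graph.  ``"auto"`` uses the
        median pairwise sample distance; the fixed default 200 matches
        bulk RNA-seq abundance scales where squared distances are of order
        1e4-1e5.
    s : int or None
        Number of top genes reported per category; ``None`` keeps every gene
        surviving the final elimination round.
    inner_rounds : int
        Number of fit / rank / remove elimination rounds.
    removal_size : int
        Genes removed per elimination round.
    repetitions : int
        Independent random restarts of the whole elimination schedule.
    consensus_min_count : int
        Minimum number of restarts a gene must appear in ("strictly more
        than half" of 100 runs gives the default 51).
    h_mode : str
        Whether the F-subproblem is fit against the binarized cluster
        indicator ("binary", default) or the continuous propagation result
        ("continuous").
    """

    mu: float = 0.2
    beta: float = 0.2
    delta: float | str = 200.0
    s: int | None = None
    inner_rounds: int = 5
    removal_size: int = 1000
    repetitions: int = 100
    consensus_min_count: int = 51
    f_tol: float = 1e-4
    outer_tol: float = 1e-4
    f_max_iter: int = 500
    outer_max_iter: int = 50
    h_mode: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        # Intended operating range for both weights is (0, 1); larger mu is
        # permitted for diagnostics (mu -> inf pins labeled samples to Y),
        # and beta = 0 disables the sparsity penalty entirely.
        if not self.mu > 0:
            raise ValidationError(f"mu must be > 0, got {self.mu}")
        if self.beta < 0:
            raise ValidationError(f"beta must be >= 0, got {self.beta}")
        if isinstance(self.delta, str):
            if self.delta != _AUTO_DELTA:
                raise ValidationError(f"delta must be a positive number or 'auto', got {self.delta!r}")
        elif not self.delta > 0:
            raise ValidationError(f"delta must be > 0, got {self.delta}")
        if self.s is not None and self.s < 1:
            raise ValidationError(f"s must be >= 1 or None, got {self.s}")
        for name in ("inner_rounds", "removal_size", "repetitions",
                     "consensus_min_count", "f_max_iter", "outer_max_iter"):
            v = getattr(self, name)
            if v < 1:
                raise ValidationError(f"{name} must be >= 1, got {v}")
        for name in ("f_tol", "outer_tol"):
            v = getattr(self, name)
            if not v > 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        if self.h_mode not in ("binary", "continuous"):
            raise ValidationError(f"h_mode must be 'binary' or 'continuous', got {self.h_mode!r}")

    def with_(self, **kwargs) -> "LPFSConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "LPFSConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
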