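"""Readers and writers for expression matrices, label files, key-gene tables
and YAML configuration, plus logging setup."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    UNLABELED,
    ExpressionMatrix,
    LabelSpec,
    LPFSConfig,
    ValidationError,
)
from .filtering import KeyGene, KeyGeneSets

logger = logging.getLogger(__name__)


def _read_table(path) -> pd.DataFrame:
    # TSV by default, comma accepted: sniff the delimiter from the header line.
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)


def load_expression_matrix(path, genes_in_rows: bool = False) -> ExpressionMatrix:
    """Load a delimited expression matrix (header row + identifier column).

    Files may store samples in rows (default) or genes in rows
    (``genes_in_rows=True``); the returned matrix is always samples x genes.
    Blank or non-numeric cells raise a validation error naming the cell.
    """
    df = _read_table(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raw = df.iat[i, j]
        what = "missing value" if pd.isna(raw) or str(raw).strip() == "" else f"non-numeric value {raw!r}"
        raise ValidationError(
            f"{what} at row {df.index[i]!r}, column {df.columns[j]!r} of {path}"
        )
    if genes_in_rows:
        numeric = numeric.T
    return ExpressionMatrix(
        values=numeric.to_numpy(dtype=float),
        sample_ids=tuple(str(s) for s in numeric.index),
        gene_ids=tuple(str(g) for g in numeric.columns),
    )


def write_expression_matrix(xm: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(xm.values, index=list(xm.sample_ids), columns=list(xm.gene_ids))
    df.to_csv(path, sep="\t", index_label="sample_id")


def load_labels(path, sample_ids: tuple[str, ...], c: int | None = None) -> LabelSpec:
    """Load a two-column file ``sample_id<TAB>label`` aligned to ``sample_ids``.

    Labels are integers in 1..c or the literal ``unlabeled``.  A header row
    is accepted and skipped.  ``c`` defaults to the largest label present.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValidationError(f"label file {path} must have exactly two columns")
    first = str(df.iat[0, 1]).strip().lower()
    if first != UNLABELED and not first.lstrip("-").isdigit():
        df = df.iloc[1:]  # header row
    mapping: dict[str, int] = {}
    for _, (sid, lab) in df.iterrows():
        lab = str(lab).strip().lower()
        mapping[str(sid)] = 0 if lab == UNLABELED else int(lab)
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValidationError(f"label file {path} lacks samples: {missing[:5]}")
    labels = np.array([mapping[s] for s in sample_ids], dtype=int)
    if c is None:
        c = int(labels.max())
    return LabelSpec(labels=labels, c=c)


def write_labels(sample_ids, labels, path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def write_key_genes(key_sets: KeyGeneSets, path) -> None:
    """Write one TSV row per (category, gene, occurrence_count, mean_F_score).

    Rows are sorted by category then descending score; categories with an
    empty consensus contribute no rows.
    """
    rows = [
        {
            "category": j + 1,
            "gene_id": kg.gene_id,
            "occurrence_count": kg.occurrence_count,
            "mean_F_score": kg.mean_score,
        }
        for j, cat in enumerate(key_sets.per_category)
        for kg in cat
    ]
    header = ["category", "gene_id", "occurrence_count", "mean_F_score"]
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


def read_key_genes(path, c: int, repetitions: int, threshold: int) -> KeyGeneSets:
    """Inverse of :func:`write_key_genes` (the file stores no run metadata)."""
    df = pd.read_csv(path, sep="\t")
    per_category: list[tuple[KeyGene, ...]] = []
    for j in range(1, c + 1):
        sub = df[df["category"] == j]
        per_category.append(
            tuple(
                KeyGene(
                    gene_id=str(r.gene_id),
                    occurrence_count=int(r.occurrence_count),
                    mean_score=float(r.mean_F_score),
                )
                for r in sub.itertuples()
            )
        )
    return KeyGeneSets(
        per_category=tuple(per_category), repetitions=repetitions, threshold=threshold
    )


def load_config(path=None, **overrides) -> LPFSConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return LPFSConfig.from_dict(data)


def save_config(cfg: LPFSConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def setup_logging(verbosity: int = 1) -> None:
    """Timestamped logging to stderr; 0 = warnings only, 1 = info, 2 = debug."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%d %H:%M:%S",
        force=True,
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
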