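"""Expression input handling: quantile normalization, alignment, filtering.

Expression comes in as features x samples matrices of nonnegative RPKM-like
(mRNA) or RPM-like (miRNA) values. Within a cohort the per-sample
distributions are made identical by quantile normalization; each sample's
mRNA/miRNA vectors are then inner-joined with the seed-match matrix, and
miRNAs that are not expressed in a sample are dropped before modelling so
that zero-probability entries reflect absent sites, not absent miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seedmatch import SeedMatchMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ExpressionPair",
    "read_expression",
    "write_expression",
    "read_manifest",
    "quantile_normalize",
    "align",
    "filter_unexpressed_mirnas",
]


@dataclass
class ExpressionMatrix:
    """Nonnegative features x samples expression values with identifiers."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/inf); "
                             "missing values are not imputed")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


@dataclass
class ExpressionPair:
    """One sample's aligned observed mRNA vector and miRNA vector."""

    gene_ids: list[str]
    mirna_ids: list[str]
    x_obs: np.ndarray
    z: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.x_obs = np.asarray(self.x_obs, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.x_obs.shape != (len(self.gene_ids),):
            raise ValueError("x_obs length does not match gene_ids")
        if self.z.shape != (len(self.mirna_ids),):
            raise ValueError("z length does not match mirna_ids")
        for name, v in (("x_obs", self.x_obs), ("z", self.z)):
            if np.any(~np.isfinite(v)):
                raise ValueError(f"{name} must be finite")
            if np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative")


def read_expression(path) -> ExpressionMatrix:
    """Read a features x samples TSV (first column ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


def write_expression(mat: ExpressionMatrix, path) -> None:
    mat.to_frame().to_csv(path, sep="\t", index_label="feature")


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest TSV: sample_id, condition {normal,tumor}, pair_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "condition", "pair_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    bad = set(df["condition"]) - {"normal", "tumor"}
    if bad:
        raise ValueError(f"unknown conditions in manifest: {sorted(bad)}")
    return df


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common per-rank-mean reference distribution.

    The reference is the mean across samples of each column's sorted values;
    entry j of every column is replaced by the reference value at its rank.
    Tied values within a column receive the mean of the reference values at
    their tied ranks, so the map is deterministic and rank-preserving.
    """
    if mat.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    v = mat.values
    order = np.sort(v, axis=0)
    reference = order.mean(axis=1)

    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = v[:, j]
        sort_idx = np.argsort(col, kind="stable")
        normalized = np.empty_like(col)
        # walk runs of tied values in sorted order; each run gets the mean
        # of the reference values occupying its rank span
        i = 0
        n = len(col)
        while i < n:
            h = i
            while h + 1 < n and col[sort_idx[h + 1]] == col[sort_idx[i]]:
                h += 1
            normalized[sort_idx[i:h + 1]] = reference[i:h + 1].mean()
            i = h + 1
        out[:, j] = normalized
    return ExpressionMatrix(list(mat.feature_ids), list(mat.sample_ids), out)


def align(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    C: SeedMatchMatrix,
) -> tuple[list[ExpressionPair], SeedMatchMatrix]:
    """Inner-join expression with the seed matrix on gene/miRNA identifiers.

    Returns one :class:`ExpressionPair` per shared sample, over the
    intersection of identifiers in the seed matrix's canonical order,
    together with the correspondingly restricted seed matrix.
    """
    samples = [s for s in mrna.sample_ids if s in set(mirna.sample_ids)]
    if not samples:
        raise ValueError("no shared sample ids between mRNA and miRNA matrices")

    genes = [g for g in C.genes if g in set(mrna.feature_ids)]
    mirnas = [m for m in C.mirnas if m in set(mirna.feature_ids)]
    if not genes:
        examples = C.genes[:3]
        raise ValueError(
            f"no gene overlap between expression and seed matrix "
            f"(e.g. seed-matrix genes {examples} absent from expression)"
        )
    if not mirnas:
        examples = C.mirnas[:3]
        raise ValueError(
            f"no miRNA overlap between expression and seed matrix "
            f"(e.g. seed-matrix miRNAs {examples} absent from expression)"
        )
    logger.info(
        "align: kept %d/%d genes, %d/%d miRNAs, %d shared samples",
        len(genes), C.n_genes, len(mirnas), C.n_mirnas, len(samples),
    )
    C_sub = C.subset(genes, mirnas)
    mrna_df = mrna.to_frame().loc[genes]
    mirna_df = mirna.to_frame().loc[mirnas]
    pairs = [
        ExpressionPair(
            gene_ids=list(genes),
            mirna_ids=list(mirnas),
            x_obs=mrna_df[s].to_numpy(float),
            z=mirna_df[s].to_numpy(float),
            sample_id=s,
        )
        for s in samples
    ]
    return pairs, C_sub


def filter_unexpressed_mirnas(
    pair: ExpressionPair,
    C: SeedMatchMatrix,
    threshold: float = 0.0,
) -> tuple[ExpressionPair, SeedMatchMatrix]:
    """Drop miRNAs with expression <= threshold from the pair and from C's columns."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = pair.z > threshold
    if not keep.any():
        logger.warning("all %d miRNAs are unexpressed at threshold %g",
                       len(pair.mirna_ids), threshold)
    kept_ids = [m for m, k in zip(pair.mirna_ids, keep) if k]
    new_pair = ExpressionPair(
        gene_ids=list(pair.gene_ids),
        mirna_ids=kept_ids,
        x_obs=pair.x_obs.copy(),
        z=pair.z[keep],
        sample_id=pair.sample_id,
    )
    return new_pair, C.subset(mirnas=kept_ids)
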