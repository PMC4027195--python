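"""Seed-match count matrices.

The central sequence-derived input to the competition models is the N x M
matrix ``C`` whose entry ``c[i, k]`` counts the conserved seed-match sites
that miRNA ``k`` has in the 3'UTR of gene ``i``. This module builds that
matrix from site-level annotations (TargetScan-style tables), reads and
writes it in dense and triplet TSV dialects, and provides the binarization
used by methods that only consume presence/absence of a site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteRecord",
    "SeedMatchMatrix",
    "build_from_sites",
    "read_site_table",
    "read_seed_matrix",
    "write_seed_matrix",
    "binarize",
]


@dataclass(frozen=True)
class SiteRecord:
    """One row of a site-level annotation: sites of one miRNA in one transcript's 3'UTR."""

    gene_id: str
    transcript_id: str
    utr_length: int
    mirna_id: str
    site_count: int

    def __post_init__(self) -> None:
        if self.site_count < 0:
            raise ValueError(f"site_count must be >= 0, got {self.site_count}")
        if self.utr_length < 0:
            raise ValueError(f"utr_length must be >= 0, got {self.utr_length}")


@dataclass
class SeedMatchMatrix:
    """Dense N x M matrix of nonnegative integer seed-match counts.

    Genes index the rows, miRNAs the columns. Identifier lists are unique
    and, when produced by :func:`build_from_sites` or the readers, sorted
    lexicographically so serialization is canonical.
    """

    genes: list[str]
    mirnas: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.mirnas)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.mirnas)} miRNAs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("seed-match counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("seed-match counts must be nonnegative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.mirnas)) != len(self.mirnas):
            raise ValueError("duplicate miRNA identifiers")
        for axis, what in ((1, "gene rows"), (0, "miRNA columns")):
            n_zero = int(np.sum(self.counts.sum(axis=axis) == 0))
            if n_zero:
                warnings.warn(
                    f"{n_zero} all-zero {what} in seed-match matrix", stacklevel=3
                )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.mirnas)

    def subset(self, genes: Sequence[str] | None = None,
               mirnas: Sequence[str] | None = None) -> "SeedMatchMatrix":
        """Restrict to the given identifiers, preserving this matrix's order."""
        genes = list(genes) if genes is not None else self.genes
        mirnas = list(mirnas) if mirnas is not None else self.mirnas
        gi = [self.genes.index(g) for g in genes]
        ki = [self.mirnas.index(m) for m in mirnas]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return SeedMatchMatrix(genes, mirnas, self.counts[np.ix_(gi, ki)])


def build_from_sites(records: Iterable[SiteRecord]) -> SeedMatchMatrix:
    """Aggregate site records into a seed-match matrix.

    For genes with several annotated transcripts only the transcript with
    the longest 3'UTR contributes (ties broken by lexicographically smallest
    transcript id). Counts for the same (transcript, miRNA) pair are summed.
    """
    records = list(records)
    if not records:
        raise ValueError("no site records given")

    utr_len: dict[str, int] = {}
    for r in records:
        if r.transcript_id in utr_len and utr_len[r.transcript_id] != r.utr_length:
            raise ValueError(
                f"conflicting utr_length for transcript {r.transcript_id!r}: "
                f"{utr_len[r.transcript_id]} vs {r.utr_length}"
            )
        utr_len[r.transcript_id] = r.utr_length

    # per gene: transcript with maximal UTR, tie -> smallest transcript_id
    chosen: dict[str, str] = {}
    for r in records:
        cur = chosen.get(r.gene_id)
        if cur is None:
            chosen[r.gene_id] = r.transcript_id
        else:
            better = (utr_len[r.transcript_id], ) + (r.transcript_id, )
            # longer UTR wins; on equal length the smaller id wins
            if (utr_len[r.transcript_id] > utr_len[cur]
                    or (utr_len[r.transcript_id] == utr_len[cur]
                        and r.transcript_id < cur)):
                chosen[r.gene_id] = r.transcript_id

    agg: dict[tuple[str, str], int] = {}
    mirnas: set[str] = set()
    for r in records:
        mirnas.add(r.mirna_id)
        if r.transcript_id != chosen[r.gene_id]:
            continue
        key = (r.gene_id, r.mirna_id)
        agg[key] = agg.get(key, 0) + r.site_count

    genes = sorted(chosen)
    mirna_list = sorted(mirnas)
    counts = np.zeros((len(genes), len(mirna_list)), dtype=np.int64)
    gi = {g: i for i, g in enumerate(genes)}
    ki = {m: k for k, m in enumerate(mirna_list)}
    for (g, m), c in agg.items():
        counts[gi[g], ki[m]] = c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SeedMatchMatrix(genes, mirna_list, counts)


#: default column mapping for TargetScan-style conserved-site tables
DEFAULT_SITE_COLUMNS: Mapping[str, str] = {
    "gene_id": "Gene Symbol",
    "transcript_id": "Transcript ID",
    "utr_length": "UTR length",
    "mirna_id": "miRNA",
    "site_count": "Conserved sites total",
}


def read_site_table(path, columns: Mapping[str, str] | None = None,
                    sep: str = "\t") -> list[SiteRecord]:
    """Read a TargetScan-style conserved-site table into site records.

    ``columns`` maps the record field names to the table's column headers;
    defaults follow the TargetScan summary-count layout. miRNA family
    members are kept as separate columns of the eventual matrix (members of
    one seed family can be expressed differently, and competition within a
    family is part of the model), so the miRNA column should identify the
    member, not the family, whenever the table distinguishes them.
    """
    cols = dict(DEFAULT_SITE_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    return [
        SiteRecord(
            gene_id=str(row[cols["gene_id"]]),
            transcript_id=str(row[cols["transcript_id"]]),
            utr_length=int(row[cols["utr_length"]]),
            mirna_id=str(row[cols["mirna_id"]]),
            site_count=int(row[cols["site_count"]]),
        )
        for _, row in df.iterrows()
    ]


def _read_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_seed_matrix(path, dialect: str = "dense_tsv") -> SeedMatchMatrix:
    """Read a seed-match matrix from a dense or triplet TSV file.

    Dense: header row of miRNA ids, first column gene ids, integer cells.
    Triplet: ``gene<TAB>mirna<TAB>count`` lines; absent pairs are zero and
    duplicate pairs are rejected as ambiguous.
    """
    if dialect == "dense_tsv":
        rows = [(no, line.split("\t")) for no, line in _read_lines(path)]
        if not rows:
            raise ValueError(f"{path}: empty seed matrix file")
        header = rows[0][1]
        mirnas = header[1:]
        genes: list[str] = []
        data: list[list[int]] = []
        for lineno, fields in rows[1:]:
            genes.append(fields[0])
            try:
                vals = [int(v) for v in fields[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer count ({e})") from None
            if any(v < 0 for v in vals):
                raise ValueError(f"{path}:{lineno}: negative count")
            if len(vals) != len(mirnas):
                raise ValueError(f"{path}:{lineno}: expected {len(mirnas)} counts")
            data.append(vals)
        counts = np.array(data, dtype=np.int64).reshape(len(genes), len(mirnas))
    elif dialect == "triplet_tsv":
        entries: dict[tuple[str, str], int] = {}
        for lineno, line in _read_lines(path):
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            g, m, cs = fields
            try:
                c = int(cs)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer count {cs!r}") from None
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count {c}")
            if (g, m) in entries:
                raise ValueError(
                    f"{path}:{lineno}: duplicate entry for pair ({g}, {m})"
                )
            entries[(g, m)] = c
        if not entries:
            raise ValueError(f"{path}: empty triplet file")
        genes = sorted({g for g, _ in entries})
        mirnas = sorted({m for _, m in entries})
        counts = np.zeros((len(genes), len(mirnas)), dtype=np.int64)
        gi = {g: i for i, g in enumerate(genes)}
        ki = {m: k for k, m in enumerate(mirnas)}
        for (g, m), c in entries.items():
            counts[gi[g], ki[m]] = c
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SeedMatchMatrix(list(genes), list(mirnas), counts)


def write_seed_matrix(C: SeedMatchMatrix, path, dialect: str = "dense_tsv") -> None:
    """Write a seed-match matrix; round-trips bit-exactly with the reader."""
    with open(path, "w") as fh:
        if dialect == "dense_tsv":
            fh.write("gene\t" + "\t".join(C.mirnas) + "\n")
            for g, row in zip(C.genes, C.counts):
                fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        elif dialect == "triplet_tsv":
            for i, g in enumerate(C.genes):
                for k, m in enumerate(C.mirnas):
                    c = int(C.counts[i, k])
                    if c:
                        fh.write(f"{g}\t{m}\t{c}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def binarize(C: SeedMatchMatrix) -> SeedMatchMatrix:
    """Collapse site counts to presence/absence: any nonzero count becomes 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SeedMatchMatrix(
            list(C.genes), list(C.mirnas), (C.counts > 0).astype(np.int64)
        )
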