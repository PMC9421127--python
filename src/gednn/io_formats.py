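"""Readers and writers for the on-disk table dialects.

All inputs are plain delimited text:

* genotype table    -- header row of SNP ids, first column of sample ids,
                       calls coded as minor-allele dosage ``{0, 1, 2}`` with a
                       configurable missing token (default ``NA``);
* label file        -- two columns ``sample_id <tab> label`` with binary labels;
* edge lists        -- two whitespace/tab-delimited columns (eQTL SNP-gene
                       pairs, or PPI gene-gene pairs), optional header;
* position tables   -- four columns ``id chrom start end``; native dialect is
                       1-based closed intervals, BED input (``chrom start end
                       id``, 0-based half-open) is converted on read;
* pathway tables    -- ``rank SNP Gene PS`` as printed by the pathway ranking.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "LabelVector",
    "EdgeList",
    "PositionTable",
    "read_genotypes",
    "write_genotypes",
    "read_labels",
    "write_labels",
    "read_edge_list",
    "write_edge_list",
    "read_positions",
    "write_pathway_table",
    "read_pathway_table",
]

VALID_CALLS = frozenset({0, 1, 2})


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = Counter(ids)
    dups = [k for k, v in counts.items() if v > 1]
    if dups:
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with an explicit missing mask."""

    calls: np.ndarray  # int8, (n, p); missing entries hold 0 but are masked
    missing: np.ndarray  # bool, (n, p)
    snp_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.calls.shape != self.missing.shape:
            raise ValueError("calls and missing mask must share a shape")
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("shape inconsistent with id lists")
        _check_unique(self.snp_ids, "SNP ids")
        _check_unique(self.sample_ids, "sample ids")
        observed = self.calls[~self.missing]
        if observed.size and not np.isin(observed, list(VALID_CALLS)).all():
            bad = observed[~np.isin(observed, list(VALID_CALLS))][0]
            raise ValueError(f"genotype call {bad} outside {{0,1,2}}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset in the given order; unknown ids raise KeyError."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            cols = [index[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None
        return GenotypeMatrix(
            self.calls[:, cols], self.missing[:, cols], list(snp_ids), list(self.sample_ids)
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
        return GenotypeMatrix(
            self.calls[rows], self.missing[rows], list(self.snp_ids), list(sample_ids)
        )


@dataclass
class LabelVector:
    """Binary phenotype labels aligned to sample ids."""

    labels: np.ndarray  # int8, values in {0, 1}
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must be 1-D and aligned to sample_ids")
        if self.labels.size and not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary {0,1}")
        _check_unique(self.sample_ids, "sample ids")

    def subset(self, sample_ids: Sequence[str]) -> "LabelVector":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return LabelVector(self.labels[rows], list(sample_ids))


@dataclass
class EdgeList:
    """Ordered pair list; duplicates allowed on read, deduplicated only when
    converted to adjacency masks."""

    edges: list[tuple[str, str]]
    kind: Literal["snp_gene", "gene_gene"]

    def __post_init__(self) -> None:
        if self.kind not in ("snp_gene", "gene_gene"):
            raise ValueError(f"unknown edge list kind {self.kind!r}")
        if self.kind == "snp_gene":
            for a, b in self.edges:
                if a == b:
                    raise ValueError(f"self-pair {a!r} not allowed in snp_gene edge list")

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class PositionTable:
    """Genomic intervals, 1-based closed; SNPs are length-1 intervals."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = ["id", "chrom", "start", "end"]
        if list(self.records.columns)[:4] != required:
            raise ValueError(f"position table needs columns {required}")
        if len(self.records):
            if (self.records["start"] > self.records["end"]).any():
                raise ValueError("position with start > end")
            if (self.records[["start", "end"]] < 0).to_numpy().any():
                raise ValueError("negative genomic coordinate")


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, missing_token: str = "NA") -> GenotypeMatrix:
    """Parse a delimited genotype table (header = SNP ids, column 1 = sample ids).

    Entries equal to ``missing_token`` are flagged missing; any other value
    must parse as an integer in {0,1,2} or the offending row/column is named.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: no data rows")
    sep = "\t" if "\t" in lines[0] else ("," if "," in lines[0] else None)
    header = lines[0].split(sep)
    snp_ids = [h.strip() for h in header[1:]]
    _check_unique(snp_ids, "SNP ids")
    sample_ids: list[str] = []
    calls = np.zeros((len(lines) - 1, len(snp_ids)), dtype=np.int8)
    missing = np.zeros_like(calls, dtype=bool)
    for r, line in enumerate(lines[1:]):
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != len(snp_ids) + 1:
            raise ValueError(
                f"{path}: row {r + 2} has {len(fields)} fields, expected {len(snp_ids) + 1}"
            )
        sample_ids.append(fields[0])
        for c, tok in enumerate(fields[1:]):
            if tok == missing_token:
                missing[r, c] = True
                continue
            try:
                val = int(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric genotype {tok!r} at sample {fields[0]!r}, SNP {snp_ids[c]!r}"
                ) from None
            if val not in VALID_CALLS:
                raise ValueError(
                    f"{path}: genotype {val} outside {{0,1,2}} at sample {fields[0]!r}, SNP {snp_ids[c]!r}"
                )
            calls[r, c] = val
    return GenotypeMatrix(calls, missing, snp_ids, sample_ids)


def write_genotypes(
    g: GenotypeMatrix, path: str | Path, missing_token: str = "NA", sep: str = "\t"
) -> None:
    buf = io.StringIO()
    buf.write(sep.join(["sample_id", *g.snp_ids]) + "\n")
    for r, sid in enumerate(g.sample_ids):
        row = [
            missing_token if g.missing[r, c] else str(int(g.calls[r, c]))
            for c in range(g.n_snps)
        ]
        buf.write(sep.join([sid, *row]) + "\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> LabelVector:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["sample_id", "label"], dtype=str)
    if df.iloc[0, 0] == "sample_id":  # optional header
        df = df.iloc[1:]
    try:
        labels = df["label"].astype(int).to_numpy()
    except ValueError:
        raise ValueError(f"{path}: non-integer label") from None
    return LabelVector(labels, df["sample_id"].tolist())


def write_labels(labels: LabelVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(labels.sample_ids, labels.labels):
            fh.write(f"{sid}\t{int(lab)}\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, kind: Literal["snp_gene", "gene_gene"]) -> EdgeList:
    """Two-column whitespace/tab-delimited pairs; order preserved, blank lines
    skipped, rows with a field count other than two rejected with the line number."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} columns, expected 2")
            if lineno == 1 and fields[0].lower() in ("snp", "snp_id", "gene", "gene_a", "id_a"):
                continue  # optional header
            edges.append((fields[0], fields[1]))
    return EdgeList(edges, kind)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges.edges:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# position tables
# ---------------------------------------------------------------------------

def read_positions(path: str | Path, fmt: Literal["tsv", "bed"] = "tsv") -> PositionTable:
    """Read an interval table.

    ``tsv``: columns ``id chrom start end``, 1-based closed (native dialect).
    ``bed``: columns ``chrom start end id``, 0-based half-open, converted to
    1-based closed on ingest (start+1, end unchanged).
    """
    if fmt == "tsv":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=["id", "chrom", "start", "end"],
            dtype={"id": str, "chrom": str},
        )
        if df.iloc[0]["id"] == "id":
            df = df.iloc[1:].reset_index(drop=True)
        df[["start", "end"]] = df[["start", "end"]].astype(int)
    elif fmt == "bed":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=["chrom", "start", "end", "id"],
            dtype={"id": str, "chrom": str},
        )
        df[["start", "end"]] = df[["start", "end"]].astype(int)
        df["start"] = df["start"] + 1  # 0-based half-open -> 1-based closed
        df = df[["id", "chrom", "start", "end"]]
    else:
        raise ValueError(f"unknown position format {fmt!r}")
    return PositionTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# pathway tables
# ---------------------------------------------------------------------------

def write_pathway_table(table, path: str | Path) -> None:
    """Write a ranked pathway-score table (columns rank, SNP, Gene, PS).

    The caller must rank first: rows not sorted by PS descending are rejected.
    PS is printed unrounded (repr precision).
    """
    rows = table.rows
    ps = [r[2] for r in rows]
    if any(ps[i] < ps[i + 1] for i in range(len(ps) - 1)):
        raise ValueError("pathway table rows are not sorted by PS descending; rank first")
    with open(path, "w") as fh:
        fh.write("rank\tSNP\tGene\tPS\n")
        for rank, (snp, gene, score) in enumerate(rows, start=1):
            fh.write(f"{rank}\t{snp}\t{gene}\t{score!r}\n")


def read_pathway_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
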