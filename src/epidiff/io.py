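"""Readers and writers for methylation tables, features and result files.

Internal coordinates are 1-based inclusive everywhere; BED's 0-based
half-open convention is converted at the I/O boundary only.  Per-cytosine
tables keep one record per (chromosome, position, strand): cytosines on the
two strands are independent records, and zero-coverage cytosines are
retained because they are legitimate smoothing neighbours.

Supported per-cytosine dialects:

``native-tsv``
    chrom, pos (1-based), strand, context, meth, unmeth.
``bismark-cx``
    The Bismark genome-wide cytosine (CX) report: chrom, pos, strand,
    count_meth, count_unmeth, context, trinucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CYTOSINE_CONTEXTS",
    "GenomicFeature",
    "read_cytosine_table",
    "read_features",
    "write_dmrs",
    "read_dmrs",
    "read_count_table",
    "write_count_table",
]

CYTOSINE_CONTEXTS = ("CG", "CHG", "CHH")

_CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]


@dataclass(frozen=True)
class GenomicFeature:
    """One annotated feature in 1-based inclusive coordinates."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start {self.start} > end {self.end}")


class ParseError(ValueError):
    """Malformed input file; carries a 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        super().__init__(f"{path}:{line_number}: {message}")
        self.path = path
        self.line_number = line_number


def _data_lines(path):
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield i, line


def read_cytosine_table(path, dialect: str = "native-tsv") -> pd.DataFrame:
    """Read a per-cytosine methylation count table.

    Returns a DataFrame with columns chrom, pos, strand, context, meth,
    unmeth, sorted by (chrom, pos).  Zero-coverage cytosines are retained.
    Duplicate (chrom, pos, strand) records are rejected.
    """
    if dialect not in ("native-tsv", "bismark-cx"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if dialect == "native-tsv":
            if len(fields) != 6:
                raise ParseError(path, lineno, f"expected 6 columns, got {len(fields)}")
            chrom, pos, strand, context, meth, unmeth = fields
        else:
            if len(fields) != 7:
                raise ParseError(path, lineno, f"expected 7 columns, got {len(fields)}")
            chrom, pos, strand, meth, unmeth, context, _tri = fields
        try:
            pos_i, meth_i, unmeth_i = int(pos), int(meth), int(unmeth)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer count or position in {line!r}") from None
        if context not in CYTOSINE_CONTEXTS:
            raise ParseError(path, lineno, f"unknown context token {context!r}")
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"unknown strand {strand!r}")
        if pos_i < 1:
            raise ParseError(path, lineno, "position must be >= 1")
        if meth_i < 0 or unmeth_i < 0:
            raise ParseError(path, lineno, "counts must be non-negative")
        rows.append((chrom, pos_i, strand, context, meth_i, unmeth_i))
    df = pd.DataFrame(rows, columns=_CYTOSINE_COLUMNS)
    if df.duplicated(["chrom", "pos", "strand"]).any():
        dup = df[df.duplicated(["chrom", "pos", "strand"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate cytosine record at {dup.chrom}:{dup.pos}({dup.strand})"
        )
    return df.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)


def read_features(path, format: str = "bed") -> list[GenomicFeature]:
    """Read feature annotations from BED (0-based half-open) or GFF3
    (1-based inclusive), converting to 1-based inclusive coordinates."""
    fmt = format.lower()
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"unknown feature format {format!r}")
    features = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if fmt == "bed":
            if len(fields) < 3:
                raise ParseError(path, lineno, "BED requires at least 3 columns")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer BED coordinates") from None
            start, end = start0 + 1, end0
            if start > end:
                raise ParseError(
                    path, lineno, f"empty or inverted interval ({start0}, {end0})"
                )
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 else "."
            kind = fields[6] if len(fields) > 6 else ""
            compartment = fields[7] if len(fields) > 7 else ""
        else:
            if len(fields) < 8:
                raise ParseError(path, lineno, "GFF3 requires 8+ columns")
            chrom, _source, kind = fields[0], fields[1], fields[2]
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(path, lineno, "non-integer GFF3 coordinates") from None
            if start > end:
                raise ParseError(path, lineno, f"start {start} > end {end}")
            strand = fields[6]
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            ) if len(fields) > 8 else {}
            name = attrs.get("ID", f"{chrom}:{start}-{end}")
            compartment = attrs.get("compartment", "")
        features.append(
            GenomicFeature(
                id=name, chrom=chrom, start=start, end=end,
                strand=strand, kind=kind, compartment=compartment,
            )
        )
    return features


def features_to_frame(features) -> pd.DataFrame:
    """Tabular view of a feature collection."""
    return pd.DataFrame(
        [
            (f.id, f.chrom, f.start, f.end, f.strand, f.kind, f.compartment)
            for f in features
        ],
        columns=["id", "chrom", "start", "end", "strand", "kind", "compartment"],
    )


def write_features(features, path, format: str = "gff3") -> None:
    """Write features as GFF3 (1-based inclusive; kind in the type column,
    compartment as an attribute) or BED6 (converted to 0-based half-open)."""
    fmt = format.lower()
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"unknown feature format {format!r}")
    rows = features.itertuples() if isinstance(features, pd.DataFrame) else features
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for f in rows:
                fh.write(
                    f"{f.chrom}\tepidiff\t{f.kind or 'region'}\t{f.start}\t{f.end}\t.\t"
                    f"{f.strand}\t.\tID={f.id};compartment={f.compartment}\n"
                )
        else:
            for f in rows:
                fh.write(
                    f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.id}\t0\t{f.strand}\t"
                    f"{f.kind}\t{f.compartment}\n"
                )


def write_cytosine_table(table: pd.DataFrame, path) -> None:
    """Write a per-cytosine table in the native TSV dialect."""
    table.to_csv(path, sep="\t", index=False, header=False,
                 columns=_CYTOSINE_COLUMNS)


_DMR_EXTRA = ["context", "type", "n_dmcs", "rate_wt", "rate_mut", "diff", "p_value", "fdr"]


def write_dmrs(dmrs: pd.DataFrame, path) -> None:
    """Write called DMRs as BED6+ (0-based half-open BED coordinates with
    context, type, DMC count, rates, rate difference, p-value and FDR in
    the extra columns)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\t" + "\t".join(_DMR_EXTRA) + "\n")
        for _, row in dmrs.iterrows():
            name = f"{row.chrom}:{int(row.start)}-{int(row.end)}:{row.context}:{row.type}"
            extras = [
                row.context, row.type, str(int(row.n_dmcs)),
                repr(float(row.rate_wt)), repr(float(row.rate_mut)),
                repr(float(row["diff"])), repr(float(row.p_value)), repr(float(row.fdr)),
            ]
            fh.write(
                f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t{name}\t"
                f"{int(row.n_dmcs)}\t.\t" + "\t".join(extras) + "\n"
            )


def read_dmrs(path) -> pd.DataFrame:
    """Read a DMR BED6+ file written by :func:`write_dmrs`; a write-then-read
    round trip recovers identical values."""
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 6 + len(_DMR_EXTRA):
            raise ParseError(path, lineno, f"expected {6 + len(_DMR_EXTRA)} columns")
        chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        context, typ, n_dmcs = fields[6], fields[7], int(fields[8])
        rate_wt, rate_mut, diff, p, fdr = (float(v) for v in fields[9:14])
        rows.append(
            (chrom, start0 + 1, end0, context, typ, n_dmcs, rate_wt, rate_mut, diff, p, fdr)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "type", "n_dmcs",
                 "rate_wt", "rate_mut", "diff", "p_value", "fdr"],
    )


def read_count_table(path) -> pd.DataFrame:
    """Read a per-locus read-count table (TSV with columns locus_id, chrom,
    start, end, then one integer column per library)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"locus_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    lengths = df["end"] - df["start"] + 1
    if (lengths < 1).any():
        raise ValueError(f"{path}: locus with non-positive length")
    return df.set_index("locus_id")


def write_count_table(counts: pd.DataFrame, path) -> None:
    """Write a per-locus count table readable by :func:`read_count_table`."""
    counts.to_csv(path, sep="\t", index=True, index_label="locus_id")
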