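"""Readers and writers for the pipeline's inputs and outputs.

Inputs: FASTA/FASTQ (plain, gzip or bzip2), reference FASTA plus a
2-column lineage TSV (Greengenes ``k__Bacteria; p__...`` or plain
SILVA ``Bacteria;...`` 7-rank strings — both dialects parsed).

Outputs: the per-sample tag table (.tab, schema below), the
multi-sample count matrix, the annotation table (.anno) and a BIOM
v1.0 JSON table with taxonomy as observation metadata.

Tag table columns (fixed order)::

    tag  n  npos  fp  long.total.count  long1.count  long2.count
    long3.count  long1  long2

``fp`` is printed with 4 decimal places.
"""

from __future__ import annotations

import bz2
import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotate import TaxonAnnotation
from .profiles import RANKS
from .tagcount import TagRecord

__all__ = [
    "CountMatrix", "SampleTagTable", "merge_samples", "open_text",
    "parse_lineage", "read_biom", "read_lineages", "read_reference",
    "read_seqs", "read_tag_table", "validate_biom", "write_anno",
    "write_biom", "write_fasta", "write_fastq", "write_lineages",
    "write_tag_table",
]

TAB_COLUMNS = ["tag", "n", "npos", "fp", "long.total.count", "long1.count",
               "long2.count", "long3.count", "long1", "long2"]
ANNO_COLUMNS = ["tag", "use", "taxon_level", "taxon_data", "long",
                "long_total", "long_this", "support", "confidence",
                *RANKS]


def open_text(path, mode: str = "rt"):
    """Open a possibly gzip- or bzip2-compressed text file."""
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, mode)
    if p.endswith(".bz2"):
        return bz2.open(p, mode)
    return open(p, mode)


def read_seqs(path, fmt: str | None = None
              ) -> Iterator[tuple[str, str, str | None]]:
    """Yield ``(id, seq, qual_or_None)`` from FASTA or FASTQ.

    The format is sniffed from the first character unless given
    (``"fasta"``/``"fastq"``).  Identifiers are the first whitespace
    token of the header.
    """
    with open_text(path) as fh:
        if fmt is None:
            head = fh.read(1)
            fh.seek(0)
            if head == "@":
                fmt = "fastq"
            elif head == ">":
                fmt = "fasta"
            else:
                raise ValueError(f"{path}: cannot sniff sequence format "
                                 f"(starts with {head!r})")
        if fmt == "fastq":
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq.upper(), qual
        elif fmt == "fasta":
            for title, seq in SimpleFastaParser(fh):
                yield title.split()[0], seq.upper(), None
        else:
            raise ValueError(f"unknown format {fmt!r}")


def parse_lineage(text: str) -> tuple[str, ...]:
    """Parse a semicolon-delimited lineage into a 7-rank tuple.

    Strips Greengenes-style ``k__`` prefixes; pads/truncates to 7
    ranks; placeholder labels like a bare prefix become empty strings.
    """
    parts = [p.strip() for p in text.split(";")]
    labels = []
    for p in parts:
        if len(p) >= 3 and p[1:3] == "__":
            p = p[3:]
        labels.append(p.strip())
    labels = (labels + [""] * len(RANKS))[:len(RANKS)]
    return tuple(labels)


def format_lineage(lineage: Sequence[str], dialect: str = "gg") -> str:
    if dialect == "gg":
        return "; ".join(f"{r}__{x}" for r, x in zip(RANKS, lineage))
    return ";".join(lineage)


def read_lineages(path) -> dict[str, tuple[str, ...]]:
    """2-column TSV: seq_id, lineage string."""
    out = {}
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, lin = line.split("\t", 1)
            out[sid] = parse_lineage(lin)
    return out


def read_reference(fasta_path, lineage_path
                   ) -> list[tuple[str, str, tuple[str, ...]]]:
    """Unaligned (or aligned) reference FASTA + lineage TSV."""
    lineages = read_lineages(lineage_path)
    out = []
    for sid, seq, _ in read_seqs(fasta_path, "fasta"):
        out.append((sid, seq, lineages.get(sid, ("",) * len(RANKS))))
    return out


def write_lineages(records: Iterable[tuple[str, Sequence[str]]], path,
                   dialect: str = "gg") -> None:
    with open(path, "w") as fh:
        for sid, lin in records:
            fh.write(f"{sid}\t{format_lineage(lin, dialect)}\n")


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open_text(path, "wt") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open_text(path, "wt") as fh:
        for sid, seq, qual in records:
            fh.write(f"@{sid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------- tag tables

@dataclass
class SampleTagTable:
    """One sample's ribotag table (rows unique by tag)."""

    sample_id: str
    rows: list[TagRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        tags = [r.tag for r in self.rows]
        if len(tags) != len(set(tags)):
            raise ValueError(f"duplicate tags in table for "
                             f"{self.sample_id!r}")


def write_tag_table(table: SampleTagTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TAB_COLUMNS) + "\n")
        for r in table.rows:
            fh.write("\t".join([
                r.tag, str(r.n), str(r.npos), f"{r.fp:.4f}",
                str(r.long_total_count), str(r.long1_count),
                str(r.long2_count), str(r.long3_count), r.long1, r.long2,
            ]) + "\n")


def read_tag_table(path, sample_id: str | None = None) -> SampleTagTable:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TAB_COLUMNS:
            raise ValueError(f"{path}: unexpected tag-table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(TagRecord(
                tag=f[0], n=int(f[1]), npos=int(f[2]), fp=float(f[3]),
                long_total_count=int(f[4]), long1_count=int(f[5]),
                long2_count=int(f[6]), long3_count=int(f[7]),
                long1=f[8], long2=f[9]))
    if sample_id is None:
        sample_id = str(path)
    return SampleTagTable(sample_id=sample_id, rows=rows)


CountMatrix = pd.DataFrame  # tags in rows, samples in columns


def merge_samples(tables: Sequence[SampleTagTable],
                  allow_mates: bool = False
                  ) -> tuple[CountMatrix, pd.DataFrame]:
    """Combine per-sample tables into a count matrix + long-variant
    skeleton for annotation output.

    Tags are the union across samples (zero where absent).  Duplicate
    sample ids are an error unless ``allow_mates`` is set, in which
    case mate tables of one sample are merged by summing ``n`` (and
    ``npos``, capped at ``n`` — exact recomputation needs pooled
    observations, which the CLI does upstream).

    The skeleton has one row per tag: ``long`` (overall top long
    variant), ``long_total`` (samples with any long variant) and
    ``long_this`` (samples whose major variant is ``long``).
    """
    if not tables:
        raise ValueError("need at least one sample table")
    ids = [t.sample_id for t in tables]
    if len(ids) != len(set(ids)):
        if not allow_mates:
            raise ValueError(f"duplicate sample ids: {sorted(ids)}")
        merged: dict[str, SampleTagTable] = {}
        for t in tables:
            if t.sample_id not in merged:
                merged[t.sample_id] = SampleTagTable(t.sample_id,
                                                     list(t.rows))
            else:
                base = {r.tag: r for r in merged[t.sample_id].rows}
                for r in t.rows:
                    if r.tag in base:
                        b = base[r.tag]
                        b.n += r.n
                        b.npos = min(b.npos + r.npos, b.n)
                        b.long_total_count += r.long_total_count
                        for ls, c in r.long_counts.items():
                            b.long_counts[ls] = b.long_counts.get(ls, 0) + c
                    else:
                        base[r.tag] = r
                merged[t.sample_id] = SampleTagTable(
                    t.sample_id, [base[k] for k in sorted(base)])
        tables = list(merged.values())
        ids = [t.sample_id for t in tables]

    all_tags = sorted({r.tag for t in tables for r in t.rows})
    matrix = pd.DataFrame(0, index=pd.Index(all_tags, name="tag"),
                          columns=ids, dtype=int)
    major: dict[str, dict[str, str]] = {}   # tag -> sample -> major long
    for t in tables:
        for r in t.rows:
            matrix.loc[r.tag, t.sample_id] = r.n
            if r.long_total_count:
                major.setdefault(r.tag, {})[t.sample_id] = r.long1

    skel_rows = []
    for tag in all_tags:
        per_sample = major.get(tag, {})
        majors = sorted(per_sample.values())
        if majors:
            # overall representative: most frequent major variant
            from collections import Counter
            top = sorted(Counter(majors).items(),
                         key=lambda kv: (-kv[1], kv[0]))[0][0]
            skel_rows.append((tag, top, len(per_sample),
                              sum(1 for v in per_sample.values()
                                  if v == top)))
        else:
            skel_rows.append((tag, "", 0, 0))
    skeleton = pd.DataFrame(skel_rows, columns=["tag", "long", "long_total",
                                                "long_this"]
                            ).set_index("tag")
    return matrix, skeleton


def write_anno(annotations: Sequence[TaxonAnnotation],
               skeleton: pd.DataFrame, path) -> None:
    """Write the .anno table (QC, metadata and taxonomy per tag)."""
    with open(path, "w") as fh:
        fh.write("\t".join(ANNO_COLUMNS) + "\n")
        for a in annotations:
            if a.tag in skeleton.index:
                row = skeleton.loc[a.tag]
                long_seq, lt, lth = row["long"], int(row["long_total"]), \
                    int(row["long_this"])
            else:
                long_seq, lt, lth = "", 0, 0
            fh.write("\t".join([
                a.tag, a.use, a.taxon_level, a.taxon_data, long_seq,
                str(lt), str(lth), str(a.support), f"{a.confidence:.4f}",
                *(a.labels[r] for r in RANKS),
            ]) + "\n")


# -------------------------------------------------------------------- BIOM

_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"
_BIOM_URL = "http://biom-format.org"


def write_biom(matrix: CountMatrix,
               annotations: Sequence[TaxonAnnotation] | None,
               path,
               table_id: str = "ssutag",
               generated_by: str = "ssutag",
               date: str = "1970-01-01T00:00:00") -> None:
    """Write a BIOM v1.0 (JSON, sparse) table.

    Taxonomy, when available, is attached as observation metadata
    under the key ``"taxonomy"`` (7-element list).  The ``date`` field
    defaults to a fixed epoch string so identical inputs produce
    byte-identical files.
    """
    anno_by_tag = {a.tag: a for a in (annotations or [])}
    rows = []
    for tag in matrix.index:
        a = anno_by_tag.get(tag)
        meta = ({"taxonomy": [a.labels[r] for r in RANKS]}
                if a is not None else None)
        rows.append({"id": tag, "metadata": meta})
    cols = [{"id": str(s), "metadata": None} for s in matrix.columns]
    data = []
    vals = matrix.to_numpy()
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            v = int(vals[i, j])
            if v:                       # sparse: zero cells omitted
                data.append([i, j, v])
    doc = {
        "id": table_id,
        "format": _BIOM_FORMAT,
        "format_url": _BIOM_URL,
        "type": "OTU table",
        "generated_by": generated_by,
        "date": date,
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(rows), len(cols)],
        "rows": rows,
        "columns": cols,
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, separators=(",", ":"))


_BIOM_REQUIRED = ("id", "format", "format_url", "type", "generated_by",
                  "date", "matrix_type", "matrix_element_type", "shape",
                  "rows", "columns", "data")


def validate_biom(doc: dict) -> None:
    """Minimal BIOM v1.0 structural validation (raises ValueError)."""
    for key in _BIOM_REQUIRED:
        if key not in doc:
            raise ValueError(f"BIOM document missing key {key!r}")
    if doc["format"] != _BIOM_FORMAT:
        raise ValueError(f"unexpected BIOM format {doc['format']!r}")
    nr, nc = doc["shape"]
    if len(doc["rows"]) != nr or len(doc["columns"]) != nc:
        raise ValueError("BIOM shape inconsistent with rows/columns")
    for triple in doc["data"]:
        i, j, v = triple
        if not (0 <= i < nr and 0 <= j < nc):
            raise ValueError(f"BIOM data entry out of bounds: {triple}")


def read_biom(path) -> tuple[CountMatrix, dict[str, list[str]]]:
    """Parse a BIOM v1 file back to a dense count matrix + taxonomy."""
    with open(path) as fh:
        doc = json.load(fh)
    validate_biom(doc)
    tags = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    matrix = pd.DataFrame(0, index=pd.Index(tags, name="tag"),
                          columns=samples, dtype=int)
    for i, j, v in doc["data"]:
        matrix.iloc[i, j] = v
    taxonomy = {r["id"]: r["metadata"]["taxonomy"] for r in doc["rows"]
                if r.get("metadata") and "taxonomy" in r["metadata"]}
    return matrix, taxonomy
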