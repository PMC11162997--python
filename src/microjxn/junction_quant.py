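"""Splice-junction counting and per-sample isoform proportions.

Inputs are STAR ``SJ.out.tab`` files (9 tab-separated columns, 1-based
inclusive intron coordinates) or a GTEx-style junction x sample count
matrix.  For each sample, reads on junctions leaving the anchor exon are
accumulated per isoform class; the total of those reads is the gene-level
expression proxy and each class count divided by the total is the isoform
proportion.  Samples with no anchor-donor reads have *undefined* proportions
(missing, never 0/0).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exon_model import NOT_ANCHOR, UNCLASSIFIED, JunctionClassifier, GeneModel, classify_junction, normalize_chrom

__all__ = [
    "SJParseError",
    "MetadataError",
    "JunctionRecord",
    "SampleQuant",
    "read_sj_file",
    "read_junction_matrix",
    "quantify_sample",
    "aggregate_cohort",
    "cohort_labels",
]


class SJParseError(ValueError):
    """Raised on malformed SJ.out.tab or junction-matrix input."""


class MetadataError(ValueError):
    """Raised when sample metadata does not cover the quantified samples."""


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction in STAR SJ.out.tab convention.

    ``intron_start``/``intron_end`` are the first and last intronic bases
    (1-based, inclusive).  ``strand_code`` is 0 (undefined), 1 (+) or 2 (-).
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand_code: int = 0
    motif_code: int = 0
    annotated: int = 0
    unique_reads: int = 0
    multimap_reads: int = 0
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise SJParseError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if min(self.unique_reads, self.multimap_reads, self.max_overhang) < 0:
            raise SJParseError("read counts and overhang must be non-negative")


@dataclass
class SampleQuant:
    """Per-sample junction read counts and proportions over isoform classes.

    ``counts`` covers the classifier's labels plus "unclassified";
    ``total`` is their sum (the expression proxy); ``proportions`` is None
    when ``total`` is zero.
    """

    sample_id: str
    counts: dict[str, int]
    total: int
    proportions: dict[str, float] | None

    @property
    def defined(self) -> bool:
        return self.proportions is not None


def read_sj_file(path: str | Path, min_overhang: int = 0) -> list[JunctionRecord]:
    """Parse a STAR SJ.out.tab file into junction records.

    Lines with a maximum spliced overhang below ``min_overhang`` are
    dropped; input order is preserved otherwise.
    """
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise SJParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            try:
                rec = JunctionRecord(
                    chrom=fields[0],
                    intron_start=int(fields[1]),
                    intron_end=int(fields[2]),
                    strand_code=int(fields[3]),
                    motif_code=int(fields[4]),
                    annotated=int(fields[5]),
                    unique_reads=int(fields[6]),
                    multimap_reads=int(fields[7]),
                    max_overhang=int(fields[8]),
                )
            except ValueError as exc:
                raise SJParseError(f"{path}:{lineno}: {exc}") from exc
            if rec.max_overhang >= min_overhang:
                records.append(rec)
    return records


#: junction-id dialects: "chr10_1001_2000", "chr10:1001-2000", "chr10:1001:2000"
_JUNCTION_ID_RE = re.compile(r"^(?P<chrom>.+?)[_:](?P<start>\d+)[_:\-](?P<end>\d+)$")


def parse_junction_id(junction_id: str) -> tuple[str, int, int]:
    m = _JUNCTION_ID_RE.match(junction_id)
    if not m:
        raise SJParseError(f"unparseable junction identifier {junction_id!r}")
    return m["chrom"], int(m["start"]), int(m["end"])


def read_junction_matrix(
    path: str | Path,
    model: GeneModel | None = None,
    strip_chr_prefix: bool = True,
) -> dict[str, list[JunctionRecord]]:
    """Read a junction x sample count matrix TSV into per-sample records.

    The first column holds junction identifiers encoding chromosome and
    intron coordinates; remaining columns are per-sample unique-read counts.
    When ``model`` is given, junctions on other chromosomes are dropped.
    Zero-count entries are omitted from a sample's record list.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise SJParseError(f"duplicate junction identifiers: {dups}")

    target = None
    if model is not None:
        target = normalize_chrom(model.chrom, strip_chr_prefix)

    per_sample: dict[str, list[JunctionRecord]] = {str(s): [] for s in df.columns}
    for junction_id, row in df.iterrows():
        chrom, start, end = parse_junction_id(str(junction_id))
        if target is not None and normalize_chrom(chrom, strip_chr_prefix) != target:
            continue
        for sample, value in row.items():
            count = int(value)
            if count > 0:
                per_sample[str(sample)].append(
                    JunctionRecord(
                        chrom=chrom,
                        intron_start=start,
                        intron_end=end,
                        unique_reads=count,
                    )
                )
    return per_sample


def quantify_sample(
    records: Iterable[JunctionRecord],
    clf: JunctionClassifier,
    sample_id: str = "",
    use_multimappers: bool = False,
    min_unique: int = 0,
    include_unclassified: bool = True,
    strip_chr_prefix: bool = True,
) -> SampleQuant:
    """Count anchor-donor junction reads per isoform class for one sample.

    The denominator (``total``) is the sum over all anchor-donor reads,
    including "unclassified" acceptors unless ``include_unclassified`` is
    False.  Multimapping reads are excluded by default.
    """
    counts: dict[str, int] = {label: 0 for label in clf.labels}
    counts[UNCLASSIFIED] = 0
    for rec in records:
        if rec.unique_reads < min_unique:
            continue
        label = classify_junction(rec, clf, strip_chr_prefix)
        if label == NOT_ANCHOR:
            continue
        n = rec.unique_reads + (rec.multimap_reads if use_multimappers else 0)
        counts[label] += n

    if not include_unclassified:
        counts[UNCLASSIFIED] = 0

    total = sum(counts.values())
    proportions = (
        {label: c / total for label, c in counts.items()} if total > 0 else None
    )
    return SampleQuant(sample_id=sample_id, counts=counts, total=total, proportions=proportions)


def cohort_labels(cohort: pd.DataFrame) -> list[str]:
    """Isoform-proportion columns of a cohort table (everything that is not
    metadata/bookkeeping)."""
    reserved = {"total", "excluded", "tissue", "group", "subtype", "time"}
    return [c for c in cohort.columns if c not in reserved]


def aggregate_cohort(
    quants: Sequence[SampleQuant],
    metadata: pd.DataFrame | Mapping[str, Mapping],
) -> pd.DataFrame:
    """Join per-sample quantifications with sample metadata.

    ``metadata`` is indexed by sample id (or a mapping sample id -> fields).
    Samples with zero anchor-donor reads are retained but flagged
    ``excluded=True`` and carry missing proportions, so downstream
    statistics skip them.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.DataFrame.from_dict(metadata, orient="index")

    ids = [q.sample_id for q in quants]
    missing = [s for s in ids if s not in metadata.index]
    if missing:
        raise MetadataError(f"samples missing from metadata: {missing}")

    labels: list[str] = []
    for q in quants:
        for lab in q.counts:
            if lab not in labels:
                labels.append(lab)

    rows = []
    for q in quants:
        row: dict = {}
        for lab in labels:
            row[lab] = q.proportions.get(lab, np.nan) if q.defined else np.nan
        row["total"] = q.total
        row["excluded"] = not q.defined
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    return table.join(metadata.loc[ids])
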