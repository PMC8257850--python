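"""Readers and writers for the genomic formats used throughout the package.

Internal coordinate convention
------------------------------
Every interval in memory is **0-based, half-open** (``[start, end)``), the
BED convention.  GFF3 (1-based, closed) is converted at the file boundary
and converted back on write.  Readers validate rather than repair: a record
that violates an invariant raises with enough context (line number, cell,
transcript id) to locate it in the input file.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("merip_conjoint")

VALID_STRANDS = ("+", "-", ".")


class MalformedRecordError(ValueError):
    """A file record violates a format invariant (bad coordinates, counts...)."""


class MalformedAnnotationError(ValueError):
    """A gene model is internally inconsistent (e.g. CDS outside exons)."""


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Core interval / sequence types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval. ``strand`` '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise MalformedRecordError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise MalformedRecordError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeSequence:
    """Chromosome name -> DNA sequence over {A,C,G,T,N}."""

    sequences: Dict[str, str]

    def __post_init__(self):
        for name, seq in self.sequences.items():
            if not seq:
                raise MalformedRecordError(f"empty sequence for {name!r}")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        """Slice of the forward strand for ``interval`` (uppercase)."""
        if interval.chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        seq = self.sequences[interval.chrom]
        if interval.end > len(seq):
            raise MalformedRecordError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end].upper()


@dataclass(frozen=True)
class TranscriptModel:
    """One representative transcript per gene, in genomic coordinates.

    ``exons`` are sorted, disjoint ``(start, end)`` pairs covering the mature
    transcript; ``cds_start``/``cds_end`` bound the coding span in genomic
    coordinates (both boundaries must fall inside exons).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise MalformedAnnotationError(
                f"{self.transcript_id}: transcript strand must be + or -"
            )
        if not self.exons:
            raise MalformedAnnotationError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise MalformedAnnotationError(
                    f"{self.transcript_id}: exons must be sorted and disjoint"
                )
            prev_end = e
        if not (self.cds_start < self.cds_end):
            raise MalformedAnnotationError(f"{self.transcript_id}: empty CDS")
        if not (self._in_exon(self.cds_start) and self._in_exon(self.cds_end - 1)):
            raise MalformedAnnotationError(
                f"{self.transcript_id}: CDS bounds outside exons"
            )
        if self.cds_spliced_length < 3:
            raise MalformedAnnotationError(
                f"{self.transcript_id}: spliced CDS shorter than 3 bp"
            )

    def _in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0][0], self.exons[-1][1], self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_spliced_length(self) -> int:
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start))
            for s, e in self.exons
        )

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)


@dataclass(frozen=True)
class PeakCall:
    """A single peak call from one replicate (MACS2-style)."""

    interval: GenomicInterval
    sample: Optional[str] = None
    name: str = "."
    score: float = 0.0
    summit: Optional[int] = None  # offset from interval.start

    def __post_init__(self):
        if self.score < 0:
            raise MalformedRecordError(f"peak {self.name}: negative score")
        if self.summit is not None and not (
            0 <= self.summit < self.interval.length
        ):
            raise MalformedRecordError(
                f"peak {self.name}: summit offset {self.summit} outside interval"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> GenomeSequence:
    with _open(path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with _open(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> List[TranscriptModel]:
    """Parse a GFF3 file into one representative transcript per gene.

    The representative is the mRNA with the longest spliced CDS; ties are
    broken by the lexicographically smallest transcript id.  mRNAs lacking a
    resolvable Parent gene are skipped with a warning; a CDS segment outside
    its transcript's exons raises :class:`MalformedAnnotationError`.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    models: List[TranscriptModel] = []
    seen_mrnas = set()
    for gene in db.features_of_type("gene"):
        candidates = []
        for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            seen_mrnas.add(mrna.id)
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
            )
            if not cds:
                continue
            if not exons:
                exons = cds
            for cs, ce in cds:
                if not any(s <= cs and ce <= e for s, e in exons):
                    raise MalformedAnnotationError(
                        f"{mrna.id}: CDS segment [{cs},{ce}) outside exons"
                    )
            model = TranscriptModel(
                gene_id=gene.id,
                transcript_id=mrna.id,
                chrom=gene.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds_start=cds[0][0],
                cds_end=cds[-1][1],
            )
            candidates.append((-model.cds_spliced_length, model.transcript_id, model))
        if candidates:
            candidates.sort(key=lambda c: (c[0], c[1]))
            models.append(candidates[0][2])
    n_orphans = sum(
        1
        for f in db.features_of_type(("mRNA", "transcript"))
        if f.id not in seen_mrnas
    )
    if n_orphans:
        logger.warning("skipped %d mRNA(s) without a resolvable Parent gene", n_orphans)
    return models


def _cds_segments(model: TranscriptModel) -> List[Tuple[int, int]]:
    segs = []
    for s, e in model.exons:
        lo, hi = max(s, model.cds_start), min(e, model.cds_end)
        if lo < hi:
            segs.append((lo, hi))
    return segs


def write_gff3(models: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon/CDS), 1-based closed."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.interval.start)):
            span = m.interval
            attrs_gene = f"ID={m.gene_id}"
            fh.write(
                f"{m.chrom}\tmerip_conjoint\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\t{attrs_gene}\n"
            )
            fh.write(
                f"{m.chrom}\tmerip_conjoint\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tmerip_conjoint\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
            cds_segs = _cds_segments(m)
            if m.strand == "-":
                ordered = cds_segs[::-1]
            else:
                ordered = cds_segs
            phase, lines = 0, []
            for s, e in ordered:
                lines.append((s, e, phase))
                phase = (3 - ((e - s) - phase) % 3) % 3
            for i, (s, e, ph) in enumerate(sorted(lines), 1):
                fh.write(
                    f"{m.chrom}\tmerip_conjoint\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t"
                    f"{ph}\tID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# BED6 / narrowPeak
# ---------------------------------------------------------------------------

def read_peaks(path, sample: Optional[str] = None) -> List[PeakCall]:
    """Read BED6 or ENCODE narrowPeak (10-column) peak calls.

    Coordinates are kept 0-based half-open; a narrowPeak summit of -1 maps
    to "no summit".  Malformed records raise with their line number.
    """
    peaks: List[PeakCall] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 10):
                raise MalformedRecordError(
                    f"{path}:{lineno}: expected 6 (BED6) or 10 (narrowPeak) "
                    f"columns, got {len(fields)}"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise MalformedRecordError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3]
            score = 0.0 if fields[4] == "." else float(fields[4])
            strand = fields[5]
            summit = None
            if len(fields) == 10:
                raw = int(fields[9])
                if raw != -1:
                    summit = raw
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(chrom, start, end, strand),
                    sample=sample,
                    name=name,
                    score=score,
                    summit=summit,
                )
            )
    return peaks


def write_peaks(peaks: Iterable[PeakCall], path, narrow: bool = False) -> None:
    with _open(path, "wt") as fh:
        for p in peaks:
            iv = p.interval
            base = f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t{iv.strand}"
            if narrow:
                summit = -1 if p.summit is None else p.summit
                fh.write(base + f"\t0\t-1\t-1\t{summit}\n")
            else:
                fh.write(base + "\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

SAMPLE_META_COLS = ("cultivar", "condition", "replicate", "group", "fraction")


def parse_sample_label(label: str) -> Dict[str, Optional[str]]:
    """Parse sample labels like ``9311_CK_rep1_IP`` into metadata fields.

    The trailing ``_IP``/``_input`` fraction suffix is optional (expression
    tables carry plain sample labels).
    """
    parts = label.split("_")
    fraction = None
    if parts and parts[-1] in ("IP", "input"):
        fraction = parts[-1]
        parts = parts[:-1]
    if len(parts) < 3 or not parts[-1].startswith("rep"):
        raise MalformedRecordError(
            f"cannot parse sample label {label!r} "
            "(expected <cultivar>_<condition>_rep<N>[_IP|_input])"
        )
    cultivar = "_".join(parts[:-2])
    condition, rep = parts[-2], parts[-1]
    return {
        "cultivar": cultivar,
        "condition": condition,
        "replicate": rep,
        "group": f"{cultivar}_{condition}",
        "fraction": fraction,
    }


@dataclass
class CountTable:
    """Non-negative integer counts, features x samples.

    ``library_sizes`` defaults to column sums; ``metadata`` (indexed by
    sample) carries group/fraction labels used by the differential tests;
    ``feature_info`` optionally carries chrom/start/end for peak features.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series = None
    metadata: Optional[pd.DataFrame] = None
    feature_info: Optional[pd.DataFrame] = None

    def __post_init__(self):
        counts = self.counts
        if len(counts):
            arr = counts.to_numpy()
            if not pd.api.types.is_integer_dtype(counts.dtypes.iloc[0]) or any(
                not pd.api.types.is_integer_dtype(dt) for dt in counts.dtypes
            ):
                raise MalformedRecordError("counts must be integer-typed")
            if (arr < 0).any():
                i, j = divmod(int((arr < 0).argmax()), arr.shape[1])
                raise MalformedRecordError(
                    f"negative count at feature {counts.index[i]!r}, "
                    f"sample {counts.columns[j]!r}"
                )
        if self.library_sizes is None:
            self.library_sizes = counts.sum(axis=0).astype(float)
        self.library_sizes = self.library_sizes.reindex(counts.columns)
        if self.metadata is not None:
            self.metadata = self.metadata.reindex(counts.columns)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> List[str]:
        return list(self.counts.index)

    def samples_in(self, group: str, fraction: Optional[str] = None) -> List[str]:
        if self.metadata is None:
            raise ValueError("count table has no sample metadata")
        mask = self.metadata["group"] == group
        if fraction is not None:
            mask &= self.metadata["fraction"] == fraction
        return list(self.metadata.index[mask])


FEATURE_INFO_COLS = ("chrom", "start", "end")


def read_count_table(
    path, library_sizes: Optional[Mapping[str, float]] = None,
    infer_metadata: bool = True,
) -> CountTable:
    """Read a TSV count table (first column = feature id, header row).

    Columns named ``chrom``/``start``/``end`` are split off as feature
    coordinates.  Negative or non-integer counts raise, naming the cell.
    """
    df = pd.read_csv(_open(path), sep="\t", index_col=0)
    info = None
    info_cols = [c for c in FEATURE_INFO_COLS if c in df.columns]
    if info_cols:
        info = df[info_cols].copy()
        df = df.drop(columns=info_cols)
    for col in df.columns if len(df) else []:
        vals = df[col]
        if not pd.api.types.is_integer_dtype(vals):
            bad = vals.index[(vals != vals.round()) | vals.isna()]
            if len(bad):
                raise MalformedRecordError(
                    f"non-integer count at feature {bad[0]!r}, sample {col!r}"
                )
            df[col] = vals.astype("int64")
        if len(vals) and (vals < 0).any():
            bad = vals.index[vals < 0][0]
            raise MalformedRecordError(
                f"negative count at feature {bad!r}, sample {col!r}"
            )
    df = df.astype("int64") if len(df) else df
    sizes = None
    if library_sizes is not None:
        sizes = pd.Series(library_sizes, dtype=float)
    metadata = None
    if infer_metadata:
        try:
            metadata = pd.DataFrame(
                {c: parse_sample_label(c) for c in df.columns}
            ).T.reindex(columns=list(SAMPLE_META_COLS))
        except MalformedRecordError:
            metadata = None
    return CountTable(df, library_sizes=sizes, metadata=metadata, feature_info=info)


def write_count_table(table: CountTable, path) -> None:
    df = table.counts
    if table.feature_info is not None:
        df = pd.concat([table.feature_info, table.counts], axis=1)
    df.to_csv(_open(path, "wt"), sep="\t", index=True, lineterminator="\n")


def write_results(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a results table as plain TSV (UTF-8, no quoting)."""
    df.to_csv(_open(path, "wt"), sep="\t", index=index, lineterminator="\n")
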