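"""Readers and writers for the formats the tool touches.

FASTQ (optionally gzipped), SAM/BAM alignments, GTF/GFF3 annotation, FASTA
references, and the tool's own tab-separated output tables.  No algorithmic
logic lives here.

Coordinates are 0-based, half-open everywhere inside the package; the 1-based
inclusive conventions of GTF and SAM are converted at parse time.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

_VALID_BASES = set("ACGTN")
MAX_PHRED = 60


@dataclass
class SequencingRead:
    """One sequencing read: identifier, bases, per-base Phred qualities."""

    read_id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, Sanger (+33) encoding on disk

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if self.quals.size and (self.quals.min() < 0 or self.quals.max() > MAX_PHRED):
            raise ValueError(
                f"read {self.read_id!r}: Phred scores outside [0, {MAX_PHRED}] "
                "(is this Phred+64 encoded? only Phred+33 is supported)"
            )
        if set(self.bases) - _VALID_BASES:
            bad = sorted(set(self.bases) - _VALID_BASES)
            raise ValueError(f"read {self.read_id!r}: invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.bases)


def _open_maybe_gzip(path):
    """Open text, sniffing gzip by magic bytes rather than by extension."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path, limit: Optional[int] = None) -> Iterator[SequencingRead]:
    """Yield reads from a FASTQ / FASTQ.gz file in file order.

    Raises ``ValueError`` naming the record number on malformed records
    (header not starting with ``@``, base/quality length mismatch) and on
    quality characters that decode outside [0, 60] under Phred+33 —
    the usual signature of a Phred+64 file, which is rejected, not guessed.
    """
    n = 0
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            n += 1
            if not qual:
                raise ValueError(f"FASTQ record {n}: truncated record")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@"):
                raise ValueError(f"FASTQ record {n}: header does not start with '@'")
            if not plus.startswith("+"):
                raise ValueError(f"FASTQ record {n}: separator line missing '+'")
            if len(seq) != len(qual):
                raise ValueError(
                    f"FASTQ record {n}: {len(seq)} bases but {len(qual)} "
                    "quality characters"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            try:
                read = SequencingRead(header[1:].split()[0] if header[1:] else "",
                                      seq.upper(), quals)
            except ValueError as exc:
                raise ValueError(f"FASTQ record {n}: {exc}") from exc
            yield read
            if limit is not None and n >= limit:
                break


def write_fastq(reads: Iterable[SequencingRead], path) -> None:
    """Write reads as Phred+33 FASTQ; gzip-compressed iff path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {name: uppercase sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM/BAM record, reduced to what gene assignment needs."""

    read_id: str
    chrom: Optional[str]          # None for unmapped
    start: Optional[int]          # 0-based leftmost aligned position
    end: Optional[int]            # 0-based exclusive rightmost
    strand: Optional[str]         # '+' / '-' of the aligned read
    is_secondary: bool
    is_supplementary: bool
    is_unmapped: bool
    edit_distance: Optional[int]  # NM tag when present


def read_alignments(path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM/BAM file (header required).

    Secondary and supplementary records are yielded with their flags set;
    unmapped records are yielded with a null locus.
    """
    import pysam

    try:
        af = pysam.AlignmentFile(str(path))
    except ValueError as exc:
        raise ValueError(f"{path}: missing or invalid SAM/BAM header ({exc})") from exc
    with af:
        if not af.header.to_dict().get("SQ"):
            raise ValueError(f"{path}: missing @SQ header lines")
        for rec in af:
            if rec.is_unmapped:
                yield AlignmentRecord(rec.query_name, None, None, None, None,
                                      rec.is_secondary, rec.is_supplementary,
                                      True, None)
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            yield AlignmentRecord(
                rec.query_name,
                rec.reference_name,
                rec.reference_start,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
                rec.is_secondary,
                rec.is_supplementary,
                False,
                nm,
            )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

FEATURE_TYPES = ("5'UTR", "CDS", "3'UTR", "intron")


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int                       # 0-based half-open transcript span
    end: int
    features: dict = field(default_factory=dict)  # type -> [(start, end), ...]
    tts: int = -1                    # 0-based coordinate of the 3'-most base

    def __post_init__(self) -> None:
        if self.tts < 0:
            self.tts = self.end - 1 if self.strand == "+" else self.start


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list = field(default_factory=list)


@dataclass
class AnnotationModel:
    """Gene models with typed feature intervals and per-transcript 3' ends."""

    genes: dict = field(default_factory=dict)        # gene_id -> GeneModel
    transcripts: dict = field(default_factory=dict)  # tx_id -> TranscriptModel

    def tts_of_gene(self, gene_id: str) -> list:
        return [tx.tts for tx in self.genes[gene_id].transcripts]

    def feature_index(self):
        """Per-chromosome interval tree of (feature, gene_id) payloads."""
        from intervaltree import IntervalTree

        index: dict = {}
        for tx in self.transcripts.values():
            tree = index.setdefault(tx.chrom, IntervalTree())
            for ftype, intervals in tx.features.items():
                for (s, e) in intervals:
                    if e > s:
                        tree[s:e] = (ftype, tx.gene_id)
        return index


def _subtract(intervals, lo, hi):
    """Clip a sorted disjoint interval list to [lo, hi)."""
    out = []
    for (s, e) in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append((s2, e2))
    return out


def _derive_features(exons, cds, strand):
    """Type a transcript's intervals: UTRs from the exon/CDS difference,
    introns from the gaps between exons."""
    exons = sorted(exons)
    features: dict = {}
    introns = [
        (exons[i][1], exons[i + 1][0])
        for i in range(len(exons) - 1)
        if exons[i + 1][0] > exons[i][1]
    ]
    if introns:
        features["intron"] = introns
    if cds:
        cds = sorted(cds)
        cs, ce = cds[0][0], cds[-1][1]
        features["CDS"] = cds
        left = _subtract(exons, exons[0][0], cs)
        right = _subtract(exons, ce, exons[-1][1])
        five, three = (left, right) if strand == "+" else (right, left)
        if five:
            features["5'UTR"] = five
        if three:
            features["3'UTR"] = three
    return features


def read_annotation(path) -> AnnotationModel:
    """Parse GTF/GFF3 into an :class:`AnnotationModel`.

    3'UTRs are derived as the exonic span downstream of the CDS stop on the
    coding strand (5'UTRs symmetrically); introns are the gaps between
    exons.  Transcripts without exons are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    model = AnnotationModel()
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        model.genes[gene_id] = GeneModel(gene_id, g.seqid, g.strand)
    for tx in list(db.features_of_type("transcript")) + list(db.features_of_type("mRNA")):
        tx_id = tx.attributes.get("transcript_id", [tx.id])[0]
        gene_id = tx.attributes.get("gene_id", [None])[0]
        exons, cds = [], []
        for child in db.children(tx, featuretype="exon"):
            exons.append((child.start - 1, child.end))
        for child in db.children(tx, featuretype="CDS"):
            cds.append((child.start - 1, child.end))
        if not exons:
            warnings.warn(f"transcript {tx_id} has no exons; skipped")
            continue
        exons = sorted(exons)
        tm = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_id,
            chrom=tx.seqid,
            strand=tx.strand,
            start=exons[0][0],
            end=exons[-1][1],
            features=_derive_features(exons, cds, tx.strand),
        )
        model.transcripts[tx_id] = tm
        if gene_id in model.genes:
            model.genes[gene_id].transcripts.append(tm)
    return model


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "read_id", "gene_id", "prelim_start", "prelim_end", "tail_start",
    "tail_end", "tail_len", "adaptor_found", "qc_truncated", "discard_reason",
]

PROFILE_COLUMNS = ["gene_id", "n_reads", "median_tail_len"]


@dataclass
class TailCallTable:
    """Per-read tail calls as a DataFrame, keyed by (unique) read_id."""

    df: pd.DataFrame
    sample: str = ""
    params_fingerprint: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"call table missing columns {missing}")
        if self.df["read_id"].duplicated().any():
            dup = self.df["read_id"][self.df["read_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate read_id in call table: {dup!r}")


def write_calls(table: TailCallTable, path) -> None:
    """Write a call table as TSV: fixed column order, rows sorted by
    read_id, no timestamps — byte-identical across runs."""
    df = table.df[CALL_COLUMNS].sort_values("read_id", kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_calls(path, sample: str = "") -> TailCallTable:
    df = pd.read_csv(
        path, sep="\t",
        dtype={
            "read_id": str, "gene_id": str, "prelim_start": np.int64,
            "prelim_end": np.int64, "tail_start": np.int64,
            "tail_end": np.int64, "tail_len": np.int64,
            "adaptor_found": bool, "qc_truncated": bool, "discard_reason": str,
        },
        keep_default_na=False,
    )
    return TailCallTable(df, sample=sample)


def write_gene_profiles(profiles, path) -> None:
    """Write per-gene tail profiles (gene_id, n_reads, median) sorted by
    gene_id; deterministic byte-for-byte."""
    rows = [
        {"gene_id": p.gene_id, "n_reads": p.n_reads,
         "median_tail_len": p.median_tail_len}
        for p in profiles
    ]
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    df = df.sort_values("gene_id", kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_gene_profiles(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"gene_id": str, "n_reads": np.int64, "median_tail_len": np.int64},
        keep_default_na=False,
    )
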