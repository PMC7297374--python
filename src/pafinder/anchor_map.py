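"""Gene assignment of upstream anchor sequences.

The sequence 5' of the detected poly(A) region (the "anchor") derives from
the transcript body, almost always the 3'UTR terminus, and identifies the
gene the tail belongs to.  Two routes are provided:

* a built-in ungapped mapper for toy references (exhaustively correct up to
  the configured mismatch budget via pigeonhole seeding), and
* import of external SAM/BAM alignments for real, spliced genomes.

A read is "uniquely mapped" when exactly one locus attains the minimum
mismatch count (built-in route) or when it has a single primary alignment
and no secondary records (SAM route).  The inferred cleavage /
polyadenylation position is the genomic coordinate of the anchor's 3'-most
aligned base — the last templated nucleotide before the tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .io_formats import AlignmentRecord, AnnotationModel
from .params import ParameterSet, DEFAULT_PARAMS

FEATURE_PRIORITY = ("3'UTR", "CDS", "5'UTR", "intron")
DEFAULT_EXCLUDE_CHROMS = ("chrM", "MT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MAX_BUILTIN_REFERENCE = 10_000_000


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneAssignment:
    """Gene/feature assignment of one read's anchor."""

    read_id: str
    status: str                       # unique | multimapped | unmapped | anchor_too_short
    gene_id: Optional[str] = None
    chrom: Optional[str] = None
    strand: Optional[str] = None
    anchor_3prime_genomic_pos: Optional[int] = None  # inferred cleavage site
    feature: Optional[str] = None     # 3'UTR | CDS | 5'UTR | intron | intergenic
    n_mismatches: Optional[int] = None


def _hamming_leq(a: str, ref: str, start: int, budget: int) -> Optional[int]:
    """Mismatches of ``a`` vs ``ref[start:start+len(a)]`` if <= budget."""
    mm = 0
    for i, base in enumerate(a):
        if base != ref[start + i]:
            mm += 1
            if mm > budget:
                return None
    return mm


def _seed_hits(query: str, ref: str, n_chunks: int) -> set:
    """Candidate start positions via pigeonhole seeding.

    The query is split into ``n_chunks`` contiguous chunks; any occurrence
    with fewer than ``n_chunks`` mismatches leaves at least one chunk
    exact, so exact-matching every chunk finds all such loci.
    """
    L = len(query)
    bounds = [round(i * L / n_chunks) for i in range(n_chunks + 1)]
    candidates = set()
    for i in range(n_chunks):
        lo, hi = bounds[i], bounds[i + 1]
        chunk = query[lo:hi]
        pos = ref.find(chunk)
        while pos != -1:
            start = pos - lo
            if 0 <= start <= len(ref) - L:
                candidates.add(start)
            pos = ref.find(chunk, pos + 1)
    return candidates


def find_loci(anchor: str, reference: Dict[str, str],
              max_mm: int) -> List[Tuple[str, int, str, int]]:
    """All ungapped loci of ``anchor`` with <= ``max_mm`` mismatches.

    Returns (chrom, start, strand, mismatches) on both strands; a
    minus-strand locus means the reverse complement of the anchor matches
    the forward reference there.
    """
    hits = []
    queries = (("+", anchor), ("-", revcomp(anchor)))
    for chrom, ref in reference.items():
        for strand, query in queries:
            for start in _seed_hits(query, ref, max_mm + 1):
                mm = _hamming_leq(query, ref, start, max_mm)
                if mm is not None:
                    hits.append((chrom, start, strand, mm))
    return hits


def map_anchor_builtin(
    anchor: str,
    reference: Dict[str, str],
    params: ParameterSet = DEFAULT_PARAMS,
    read_id: str = "",
) -> GeneAssignment:
    """Map one anchor to a small reference, ungapped and unspliced.

    Anchors shorter than ``min_anchor_map_len`` are not mapped
    (``anchor_too_short``); among loci with at most ``map_max_mm``
    mismatches, exactly one at the minimum count means ``unique``.
    """
    total = sum(len(s) for s in reference.values())
    if total > MAX_BUILTIN_REFERENCE:
        raise ValueError(
            f"reference is {total} bp; the built-in mapper is for toy "
            "references <= 10 Mb — align externally and import the SAM/BAM"
        )
    if len(anchor) < params.min_anchor_map_len:
        return GeneAssignment(read_id=read_id, status="anchor_too_short")
    hits = find_loci(anchor, reference, params.map_max_mm)
    if not hits:
        return GeneAssignment(read_id=read_id, status="unmapped")
    best_mm = min(h[3] for h in hits)
    best = [h for h in hits if h[3] == best_mm]
    if len(best) > 1:
        return GeneAssignment(read_id=read_id, status="multimapped")
    chrom, start, strand, mm = best[0]
    cleavage = start + len(anchor) - 1 if strand == "+" else start
    return GeneAssignment(
        read_id=read_id, status="unique", chrom=chrom, strand=strand,
        anchor_3prime_genomic_pos=cleavage, n_mismatches=mm,
    )


def import_alignments(
    read_ids: Iterable[str],
    alignments: Iterable[AlignmentRecord],
) -> Dict[str, GeneAssignment]:
    """Turn external SAM/BAM records into per-read assignments.

    unique = exactly one primary mapped alignment and no secondary records;
    reads absent from the alignment stream are reported unmapped.
    """
    primary: Dict[str, List[AlignmentRecord]] = {}
    secondary_seen: set = set()
    for rec in alignments:
        if rec.is_supplementary:
            continue
        if rec.is_secondary:
            secondary_seen.add(rec.read_id)
            continue
        primary.setdefault(rec.read_id, []).append(rec)

    out: Dict[str, GeneAssignment] = {}
    for read_id in read_ids:
        recs = [r for r in primary.get(read_id, []) if not r.is_unmapped]
        if not recs:
            out[read_id] = GeneAssignment(read_id=read_id, status="unmapped")
        elif len(recs) > 1 or read_id in secondary_seen:
            out[read_id] = GeneAssignment(read_id=read_id, status="multimapped")
        else:
            rec = recs[0]
            cleavage = rec.end - 1 if rec.strand == "+" else rec.start
            out[read_id] = GeneAssignment(
                read_id=read_id, status="unique", chrom=rec.chrom,
                strand=rec.strand, anchor_3prime_genomic_pos=cleavage,
                n_mismatches=rec.edit_distance,
            )
    return out


def assign_feature(
    chrom: str, pos: int, annotation: AnnotationModel,
    feature_index=None,
) -> Tuple[str, Optional[str]]:
    """Classify a genomic position with priority 3'UTR > CDS > 5'UTR >
    intron > intergenic across all overlapping transcripts.

    Returns (feature, gene_id); gene_id is the gene contributing the
    winning feature (lexicographically smallest on ties), or None for
    intergenic positions.
    """
    index = feature_index if feature_index is not None else annotation.feature_index()
    tree = index.get(chrom)
    if tree is None:
        return "intergenic", None
    overlaps = tree[pos]
    if not overlaps:
        return "intergenic", None
    by_feature: Dict[str, List[str]] = {}
    for iv in overlaps:
        ftype, gene_id = iv.data
        by_feature.setdefault(ftype, []).append(gene_id)
    for ftype in FEATURE_PRIORITY:
        if ftype in by_feature:
            return ftype, sorted(by_feature[ftype])[0]
    return "intergenic", None


def annotate_assignments(
    assignments: Iterable[GeneAssignment], annotation: AnnotationModel
) -> List[GeneAssignment]:
    """Fill feature and gene_id for every assignment that has a locus."""
    index = annotation.feature_index()
    out = []
    for a in assignments:
        if a.status == "unique" and a.chrom is not None:
            a.feature, a.gene_id = assign_feature(
                a.chrom, a.anchor_3prime_genomic_pos, annotation, index
            )
        out.append(a)
    return out


def tts_distance(assignment: GeneAssignment,
                 annotation: AnnotationModel) -> int:
    """Signed, strand-aware distance from the inferred cleavage position to
    the nearest annotated transcript 3' end of the assigned gene
    (negative = upstream of the TTS)."""
    if assignment.status != "unique" or assignment.gene_id is None:
        raise ValueError("tts_distance needs a uniquely assigned read")
    pos = assignment.anchor_3prime_genomic_pos
    gene = annotation.genes[assignment.gene_id]
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    sign = 1 if gene.strand == "+" else -1
    dists = [sign * (pos - tx.tts) for tx in gene.transcripts]
    return min(dists, key=lambda d: (abs(d), d))


def tts_distances(
    assignments: Iterable[GeneAssignment],
    annotation: AnnotationModel,
    exclude_chroms: Tuple[str, ...] = DEFAULT_EXCLUDE_CHROMS,
) -> np.ndarray:
    """TTS-relative positions of poly(A) 5' boundaries over a sample;
    mitochondrial chromosomes are excluded by name by default."""
    vals = [
        tts_distance(a, annotation)
        for a in assignments
        if a.status == "unique" and a.gene_id is not None
        and a.chrom not in exclude_chroms
    ]
    return np.asarray(vals, dtype=int)
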