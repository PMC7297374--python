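"""Synthetic read generation with ground truth.

Emulates the data the caller assumes: each read runs 5'→3' from a genomic
anchor (the 3'UTR terminus of its source gene) through the poly(A) tail
and, when the read is long enough, into the 3' adaptor.  Instrument
behaviour at the tail/adaptor junction is modelled with two ingredients:

* a per-cycle quality collapse — high Phred scores through the true tail,
  a low plateau from the junction onward; and
* homopolymer A-signal bleeding — with probability ``bleed_prob`` a read
  gains a geometric number of spurious low-quality As past its true tail,
  which inflates naive tail calls and is exactly what the quality-bleeding
  filter is meant to remove.

Every read carries a truth record (source gene, true tail length, bled As,
adaptor presence, anchor length) so each pipeline stage is verifiable
without external data.  Identical config + seed gives byte-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io_formats import SequencingRead
from .spikein import SpikeInSpec

# Default 3' adaptor of the simulator: A-free (like an adaptor chosen to be
# distinguishable from the tail), so called tails are not systematically
# offset by adaptor bases aliasing into the fuzzy poly(A) anchors.  An
# adaptor with As near its start merely shifts calls by the length of the
# initial A-alias — the same effect that merges a 5'-adaptor terminal A
# into the tail.
DEFAULT_SIM_ADAPTOR3 = "TCGGTCGTCGCTGTCGGTTGCCGTTGGTGC"

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_COLUMNS = [
    "read_id", "gene_id", "true_tail_len", "visible_tail_len",
    "bled_extra_As", "adaptor_in_read", "anchor_len",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulator; defaults are the study conditions the
    package is validated under (150-nt end-1 reads, 50 genes, low
    substitution noise, no bleeding unless asked for)."""

    seed: int = 0
    n_reads: int = 20_000
    read_len: int = 150
    n_genes: int = 50
    utr3_len_range: Tuple[int, int] = (200, 400)
    utr5_len: int = 100
    cds_len: int = 300
    intron_len: int = 80
    spacer_len: int = 100
    tail_mean_range: Tuple[float, float] = (30.0, 150.0)
    tail_sd: float = 10.0
    anchor_len_range: Tuple[int, int] = (20, 60)
    adaptor3: str = DEFAULT_SIM_ADAPTOR3
    substitution_rate: float = 0.001
    qual_hi: int = 37
    qual_lo: int = 10
    bleed_prob: float = 0.0
    bleed_len_geom_p: float = 0.25   # geometric run length, mean 1/p = 4 nt

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "bleed_prob", "bleed_len_geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_len < 30:
            raise ValueError("read_len too short to hold anchor + minimal tail")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("utr3_len_range", "tail_mean_range", "anchor_len_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class ToyGene:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int            # 0-based half-open genomic transcript span
    tx_end: int
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]]
    transcript_seq: str      # spliced, transcript orientation
    tts: int                 # genomic coordinate of the 3'-most base
    tail_mean: float = 0.0


@dataclass
class ToyGenome:
    sequences: Dict[str, str]
    genes: List[ToyGene]
    gtf_text: str

    def write(self, fasta_path, gtf_path) -> None:
        from .io_formats import write_fasta

        write_fasta(self.sequences, fasta_path)
        with open(gtf_path, "w") as fh:
            fh.write(self.gtf_text)


def _random_seq(rng: np.random.Generator, n: int, forbid_a_runs: bool = False) -> str:
    """Random sequence; optionally with A down-weighted so no long A runs
    arise that could mimic a tail inside the transcript body."""
    if forbid_a_runs:
        probs = np.array([0.10, 0.30, 0.30, 0.30])
    else:
        probs = np.full(4, 0.25)
    arr = rng.choice(_ALPHABET, size=n, p=probs)
    return arr.tobytes().decode("ascii")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def make_toy_genome(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> ToyGenome:
    """Build a deterministic toy genome + GTF.

    One chromosome; each gene has a 5'UTR, a CDS split by one intron, and a
    3'UTR whose two terminal bases are forced non-A (so templated 3'UTR As
    never blur into the non-templated tail).  Strands alternate.  All 20-mers of
    the transcript sequences are verified unique across genes (exact k-mer
    index; offending genes are re-drawn) so anchors map back uniquely.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    chrom = "chr1"
    parts: List[str] = []
    genes: List[ToyGene] = []
    kmer_index: set = set()
    K = 20
    cursor = 0
    tail_means = rng.uniform(*config.tail_mean_range, size=max(config.n_genes, 1))
    for i in range(config.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        utr3_len = int(rng.integers(config.utr3_len_range[0],
                                    config.utr3_len_range[1] + 1))
        for _attempt in range(50):
            utr5 = _random_seq(rng, config.utr5_len, forbid_a_runs=True)
            cds = _random_seq(rng, config.cds_len, forbid_a_runs=True)
            utr3 = _random_seq(rng, utr3_len, forbid_a_runs=True)
            # Last two 3'UTR bases are forced non-A: with >= 2 non-A bases
            # at the cleavage site, the fuzzy one-mismatch anchors cannot
            # reach templated As, so zero-noise calls recover the tail
            # boundary exactly (genes with A-rich cleavage contexts merge
            # templated As into the tail, like the spike-in's +1 adaptor A).
            tail2 = "".join(str(rng.choice(list("CGT"))) for _ in range(2))
            utr3 = utr3[:-2] + tail2
            tx_seq = utr5 + cds + utr3
            kmers = {tx_seq[j:j + K] for j in range(len(tx_seq) - K + 1)}
            rc = _revcomp(tx_seq)
            kmers |= {rc[j:j + K] for j in range(len(rc) - K + 1)}
            if not (kmers & kmer_index):
                kmer_index |= kmers
                break
        else:
            raise RuntimeError("could not draw a distinct gene sequence")
        intron = _random_seq(rng, config.intron_len, forbid_a_runs=True)
        # genomic (+) layout of the spliced transcript with one intron in
        # the middle of the CDS
        half = config.cds_len // 2
        if strand == "+":
            genomic = utr5 + cds[:half] + intron + cds[half:] + utr3
        else:
            genomic = _revcomp(utr5 + cds[:half] + intron + cds[half:] + utr3)
        spacer = _random_seq(rng, config.spacer_len)
        parts.append(spacer)
        cursor += len(spacer)
        tx_start, tx_end = cursor, cursor + len(genomic)
        parts.append(genomic)
        cursor = tx_end

        if strand == "+":
            e1 = (tx_start, tx_start + config.utr5_len + half)
            e2 = (e1[1] + config.intron_len, tx_end)
            cds_iv = [
                (tx_start + config.utr5_len, e1[1]),
                (e2[0], e2[0] + (config.cds_len - half)),
            ]
            tts = tx_end - 1
        else:
            # genomic reverse of the + layout: utr3 comes first on the
            # forward strand
            e1 = (tx_start, tx_start + utr3_len + (config.cds_len - half))
            e2 = (e1[1] + config.intron_len, tx_end)
            cds_iv = [
                (tx_start + utr3_len, e1[1]),
                (e2[0], e2[0] + half),
            ]
            tts = tx_start
        genes.append(ToyGene(
            gene_id=f"gene{i:03d}", chrom=chrom, strand=strand,
            tx_start=tx_start, tx_end=tx_end, exons=[e1, e2], cds=cds_iv,
            transcript_seq=tx_seq, tts=tts, tail_mean=float(tail_means[i]),
        ))
    sequences = {chrom: "".join(parts)}
    return ToyGenome(sequences, genes, _gtf_text(genes))


def _gtf_text(genes: List[ToyGene]) -> str:
    """GTF (1-based inclusive) for the toy genes."""
    lines = []

    def row(gene, feature, start, end, tx=True):
        attrs = f'gene_id "{gene.gene_id}";'
        if tx:
            attrs += f' transcript_id "{gene.gene_id}.t1";'
        lines.append(
            "\t".join([
                gene.chrom, "toysim", feature, str(start + 1), str(end),
                ".", gene.strand, ".", attrs,
            ])
        )

    for gene in genes:
        row(gene, "gene", gene.tx_start, gene.tx_end, tx=False)
        row(gene, "transcript", gene.tx_start, gene.tx_end)
        for (s, e) in gene.exons:
            row(gene, "exon", s, e)
        for (s, e) in gene.cds:
            row(gene, "CDS", s, e)
    return "\n".join(lines) + "\n"


def _apply_substitutions(bases: np.ndarray, rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return bases
    hit = np.flatnonzero(rng.random(bases.size) < rate)
    if hit.size == 0:
        return bases
    # replace with a uniformly drawn *different* base
    repl = rng.integers(0, 3, size=hit.size)
    cur_idx = np.searchsorted(_ALPHABET, bases[hit])
    new_idx = repl + (repl >= cur_idx)
    bases = bases.copy()
    bases[hit] = _ALPHABET[new_idx]
    return bases


def _assemble_read(read_id: str, anchor: str, true_tail: int, bled: int,
                   adaptor3: str, read_len: int, qual_hi: int, qual_lo: int,
                   substitution_rate: float,
                   rng: np.random.Generator) -> Tuple[SequencingRead, bool]:
    """Anchor + tail As + bled As + tiled adaptor, truncated at read_len;
    high quality through the true tail, low after the junction."""
    junction = len(anchor) + true_tail
    n_adaptor = max(0, read_len - junction - bled)
    adaptor_fill = (adaptor3 * (n_adaptor // len(adaptor3) + 2))[:n_adaptor]
    seq = (anchor + "A" * (true_tail + bled) + adaptor_fill)[:read_len]
    quals = np.full(len(seq), qual_lo, dtype=np.int16)
    quals[:min(junction, len(seq))] = qual_hi
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    arr = _apply_substitutions(arr, substitution_rate, rng)
    adaptor_in_read = n_adaptor > 0 and junction + bled < read_len
    return SequencingRead(read_id, arr.tobytes().decode("ascii"), quals), adaptor_in_read


def simulate_reads(
    config: SimulationConfig,
    genome: Optional[ToyGenome] = None,
) -> Tuple[ToyGenome, List[SequencingRead], pd.DataFrame]:
    """Generate reads + truth from a toy genome (built here if not given).

    Per read: a uniformly chosen gene, an anchor that is a suffix of its
    3'UTR ending at the TTS, a truncated-normal integer tail (floor 0,
    per-gene mean, common sd), optional geometric bleeding, then the 3'
    adaptor tiled to the read end.  The truth table also records
    ``visible_tail_len`` = min(true tail, bases available after the
    anchor), the quantity a read-bounded caller can report.
    """
    ss = np.random.SeedSequence(config.seed).spawn(2)
    if genome is None:
        genome = make_toy_genome(config, np.random.default_rng(ss[0]))
    rng = np.random.default_rng(ss[1])
    reads: List[SequencingRead] = []
    truth_rows = []
    n_genes = len(genome.genes)
    if n_genes == 0:
        raise ValueError("toy genome has no genes")
    gene_idx = rng.integers(0, n_genes, size=config.n_reads)
    anchor_lens = rng.integers(config.anchor_len_range[0],
                               config.anchor_len_range[1] + 1,
                               size=config.n_reads)
    for i in range(config.n_reads):
        gene = genome.genes[int(gene_idx[i])]
        a_len = int(anchor_lens[i])
        anchor = gene.transcript_seq[-a_len:]
        true_tail = max(0, int(round(rng.normal(gene.tail_mean, config.tail_sd))))
        bled = 0
        if config.bleed_prob > 0 and rng.random() < config.bleed_prob:
            bled = int(rng.geometric(config.bleed_len_geom_p))
        read_id = f"read{i:06d}"
        read, adaptor_in_read = _assemble_read(
            read_id, anchor, true_tail, bled, config.adaptor3,
            config.read_len, config.qual_hi, config.qual_lo,
            config.substitution_rate, rng,
        )
        reads.append(read)
        truth_rows.append((
            read_id, gene.gene_id, true_tail,
            min(true_tail, config.read_len - a_len),
            min(bled, max(0, config.read_len - a_len - true_tail)),
            adaptor_in_read, a_len,
        ))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return genome, reads, truth


def simulate_spikein_reads(
    spec: SpikeInSpec,
    n: int,
    read_len: int = 150,
    adaptor3: Optional[str] = DEFAULT_SIM_ADAPTOR3,
    qual_hi: int = 37,
    qual_lo: int = 10,
    substitution_rate: float = 0.0,
    bleed_prob: float = 0.0,
    bleed_len_geom_p: float = 0.25,
    seed: int = 0,
) -> Tuple[List[SequencingRead], pd.DataFrame]:
    """Reads reconstructing a spike-in: a 6-nt library prefix of Gs, the
    transcribed 5' adaptor, the expected tail, then (optionally) bleeding
    and the 3' adaptor; truncated at ``read_len``."""
    rng = np.random.default_rng(seed)
    prefix = "G" * spec.library_prefix_len + spec.transcribed_adaptor
    reads, rows = [], []
    for i in range(n):
        bled = 0
        if bleed_prob > 0 and rng.random() < bleed_prob:
            bled = int(rng.geometric(bleed_len_geom_p))
        read_id = f"{spec.name.lower()}:{i:06d}"
        read, adaptor_in_read = _assemble_read(
            read_id, prefix, spec.expected_tail_len, bled,
            adaptor3 if adaptor3 else "N", read_len, qual_hi, qual_lo,
            substitution_rate, rng,
        )
        if not adaptor3:
            read = SequencingRead(
                read.read_id,
                read.bases[: len(prefix) + spec.expected_tail_len + bled],
                read.quals[: len(prefix) + spec.expected_tail_len + bled],
            )
        reads.append(read)
        rows.append((
            read_id, spec.name, spec.expected_tail_len,
            min(spec.expected_tail_len, read_len - len(prefix)),
            min(bled, max(0, read_len - len(prefix) - spec.expected_tail_len)),
            adaptor_in_read and bool(adaptor3), len(prefix),
        ))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
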