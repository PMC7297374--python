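"""Aggregate tail-length statistics and figure-ready tables.

Per-gene medians, tail-length histograms, per-cycle and junction-anchored
base composition, empirical cumulative fractions, adaptor-detection error-
rate sweeps, and cross-sample per-gene concordance.  Everything here
consumes per-read calls (and, where needed, the reads themselves) and emits
plain pandas DataFrames that serialize to TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .params import ParameterSet, DEFAULT_PARAMS
from .tailcall import PolyACall, detect_adaptor

BASES = ("A", "C", "G", "T", "N")


@dataclass
class GeneTailProfile:
    """Per-gene aggregate of called tail lengths."""

    gene_id: str
    tail_lengths: List[int]
    n_reads: int
    median_tail_len: int

    def __post_init__(self) -> None:
        if self.n_reads != len(self.tail_lengths) or self.n_reads < 1:
            raise ValueError("n_reads must equal |tail_lengths| >= 1")


def lower_median(values: Sequence[int]) -> int:
    """Median with the lower of the two central values on even counts.

    Keeps the statistic integer-valued for integer tails.
    """
    if len(values) == 0:
        raise ValueError("median of empty set")
    ordered = sorted(values)
    return int(ordered[(len(ordered) - 1) // 2])


def gene_medians(
    tail_lengths_by_gene: Dict[str, Sequence[int]],
) -> Tuple[List[GeneTailProfile], Optional[int]]:
    """Per-gene tail profiles plus the pooled sample-level median.

    Input maps gene_id to the tail lengths of its retained, uniquely
    assigned reads; genes with zero reads simply do not appear.
    """
    profiles = []
    pooled: List[int] = []
    for gene_id in sorted(tail_lengths_by_gene):
        lengths = [int(v) for v in tail_lengths_by_gene[gene_id]]
        if not lengths:
            continue
        pooled.extend(lengths)
        profiles.append(
            GeneTailProfile(gene_id, lengths, len(lengths), lower_median(lengths))
        )
    sample_median = lower_median(pooled) if pooled else None
    return profiles, sample_median


def group_tails_by_gene(calls: Iterable[PolyACall],
                        gene_of_read: Dict[str, str]) -> Dict[str, List[int]]:
    """Collect retained calls' tail lengths per assigned gene."""
    out: Dict[str, List[int]] = {}
    for call in calls:
        if not call.retained:
            continue
        gene = gene_of_read.get(call.read_id)
        if gene is None:
            continue
        out.setdefault(gene, []).append(call.tail_len)
    return out


def tail_histogram(tail_lengths: Sequence[int], bin_width: int = 1) -> pd.DataFrame:
    """Histogram over half-open bins [k*w, (k+1)*w); fractions sum to 1."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    lengths = np.asarray(list(tail_lengths), dtype=int)
    if lengths.size == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count", "fraction"])
    idx = lengths // bin_width
    counts = np.bincount(idx)
    ks = np.arange(len(counts))
    df = pd.DataFrame({
        "bin_start": ks * bin_width,
        "bin_end": (ks + 1) * bin_width,
        "count": counts,
        "fraction": counts / lengths.size,
    })
    return df[df["count"] > 0].reset_index(drop=True)


def _composition(columns: Iterable[Tuple[int, str]]) -> pd.DataFrame:
    """Tally (position, base) pairs into per-position base fractions."""
    counts: Dict[int, np.ndarray] = {}
    base_idx = {b: i for i, b in enumerate(BASES)}
    for pos, base in columns:
        row = counts.setdefault(pos, np.zeros(len(BASES), dtype=np.int64))
        row[base_idx.get(base, len(BASES) - 1)] += 1
    positions = sorted(counts)
    data = {"position": positions}
    totals = np.array([counts[p].sum() for p in positions], dtype=float)
    for i, b in enumerate(BASES):
        data[b] = np.array([counts[p][i] for p in positions]) / totals
    data["n_reads"] = totals.astype(int)
    return pd.DataFrame(data)


def base_composition_by_cycle(reads) -> pd.DataFrame:
    """Fraction of each base among reads covering each sequencing cycle.

    Rows are cycles (0-based); base columns sum to 1 over the reads that
    reach that cycle.
    """
    max_len = 0
    counts = None
    base_idx = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        base_idx[ord(b)] = i
    chunks = []
    for read in reads:
        chunks.append(np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8))
    if not chunks:
        return pd.DataFrame(columns=["position", *BASES, "n_reads"])
    max_len = max(len(c) for c in chunks)
    counts = np.zeros((max_len, len(BASES)), dtype=np.int64)
    for arr in chunks:
        idx = base_idx[arr]
        np.add.at(counts[: len(arr)], (np.arange(len(arr)), idx), 1)
    totals = counts.sum(axis=1).astype(float)
    data = {"position": np.arange(max_len)}
    for i, b in enumerate(BASES):
        data[b] = counts[:, i] / totals
    data["n_reads"] = counts.sum(axis=1)
    return pd.DataFrame(data)


def junction_composition(
    pairs: Iterable[Tuple[str, int]], upstream: int = 10, downstream: int = 30
) -> pd.DataFrame:
    """Base composition around the tail/adaptor junction.

    ``pairs`` yields (trimmed read bases, tail_end); offset 0 is the first
    base after the called tail, negative offsets reach back into the tail.
    The A-fraction decay over offsets 0..downstream quantifies homopolymer
    signal bleeding into the adaptor.
    """
    cols = []
    for bases, tail_end in pairs:
        lo = max(0, tail_end - upstream)
        hi = min(len(bases), tail_end + downstream)
        for pos in range(lo, hi):
            cols.append((pos - tail_end, bases[pos]))
    df = _composition(cols)
    return df.rename(columns={"position": "offset"})


def cumulative_fraction(tail_lengths: Sequence[int]) -> pd.DataFrame:
    """Right-continuous empirical CDF of tail lengths; reaches 1 at the max."""
    lengths = np.asarray(list(tail_lengths), dtype=int)
    if lengths.size == 0:
        raise ValueError("cumulative_fraction needs at least one length")
    values, counts = np.unique(lengths, return_counts=True)
    return pd.DataFrame({
        "tail_len": values,
        "cum_fraction": np.cumsum(counts) / lengths.size,
    })


def adaptor_detection_sweep(
    pairs: Iterable[Tuple[str, int]],
    adaptor3: str,
    rates: Sequence[float] = (0.1, 0.2, 0.25, 0.3, 0.35),
    params: ParameterSet = DEFAULT_PARAMS,
    eligible_only: bool = False,
) -> pd.DataFrame:
    """Fraction of tail-reads with a detectable 3' adaptor at each error rate.

    ``pairs`` yields (trimmed read bases, tail_end) for retained calls.  By
    default the denominator is all retained tail-reads, so tails running to
    the read end count as not-detected; with ``eligible_only`` the
    denominator keeps only reads with at least a probe length of sequence
    downstream of the tail.  Output is monotone nondecreasing in rate.
    """
    rates = sorted(rates)
    pairs = list(pairs)
    if eligible_only:
        pairs = [
            (b, e) for b, e in pairs if len(b) - e >= params.adaptor_probe_len
        ]
    found = np.zeros(len(rates), dtype=np.int64)
    n = len(pairs)
    for bases, tail_end in pairs:
        for i, rate in enumerate(rates):
            # monotone: first detecting rate implies all larger rates
            if detect_adaptor(bases, tail_end, adaptor3, error_rate=rate,
                              params=params):
                found[i:] += 1
                break
    return pd.DataFrame({
        "error_rate": rates,
        "n_reads": n,
        "fraction_detected": found / n if n else np.zeros(len(rates)),
    })


def median_concordance(
    profiles_a: Sequence[GeneTailProfile],
    profiles_b: Sequence[GeneTailProfile],
) -> Tuple[pd.DataFrame, float, float]:
    """Per-gene median comparison between two samples.

    Inner-joins on gene_id and reports Pearson and Spearman correlation of
    the paired medians; requires at least 3 shared genes.
    """
    a = {p.gene_id: p.median_tail_len for p in profiles_a}
    b = {p.gene_id: p.median_tail_len for p in profiles_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    df = pd.DataFrame({
        "gene_id": shared,
        "median_a": [a[g] for g in shared],
        "median_b": [b[g] for g in shared],
    })
    pearson = float(_scipy_stats.pearsonr(df["median_a"], df["median_b"])[0])
    spearman = float(_scipy_stats.spearmanr(df["median_a"], df["median_b"])[0])
    return df, pearson, spearman
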