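# pafinder

Poly(A)-tail length profiling from Illumina-style reads sequenced 5'→3'
from the transcript body *into* the tail.

## The problem

The length of the poly(A) tail — the homopolymeric adenosine run appended
to the 3' end of eukaryotic mRNAs — regulates transcript stability and
translation. Direct short-read sequencing through the tail is attractive
(depth, cost), but calling tail lengths from such reads is not trivial:

* the tail boundaries must be found fuzzily (sequencing error inside long
  A homopolymers is high);
* genomic A-runs must not be mistaken for tails;
* on two-channel chemistries the strong homopolymer signal *bleeds* into
  the 3' adaptor, appending spurious As and inflating the call; absent
  signal is read as G, producing trailing poly(G) artifacts;
* a read only shows the part of the tail it covers, so spike-in controls
  of known tail length are needed to calibrate what the caller reports.

`pafinder` implements the complete calling pipeline per read:

1. **Trim** — optional fuzzy 5'-adaptor removal and truncation at
   dark-signal poly(G) runs (≥ 10 G).
2. **Preliminary region** — the interval between the 5'-most fuzzy **9-A**
   window and the 3'-most fuzzy **6-A** window (1 mismatch each); regions
   < 10 nt are discarded.
3. **Refine** — non-A runs ≥ 5 nt split the region; the longest qualifying
   segment (ties: 5'-most) is the tail; it must contain ≥ 10 consecutive
   As and start/end on A.
4. **Quality-bleeding filter** (opt-in) — the tail is truncated at the
   first 3-position window with mean Phred < 25, removing bled As.
5. **Adaptor detection** — a fuzzy 20-nt probe of the 3' adaptor just
   downstream of the tail (error rate 0.2 by default) tells whether the
   tail was sequenced to its natural end.

The sequence upstream of the preliminary region (the *anchor*, ≥ 20 nt,
≤ 2 mismatches) assigns the read to its gene — via a built-in exhaustive
mapper for toy references or imported SAM/BAM alignments for real genomes.
Per-gene statistics use the **lower median** of the per-read tail lengths.
A synthetic read simulator (toy genome + tails + junction quality collapse
+ geometric A-bleeding, with per-read ground truth) makes every stage
verifiable without external data.

## Worked example

```python
import numpy as np
from pafinder import SequencingRead, call_read
from pafinder.simulate import DEFAULT_SIM_ADAPTOR3, simulate_spikein_reads
from pafinder.spikein import DEFAULT_SPIKEINS
from pafinder.profiles import lower_median

a40, a120 = DEFAULT_SPIKEINS     # shipped spike-in constructs

# 150-nt reads over the 120-nt-tail spike-in: the read end caps the tail
reads, _ = simulate_spikein_reads(a120, 1000, read_len=150, adaptor3=None, seed=0)
print(lower_median([call_read(r).tail_len for r in reads]))
# -> 105   (104 tail As fit in the read, plus the adaptor's terminal A)

# 40-nt-tail spike-in with full 3'-adaptor readthrough
reads, _ = simulate_spikein_reads(a40, 1000, read_len=150,
                                  adaptor3=DEFAULT_SIM_ADAPTOR3, seed=0)
calls = [call_read(r, adaptor3=DEFAULT_SIM_ADAPTOR3) for r in reads]
print(lower_median([c.tail_len for c in calls]), all(c.adaptor_found for c in calls))
# -> 40 True
```

The first number shows the read-length cap: a 120-nt tail on a 150-nt read
is reported at its visible length, 105 nt (no extrapolation past the read
end). The second shows exact recovery of a fully sequenced 40-nt tail with
the adaptor detected downstream of every tail.

## Command line

```bash
pafinder simulate --seed 7 --n-reads 5000 --out-dir sim/
pafinder call     --fastq sim/reads.fq.gz --adaptor3 TCGGTCGTCGCTGTCGGTTGCCGTTGGTGC \
                  --out calls.tsv
pafinder map      --calls calls.tsv --fastq sim/reads.fq.gz \
                  --reference sim/genome.fa --gtf sim/genes.gtf --out assign.tsv
pafinder stats    --calls calls.tsv --assign assign.tsv \
                  --fastq sim/reads.fq.gz --out-dir stats/
pafinder spikein  --fastq spike.fq --out-dir spike/
```

Every output directory gets a `manifest.json` (version, parameters, input
digests) sufficient to re-run the command. Exit codes: 0 success, 1 usage
error, 2 data error. The `--qc-bleed-filter` flag (or the `novaseq`
preset) enables the quality-bleeding truncation.

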