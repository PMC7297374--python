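# Methods

## The calling model

A read is assumed to run 5'→3' from the transcript body (the *anchor*),
through the non-templated poly(A) tail, and — when the cDNA insert is
short enough — into the 3' sequencing adaptor. Tail calling is a per-read
decision problem: locate the tail interval on the read, robustly to
homopolymer sequencing error, and report its length.

**Fuzzy anchors.** The preliminary tail region is bounded by the 5'-most
9-nt window with at most one non-A base and the 3'-most 6-nt window with
at most one non-A base. One mismatch per window is the operational default;
rate-based budgets (0.1 on the 9-mer ⇒ 0 mismatches by flooring, 0.2 on
the 6-mer ⇒ 1) remain available via
`ParameterSet(use_anchor_error_rates=True)`. Because a one-mismatch window
may begin or end on a non-A base, each boundary can sit one base outside
the true A-run; the refinement step strips the tail back to start and end
on 'A'. Preliminary regions shorter than 10 nt are discarded. Note a
practical consequence of the fuzzy edges: the framed region of a clean
k-A run is k+2 long, so reads with 8- or 9-A tails pass the length gate
and are instead removed by the pure-run criterion below — either way, no
tail below 10 nt is ever reported.

**Refinement.** Within the preliminary region, maximal non-A runs of
length ≥ 5 split the region into segments (this is what shields against
genomic A-rich stretches: a templated interruption ≥ 5 nt ends the tail).
Each segment is stripped to its A boundaries; segments qualify if they
contain ≥ 10 consecutive As without mismatch. Among qualifying segments
the longest wins, ties going 5'-most (the 5' segment is contiguous with
the mapped anchor). This is provably equivalent to choosing the longest
subinterval of the preliminary region that starts/ends on A, contains no
disqualifying non-A run and holds a pure 10-A stretch — the brute-force
enumeration the test suite checks against, exhaustively for all {A,C}
strings up to length 14 and on 10,000 random longer strings.

**Quality-bleeding filter (opt-in).** On two-channel chemistries the
homopolymer A signal bleeds into the adaptor, appending spurious
low-quality As. The filter scans the called tail 5'→3' and truncates at
the start of the first 3-position window whose mean Phred score is
strictly below 25. The window mean makes the cut conservative: a window
straddling the junction (e.g. qualities 37, 10, 10) already triggers, so
truncation lands at most one base inside the true tail. The filter is
monotone (never lengthens) and idempotent; a truncated tail that loses its
minimum length or pure-A run discards the read. It is off by default and
enabled per run (`--qc-bleed-filter`, or the `novaseq` preset) because on
chemistries without pronounced bleeding it costs a base of accuracy for no
benefit.

**Adaptor detection.** A tail that reaches its natural end is followed by
the 3' adaptor. The first 20 nt of the adaptor are Hamming-compared to the
read at offsets 0..3 downstream of the tail end, allowing
`floor(rate × 20)` mismatches (default rate 0.2; the sweep rates 0.1,
0.2, 0.25, 0.3, 0.35 are provided for sensitivity analysis — detection is
monotone in the rate by construction). The small offset window absorbs a
few bled As between tail and adaptor. Tails running to the read end can
never have their adaptor detected; the sweep's default denominator counts
them as not-detected (an `eligible_only` mode restricts the denominator
to reads with a full probe length downstream).

**Reported length.** Always the visible length on the read — no
extrapolation past the read end. This is why a 120-nt spike-in tail on a
150-nt read is reported at 105 nt: 104 tail As fit after the 46-nt prefix,
plus the transcribed 5' adaptor's terminal A, which is indistinguishable
from the tail and merges into it.

## Gene assignment

The anchor (read prefix upstream of the preliminary region) maps the read
to its gene. Anchors under 20 nt are not mapped. The built-in mapper is
ungapped and unspliced, intended for toy references ≤ 10 Mb: pigeonhole
seeding (max_mm+1 contiguous exact chunks) guarantees it finds exactly the
loci an all-positions Hamming scan would find within the 2-mismatch
budget; a single minimum-mismatch locus counts as unique. Real, spliced
genomes are handled by importing external SAM/BAM alignments (unique =
one primary alignment, no secondary records). The inferred cleavage /
polyadenylation position is the genomic coordinate of the anchor's
3'-most aligned base; positions are classified against the annotation with
priority 3'UTR > CDS > 5'UTR > intron > intergenic, and strand-aware
signed distances to the nearest annotated transcript 3' end (TTS) are
provided (mitochondrial chromosomes excluded by name, default chrM/MT).

## Aggregation

Per-gene tail profiles use the **lower median** (the smaller central value
on even counts), keeping the statistic integer-valued. The sample-level
median pools all retained reads and is therefore invariant to how reads
are assigned to genes. Histograms use half-open bins [k·w, (k+1)·w);
cumulative fractions are right-continuous empirical CDFs. Junction-anchored
base composition aligns reads at the called tail end (offset 0 = first
post-tail base); the decay of the A fraction over offsets 0..30 is the
bleeding signature. Cross-sample concordance inner-joins per-gene medians
(≥ 3 shared genes) and reports Pearson and Spearman correlations.

## Spike-in analysis

Two constructs ship as defaults, named by their tail lengths (A40, A120).
Their printed 5' adaptors begin with the 20-nt T7 promoter
`TAATACGACTCACTATAGGG`; transcription retains everything after it, so the
transcribed adaptor is 40 nt for both. The A120 transcribed adaptor ends
in A (hence the +1 in its called tails); A40's ends in G. Spike-in reads
are identified by a fuzzy match of the transcribed adaptor within the
first `library_prefix_len + 4` start positions (≤ 2 mismatches, matching
the mapping budget; specs must be pairwise distinguishable at twice that
budget or configuration fails). Matched reads are called with the 5'
anchor search constrained to start at the adaptor's end minus one — so the
adaptor's terminal A may join the tail but internal adaptor A-runs cannot
masquerade as it.

## The simulator

The generator emulates exactly the structure the caller assumes, with
per-read ground truth:

* **Toy genome** — one chromosome; each gene has a 5'UTR (100 nt), a CDS
  (300 nt) split by one 80-nt intron, and a 3'UTR of 200–400 nt; strands
  alternate. All transcript 20-mers are kept unique across genes (exact
  k-mer index, redraw on collision) so anchors map back uniquely. The two
  junction-adjacent 3'UTR bases are forced non-A: with two non-A bases at
  the cleavage site the one-mismatch anchors provably cannot reach
  templated As, so zero-noise calls recover the tail boundary exactly.
  Real genes with A-rich cleavage contexts *do* merge templated As into
  the called tail (the same effect as the spike-in's +1 adaptor A); the
  simulator deliberately excludes that ambiguity so that recovery tests
  measure the caller, not the genome.
* **Reads** — uniform gene choice; anchor = 3'UTR suffix ending at the
  TTS, length uniform 20–60 nt; true tail ~ round(Normal(per-gene mean,
  sd 10)) floored at 0, with per-gene means drawn uniformly from 30–150 nt;
  then the 3' adaptor tiled to the 150-nt read end. Per-base substitution
  noise (default 0.001) replaces a base with a uniformly drawn different
  base.
* **Junction instrument model** — qualities are a high plateau (Q37)
  through the true tail and a low plateau (Q10) after the junction. With
  probability `bleed_prob` a read gains Geometric(p = 0.25; mean 4 nt)
  spurious As past its true tail, at the low quality — so the quality
  filter is the correct remedy, mirroring how bleeding manifests on real
  two-channel data. No quantitative bleeding distribution is established
  for these instruments; the geometric model is a configurable stand-in.
* **Truth** — per read: source gene, true tail length, `visible_tail_len`
  = min(true tail, read length − anchor length) (the quantity a
  read-bounded caller can report, and what recovery tests compare
  against), bled As actually present in the read, adaptor presence,
  anchor length.

Identical config + seed gives byte-identical FASTQ/truth output (seeds are
split deterministically between genome and reads, so the same genome seed
yields the same genome regardless of read parameters).

What the simulator does **not** model: oligo(dT) capture bias toward
longer tails, PCR duplicates, indels, instrument-specific error spectra,
RNase fragmentation biology (anchors always end at the TTS), mixed G/U
tailing, and paired-end mates (tail calling uses end-1 layout only).
Passing recovery tests therefore demonstrate correctness of the caller's
logic under its stated read model, not end-to-end accuracy on an arbitrary
real library.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; GTF/SAM conventions are
  converted at parse time. Quality encoding is fixed to Phred+33; files
  that decode outside [0, 60] are rejected rather than guessed at.
* N counts as a mismatch against A everywhere.
* Trailing poly(G) (dark-signal) trimming requires a run ≥ 10 nt, with no
  quality condition; the run and everything after it are removed.
* Ties everywhere break deterministically (5'-most segment, smallest
  gene_id, upstream TTS on equidistant ties); outputs are sorted and
  timestamp-free, so re-runs are byte-identical.
* Problem sizes in the test suite (20,000 reads × 50 genes for recovery
  and bleeding checks; 1,000 reads per worked example; exhaustive
  enumeration to length 14 plus 10,000 random strings for the refinement
  oracle) were chosen to give stable medians and exhaustive coverage of
  the combinatorial core at interactive runtimes.

## Known limitations

* Tails longer than the read can only be reported at the read-end cap;
  interpreting capped medians requires knowing the read length (the
  spike-in examples quantify this).
* Adaptor matching is substitution-only (no indels).
* The built-in mapper is deliberately tiny: unspliced, ungapped, toy-scale;
  real data should come in as external alignments.
* The quality filter assumes bleeding manifests as a sharp quality drop;
  chemistries with gradual decay may need a different window/threshold.
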