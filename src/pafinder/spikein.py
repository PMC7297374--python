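"""Spike-in control analysis.

Spike-in RNAs are in-vitro-transcribed standards of known adaptor sequence
and known tail length (here 40 nt and 120 nt) added to a library as
internal calibration.  Their reads are identified by the unique transcribed
5' adaptor, tail-called with the 5' search constrained past that adaptor,
and summarized with the usual profile statistics.

Transcription starts within the T7 promoter's terminal GGG, so the
transcribed adaptor is the printed construct minus the 20-nt promoter —
40 nt for both shipped constructs.  The A120 transcribed adaptor ends in
'A'; that terminal adenosine is indistinguishable from the tail and merges
into it, which is why a 150-nt read over the 120-nt spike-in tops out at a
105-nt called tail (104 visible tail As + 1 adaptor A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .io_formats import SequencingRead
from .params import ParameterSet, DEFAULT_PARAMS
from .tailcall import PolyACall, call_read, _hamming
from . import profiles as _profiles

T7_PROMOTER = "TAATACGACTCACTATAGGG"

A40_FULL_ADAPTOR = "TAATACGACTCACTATAGGGTTTAACGCGAATTAATTCTGTGGAATGTGTGTCAGTTAGG"
A120_FULL_ADAPTOR = "TAATACGACTCACTATAGGGTCGACGCTCAAGTCAGAGGTGGCGAAACCCGACAGGACTA"
TEMPLATE_3PRIME_ADAPTOR = "CATTGCCTAGAGTCGGACTGA"


@dataclass(frozen=True)
class SpikeInSpec:
    """One spike-in construct: printed 5' adaptor and expected tail length."""

    name: str
    full_5prime_adaptor: str
    expected_tail_len: int
    library_prefix_len: int = 6

    def __post_init__(self) -> None:
        if not self.full_5prime_adaptor.startswith(T7_PROMOTER):
            raise ValueError(
                f"spike-in {self.name}: 5' adaptor must start with the "
                f"20-nt T7 promoter {T7_PROMOTER}"
            )
        if self.expected_tail_len <= 0:
            raise ValueError("expected_tail_len must be > 0")

    @property
    def transcribed_adaptor(self) -> str:
        """The adaptor as it appears in reads: promoter removed."""
        return self.full_5prime_adaptor[len(T7_PROMOTER):]


DEFAULT_SPIKEINS = (
    SpikeInSpec("A40", A40_FULL_ADAPTOR, 40),
    SpikeInSpec("A120", A120_FULL_ADAPTOR, 120),
)


def _check_distinguishable(specs: Iterable[SpikeInSpec], max_mm: int) -> None:
    specs = list(specs)
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            a, b = specs[i].transcribed_adaptor, specs[j].transcribed_adaptor
            n = min(len(a), len(b))
            if _hamming(a[:n], b[:n]) <= 2 * max_mm:
                raise ValueError(
                    f"spike-ins {specs[i].name} and {specs[j].name} are not "
                    f"distinguishable at max_mm={max_mm}"
                )


def _match_spec(read: SequencingRead, spec: SpikeInSpec,
                max_mm: int) -> Optional[int]:
    """Offset-scanned fuzzy match of the transcribed adaptor near the read
    start; returns the adaptor end position in the read, or None."""
    adaptor = spec.transcribed_adaptor
    for start in range(spec.library_prefix_len + 4 + 1):
        segment = read.bases[start:start + len(adaptor)]
        if len(segment) < len(adaptor):
            break
        if _hamming(segment, adaptor) <= max_mm:
            return start + len(adaptor)
    return None


def extract_spikein_reads(
    reads: Iterable[SequencingRead],
    specs: Iterable[SpikeInSpec] = DEFAULT_SPIKEINS,
    max_mm: int = 2,
) -> Tuple[Dict[str, List[Tuple[SequencingRead, int]]],
           List[SequencingRead], int]:
    """Partition reads by spike-in identity.

    A read matches a spec iff the spec's transcribed adaptor occurs within
    the first ``library_prefix_len + 4`` start positions with at most
    ``max_mm`` mismatches.  Every read lands in exactly one bucket; reads
    matching two specs are counted ambiguous and returned unmatched.

    Returns (matched, unmatched, n_ambiguous) where matched maps spec name
    to (read, adaptor_end_position) pairs.
    """
    specs = list(specs)
    _check_distinguishable(specs, max_mm)
    matched: Dict[str, List[Tuple[SequencingRead, int]]] = {
        s.name: [] for s in specs
    }
    unmatched: List[SequencingRead] = []
    n_ambiguous = 0
    for read in reads:
        hits = [
            (spec, end) for spec in specs
            if (end := _match_spec(read, spec, max_mm)) is not None
        ]
        if len(hits) == 1:
            spec, end = hits[0]
            matched[spec.name].append((read, end))
        else:
            if len(hits) > 1:
                n_ambiguous += 1
            unmatched.append(read)
    return matched, unmatched, n_ambiguous


def call_spikein_reads(
    matched: Iterable[Tuple[SequencingRead, int]],
    spec: SpikeInSpec,
    params: ParameterSet = DEFAULT_PARAMS,
    adaptor3: Optional[str] = None,
) -> List[PolyACall]:
    """Tail-call matched spike-in reads with the preliminary 5' search
    constrained to start at or after the transcribed adaptor's end minus
    one — the adaptor's terminal base may be an A that joins the tail."""
    calls = []
    for read, adaptor_end in matched:
        calls.append(
            call_read(read, adaptor3=adaptor3, params=params,
                      search_start=max(0, adaptor_end - 1))
        )
    return calls


def spikein_profile(
    matched: Iterable[Tuple[SequencingRead, int]],
    spec: SpikeInSpec,
    params: ParameterSet = DEFAULT_PARAMS,
    adaptor3: Optional[str] = None,
    bin_width: int = 1,
    sweep_rates: Tuple[float, ...] = (0.1, 0.2, 0.25, 0.3, 0.35),
) -> dict:
    """Tail histogram, median, ECDF and (optionally) adaptor-detection
    sweep for one spike-in's matched reads."""
    matched = list(matched)
    if not matched:
        raise ValueError(f"no reads matched spike-in {spec.name}")
    calls = call_spikein_reads(matched, spec, params, adaptor3)
    tails = [c.tail_len for c in calls if c.retained]
    result = {
        "name": spec.name,
        "n_matched": len(matched),
        "n_retained": len(tails),
        "calls": calls,
        "median_tail_len": _profiles.lower_median(tails) if tails else None,
        "histogram": _profiles.tail_histogram(tails, bin_width) if tails else None,
        "ecdf": _profiles.cumulative_fraction(tails) if tails else None,
    }
    if adaptor3 is not None and tails:
        pairs = [
            (c.trimmed.bases, c.tail[1]) for c in calls if c.retained
        ]
        result["adaptor_sweep"] = _profiles.adaptor_detection_sweep(
            pairs, adaptor3, rates=sweep_rates, params=params
        )
    return result


def specs_from_json(path) -> List[SpikeInSpec]:
    """Load spike-in specs from JSON: a list of {name, full_5prime_adaptor,
    expected_tail_len[, library_prefix_len]} objects."""
    import json

    with open(path) as fh:
        data = json.load(fh)
    return [SpikeInSpec(**entry) for entry in data]
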