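"""Per-read poly(A) tail calling.

The caller works on reads sequenced 5'→3' from the transcript body through
the poly(A) tail (and, when the insert is short enough, into the 3'
adaptor).  Per read it performs, in order:

1. trimming — optional 5'-adaptor removal and truncation at dark-signal
   poly(G) runs (two-channel chemistries call absent signal as G);
2. preliminary poly(A) detection — the interval between the 5'-most fuzzy
   9-A window and the 3'-most fuzzy 6-A window, one mismatch each;
3. refinement — non-A runs of >= 5 nt split the preliminary region; the
   longest segment (ties: 5'-most) is kept, trimmed to start and end on A,
   and must contain >= 10 consecutive As;
4. optional quality-bleeding truncation — the tail is cut at the first
   3-position window whose mean Phred score falls below 25, removing
   spurious As produced by homopolymer signal bleeding;
5. 3'-adaptor detection — a fuzzy 20-nt probe just downstream of the tail,
   which tells whether the tail was sequenced to its natural end.

All coordinates are 0-based half-open on the *trimmed* read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import floor
from typing import Iterable, Iterator, Optional, Tuple

import numpy as np
import pandas as pd

from .io_formats import SequencingRead, TailCallTable, CALL_COLUMNS
from .params import ParameterSet, DEFAULT_PARAMS

Interval = Tuple[int, int]

DISCARD_REASONS = (
    "none", "no_prelim", "prelim_too_short", "no_pure_run",
    "anchor_too_short", "unmapped", "multimapped",
)

_NONA_SPLIT_RE_CACHE: dict = {}


@dataclass
class PolyACall:
    """Result of tail calling on one read.

    ``prelim`` and ``tail`` are intervals on the trimmed read; ``tail`` is
    non-null iff ``discard_reason == "none"``.  ``anchor_seq`` (the trimmed
    read upstream of the preliminary region) is carried for gene mapping
    but not serialized.
    """

    read_id: str
    prelim: Optional[Interval] = None
    tail: Optional[Interval] = None
    tail_len: int = 0
    adaptor_found: bool = False
    qc_truncated: bool = False
    discard_reason: str = "none"
    anchor_seq: str = field(default="", repr=False, compare=False)
    trimmed: Optional[SequencingRead] = field(default=None, repr=False, compare=False)

    @property
    def retained(self) -> bool:
        return self.discard_reason == "none"

    @property
    def anchor_len(self) -> int:
        return len(self.anchor_seq)


def _mismatch_counts(bases: str, window: int) -> np.ndarray:
    """Number of non-A bases in every length-``window`` substring.

    N counts as a mismatch against A, like any other non-A base.
    """
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    non_a = (arr != ord("A")).astype(np.int32)
    if arr.size < window:
        return np.empty(0, dtype=np.int32)
    cs = np.concatenate(([0], np.cumsum(non_a)))
    return cs[window:] - cs[:-window]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_read(read: SequencingRead, adaptor5: Optional[str],
              params: ParameterSet = DEFAULT_PARAMS) -> SequencingRead:
    """Remove a fuzzy 5'-adaptor prefix (with any preceding template-switch
    G run) and truncate at the first poly(G) run of >= ``polyG_min_run``.

    The 3' adaptor is deliberately left in place: adaptor detection needs it.
    A read may trim to empty; it is discarded later as ``no_prelim``.
    """
    bases, quals = read.bases, read.quals
    if adaptor5:
        g = 0
        while g < len(bases) and bases[g] == "G":
            g += 1
        budget = floor(params.adaptor_error_rate * len(adaptor5))
        prefix = bases[g:g + len(adaptor5)]
        if len(prefix) == len(adaptor5) and _hamming(prefix, adaptor5) <= budget:
            cut = g + len(adaptor5)
            bases, quals = bases[cut:], quals[cut:]
    m = re.search("G{%d,}" % params.polyG_min_run, bases)
    if m:
        bases, quals = bases[: m.start()], quals[: m.start()]
    if len(bases) == len(read.bases):
        return read
    return SequencingRead(read.read_id, bases, quals)


def find_preliminary_region(
    bases: str, params: ParameterSet = DEFAULT_PARAMS, search_start: int = 0
) -> Tuple[Optional[Interval], str]:
    """Locate the preliminary poly(A) region of a trimmed read.

    The 5' boundary is the start of the first (5'-most) 9-nt window at or
    after ``search_start`` with at most one non-A base; the 3' boundary is
    the end of the last (3'-most) qualifying 6-nt window.  Returns
    ``(interval, "none")`` or ``(None, reason)``.
    """
    mm5 = _mismatch_counts(bases, params.anchor5_len)
    mm3 = _mismatch_counts(bases, params.anchor3_len)
    b5 = params.effective_anchor5_max_mm
    b3 = params.effective_anchor3_max_mm

    start = None
    hits5 = np.flatnonzero(mm5[search_start:] <= b5) if mm5.size else np.empty(0, int)
    if hits5.size:
        start = int(hits5[0]) + search_start
    if start is None:
        return None, "no_prelim"
    hits3 = np.flatnonzero(mm3[search_start:] <= b3) if mm3.size else np.empty(0, int)
    if not hits3.size:
        return None, "no_prelim"
    end = int(hits3[-1]) + search_start + params.anchor3_len
    if end <= start:
        return None, "no_prelim"
    if end - start < params.min_prelim_len:
        return None, "prelim_too_short"
    return (start, end), "none"


def _strip_non_a(bases: str, s: int, e: int) -> Tuple[int, int]:
    while s < e and bases[s] != "A":
        s += 1
    while e > s and bases[e - 1] != "A":
        e -= 1
    return s, e


def _has_pure_run(segment: str, min_run: int) -> bool:
    return "A" * min_run in segment


def refine_region(
    bases: str, prelim: Interval, params: ParameterSet = DEFAULT_PARAMS
) -> Tuple[Optional[Interval], str]:
    """Refine a preliminary region to the final poly(A) tail interval.

    Maximal non-A runs of length >= ``nonA_split_run`` split the region;
    each resulting segment is stripped to start/end on 'A'; among the
    segments that qualify as a tail (contain >= ``min_pure_A_run``
    consecutive As and satisfy ``min_prelim_len``) the longest wins, ties
    5'-most.  Equivalent to picking the longest qualifying subinterval of
    the preliminary region.  ``(None, "no_pure_run")`` when no segment
    qualifies.
    """
    ps, pe = prelim
    region = bases[ps:pe]
    pattern = _NONA_SPLIT_RE_CACHE.get(params.nonA_split_run)
    if pattern is None:
        pattern = re.compile("[^A]{%d,}" % params.nonA_split_run)
        _NONA_SPLIT_RE_CACHE[params.nonA_split_run] = pattern

    segments = []
    prev = 0
    for m in pattern.finditer(region):
        segments.append((prev, m.start()))
        prev = m.end()
    segments.append((prev, len(region)))

    min_len = max(params.min_pure_A_run, params.min_prelim_len)
    best = None
    for seg in segments:
        s, e = _strip_non_a(region, *seg)
        if e - s < min_len or not _has_pure_run(region[s:e], params.min_pure_A_run):
            continue
        if best is None or e - s > best[1] - best[0]:
            best = (s, e)
    if best is None:
        return None, "no_pure_run"
    return (ps + best[0], ps + best[1]), "none"


def apply_quality_bleed_filter(
    tail: Interval,
    quals: np.ndarray,
    params: ParameterSet = DEFAULT_PARAMS,
    bases: Optional[str] = None,
) -> Tuple[Optional[Interval], bool, str]:
    """Truncate the tail at the first low-quality window (signal bleeding).

    Scans windows of ``qc_window`` consecutive tail positions 5'→3'; at the
    first window whose mean Phred score is strictly below
    ``qc_mean_threshold`` the tail end moves to the window start.  A no-op
    pass-through unless ``qc_filter_enabled``.  Returns
    ``(tail, qc_truncated, reason)``; the read is discarded
    (``no_pure_run``) when the truncated tail falls below the minimum
    length or loses its pure-A stretch.
    """
    if not params.qc_filter_enabled:
        return tail, False, "none"
    s, e = tail
    w = params.qc_window
    q = np.asarray(quals[s:e], dtype=float)
    if q.size >= w:
        cs = np.concatenate(([0.0], np.cumsum(q)))
        means = (cs[w:] - cs[:-w]) / w
        bad = np.flatnonzero(means < params.qc_mean_threshold)
        if bad.size:
            e = s + int(bad[0])
            if bases is not None:
                s, e = _strip_non_a(bases, s, e)
            if e - s < max(params.min_pure_A_run, params.min_prelim_len):
                return None, True, "no_pure_run"
            if bases is not None and not _has_pure_run(bases[s:e], params.min_pure_A_run):
                return None, True, "no_pure_run"
            return (s, e), True, "none"
    return tail, False, "none"


def detect_adaptor(
    bases: str,
    tail_end: int,
    adaptor3: str,
    error_rate: Optional[float] = None,
    params: ParameterSet = DEFAULT_PARAMS,
    max_offset: Optional[int] = None,
) -> bool:
    """Fuzzy-match the 3' adaptor just downstream of the tail.

    True iff at some start offset 0..``max_offset`` after ``tail_end`` the
    first ``adaptor_probe_len`` nt of the adaptor match the read with at
    most ``floor(error_rate * probe_len)`` mismatches.  False whenever
    fewer than ``probe_len`` bases remain (a tail running to the read end
    can never have its adaptor detected).  Monotone in ``error_rate``.
    """
    probe_len = params.adaptor_probe_len
    if len(adaptor3) < probe_len:
        raise ValueError(
            f"3' adaptor ({len(adaptor3)} nt) shorter than probe length {probe_len}"
        )
    rate = params.adaptor_error_rate if error_rate is None else error_rate
    offs = params.adaptor_max_offset if max_offset is None else max_offset
    probe = adaptor3[:probe_len]
    budget = floor(rate * probe_len)
    for o in range(offs + 1):
        seg = bases[tail_end + o: tail_end + o + probe_len]
        if len(seg) < probe_len:
            break
        if _hamming(seg, probe) <= budget:
            return True
    return False


def call_read(
    read: SequencingRead,
    adaptor3: Optional[str] = None,
    adaptor5: Optional[str] = None,
    params: ParameterSet = DEFAULT_PARAMS,
    search_start: int = 0,
) -> PolyACall:
    """Run the full per-read pipeline and return a :class:`PolyACall`.

    ``search_start`` (on the trimmed read) constrains where the 5' anchor
    search may begin — used for spike-in reads whose known 5' adaptor
    would otherwise be scanned too.  The upstream anchor sequence
    (trimmed read up to ``prelim.start``) is exposed for gene mapping.
    """
    trimmed = trim_read(read, adaptor5, params)
    call = PolyACall(read_id=read.read_id, trimmed=trimmed)
    prelim, reason = find_preliminary_region(trimmed.bases, params, search_start)
    if prelim is None:
        call.discard_reason = reason
        return call
    call.prelim = prelim
    call.anchor_seq = trimmed.bases[: prelim[0]]
    tail, reason = refine_region(trimmed.bases, prelim, params)
    if tail is None:
        call.discard_reason = reason
        return call
    tail, qc_truncated, reason = apply_quality_bleed_filter(
        tail, trimmed.quals, params, bases=trimmed.bases
    )
    call.qc_truncated = qc_truncated
    if tail is None:
        call.discard_reason = reason
        return call
    call.tail = tail
    call.tail_len = tail[1] - tail[0]
    if adaptor3 is not None:
        call.adaptor_found = detect_adaptor(
            trimmed.bases, tail[1], adaptor3, params=params
        )
    return call


def call_reads(
    reads: Iterable[SequencingRead],
    adaptor3: Optional[str] = None,
    adaptor5: Optional[str] = None,
    params: ParameterSet = DEFAULT_PARAMS,
    search_start: int = 0,
) -> Iterator[PolyACall]:
    for read in reads:
        yield call_read(read, adaptor3, adaptor5, params, search_start)


def calls_to_table(
    calls: Iterable[PolyACall],
    sample: str = "",
    params: ParameterSet = DEFAULT_PARAMS,
    gene_ids: Optional[dict] = None,
) -> TailCallTable:
    """Materialize calls into a :class:`TailCallTable` (absent intervals are
    encoded as -1; gene_id '.' until assignment)."""
    gene_ids = gene_ids or {}
    rows = []
    for c in calls:
        ps, pe = c.prelim if c.prelim else (-1, -1)
        ts, te = c.tail if c.tail else (-1, -1)
        rows.append((c.read_id, gene_ids.get(c.read_id, "."), ps, pe, ts, te,
                     c.tail_len, c.adaptor_found, c.qc_truncated,
                     c.discard_reason))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return TailCallTable(df, sample=sample, params_fingerprint=params.fingerprint())
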