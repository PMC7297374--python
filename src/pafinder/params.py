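"""Algorithm parameters for poly(A)-tail calling.

Every threshold of the caller lives in one frozen dataclass so that a run is
fully described by its :class:`ParameterSet`.  Defaults are the published
values of the pA-finder procedure: fuzzy 9-A / 6-A anchors with one mismatch
each, a 10-nt minimum preliminary region, splitting on non-A runs of >= 5 nt,
a mandatory 10-nt pure-A stretch, a >= 20-nt upstream anchor with <= 2
mismatches for mapping, and an optional quality-bleeding filter that truncates
the tail at the first 3-A window whose mean Phred score drops below 25.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass(frozen=True)
class ParameterSet:
    """All thresholds of the tail caller.

    Attributes
    ----------
    anchor5_len, anchor5_max_mm
        Length of the 5' poly(A) anchor window (9 nt) and the number of
        non-A bases tolerated inside it (1).
    anchor3_len, anchor3_max_mm
        Length of the 3' anchor window (6 nt) and its mismatch budget (1).
    min_prelim_len
        Preliminary poly(A) regions shorter than this (10 nt) are discarded.
    nonA_split_run
        A run of >= this many consecutive non-A bases (5) splits the
        preliminary region into segments.
    min_pure_A_run
        A retained tail must contain at least this many consecutive As
        without mismatch (10).
    min_anchor_map_len, map_max_mm
        Minimum upstream-anchor length usable for genome mapping (20 nt)
        and the mismatch budget of the mapper (2).
    qc_window, qc_mean_threshold, qc_filter_enabled
        The bleeding filter truncates the tail at the first window of
        ``qc_window`` consecutive positions whose mean quality is strictly
        below ``qc_mean_threshold``; off by default (it was introduced for
        two-channel chemistries with pronounced A-signal bleeding).
    adaptor_probe_len, adaptor_error_rate, adaptor_max_offset
        The 3'-adaptor scan compares the first ``adaptor_probe_len`` bases
        of the adaptor against the read just downstream of the tail,
        allowing ``floor(error_rate * probe_len)`` mismatches, at start
        offsets 0..``adaptor_max_offset``.
    polyG_min_run
        A G run of at least this length (10) is treated as a dark-signal
        artifact: it and everything after it are trimmed.
    anchor5_error_rate, anchor3_error_rate
        Alternative rate-based anchor budgets (0.1 on the 9-mer, 0.2 on the
        6-mer).  When ``use_anchor_error_rates`` is set the mismatch budget
        becomes ``floor(rate * window)`` instead of the fixed counts above.
    """

    anchor5_len: int = 9
    anchor5_max_mm: int = 1
    anchor3_len: int = 6
    anchor3_max_mm: int = 1
    min_prelim_len: int = 10
    nonA_split_run: int = 5
    min_pure_A_run: int = 10
    min_anchor_map_len: int = 20
    map_max_mm: int = 2
    qc_window: int = 3
    qc_mean_threshold: float = 25.0
    qc_filter_enabled: bool = False
    adaptor_probe_len: int = 20
    adaptor_error_rate: float = 0.2
    adaptor_max_offset: int = 3
    polyG_min_run: int = 10
    anchor5_error_rate: float = 0.1
    anchor3_error_rate: float = 0.2
    use_anchor_error_rates: bool = False

    def __post_init__(self) -> None:
        for name in (
            "anchor5_len", "anchor3_len", "min_prelim_len", "nonA_split_run",
            "min_pure_A_run", "min_anchor_map_len", "qc_window",
            "adaptor_probe_len", "polyG_min_run",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("anchor5_max_mm", "anchor3_max_mm", "map_max_mm",
                     "adaptor_max_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.anchor5_max_mm < self.anchor5_len:
            raise ValueError("anchor5_max_mm must be < anchor5_len")
        if not self.anchor3_max_mm < self.anchor3_len:
            raise ValueError("anchor3_max_mm must be < anchor3_len")
        if self.min_prelim_len < self.anchor3_len:
            raise ValueError("min_prelim_len must be >= anchor3_len")
        if self.min_pure_A_run < self.anchor3_len:
            raise ValueError("min_pure_A_run must be >= anchor3_len")
        for name in ("adaptor_error_rate", "anchor5_error_rate",
                     "anchor3_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def effective_anchor5_max_mm(self) -> int:
        if self.use_anchor_error_rates:
            return int(self.anchor5_error_rate * self.anchor5_len)
        return self.anchor5_max_mm

    @property
    def effective_anchor3_max_mm(self) -> int:
        if self.use_anchor_error_rates:
            return int(self.anchor3_error_rate * self.anchor3_len)
        return self.anchor3_max_mm

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def fingerprint(self) -> str:
        """Deterministic short identifier of the parameter values."""
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


DEFAULT_PARAMS = ParameterSet()
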