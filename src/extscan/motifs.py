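"""Locate and count the repeat motifs that define extensin candidates.

Counting conventions (fixed and tested):

* SP runs use maximal munch: one serine followed by the maximal block of
  three or more consecutive prolines yields exactly one hit, binned by the
  proline count (3 -> SP3, 4 -> SP4, >=5 -> SP5PLUS).  ``SPPPPP`` is a single
  SP5PLUS hit, never SP4 plus a leftover, so the three bins are mutually
  exclusive.
* The candidate screen counts maximal runs (serine anchors), not substring
  occurrences of ``SPPP``.
* YXY hits are counted with overlap (``YAYAY`` = 2): every Tyr pair is a
  potential cross-link site.
* Predicted proteomes cannot distinguish hydroxyproline from proline, so
  every P is treated as potential Hyp.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable


class MotifKind(str, Enum):
    SP3 = "SP3"
    SP4 = "SP4"
    SP5PLUS = "SP5PLUS"
    YXY = "YXY"
    AGP_DIPEPTIDE = "AGP_DIPEPTIDE"
    CUSTOM = "CUSTOM"


#: Dipeptide repeats typical of arabinogalactan-proteins.
AGP_DIPEPTIDES = ("AP", "PA", "SP", "TP", "VP", "GP")

_SP_RUN = re.compile(r"S(P{3,})")


@dataclass
class MotifHit:
    """A located motif occurrence; interval is 0-based half-open."""

    record_id: str
    kind: MotifKind
    start: int
    end: int
    text: str
    run_length: int | None = None


def _sp_kind(n: int) -> MotifKind:
    if n == 3:
        return MotifKind.SP3
    if n == 4:
        return MotifKind.SP4
    return MotifKind.SP5PLUS


def scan_sp_runs(sequence: str, record_id: str = "") -> list[MotifHit]:
    """Find maximal S-P_n runs (n >= 3), left to right, non-overlapping."""
    hits = []
    for m in _SP_RUN.finditer(sequence):
        n = m.end() - m.start() - 1
        hits.append(
            MotifHit(
                record_id=record_id,
                kind=_sp_kind(n),
                start=m.start(),
                end=m.end(),
                text=m.group(0),
                run_length=n,
            )
        )
    return hits


def scan_yxy(sequence: str, record_id: str = "") -> list[MotifHit]:
    """Find every Tyr-X-Tyr triplet; overlapping occurrences all count."""
    hits = []
    for i in range(len(sequence) - 2):
        if sequence[i] == "Y" and sequence[i + 2] == "Y":
            hits.append(
                MotifHit(
                    record_id=record_id,
                    kind=MotifKind.YXY,
                    start=i,
                    end=i + 3,
                    text=sequence[i : i + 3],
                )
            )
    return hits


def scan_pattern(
    sequence: str,
    pattern: str,
    kind: MotifKind = MotifKind.CUSTOM,
    record_id: str = "",
) -> list[MotifHit]:
    """Non-overlapping left-to-right occurrences of a fixed word."""
    if not pattern:
        raise ValueError("motif pattern must be non-empty")
    hits = []
    i = sequence.find(pattern)
    while i != -1:
        hits.append(
            MotifHit(
                record_id=record_id,
                kind=kind,
                start=i,
                end=i + len(pattern),
                text=pattern,
            )
        )
        i = sequence.find(pattern, i + len(pattern))
    return hits


def scan_agp_dipeptides(sequence: str, record_id: str = "") -> list[MotifHit]:
    """Scan all six AGP-style dipeptides, tagged AGP_DIPEPTIDE, sorted by start."""
    hits: list[MotifHit] = []
    for dip in AGP_DIPEPTIDES:
        hits.extend(scan_pattern(sequence, dip, MotifKind.AGP_DIPEPTIDE, record_id))
    hits.sort(key=lambda h: (h.start, h.text))
    return hits


@dataclass
class MotifProfile:
    """Per-protein motif summary used as classifier evidence.

    ``sp_span`` runs from the first SP hit start to the last SP hit end;
    ``sp_coverage`` is that span divided by the record length;
    ``sp_position_bias`` is the fraction of SP hits whose midpoint lies in
    the N-terminal half.  All three are None when no SP hit exists.
    """

    record_id: str
    length: int
    counts: dict = field(default_factory=dict)
    sp_total: int = 0
    yxy_count: int = 0
    sp_span: tuple[int, int] | None = None
    sp_coverage: float | None = None
    sp_position_bias: float | None = None


def profile_motifs(sequence: str, record_id: str = "") -> MotifProfile:
    """Compute the motif profile of one sequence."""
    sp_hits = scan_sp_runs(sequence, record_id)
    yxy_hits = scan_yxy(sequence, record_id)
    counts = {
        MotifKind.SP3: sum(1 for h in sp_hits if h.kind is MotifKind.SP3),
        MotifKind.SP4: sum(1 for h in sp_hits if h.kind is MotifKind.SP4),
        MotifKind.SP5PLUS: sum(1 for h in sp_hits if h.kind is MotifKind.SP5PLUS),
        MotifKind.YXY: len(yxy_hits),
    }
    profile = MotifProfile(
        record_id=record_id,
        length=len(sequence),
        counts=counts,
        sp_total=len(sp_hits),
        yxy_count=len(yxy_hits),
    )
    if sp_hits:
        span = (sp_hits[0].start, sp_hits[-1].end)
        profile.sp_span = span
        profile.sp_coverage = (span[1] - span[0]) / len(sequence)
        half = len(sequence) / 2
        profile.sp_position_bias = sum(
            1 for h in sp_hits if (h.start + h.end) / 2 < half
        ) / len(sp_hits)
    return profile


def is_candidate(profile: MotifProfile) -> bool:
    """Candidate screen: two or more maximal S-P>=3 runs."""
    return profile.sp_total >= 2


def all_motif_hits(sequence: str, record_id: str = "") -> list[MotifHit]:
    """SP runs + YXY hits for one record, sorted by start (for GFF export)."""
    hits = scan_sp_runs(sequence, record_id) + scan_yxy(sequence, record_id)
    hits.sort(key=lambda h: (h.start, h.kind.value))
    return hits
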