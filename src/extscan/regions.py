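"""Structural-region prediction: composition-biased HRGP domains, signal
peptides, transmembrane segments and GPI omega-sites.

These are documented heuristics, not re-implementations of external
predictors; an adapter (:func:`load_external_regions`) lets real predictor
output override every heuristic call.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE


class RegionKind(str, Enum):
    SIGNAL_PEPTIDE = "SIGNAL_PEPTIDE"
    TM = "TM"
    HRGP_DOMAIN = "HRGP_DOMAIN"
    GPI_OMEGA = "GPI_OMEGA"


@dataclass
class RegionCall:
    """A predicted structural region, 0-based half-open interval."""

    record_id: str
    region: RegionKind
    start: int
    end: int
    score: float
    source: str = "HEURISTIC"


#: Residue classes.  HRGP6 is the composition bias of HRGP domains.
HRGP6 = set("PAVSGT")
PAST = set("PAST")
#: Hydrophobic residues accepted in a signal-peptide h-region or GPI tail.
HYDROPHOBIC = set("AILFVMWC")
#: Small residues accepted at the -3/-1 positions of a cleavage site.
SMALL_CLEAVAGE = set("AGSCT")
#: Small residues accepted at a GPI omega-site (omega and omega+2).
GPI_SMALL = set("SGANDC")


@dataclass
class CompositionProfile:
    record_id: str
    fractions: dict
    past_fraction: float
    hrgp6_fraction: float


def amino_acid_composition(sequence: str, record_id: str = "") -> CompositionProfile:
    """Exact residue fractions; X counts in the denominator, in no class."""
    if not sequence:
        raise ValueError("cannot compute composition of an empty sequence")
    n = len(sequence)
    fractions: dict[str, float] = {}
    for c in sequence:
        fractions[c] = fractions.get(c, 0.0) + 1.0
    for c in fractions:
        fractions[c] /= n
    return CompositionProfile(
        record_id=record_id,
        fractions=fractions,
        past_fraction=sum(f for c, f in fractions.items() if c in PAST),
        hrgp6_fraction=sum(f for c, f in fractions.items() if c in HRGP6),
    )


def find_hrgp_regions(
    sequence: str,
    window: int = 50,
    threshold: float = 0.6,
    record_id: str = "",
) -> list[RegionCall]:
    """Sliding-window (step 1) segmentation of HRGP-biased regions.

    Windows whose P/A/V/S/G/T fraction reaches ``threshold`` are merged into
    maximal regions; the region score is the mean fraction of contributing
    windows.  Sequences shorter than the window are evaluated as one
    whole-sequence window.
    """
    if window < 10:
        raise ValueError(f"window must be >= 10, got {window}")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n = len(sequence)
    if n == 0:
        return []
    mask = np.fromiter((c in HRGP6 for c in sequence), dtype=np.float64, count=n)
    if n < window:
        frac = float(mask.mean())
        if frac >= threshold:
            return [RegionCall(record_id, RegionKind.HRGP_DOMAIN, 0, n, frac)]
        return []
    # window sums via cumulative sum; fracs[i] covers [i, i+window)
    cs = np.concatenate(([0.0], np.cumsum(mask)))
    fracs = (cs[window:] - cs[:-window]) / window
    qualifying = np.flatnonzero(fracs >= threshold)
    regions: list[RegionCall] = []
    if qualifying.size == 0:
        return regions
    run_start = qualifying[0]
    prev = qualifying[0]
    contributing = [fracs[qualifying[0]]]

    def _flush(ws: int, we: int, scores: list[float]) -> None:
        regions.append(
            RegionCall(
                record_id,
                RegionKind.HRGP_DOMAIN,
                int(ws),
                int(we + window),
                float(np.mean(scores)),
            )
        )

    for i in qualifying[1:]:
        if i <= prev + window:  # windows overlap or touch -> same region
            contributing.append(fracs[i])
        else:
            _flush(run_start, prev, contributing)
            run_start = i
            contributing = [fracs[i]]
        prev = i
    _flush(run_start, prev, contributing)
    return regions


def hrgp_coverage(regions: Iterable[RegionCall], length: int) -> float:
    """Fraction of the sequence covered by HRGP_DOMAIN regions."""
    covered = sum(
        r.end - r.start for r in regions if r.region is RegionKind.HRGP_DOMAIN
    )
    return covered / length if length else 0.0


def predict_signal_peptide(sequence: str, record_id: str = "") -> RegionCall | None:
    """Heuristic cleavable N-terminal signal peptide call.

    Positive iff, within the first 30 residues: (a) position 0 is M; (b) a
    hydrophobic h-region of >= 7 consecutive residues from {A,I,L,F,V,M,W,C}
    starts at position <= 8; (c) a cleavage site exists 15-30 residues in,
    with small residues {A,G,S,C,T} at -3 and -1 relative to the cut.  The
    first valid cut point is reported; the interval is [0, cleavage).

    Score = mean of three sub-scores in [0, 1]: 1.0 for the Met start, the
    h-region length capped at 10 and divided by 10, and 1.0 for the -3/-1
    smallness (both required, so both present when positive).
    """
    if len(sequence) < 18:
        return None
    if sequence[0] != "M":
        return None
    head = sequence[:30]
    # longest hydrophobic run starting at each position <= 8
    h_len = 0
    for s in range(1, 9):
        run = 0
        for c in head[s:]:
            if c in HYDROPHOBIC:
                run += 1
            else:
                break
        h_len = max(h_len, run)
    if h_len < 7:
        return None
    for cut in range(15, min(30, len(sequence)) + 1):
        if sequence[cut - 3] in SMALL_CLEAVAGE and sequence[cut - 1] in SMALL_CLEAVAGE:
            score = (1.0 + min(h_len, 10) / 10.0 + 1.0) / 3.0
            return RegionCall(record_id, RegionKind.SIGNAL_PEPTIDE, 0, cut, score)
    return None


def predict_transmembrane(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    signal_peptide: RegionCall | None = None,
    record_id: str = "",
) -> list[RegionCall]:
    """Kyte-Doolittle sliding-window transmembrane segment prediction.

    Maximal stretches of windows whose mean hydropathy exceeds ``threshold``
    are merged and extended to window bounds.  Regions overlapping a signal
    peptide call are suppressed.  Score is the peak window hydropathy mapped
    to [0, 1] via peak/4.5 (the scale maximum), clipped.
    """
    n = len(sequence)
    if n < window:
        return []
    # hydropathy values all carry one decimal: scale by 10 and use integer
    # window sums so that exact-threshold windows are decided consistently
    values = np.fromiter(
        (round(_KYTE_DOOLITTLE.get(c, 0.0) * 10) for c in sequence),
        dtype=np.int64,
        count=n,
    )
    cs = np.concatenate(([0], np.cumsum(values)))
    sums = cs[window:] - cs[:-window]  # sums[i] covers [i, i+window)
    means = sums / (10.0 * window)
    qualifying = np.flatnonzero(sums > threshold * 10 * window)
    if qualifying.size == 0:
        return []
    regions: list[RegionCall] = []
    run_start = qualifying[0]
    prev = qualifying[0]
    peak = means[qualifying[0]]
    for i in qualifying[1:]:
        if i <= prev + window:
            peak = max(peak, means[i])
        else:
            regions.append(
                RegionCall(
                    record_id,
                    RegionKind.TM,
                    int(run_start),
                    int(prev + window),
                    float(min(peak / 4.5, 1.0)),
                )
            )
            run_start = i
            peak = means[i]
        prev = i
    regions.append(
        RegionCall(
            record_id,
            RegionKind.TM,
            int(run_start),
            int(prev + window),
            float(min(peak / 4.5, 1.0)),
        )
    )
    if signal_peptide is not None:
        regions = [
            r
            for r in regions
            if not (r.start < signal_peptide.end and r.end > signal_peptide.start)
        ]
    return regions


def predict_gpi_omega(sequence: str, record_id: str = "") -> RegionCall | None:
    """Heuristic GPI omega-site call in the final 25 residues.

    Positive when a position omega has small residues {S,G,A,N,D,C} at omega
    and omega+2, followed within 12 residues by a hydrophobic tail of >= 8
    residues from {A,I,L,F,V,M,W,C} reaching the C-terminus.  Returns the
    most N-terminal valid omega as a length-1 interval.
    """
    n = len(sequence)
    if n < 25:
        return None
    # maximal hydrophobic suffix
    tail = 0
    for c in reversed(sequence):
        if c in HYDROPHOBIC:
            tail += 1
        else:
            break
    if tail < 8:
        return None
    tail_start = n - tail
    for omega in range(n - 25, n - 10):
        if omega < 0 or omega + 2 >= n:
            continue
        if sequence[omega] in GPI_SMALL and sequence[omega + 2] in GPI_SMALL:
            if omega < tail_start <= omega + 12:
                score = min(tail, 12) / 12.0
                return RegionCall(
                    record_id, RegionKind.GPI_OMEGA, omega, omega + 1, score
                )
    return None


_REGION_TOKENS = {k.value for k in RegionKind}


def load_external_regions(path: str | Path) -> list[RegionCall]:
    """Parse external predictor output (TSV: record_id, region, start, end,
    score; 0-based half-open).  Calls carry source EXTERNAL and override
    heuristic calls of the same record and region kind."""
    calls: list[RegionCall] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and fields[0] == "record_id":
                continue
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 columns "
                    "(record_id, region, start, end, score)"
                )
            rid, region, start_s, end_s, score_s = fields
            if region not in _REGION_TOKENS:
                raise ValueError(f"{path}:{lineno}: unknown region token {region!r}")
            try:
                start, end, score = int(start_s), int(end_s), float(score_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed interval/score") from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}:{lineno}: malformed interval [{start},{end})"
                )
            calls.append(
                RegionCall(rid, RegionKind(region), start, end, score, source="EXTERNAL")
            )
    return calls


def combine_regions(
    heuristic: Sequence[RegionCall], external: Sequence[RegionCall]
) -> list[RegionCall]:
    """Merge heuristic and external calls; EXTERNAL wins per (record, kind)."""
    overridden = {(c.record_id, c.region) for c in external}
    kept = [c for c in heuristic if (c.record_id, c.region) not in overridden]
    return sorted(
        kept + list(external), key=lambda c: (c.record_id, c.region.value, c.start)
    )
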