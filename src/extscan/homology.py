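"""Local-alignment domain evidence against a small bundled reference set.

An exact Smith-Waterman search (affine gaps, BLOSUM62) replaces a heuristic
database search: it removes any external binary or database-version
dependence while preserving the evidential role.  Scores are normalized by
the reference self-score, giving a length-free relative score in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seqio import ProteinRecord, read_proteome

FAMILIES = frozenset({"LRR", "KINASE", "FH2", "CLASSICAL_EXT", "SHORT_EXT", "OTHER"})
#: Families that count as foreign (non-EXT) domain evidence downstream.
NON_EXT_FAMILIES = frozenset({"LRR", "KINASE", "FH2", "OTHER"})

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_X = _INDEX["X"]


def _build_matrix() -> np.ndarray:
    """BLOSUM62 over the 20 standard residues; X scores -1 vs everything."""
    b62 = substitution_matrices.load("BLOSUM62")
    sub = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(_ALPHABET[:-1]):
        for j, b in enumerate(_ALPHABET[:-1]):
            sub[i, j] = int(b62[a, b])
    sub[_X, :] = -1
    sub[:, _X] = -1
    return sub


BLOSUM62_X = _build_matrix()


def encode(sequence: str) -> np.ndarray:
    """Map a sequence to matrix indices; anything non-standard becomes X."""
    return np.fromiter(
        (_INDEX.get(c, _X) for c in sequence), dtype=np.int32, count=len(sequence)
    )


_NEG = -(2**30)


@njit(cache=False)
def _sw_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - numba kernel
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i - 1, j] - gap_open - gap_extend
            if E[i - 1, j] - gap_extend > e:
                e = E[i - 1, j] - gap_extend
            f = H[i, j - 1] - gap_open - gap_extend
            if F[i, j - 1] - gap_extend > f:
                f = F[i, j - 1] - gap_extend
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            v = h
            if e > v:
                v = e
            if f > v:
                v = f
            if v < 0:
                v = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = v
            if v > best:  # strict: first maximum in row-major order wins
                best = v
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@dataclass
class LocalAlignment:
    """Optimal local alignment; intervals are 0-based half-open."""

    raw_score: int
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]


def smith_waterman(
    a: str, b: str, gap_open: int = 11, gap_extend: int = 1
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment with affine gaps.

    A gap of length L costs ``gap_open + L * gap_extend``.  The score floor
    is 0; an all-negative comparison yields score 0 with empty intervals.
    Traceback tie-breaking is deterministic: prefer diagonal, then up (gap in
    ``b``), then left (gap in ``a``); inside a gap, prefer closing it.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    ea, eb = encode(a), encode(b)
    H, E, F, best, bi, bj = _sw_fill(ea, eb, BLOSUM62_X, gap_open, gap_extend)
    if best == 0:
        return LocalAlignment(0, (0, 0), (0, 0))
    i, j = bi, bj
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + BLOSUM62_X[ea[i - 1], eb[j - 1]]:
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "E":
            closing = E[i, j] == H[i - 1, j] - gap_open - gap_extend
            i -= 1
            if closing:
                state = "M"
        else:  # state == "F"
            closing = F[i, j] == H[i, j - 1] - gap_open - gap_extend
            j -= 1
            if closing:
                state = "M"
    return LocalAlignment(int(best), (int(i), int(bi)), (int(j), int(bj)))


@dataclass
class ReferenceDomain:
    """One bundled domain exemplar (user-replaceable via FASTA)."""

    ref_id: str
    family: str
    sequence: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown reference family {self.family!r}")
        if not (40 <= len(self.sequence) <= 600):
            raise ValueError(
                f"reference {self.ref_id!r}: length {len(self.sequence)} "
                "outside [40, 600]"
            )


@dataclass
class HomologyHit:
    record_id: str
    ref_id: str
    family: str
    raw_score: int
    normalized_score: float
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]


def default_bundle_path() -> Path:
    return Path(__file__).parent / "data" / "reference_domains.fasta"


def load_reference_bundle(path: str | Path | None = None) -> list[ReferenceDomain]:
    """Load reference domains from FASTA whose headers carry ``family=<TOKEN>``."""
    path = Path(path) if path is not None else default_bundle_path()
    refs = []
    for rec in read_proteome(path):
        family = None
        note = []
        for token in rec.description.split():
            if token.startswith("family="):
                family = token.split("=", 1)[1]
            else:
                note.append(token)
        if family is None:
            raise ValueError(f"reference {rec.id!r} missing family=<TOKEN> in header")
        refs.append(ReferenceDomain(rec.id, family, rec.sequence, " ".join(note)))
    return refs


def assign_domain_families(
    record: ProteinRecord,
    references: Sequence[ReferenceDomain],
    min_normalized: float = 0.25,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[HomologyHit]:
    """Best hit per family with normalized score >= ``min_normalized``.

    Query intervals mark where the family lies on the query, which the
    classifier needs for N-/C-terminal architecture checks.
    """
    if not references:
        raise ValueError("reference set is empty")
    best: dict[str, HomologyHit] = {}
    for ref in references:
        self_score = smith_waterman(
            ref.sequence, ref.sequence, gap_open, gap_extend
        ).raw_score
        aln = smith_waterman(record.sequence, ref.sequence, gap_open, gap_extend)
        if self_score <= 0:
            continue
        norm = aln.raw_score / self_score
        if norm < min_normalized:
            continue
        hit = HomologyHit(
            record_id=record.id,
            ref_id=ref.ref_id,
            family=ref.family,
            raw_score=aln.raw_score,
            normalized_score=norm,
            query_interval=aln.a_interval,
            ref_interval=aln.b_interval,
        )
        prev = best.get(ref.family)
        if prev is None or hit.normalized_score > prev.normalized_score:
            best[ref.family] = hit
    return sorted(best.values(), key=lambda h: h.family)
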