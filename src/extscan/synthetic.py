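"""Seeded synthetic proteomes with planted, labelled members of every
extensin class, so the whole pipeline is testable without any download.

Construction rules that keep the planted truth exhaustive:

* spacers inside repeat blocks use only {A,V,G,T} (HRGP-biased, but free of
  S, P and Y, so no unplanned SP or YXY motif can appear);
* foreign segments use a hydrophilic-plus-aromatic alphabet with S, P, Y,
  A, V, G and T excluded, so they can neither create motifs nor look
  HRGP-rich;
* domain copies come from the bundled reference exemplars, which are
  checked to be SP-run- and YXY-free.

At ambiguity 0 every planted protein clears the relevant classifier
threshold by >= 20%; raising ambiguity moves lengths and coverages toward
the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import ExtClass
from .homology import load_reference_bundle
from .motifs import scan_sp_runs
from .seqio import ProteinRecord

#: Fixed generation order (determinism).
PLANTED_LABELS = (
    ExtClass.CLASSICAL,
    ExtClass.SHORT,
    ExtClass.LRX,
    ExtClass.PERK,
    ExtClass.FH_EXT,
    ExtClass.LONG_CHIMERIC,
    ExtClass.OTHER_CHIMERIC,
    ExtClass.POTENTIAL,
)

_HRGP_SPACER = "AVGT"
_FOREIGN_ALPHABET = "DEKRNQHLIFMWC"
_YXY_X = "AVT"


def _load_background_composition() -> tuple[str, np.ndarray]:
    path = Path(__file__).parent / "data" / "background_composition.tsv"
    residues = []
    weights = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, pct = line.split("\t")
            residues.append(res)
            weights.append(float(pct))
    w = np.asarray(weights, dtype=float)
    return "".join(residues), w / w.sum()


_BG_RESIDUES, _BG_WEIGHTS = _load_background_composition()


@dataclass
class GeneratorSpec:
    seed: int = 1
    n_per_class: dict = field(
        default_factory=lambda: {label: 10 for label in PLANTED_LABELS}
    )
    background_n: int = 20
    background_len_range: tuple[int, int] = (80, 400)
    ambiguity: float = 0.0
    #: (SP3, SP4, SP5+) unit mix inside repeat blocks; SP4-dominant.
    sp_mix: tuple[float, float, float] = (0.25, 0.60, 0.15)
    yxy_density: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.ambiguity <= 1.0:
            raise ValueError("ambiguity must be in [0, 1]")
        if any(n < 0 for n in self.n_per_class.values()) or self.background_n < 0:
            raise ValueError("class counts must be non-negative")
        if sum(self.n_per_class.values()) == 0 and self.background_n == 0:
            raise ValueError("empty generator spec")


@dataclass
class SyntheticTruth:
    record_id: str
    planted_label: ExtClass
    #: (kind, start, end) for every planted motif, 0-based half-open.
    motifs: list = field(default_factory=list)
    #: (kind, start, end) for planted structural regions and domain copies.
    regions: list = field(default_factory=list)


class _Builder:
    """Accumulates sequence pieces while recording planted coordinates."""

    def __init__(self) -> None:
        self.pieces: list[str] = []
        self.pos = 0
        self.motifs: list[tuple[str, int, int]] = []
        self.regions: list[tuple[str, int, int]] = []

    def add(self, text: str) -> int:
        start = self.pos
        self.pieces.append(text)
        self.pos += len(text)
        return start

    def add_sp_run(self, n: int) -> None:
        kind = "SP3" if n == 3 else ("SP4" if n == 4 else "SP5PLUS")
        start = self.add("S" + "P" * n)
        self.motifs.append((kind, start, start + n + 1))

    def add_yxy(self, x: str) -> None:
        start = self.add(f"Y{x}Y")
        self.motifs.append(("YXY", start, start + 3))

    def sequence(self) -> str:
        return "".join(self.pieces)


def _choice_str(rng: np.random.Generator, alphabet: str, n: int) -> str:
    idx = rng.integers(0, len(alphabet), size=n)
    return "".join(alphabet[i] for i in idx)


def _foreign(rng: np.random.Generator, n: int) -> str:
    return _choice_str(rng, _FOREIGN_ALPHABET, n)


def sample_signal_peptide(rng: np.random.Generator) -> str:
    """An N-terminus that the heuristic accepts, with margin, and whose
    cleavage site is exactly at the end of the returned string."""
    n_region = _choice_str(rng, "KRNQ", int(rng.integers(1, 4)))
    h_region = _choice_str(rng, "LVIF", int(rng.integers(10, 14)))
    return "M" + n_region + h_region + "AQA"


def sample_non_signal_nterm(rng: np.random.Generator, length: int = 30) -> str:
    """An N-terminus the heuristic must reject: charged breakers at fixed
    positions forbid any 7-residue hydrophobic run starting at <= 8."""
    chars = list(
        "".join(rng.choice(list(_BG_RESIDUES), size=length, p=_BG_WEIGHTS))
    )
    for pos in (3, 9, 15):
        if pos < length:
            chars[pos] = "DEKR"[int(rng.integers(0, 4))]
    return "".join(chars)


def _add_repeat_unit(
    builder: _Builder, rng: np.random.Generator, spec: GeneratorSpec
) -> None:
    r = rng.random()
    if r < spec.sp_mix[0]:
        n = 3
    elif r < spec.sp_mix[0] + spec.sp_mix[1]:
        n = 4
    else:
        n = int(rng.integers(5, 7))
    builder.add_sp_run(n)
    if rng.random() < spec.yxy_density:
        builder.add(_choice_str(rng, _HRGP_SPACER, int(rng.integers(1, 3))))
        builder.add_yxy(_YXY_X[int(rng.integers(0, len(_YXY_X)))])
    builder.add(_choice_str(rng, _HRGP_SPACER, int(rng.integers(2, 6))))


def _add_repeat_block(
    builder: _Builder,
    rng: np.random.Generator,
    spec: GeneratorSpec,
    n_units: int,
) -> None:
    for _ in range(n_units):
        _add_repeat_unit(builder, rng, spec)


def _exemplars() -> dict[str, str]:
    by_family: dict[str, str] = {}
    for ref in load_reference_bundle():
        by_family.setdefault(ref.family, ref.sequence)
    return by_family


def generate_proteome(
    spec: GeneratorSpec,
) -> tuple[list[ProteinRecord], list[SyntheticTruth]]:
    """Deterministic (seeded) proteome with planted per-class ground truth."""
    rng = np.random.default_rng(spec.seed)
    exemplars = _exemplars()
    records: list[ProteinRecord] = []
    truths: list[SyntheticTruth] = []
    a = spec.ambiguity

    builders = {
        ExtClass.CLASSICAL: _build_classical,
        ExtClass.SHORT: _build_short,
        ExtClass.LRX: _build_lrx,
        ExtClass.PERK: _build_perk,
        ExtClass.FH_EXT: _build_fh,
        ExtClass.LONG_CHIMERIC: _build_long_chimeric,
        ExtClass.OTHER_CHIMERIC: _build_other_chimeric,
        ExtClass.POTENTIAL: _build_potential,
    }

    for label in PLANTED_LABELS:
        for i in range(spec.n_per_class.get(label, 0)):
            rid = f"{label.value.lower()}_{i + 1:03d}"
            builder = builders[label](rng, spec, a, exemplars)
            seq = builder.sequence()
            if label is ExtClass.SHORT and len(seq) >= 200:
                raise ValueError(
                    f"impossible SHORT template: built length {len(seq)} >= 200"
                )
            records.append(
                ProteinRecord(rid, f"planted={label.value}", seq)
            )
            truths.append(
                SyntheticTruth(rid, label, builder.motifs, builder.regions)
            )

    for i in range(spec.background_n):
        rid = f"background_{i + 1:03d}"
        seq = _build_background(rng, spec)
        records.append(ProteinRecord(rid, "planted=NON_EXT", seq))
        truths.append(SyntheticTruth(rid, ExtClass.NON_EXT))
    return records, truths


def _build_classical(rng, spec, a, exemplars) -> _Builder:
    b = _Builder()
    sig = sample_signal_peptide(rng)
    b.add(sig)
    b.regions.append(("SIGNAL_PEPTIDE", 0, len(sig)))
    _add_repeat_block(b, rng, spec, int(rng.integers(14, 31)))
    while b.pos < 250:  # stay clear of the SHORT length rule by >= 20%
        _add_repeat_unit(b, rng, spec)
    # ambiguity drags HRGP coverage toward the classical threshold
    tail = int(b.pos * 0.45 * a)
    if tail:
        b.add(_foreign(rng, tail))
    return b


def _build_short(rng, spec, a, exemplars) -> _Builder:
    b = _Builder()
    sig = sample_signal_peptide(rng)
    b.add(sig)
    b.regions.append(("SIGNAL_PEPTIDE", 0, len(sig)))
    target = int(200 * (0.78 + 0.21 * a))
    while b.pos < target - 16:
        _add_repeat_unit(b, rng, spec)
    return b


def _build_lrx(rng, spec, a, exemplars) -> _Builder:
    b = _Builder()
    sig = sample_signal_peptide(rng)
    b.add(sig)
    b.regions.append(("SIGNAL_PEPTIDE", 0, len(sig)))
    lrr = exemplars["LRR"]
    for _ in range(2):
        start = b.add(lrr)
        b.regions.append(("LRR", start, start + len(lrr)))
        b.add(_choice_str(rng, "KQEN", int(rng.integers(3, 8))))
    _add_repeat_block(b, rng, spec, int(rng.integers(8, 16)))
    return b


def _build_perk(rng, spec, a, exemplars) -> _Builder:
    b = _Builder()
    b.add("M")
    _add_repeat_block(b, rng, spec, int(rng.integers(7, 13)))
    b.add(_choice_str(rng, "DEKNQ", int(rng.integers(10, 18))))
    tm_start = b.add(_choice_str(rng, "LIVF", 23))
    b.regions.append(("TM", tm_start, tm_start + 23))
    b.add(_choice_str(rng, "DEKNQ", int(rng.integers(6, 12))))
    kin = exemplars["KINASE"]
    start = b.add(kin)
    b.regions.append(("KINASE", start, start + len(kin)))
    b.add(_foreign(rng, int(rng.integers(5, 12))))
    return b


def _build_fh(rng, spec, a, exemplars) -> _Builder:
    b = _Builder()
    sig = sample_signal_peptide(rng)
    b.add(sig)
    b.regions.append(("SIGNAL_PEPTIDE", 0, len(sig)))
    _add_repeat_block(b, rng, spec, int(rng.integers(3, 7)))
    b.add(_choice_str(rng, "KQEN", int(rng.integers(5, 12))))
    fh2 = exemplars["FH2"]
    start = b.add(fh2)
    b.regions.append(("FH2", start, start + len(fh2)))
    b.add(_choice_str(rng, "KQEN", int(rng.integers(3, 8))))
    _add_repeat_block(b, rng, spec, int(rng.integers(3, 7)))
    return b


def _build_long_chimeric(rng, spec, a, exemplars) -> _Builder:
    b = _Builder()
    b.add("M")
    target = int(2001 + 500 * (1.0 - a))
    b.add(_foreign(rng, int(rng.integers(300, 450))))
    for _ in range(3):
        _add_repeat_block(b, rng, spec, int(rng.integers(6, 11)))
        b.add(_foreign(rng, int(rng.integers(250, 400))))
    if b.pos < target:
        b.add(_foreign(rng, target - b.pos))
    return b


def _build_other_chimeric(rng, spec, a, exemplars) -> _Builder:
    b = _Builder()
    b.add("M")
    block_start = b.pos
    _add_repeat_block(b, rng, spec, int(rng.integers(7, 11)))
    block_len = b.pos - block_start
    coverage_target = 0.30 + 0.15 * a
    foreign_len = max(150, int(block_len * (1.0 / coverage_target - 1.0)))
    b.add(_foreign(rng, foreign_len))
    return b


_TO_MOTIF_FREE = str.maketrans({"S": "T", "P": "Q", "Y": "F"})


def _build_potential(rng, spec, a, exemplars) -> _Builder:
    b = _Builder()
    length = int(rng.integers(140, 241))
    # the sampled N-terminus must stay motif-free so the planted truth is
    # exhaustive; swap S/P/Y for residues with similar character
    nterm = sample_non_signal_nterm(rng, 30).translate(_TO_MOTIF_FREE)
    body = list(nterm + _foreign(rng, length - 30))
    p1 = int(rng.integers(35, 61))
    p2 = int(rng.integers(85, length - 25))
    b.add("".join(body[:p1]))
    b.add_sp_run(3)
    b.add("".join(body[p1:p2]))
    b.add_sp_run(3)
    b.add("".join(body[p2:]))
    return b


def _build_background(rng, spec: GeneratorSpec) -> str:
    lo, hi = spec.background_len_range
    for _ in range(200):
        length = int(rng.integers(lo, hi + 1))
        nterm = sample_non_signal_nterm(rng, min(30, length))
        body = "".join(
            rng.choice(list(_BG_RESIDUES), size=max(0, length - 30), p=_BG_WEIGHTS)
        )
        seq = nterm + body
        if len(scan_sp_runs(seq)) <= 1:  # composition-matched, SPPP-pair-free
            return seq
    raise RuntimeError("failed to sample an SPPP-pair-free background protein")


def write_truth_tsv(truths: Sequence[SyntheticTruth], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("record_id\tplanted_label\tmotifs\tregions\n")
        for t in truths:
            motifs = ";".join(f"{k}:{s}-{e}" for k, s, e in t.motifs)
            regions = ";".join(f"{k}:{s}-{e}" for k, s, e in t.regions)
            out.write(f"{t.record_id}\t{t.planted_label.value}\t{motifs}\t{regions}\n")


def read_truth_tsv(path: str | Path) -> list[SyntheticTruth]:
    truths = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("record_id"):
            raise ValueError(f"{path}: missing truth TSV header")
        for line in handle:
            rid, label, motifs_s, regions_s = line.rstrip("\n").split("\t")

            def _parse(cell: str) -> list:
                out = []
                for item in cell.split(";"):
                    if not item:
                        continue
                    kind, span = item.split(":")
                    s, e = span.split("-")
                    out.append((kind, int(s), int(e)))
                return out

            truths.append(
                SyntheticTruth(rid, ExtClass(label), _parse(motifs_s), _parse(regions_s))
            )
    return truths
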