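"""Rule-based extensin class assignment.

Evidence from the motif scanner, region profiler and homology search is
combined by a fixed, ordered rule list (first match wins).  The order is
deliberate and testable: chimeric-architecture rules fire before length
rules so that, e.g., an LRX under 200 residues cannot be mislabeled SHORT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Sequence

from .homology import (
    NON_EXT_FAMILIES,
    HomologyHit,
    ReferenceDomain,
    assign_domain_families,
    load_reference_bundle,
)
from .motifs import MotifProfile, is_candidate, profile_motifs
from .regions import (
    RegionCall,
    RegionKind,
    combine_regions,
    find_hrgp_regions,
    hrgp_coverage,
    predict_gpi_omega,
    predict_signal_peptide,
    predict_transmembrane,
)
from .seqio import ProteinRecord


class ExtClass(str, Enum):
    CLASSICAL = "CLASSICAL"
    SHORT = "SHORT"
    LRX = "LRX"
    PERK = "PERK"
    FH_EXT = "FH_EXT"
    LONG_CHIMERIC = "LONG_CHIMERIC"
    OTHER_CHIMERIC = "OTHER_CHIMERIC"
    POTENTIAL = "POTENTIAL"
    NON_EXT = "NON_EXT"


#: Labels counted as determined EXTs (excludes the candidate-only POTENTIAL
#: bucket and the screen-negative NON_EXT bucket).
EXT_LABELS = frozenset(
    {
        ExtClass.CLASSICAL,
        ExtClass.SHORT,
        ExtClass.LRX,
        ExtClass.PERK,
        ExtClass.FH_EXT,
        ExtClass.LONG_CHIMERIC,
        ExtClass.OTHER_CHIMERIC,
    }
)


@dataclass
class ClassifierConfig:
    """All classification thresholds; no hidden constants live in rule code.

    Signal-peptide presence is recorded as evidence but is never a hard
    requirement: genuine classical extensins can lack a predicted signal
    peptide.
    """

    short_max_len: int = 200
    long_min_len: int = 2000
    classical_min_coverage: float = 0.5
    classical_min_sp: int = 4
    perk_nterm_bias: float = 0.7
    min_normalized: float = 0.25
    hrgp_window: int = 50
    hrgp_threshold: float = 0.6
    tm_window: int = 19
    tm_threshold: float = 1.6

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.short_max_len >= self.long_min_len:
            raise ValueError("short_max_len must be < long_min_len")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as out:
            for f in fields(self):
                out.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ClassifierConfig":
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = type(getattr(cls(), key))(value)
        return cls(**kwargs)


@dataclass
class Classification:
    """Assigned class plus an auditable evidence / rule trace."""

    record_id: str
    label: ExtClass
    evidence: dict = field(default_factory=dict)
    rule_trace: list[str] = field(default_factory=list)


def _overlaps(start: int, end: int, r: RegionCall) -> bool:
    return r.start < end and r.end > start


def classify_protein(
    record: ProteinRecord,
    profile: MotifProfile,
    regions: Sequence[RegionCall],
    homology: Sequence[HomologyHit],
    config: ClassifierConfig | None = None,
) -> Classification:
    """Apply the fixed rule order R0-R8; first match wins.

    R0 not a candidate (fewer than two SP runs)        -> NON_EXT
    R1 very long with chimeric character               -> LONG_CHIMERIC
    R2 LRR domain before the SP-motif span             -> LRX
    R3 kinase domain after the span + TM or N-bias     -> PERK
    R4 FH2 homology                                    -> FH_EXT
    R5 short with an HRGP region                       -> SHORT
    R6 HRGP-dominated repeat protein, no foreign domain-> CLASSICAL
    R7 HRGP region plus foreign material               -> OTHER_CHIMERIC
    R8 anything else that passed the screen            -> POTENTIAL
    """
    config = config or ClassifierConfig()
    for ev in (profile,):
        if ev.record_id != record.id:
            raise ValueError(
                f"evidence record id {ev.record_id!r} does not match {record.id!r}"
            )
    for call in regions:
        if call.record_id != record.id:
            raise ValueError(
                f"region record id {call.record_id!r} does not match {record.id!r}"
            )
    for hit in homology:
        if hit.record_id != record.id:
            raise ValueError(
                f"homology record id {hit.record_id!r} does not match {record.id!r}"
            )

    hrgp = [r for r in regions if r.region is RegionKind.HRGP_DOMAIN]
    tms = [r for r in regions if r.region is RegionKind.TM]
    sig = next((r for r in regions if r.region is RegionKind.SIGNAL_PEPTIDE), None)
    gpi = next((r for r in regions if r.region is RegionKind.GPI_OMEGA), None)
    by_family = {h.family: h for h in homology}
    foreign_hits = [h for h in homology if h.family in NON_EXT_FAMILIES]
    coverage = hrgp_coverage(hrgp, record.length)

    evidence = {
        "candidate": is_candidate(profile),
        "length": record.length,
        "sp_total": profile.sp_total,
        "sp3": _count(profile, "SP3"),
        "sp4": _count(profile, "SP4"),
        "sp5plus": _count(profile, "SP5PLUS"),
        "yxy": profile.yxy_count,
        "sp_position_bias": profile.sp_position_bias,
        "signal_peptide": sig is not None,
        "signal_peptide_score": sig.score if sig else 0.0,
        "gpi": gpi is not None,
        "tm_count": len(tms),
        "hrgp_coverage": coverage,
        "hrgp_present": bool(hrgp),
        "lrr_score": by_family["LRR"].normalized_score if "LRR" in by_family else 0.0,
        "kinase_score": by_family["KINASE"].normalized_score
        if "KINASE" in by_family
        else 0.0,
        "fh2_score": by_family["FH2"].normalized_score if "FH2" in by_family else 0.0,
    }

    trace: list[str] = []

    def _done(label: ExtClass, rule: str) -> Classification:
        trace.append(rule)
        return Classification(record.id, label, evidence, trace)

    trace_rule = trace.append

    if not is_candidate(profile):
        return _done(ExtClass.NON_EXT, "R0")
    trace_rule("R0:pass")

    span = profile.sp_span
    assert span is not None  # guaranteed by the candidate screen

    # R1: long chimeric — extraordinary length plus chimeric character
    if record.length > config.long_min_len and (
        foreign_hits or coverage < config.classical_min_coverage
    ):
        return _done(ExtClass.LONG_CHIMERIC, "R1")

    # R2: LRX — LRR domain N-terminal to the EXT repeat span
    lrr = by_family.get("LRR")
    if lrr is not None and lrr.query_interval[1] <= span[0]:
        return _done(ExtClass.LRX, "R2")

    # R3: PERK — kinase domain C-terminal to the repeat span, with a TM
    # segment between them or strongly N-terminal repeats
    kin = by_family.get("KINASE")
    if kin is not None and kin.query_interval[0] >= span[1]:
        tm_between = any(
            r.end > span[1] and r.start < kin.query_interval[0] for r in tms
        )
        bias = profile.sp_position_bias or 0.0
        if tm_between or bias >= config.perk_nterm_bias:
            return _done(ExtClass.PERK, "R3")

    # R4: formin-homolog EXT
    if "FH2" in by_family:
        return _done(ExtClass.FH_EXT, "R4")

    # R5: short EXT
    if record.length < config.short_max_len and hrgp:
        return _done(ExtClass.SHORT, "R5")

    # R6: classical EXT — repeats dominate, no foreign domain evidence
    if (
        coverage >= config.classical_min_coverage
        and profile.sp_total >= config.classical_min_sp
        and not foreign_hits
    ):
        return _done(ExtClass.CLASSICAL, "R6")

    # R7: other chimeric — an HRGP region plus foreign material (a foreign
    # domain hit, membrane anchoring, or a substantial non-HRGP remainder)
    if hrgp and (
        foreign_hits
        or tms
        or gpi is not None
        or coverage < config.classical_min_coverage
    ):
        return _done(ExtClass.OTHER_CHIMERIC, "R7")

    return _done(ExtClass.POTENTIAL, "R8")


def _count(profile: MotifProfile, kind: str) -> int:
    for key, value in profile.counts.items():
        if getattr(key, "value", key) == kind:
            return value
    return 0


def compute_evidence(
    record: ProteinRecord,
    config: ClassifierConfig,
    references: Sequence[ReferenceDomain],
    external_regions: Sequence[RegionCall] = (),
) -> tuple[MotifProfile, list[RegionCall], list[HomologyHit]]:
    """Run all evidence channels for one record."""
    profile = profile_motifs(record.sequence, record.id)
    sig = predict_signal_peptide(record.sequence, record.id)
    regions: list[RegionCall] = []
    if sig is not None:
        regions.append(sig)
    regions.extend(
        find_hrgp_regions(
            record.sequence, config.hrgp_window, config.hrgp_threshold, record.id
        )
    )
    regions.extend(
        predict_transmembrane(
            record.sequence,
            config.tm_window,
            config.tm_threshold,
            signal_peptide=sig,
            record_id=record.id,
        )
    )
    gpi = predict_gpi_omega(record.sequence, record.id)
    if gpi is not None:
        regions.append(gpi)
    mine = [c for c in external_regions if c.record_id == record.id]
    if mine:
        regions = combine_regions(regions, mine)
    homology = assign_domain_families(record, references, config.min_normalized)
    return profile, regions, homology


def classify_proteome(
    records: Sequence[ProteinRecord],
    config: ClassifierConfig | None = None,
    references: Sequence[ReferenceDomain] | None = None,
    external_regions: Sequence[RegionCall] = (),
) -> list[Classification]:
    """Classify every record; output order matches input; deterministic.

    Non-candidates short-circuit at R0 without running the region or
    homology machinery (the screen rejects the bulk of any real proteome).
    """
    config = config or ClassifierConfig()
    if references is None:
        references = load_reference_bundle()
    results = []
    for record in records:
        profile = profile_motifs(record.sequence, record.id)
        if not is_candidate(profile):
            results.append(classify_protein(record, profile, [], [], config))
            continue
        profile, regions, homology = compute_evidence(
            record, config, references, external_regions
        )
        results.append(classify_protein(record, profile, regions, homology, config))
    return results
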