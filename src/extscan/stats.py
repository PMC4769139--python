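"""Aggregate statistics over a classified proteome: class census, pooled
SP_n repeat-type frequencies, and mean YXY counts per class grouping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .classify import EXT_LABELS, Classification, ExtClass
from .motifs import MotifKind, MotifProfile


@dataclass
class ClassSummary:
    group_label: str
    counts: dict = field(default_factory=dict)
    total: int = 0
    ext_total: int = 0
    f_sp3: float | None = None
    f_sp4: float | None = None
    f_sp5: float | None = None
    mean_yxy_classical: float | None = None
    mean_yxy_nonclassical: float | None = None


def class_census(classifications: Iterable[Classification]) -> ClassSummary:
    """Per-label counts; the EXT total excludes NON_EXT and POTENTIAL."""
    counts = {label: 0 for label in ExtClass}
    total = 0
    for c in classifications:
        counts[c.label] += 1
        total += 1
    return ClassSummary(
        group_label="all",
        counts={label.value: n for label, n in counts.items()},
        total=total,
        ext_total=sum(n for label, n in counts.items() if label in EXT_LABELS),
    )


def _profiles_by_id(profiles: Sequence[MotifProfile]) -> dict[str, MotifProfile]:
    return {p.record_id: p for p in profiles}


def spn_frequencies(
    classifications: Sequence[Classification],
    profiles: Sequence[MotifProfile],
    restrict_to: frozenset | set = frozenset({ExtClass.CLASSICAL}),
) -> tuple[float, float, float] | None:
    """Pooled SP3/SP4/SP5+ repeat-type frequencies over a label set.

    Each frequency is the pooled count of that repeat type divided by the
    pooled total of all three; None when no SP repeat exists in the group.
    The restriction set defaults to classical EXTs but is a parameter.
    """
    by_id = _profiles_by_id(profiles)
    n3 = n4 = n5 = 0
    for c in classifications:
        if c.label not in restrict_to:
            continue
        p = by_id.get(c.record_id)
        if p is None:
            raise ValueError(f"no motif profile for classified record {c.record_id!r}")
        n3 += p.counts.get(MotifKind.SP3, 0)
        n4 += p.counts.get(MotifKind.SP4, 0)
        n5 += p.counts.get(MotifKind.SP5PLUS, 0)
    total = n3 + n4 + n5
    if total == 0:
        return None
    return n3 / total, n4 / total, n5 / total


def mean_yxy(
    classifications: Sequence[Classification],
    profiles: Sequence[MotifProfile],
) -> tuple[float | None, float | None]:
    """Mean YXY count in classical vs non-classical EXTs.

    Non-classical means every determined EXT label except CLASSICAL;
    NON_EXT and POTENTIAL records are excluded from both groups.  A group
    with no members reports None.
    """
    by_id = _profiles_by_id(profiles)
    classical: list[int] = []
    nonclassical: list[int] = []
    for c in classifications:
        if c.label not in EXT_LABELS:
            continue
        p = by_id.get(c.record_id)
        if p is None:
            raise ValueError(f"no motif profile for classified record {c.record_id!r}")
        if c.label is ExtClass.CLASSICAL:
            classical.append(p.yxy_count)
        else:
            nonclassical.append(p.yxy_count)
    mc = sum(classical) / len(classical) if classical else None
    mn = sum(nonclassical) / len(nonclassical) if nonclassical else None
    return mc, mn


def summarize(
    classifications: Sequence[Classification],
    profiles: Sequence[MotifProfile],
    group_label: str = "all",
) -> ClassSummary:
    summary = class_census(classifications)
    summary.group_label = group_label
    freqs = spn_frequencies(classifications, profiles)
    if freqs is not None:
        summary.f_sp3, summary.f_sp4, summary.f_sp5 = freqs
    summary.mean_yxy_classical, summary.mean_yxy_nonclassical = mean_yxy(
        classifications, profiles
    )
    return summary


def format_report(summary: ClassSummary) -> str:
    """Human-readable report; means shown to one decimal, full precision
    belongs in the TSV."""
    lines = [f"Class census ({summary.group_label}): {summary.total} proteins"]
    for label in ExtClass:
        lines.append(f"  {label.value:<15} {summary.counts.get(label.value, 0)}")
    lines.append(f"  EXT total (determined classes): {summary.ext_total}")
    if summary.f_sp4 is not None:
        lines.append(
            "SP repeat-type frequencies (classical EXTs): "
            f"SP3 {100 * summary.f_sp3:.1f}%  SP4 {100 * summary.f_sp4:.1f}%  "
            f"SP5+ {100 * summary.f_sp5:.1f}%"
        )
    else:
        lines.append("SP repeat-type frequencies: undefined (no SP repeats in group)")
    mc = "absent" if summary.mean_yxy_classical is None else f"{summary.mean_yxy_classical:.1f}"
    mn = (
        "absent"
        if summary.mean_yxy_nonclassical is None
        else f"{summary.mean_yxy_nonclassical:.1f}"
    )
    lines.append(f"Mean YXY motifs: classical {mc}, non-classical {mn}")
    return "\n".join(lines) + "\n"
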