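"""Read and write proteome FASTA files and motif/region GFF3 tracks.

All coordinates inside the package are 0-based half-open; conversion to the
1-based inclusive convention happens only when writing GFF3.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio import SeqIO

#: The 20 standard amino acids.
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / rare codes remapped to X on load.  X never matches S, P or Y
#: in any motif pattern downstream.
NONSTANDARD_AA = set("BZJUO")

_NUCLEOTIDE_LIKE = set("ACGTUN")


@dataclass
class ProteinRecord:
    """One amino-acid sequence; the unit of analysis.

    ``id`` is the first whitespace-delimited token of the FASTA header and is
    unique within a loaded proteome; ``description`` is the remainder of the
    header line.  A single trailing ``*`` (stop) is stripped on load; internal
    ``*`` characters are preserved but flagged.
    """

    id: str
    description: str
    sequence: str
    has_internal_stop: bool = False
    had_nonstandard: bool = field(default=False, repr=False)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _clean_sequence(raw: str, header: str) -> tuple[str, bool, bool]:
    seq = "".join(raw.split()).upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise ValueError(f"FASTA entry {header!r} has an empty sequence")
    nonstandard = False
    if NONSTANDARD_AA & set(seq):
        nonstandard = True
        seq = "".join("X" if c in NONSTANDARD_AA else c for c in seq)
    internal_stop = "*" in seq
    return seq, internal_stop, nonstandard


def read_proteome(path: str | Path) -> list[ProteinRecord]:
    """Parse an amino-acid FASTA file into validated :class:`ProteinRecord`.

    Lowercase input is upper-cased, a single trailing stop ``*`` is stripped,
    non-standard residues (B, Z, J, U, O) are remapped to X with a warning,
    and duplicate ids are kept but suffixed ``.2``, ``.3``, ... with a warning
    (silently dropping splice forms would skew class counts).  A file that
    looks nucleotide-like (>=95% of residues in A/C/G/T/U/N) triggers a
    warning, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"proteome file not found: {path}")

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    n_nonstandard = 0
    total = 0
    nuc_like = 0
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            header = entry.description or entry.id
            seq, internal_stop, nonstandard = _clean_sequence(str(entry.seq), header)
            if nonstandard:
                n_nonstandard += 1
            rid = entry.id
            count = seen.get(rid, 0) + 1
            seen[rid] = count
            if count > 1:
                new_id = f"{rid}.{count}"
                warnings.warn(
                    f"duplicate FASTA id {rid!r}; renamed occurrence {count} to {new_id!r}"
                )
                rid = new_id
            desc = header.split(None, 1)
            description = desc[1] if len(desc) > 1 else ""
            if internal_stop:
                warnings.warn(f"record {rid!r} contains internal stop codon(s)")
            records.append(
                ProteinRecord(
                    id=rid,
                    description=description,
                    sequence=seq,
                    has_internal_stop=internal_stop,
                    had_nonstandard=nonstandard,
                )
            )
            total += len(seq)
            nuc_like += sum(1 for c in seq if c in _NUCLEOTIDE_LIKE)
    if n_nonstandard:
        warnings.warn(
            f"{n_nonstandard} record(s) contained non-standard residues "
            "(B/Z/J/U/O); remapped to X"
        )
    if total and nuc_like / total >= 0.95:
        warnings.warn(
            f"{path} looks nucleotide-like "
            f"({100 * nuc_like / total:.1f}% A/C/G/T/U/N residues); "
            "expected amino-acid FASTA"
        )
    return records


def write_proteome(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as multi-line FASTA (round-trips through read_proteome)."""
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def write_motif_gff(
    records: Sequence[ProteinRecord],
    hits: Iterable,
    path: str | Path,
    source: str = "extscan",
) -> None:
    """Serialize motif hits as GFF3, one feature line per hit.

    Internal 0-based half-open intervals become 1-based inclusive here and
    only here.  Lines are ordered by (record id, start).  A hit that extends
    beyond its record raises ``ValueError``.
    """
    lengths = {rec.id: rec.length for rec in records}
    rows = []
    for hit in hits:
        if hit.record_id not in lengths:
            raise ValueError(f"motif hit references unknown record {hit.record_id!r}")
        if not (0 <= hit.start < hit.end <= lengths[hit.record_id]):
            raise ValueError(
                f"motif hit [{hit.start},{hit.end}) outside record "
                f"{hit.record_id!r} (length {lengths[hit.record_id]})"
            )
        kind = getattr(hit.kind, "value", hit.kind)
        attrs = f"ID={hit.record_id}:{kind}:{hit.start};kind={kind}"
        run_length = getattr(hit, "run_length", None)
        if run_length is not None:
            attrs += f";run_length={run_length}"
        rows.append(
            (
                hit.record_id,
                hit.start,
                f"{hit.record_id}\t{source}\t{kind}\t{hit.start + 1}\t{hit.end}\t.\t.\t.\t{attrs}",
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for _, _, line in rows:
            out.write(line + "\n")


def write_region_gff(
    records: Sequence[ProteinRecord],
    regions: Iterable,
    path: str | Path,
    source: str = "extscan",
) -> None:
    """GFF3 track for structural region calls (same conventions as motifs)."""
    lengths = {rec.id: rec.length for rec in records}
    rows = []
    for call in regions:
        if call.record_id not in lengths:
            raise ValueError(f"region call references unknown record {call.record_id!r}")
        if not (0 <= call.start < call.end <= lengths[call.record_id]):
            raise ValueError(
                f"region [{call.start},{call.end}) outside record {call.record_id!r}"
            )
        region = getattr(call.region, "value", call.region)
        attrs = f"ID={call.record_id}:{region}:{call.start};source_kind={call.source}"
        rows.append(
            (
                call.record_id,
                call.start,
                f"{call.record_id}\t{source}\t{region}\t{call.start + 1}\t{call.end}"
                f"\t{call.score:.3f}\t.\t.\t{attrs}",
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for _, _, line in rows:
            out.write(line + "\n")
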