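"""Sequence, label and hit-table I/O.

FASTA reading/writing goes through Biopython; this module adds the strict
validation the pipeline relies on (unique ids, alphabet checks, uppercase
normalization) and the two sidecar formats: the label map (two tab-separated
columns, sequence id and SCOP sccs string) and the 12-column hit table.

Coordinates are 0-based half-open everywhere inside the package and converted
to 1-based inclusive only in :class:`HitTableRow` and on disk, following the
BLAST tabular convention.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import ALPHABET

logger = logging.getLogger(__name__)

_ALPHABET_SET = set(ALPHABET)


class FormatError(ValueError):
    """Raised for malformed FASTA, labels or hit tables."""


@dataclasses.dataclass(frozen=True)
class ScopLabel:
    """A SCOP classification path: class -> fold -> superfamily -> family.

    Encoded by sccs strings such as ``"c.67.1.1"`` (class ``c``, fold
    ``c.67``, superfamily ``c.67.1``, family ``c.67.1.1``); each level is a
    dot-extension of the previous.
    """

    class_id: str
    fold_id: str
    superfamily_id: str
    family_id: str

    def __post_init__(self) -> None:
        if not self.fold_id.startswith(self.class_id + "."):
            raise FormatError(f"fold {self.fold_id!r} does not extend class {self.class_id!r}")
        if not self.superfamily_id.startswith(self.fold_id + "."):
            raise FormatError(
                f"superfamily {self.superfamily_id!r} does not extend fold {self.fold_id!r}"
            )
        if not self.family_id.startswith(self.superfamily_id + "."):
            raise FormatError(
                f"family {self.family_id!r} does not extend superfamily "
                f"{self.superfamily_id!r}"
            )

    def __str__(self) -> str:
        return self.family_id


_SCCS_RE = re.compile(r"^([A-Za-z])\.(\d+)\.(\d+)\.(\d+)$")


def parse_sccs(text: str) -> ScopLabel:
    """Parse an sccs string like ``"c.67.1.1"`` into its four hierarchy levels."""
    m = _SCCS_RE.match(text.strip())
    if m is None:
        raise FormatError(
            f"malformed sccs string {text!r}: expected class letter followed by "
            "three dot-separated integers, e.g. 'c.67.1.1'"
        )
    cls, fold, sf, fam = m.groups()
    return ScopLabel(
        class_id=cls,
        fold_id=f"{cls}.{fold}",
        superfamily_id=f"{cls}.{fold}.{sf}",
        family_id=f"{cls}.{fold}.{sf}.{fam}",
    )


@dataclasses.dataclass
class SequenceRecord:
    """A protein sequence with identifier and optional SCOP label."""

    id: str
    residues: str
    description: str = ""
    label: ScopLabel | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        self.residues = self.residues.upper()
        if len(self.residues) == 0:
            raise FormatError(f"empty sequence for id {self.id!r}")
        for pos, ch in enumerate(self.residues):
            if ch not in _ALPHABET_SET:
                raise FormatError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def _records_from_seqio(parsed: Iterable[SeqRecord]) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in parsed:
        if not rec.id:
            raise FormatError("FASTA record with empty id")
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into validated records.

    The id is the first whitespace-delimited token of the header; multi-line
    bodies are concatenated and uppercased.  Duplicate ids, empty ids and
    residues outside the 20-letter alphabet (plus X) are format errors.
    """
    with open(path) as fh:
        return _records_from_seqio(SeqIO.parse(fh, "fasta"))


def read_fasta_string(text: str) -> list[SequenceRecord]:
    return _records_from_seqio(SeqIO.parse(io.StringIO(text), "fasta"))


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_label_map(path: str | Path) -> dict[str, ScopLabel]:
    """Read a two-column TSV of sequence id and sccs string."""
    out: dict[str, ScopLabel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            seq_id, sccs = parts
            if seq_id in out:
                raise FormatError(f"{path}:{lineno}: duplicate id {seq_id!r}")
            out[seq_id] = parse_sccs(sccs)
    return out


def write_label_map(labels: Mapping[str, ScopLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id in labels:
            fh.write(f"{seq_id}\t{labels[seq_id]}\n")


def attach_labels(
    records: Sequence[SequenceRecord], labels: Mapping[str, ScopLabel]
) -> list[SequenceRecord]:
    """Attach labels to records by id; unlabeled ids get ``label=None``.

    Records absent from the map are excluded from benchmarking downstream; a
    warning is logged for each.
    """
    out = []
    for rec in records:
        label = labels.get(rec.id)
        if label is None:
            logger.warning("sequence %s has no label; excluded from benchmarking", rec.id)
        out.append(dataclasses.replace(rec, label=label))
    return out


_HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "generation",
    "bit_score",
    "e_value",
    "identity_pct",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "aln_length",
    "coverage_pct",
)


@dataclasses.dataclass(frozen=True)
class HitTableRow:
    """One row of the tab-separated hit table (1-based inclusive coordinates)."""

    query_id: str
    subject_id: str
    generation: int
    bit_score: float
    e_value: float
    identity_pct: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aln_length: int
    coverage_pct: float

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise FormatError("generation must be >= 0")
        if not (self.q_start <= self.q_end and self.s_start <= self.s_end):
            raise FormatError("start must not exceed end")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise FormatError("identity_pct outside [0, 100]")
        if self.e_value < 0 or not math.isfinite(self.e_value):
            raise FormatError("e_value must be finite and >= 0")


def write_hit_table(rows: Sequence[HitTableRow], path: str | Path) -> None:
    """Write rows as TSV with a commented header; E-values in scientific notation."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_HIT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        str(r.generation),
                        repr(float(r.bit_score)),
                        format(r.e_value, ".6e"),
                        repr(float(r.identity_pct)),
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        str(r.aln_length),
                        repr(float(r.coverage_pct)),
                    ]
                )
                + "\n"
            )


def read_hit_table(path: str | Path) -> list[HitTableRow]:
    rows: list[HitTableRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_HIT_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_HIT_COLUMNS)} columns, got {len(parts)}"
                )
            rows.append(
                HitTableRow(
                    query_id=parts[0],
                    subject_id=parts[1],
                    generation=int(parts[2]),
                    bit_score=float(parts[3]),
                    e_value=float(parts[4]),
                    identity_pct=float(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    aln_length=int(parts[10]),
                    coverage_pct=float(parts[11]),
                )
            )
    return rows
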