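"""Reading, validation and filtering of protein sequences and labelled pair lists.

Sequences are plain strings over the 20 standard one-letter amino-acid codes.
Ambiguous residues (B, Z, U, X) are handled by an explicit policy rather than
silently: real interaction databases contain them, but how to treat them is a
modelling choice that should never distort descriptor statistics unnoticed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: nearest-standard-residue substitutions for the common ambiguity codes;
#: X (fully unknown) has no nearest residue, so records containing it are
#: skipped even under the mapping policy.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C"}

AMBIGUITY_POLICIES = ("reject", "skip_record", "map_to_nearest")


class SequenceError(ValueError):
    """Malformed or invalid sequence / pair-list input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabelledPair:
    """A protein pair labelled interacting (1) or non-interacting (0)."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise SequenceError(
                f"pair ({self.id_a}, {self.id_b}): label must be 0 or 1, got {self.label!r}"
            )


def _apply_policy(rec_id: str, seq: str, policy: str) -> str | None:
    """Return the cleaned sequence, or None if the record is to be skipped."""
    # a trailing stop-codon '*' is a translation artefact, not a residue
    seq = seq.upper().rstrip("*")
    if not seq:
        raise SequenceError(f"record {rec_id!r}: empty sequence")
    bad = [(i, c) for i, c in enumerate(seq, start=1) if c not in STANDARD_AA]
    if not bad:
        return seq
    if policy == "reject":
        pos, char = bad[0]
        raise SequenceError(
            f"record {rec_id!r}: non-standard residue {char!r} at position {pos}"
        )
    if policy == "skip_record":
        logger.warning(
            "skipping record %r: non-standard residue %r at position %d",
            rec_id, bad[0][1], bad[0][0],
        )
        return None
    # map_to_nearest: B->D, Z->E, U->C; anything else (X, rare codes) skips
    unmappable = [(i, c) for i, c in bad if c not in AMBIGUITY_MAP]
    if unmappable:
        logger.warning(
            "skipping record %r: unmappable residue %r at position %d",
            rec_id, unmappable[0][1], unmappable[0][0],
        )
        return None
    table = str.maketrans(AMBIGUITY_MAP)
    return seq.translate(table)


def read_fasta(path: str | Path, policy: str = "skip_record") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord` s.

    Parameters
    ----------
    path
        FASTA file; wrapped or unwrapped sequence lines are both accepted.
    policy
        How to treat non-standard residues: ``"reject"`` (error naming the
        residue and position), ``"skip_record"`` (drop the record with a
        logged warning; the default), or ``"map_to_nearest"`` (B→D, Z→E,
        U→C; records containing X are still skipped).

    Returns
    -------
    Records in file order, ids unique, sequences upper-cased.
    """
    if policy not in AMBIGUITY_POLICIES:
        raise ValueError(f"unknown ambiguity policy {policy!r}; choose from {AMBIGUITY_POLICIES}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SequenceError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise SequenceError(
                    f"{path}: malformed FASTA — line {lineno} precedes any '>' header"
                )
            break

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        cleaned = _apply_policy(rec.id, str(rec.seq), policy)
        if cleaned is not None:
            records.append(ProteinRecord(id=rec.id, sequence=cleaned))
    if not records and not seen:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (inverse of :func:`read_fasta` for valid input)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(Path(path)), "fasta")


def _coerce_label(raw: str, lineno: int, path: Path) -> int:
    try:
        value = float(raw)
    except ValueError:
        raise SequenceError(f"{path}, line {lineno}: label {raw!r} is not numeric") from None
    if value not in (0.0, 1.0):
        raise SequenceError(f"{path}, line {lineno}: label must be 0 or 1, got {raw!r}")
    return int(value)


def read_pairs(path: str | Path, records: Sequence[ProteinRecord]) -> list[LabelledPair]:
    """Read a labelled pair list (``id_a, id_b, label`` per line).

    The delimiter (tab or comma) is sniffed from the first line; an optional
    header row is detected by a non-numeric third column. Every id must
    resolve to one of *records*.
    """
    path = Path(path)
    known = {r.id for r in records}
    lines = path.read_text().splitlines()
    content = [(i, ln) for i, ln in enumerate(lines, start=1) if ln.strip()]
    if not content:
        logger.warning("%s: empty pair file", path)
        return []

    first = content[0][1]
    delim = "\t" if "\t" in first else ","

    def split(line: str, lineno: int) -> list[str]:
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) < 3:
            raise SequenceError(
                f"{path}, line {lineno}: expected 3 columns (id_a, id_b, label), got {len(fields)}"
            )
        return fields[:3]

    header_fields = split(first, content[0][0])
    try:
        float(header_fields[2])
        start = 0
    except ValueError:
        start = 1  # non-numeric third column -> header row

    pairs: list[LabelledPair] = []
    for lineno, line in content[start:]:
        id_a, id_b, raw_label = split(line, lineno)
        for pid in (id_a, id_b):
            if pid not in known:
                raise SequenceError(f"{path}, line {lineno}: unknown protein id {pid!r}")
        pairs.append(LabelledPair(id_a, id_b, _coerce_label(raw_label, lineno, path)))
    if not pairs:
        logger.warning("%s: pair file contains a header but no data rows", path)
    return pairs


def write_pairs(pairs: Iterable[LabelledPair], path: str | Path) -> None:
    """Write pairs as a tab-separated ``id_a  id_b  label`` file."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


def filter_min_length(
    records: Sequence[ProteinRecord], min_len: int = 50
) -> list[ProteinRecord]:
    """Drop records shorter than *min_len* residues, preserving order.

    The default of 50 follows the standard curation rule for interaction
    datasets: very short chains carry too little compositional information
    for sequence-only features.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    kept = [r for r in records if r.length >= min_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_min_length: removed %d of %d records (< %d residues)",
                    removed, len(records), min_len)
    return kept
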