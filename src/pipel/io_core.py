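"""Peptide and dataset types, FASTA/label I/O, validation and length filtering.

Peptides are short linear amino-acid sequences (canonical 20-letter
alphabet) optionally carrying a binary class label: PIP (induces
proinflammatory cytokines in T-cell assays) or NONPIP.  Labels travel
either as a pipe-delimited FASTA header suffix (``>id|PIP``) or in a
companion two-column TSV (id, label); the header form wins on conflict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("pipel")

CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_ALPHABET)

LABEL_PIP = "PIP"
LABEL_NONPIP = "NONPIP"
LABEL_UNKNOWN = "UNKNOWN"
VALID_LABELS = (LABEL_PIP, LABEL_NONPIP, LABEL_UNKNOWN)

# dataset-construction length bounds, inclusive
MIN_LENGTH = 5
MAX_LENGTH = 25


class PipelError(Exception):
    """Base class for package errors."""


class FastaParseError(PipelError):
    """Malformed FASTA input, names the offending record where possible."""


class ValidationError(PipelError):
    """A peptide or dataset invariant is violated."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with an optional class label."""

    id: str
    sequence: str
    label: str = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("peptide id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"peptide {self.id!r}: sequence is empty")
        bad = sorted(set(self.sequence) - _CANONICAL_SET)
        if bad:
            raise ValidationError(
                f"peptide {self.id!r}: non-canonical residues {''.join(bad)!r}"
            )
        if self.label not in VALID_LABELS:
            raise ValidationError(
                f"peptide {self.id!r}: label {self.label!r} not in {VALID_LABELS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideDataset:
    """Ordered collection of peptides with unique ids and a provenance trail."""

    peptides: list[Peptide] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.peptides:
            if p.id in seen:
                raise ValidationError(f"duplicate peptide id {p.id!r} in dataset")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def labels(self) -> list[str]:
        return [p.label for p in self.peptides]

    def subset(self, ids: Iterable[str], note: str = "") -> "PeptideDataset":
        wanted = set(ids)
        missing = wanted - set(self.ids())
        if missing:
            raise ValidationError(f"unknown peptide ids: {sorted(missing)[:5]}")
        kept = [p for p in self.peptides if p.id in wanted]
        return PeptideDataset(kept, self.provenance + [note or f"subset of {len(kept)}"])

    def by_label(self, label: str) -> "PeptideDataset":
        return PeptideDataset(
            [p for p in self.peptides if p.label == label],
            self.provenance + [f"label == {label}"],
        )

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.peptides:
            counts[p.label] = counts.get(p.label, 0) + 1
        return counts


def _parse_header(header: str) -> tuple[str, Optional[str]]:
    """Split ``id|LABEL`` headers; anything after the first pipe is the label."""
    if "|" in header:
        pid, raw = header.split("|", 1)
        return pid.strip(), raw.strip().upper().replace("-", "").replace("_", "")
    return header.strip(), None


def _normalize_label(raw: Optional[str]) -> str:
    if raw is None or raw == "":
        return LABEL_UNKNOWN
    raw = raw.upper().replace("-", "").replace("_", "")
    if raw in ("PIP", "POS", "POSITIVE", "1"):
        return LABEL_PIP
    if raw in ("NONPIP", "NEG", "NEGATIVE", "0"):
        return LABEL_NONPIP
    if raw == "UNKNOWN":
        return LABEL_UNKNOWN
    raise ValidationError(f"unrecognized label {raw!r}")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, label) TSV with no header."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        pid, raw = parts
        table[pid.strip()] = _normalize_label(raw.strip())
    return table


def read_fasta(
    path: str | Path,
    label_table: Optional[dict[str, str] | str | Path] = None,
) -> PeptideDataset:
    """Read peptides from FASTA, validating sequences and resolving labels.

    Sequences are upper-cased.  Records containing non-canonical residues
    are rejected with a logged per-record diagnostic rather than aborting
    the whole file.  Duplicate ids raise.  Labels come from a ``>id|LABEL``
    header suffix or, failing that, from ``label_table`` (a dict or a TSV
    path); the header wins on conflict.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    if label_table is not None and not isinstance(label_table, dict):
        label_table = read_label_table(label_table)

    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython names the bad record in its message
        raise FastaParseError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"empty FASTA (no records): {path}")

    peptides: list[Peptide] = []
    seen: set[str] = set()
    rejected: list[str] = []
    for rec in records:
        pid, header_label = _parse_header(rec.id if "|" in rec.id else rec.description.split()[0])
        if pid in seen:
            raise ValidationError(f"duplicate peptide id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        raw = header_label
        if raw is None and label_table is not None:
            raw = label_table.get(pid)
        try:
            peptides.append(Peptide(pid, seq, _normalize_label(raw)))
        except ValidationError as exc:
            rejected.append(pid)
            logger.warning("rejected record %s: %s", pid, exc)
    prov = [f"read_fasta {path.name}: {len(peptides)} kept, {len(rejected)} rejected"]
    if rejected:
        prov.append("rejected ids: " + ",".join(rejected))
    return PeptideDataset(peptides, prov)


def write_fasta(ds: PeptideDataset, path: str | Path, with_labels: bool = True) -> None:
    """Write a dataset as FASTA wrapped at 60 columns, labels in headers."""
    records = []
    for p in ds:
        header = f"{p.id}|{p.label}" if with_labels else p.id
        records.append(SeqRecord(Seq(p.sequence), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def write_label_table(ds: PeptideDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in ds:
            fh.write(f"{p.id}\t{p.label}\n")


def filter_by_length(
    ds: PeptideDataset, min_len: int = MIN_LENGTH, max_len: int = MAX_LENGTH
) -> PeptideDataset:
    """Keep peptides with min_len <= L <= max_len (bounds inclusive).

    Mirrors the dataset-construction step that excludes peptides shorter
    than 5 or longer than 25 residues as outlier-prone.  Idempotent.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    kept = [p for p in ds if min_len <= len(p) <= max_len]
    dropped = len(ds) - len(kept)
    return PeptideDataset(
        kept,
        ds.provenance
        + [f"filter_by_length [{min_len},{max_len}]: kept {len(kept)}, dropped {dropped}"],
    )


def relabel(p: Peptide, label: str) -> Peptide:
    return replace(p, label=label)
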