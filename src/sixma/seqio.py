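"""FASTA I/O and 41-nt adenine-centred window handling.

The predictor operates on fixed DNA windows of 41 nucleotides with the
candidate adenine at the central position: 20 nucleotides of upstream
context, the adenine, and 20 nucleotides of downstream context.  This
module reads and writes such windows as FASTA, validates them, and
extracts candidate windows from longer sequences for prediction-time
scanning.

Conventions
-----------
* All positions reported to users are 1-based; the central adenine of a
  window sits at position 21.
* Only the forward strand is scanned; reverse-complement calling is out
  of scope for this tool.
* Lowercase input is uppercased on read.  ``U`` is rejected: this is a
  DNA tool.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

WINDOW_LENGTH = 41
#: 0-based index of the central adenine (position 21 when 1-based).
CENTER_INDEX = WINDOW_LENGTH // 2
DNA_ALPHABET = frozenset("ACGT")

__all__ = [
    "WINDOW_LENGTH",
    "CENTER_INDEX",
    "SequenceRecord",
    "LabeledDataset",
    "WindowValidationError",
    "FastaParseError",
    "validate_window",
    "read_fasta",
    "read_fasta_pair",
    "write_fasta",
    "extract_adenine_windows",
]


class WindowValidationError(ValueError):
    """A sequence does not satisfy the 41-nt adenine-centred window contract."""


class FastaParseError(ValueError):
    """A FASTA file could not be parsed."""


def validate_window(seq: str) -> tuple[bool, Optional[str]]:
    """Check the window contract and return ``(ok, reason)``.

    A valid window has length 41, an ``A`` at the central position, and
    uses only the unambiguous DNA alphabet ``{A, C, G, T}``.  The reason
    code is ``None`` for valid windows, otherwise one of ``"wrong
    length"``, ``"ambiguous base"``, ``"invalid character"`` or
    ``"central base not A"``.
    """
    if len(seq) != WINDOW_LENGTH:
        return False, "wrong length"
    bad = set(seq) - DNA_ALPHABET
    if bad:
        if bad <= {"N"}:
            return False, "ambiguous base"
        return False, "invalid character"
    if seq[CENTER_INDEX] != "A":
        return False, "central base not A"
    return True, None


@dataclass(frozen=True)
class SequenceRecord:
    """One 41-nt adenine-centred window.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to first whitespace).
    seq : str
        41-nt window over ``{A, C, G, T}``, central base ``A``.
    label : int, optional
        1 for a methylated (6mA) site, 0 for an unmethylated one.
    source_pos : int, optional
        1-based coordinate of the central adenine in the source sequence.
    """

    id: str
    seq: str
    label: Optional[int] = None
    source_pos: Optional[int] = None

    def __post_init__(self) -> None:
        ok, reason = validate_window(self.seq)
        if not ok:
            raise WindowValidationError(f"record {self.id!r}: {reason}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    def with_label(self, label: int) -> "SequenceRecord":
        return replace(self, label=label)


@dataclass
class LabeledDataset:
    """A collection of window records, possibly with class labels."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    def labels(self) -> np.ndarray:
        """Labels as an int array; raises if any record is unlabeled."""
        labs = [r.label for r in self.records]
        if any(l is None for l in labs):
            raise ValueError("dataset contains unlabeled records")
        return np.asarray(labs, dtype=int)

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])

    @staticmethod
    def concat(*datasets: "LabeledDataset") -> "LabeledDataset":
        out: list[SequenceRecord] = []
        for d in datasets:
            out.extend(d.records)
        return LabeledDataset(out)


def read_fasta(path: os.PathLike | str, label: Optional[int] = None) -> LabeledDataset:
    """Read a FASTA file of 41-nt windows.

    Sequences are uppercased; when ``label`` is given it is applied to
    every entry (the benchmark datasets ship as one positive and one
    negative FASTA file).  Entries violating the window contract raise
    :class:`WindowValidationError` naming the offending record.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython is permissive
        raise FastaParseError(f"{path}: {exc}") from exc
    if not parsed:
        raise FastaParseError(f"{path}: no FASTA entries found")
    for entry in parsed:
        seq = str(entry.seq).upper()
        if "U" in seq:
            raise WindowValidationError(
                f"record {entry.id!r}: contains 'U' (RNA input not supported)"
            )
        records.append(SequenceRecord(id=entry.id, seq=seq, label=label))
    return LabeledDataset(records)


def read_fasta_pair(pos_path: os.PathLike | str, neg_path: os.PathLike | str) -> LabeledDataset:
    """Read paired positive/negative FASTA files into one labeled dataset."""
    pos = read_fasta(pos_path, label=1)
    neg = read_fasta(neg_path, label=0)
    return LabeledDataset.concat(pos, neg)


def write_fasta(dataset: LabeledDataset | Iterable[SequenceRecord], path: os.PathLike | str) -> None:
    """Write records to FASTA (sequence on a single line per record)."""
    records = dataset.records if isinstance(dataset, LabeledDataset) else list(dataset)
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(bio, handle, "fasta-2line")


def extract_adenine_windows(genome: str, flank: int = 20) -> list[SequenceRecord]:
    """Extract every adenine-centred window from a longer sequence.

    One window is emitted per adenine with at least ``flank`` bases of
    context on both sides, provided the window contains no ``N``.
    Windows near contig edges (insufficient context) are dropped.
    ``source_pos`` records the 1-based position of the central adenine.
    """
    if flank != CENTER_INDEX:
        raise ValueError(
            f"flank must be {CENTER_INDEX}: the window contract is fixed at "
            f"{WINDOW_LENGTH} nt"
        )
    genome = genome.upper()
    bad = set(genome) - (DNA_ALPHABET | {"N"})
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)!r}")
    width = 2 * flank + 1
    out: list[SequenceRecord] = []
    if len(genome) < width:
        return out
    for i in range(flank, len(genome) - flank):
        if genome[i] != "A":
            continue
        window = genome[i - flank : i + flank + 1]
        if "N" in window:
            continue
        pos = i + 1
        out.append(SequenceRecord(id=f"win_{pos}", seq=window, source_pos=pos))
    return out
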