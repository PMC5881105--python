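"""Peptide sequence I/O, validation, and redundancy reduction.

Peptides are short (typically 5-30 residue) sequences over the 20 canonical
amino acids, optionally carrying a binary class label (1 = anti-inflammatory,
0 = not). Labels travel either in a two-column TSV (``id<TAB>label``) or in a
``>id|label`` FASTA header convention; the FASTA body stays standard.

Redundancy reduction is a greedy longest-first (Hobohm-style) clustering on
global pairwise identity, a deliberately simple stand-in for CD-HIT: identity
is the maximal number of matched residues under a global alignment with unit
match score and free gaps/mismatches, normalized by the shorter sequence
length (the CD-HIT convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import ParameterError, SequenceError

#: The 20 canonical amino acids in alphabetical one-letter order.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_SET = frozenset(AMINO_ACIDS)

#: Minimum sequence length: dipeptide composition needs at least one pair.
MIN_LENGTH = 2


def validate_sequence(sequence: str, record_id: str = "?") -> str:
    """Validate (and return) an uppercase canonical peptide sequence.

    Lowercase input is uppercased with a warning. Raises
    :class:`SequenceError` naming the record and the offending residue on
    non-canonical characters, and on sequences shorter than 2 residues.
    """
    if not isinstance(sequence, str) or not sequence:
        raise SequenceError(f"record {record_id!r}: empty sequence")
    if sequence != sequence.upper():
        warnings.warn(
            f"record {record_id!r}: lowercase residues uppercased", stacklevel=2
        )
        sequence = sequence.upper()
    for ch in sequence:
        if ch not in AA_SET:
            raise SequenceError(
                f"record {record_id!r}: non-canonical residue {ch!r}"
            )
    if len(sequence) < MIN_LENGTH:
        raise SequenceError(
            f"record {record_id!r}: length {len(sequence)} < {MIN_LENGTH} "
            "(dipeptide composition is undefined)"
        )
    return sequence


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with an optional binary class label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, self.id))
        if self.label is not None and self.label not in (0, 1):
            raise SequenceError(f"record {self.id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideDataset:
    """An ordered collection of :class:`PeptideRecord` with unique ids."""

    records: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SequenceError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> PeptideRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[int | None]:
        return [r.label for r in self.records]

    @property
    def positives_count(self) -> int:
        """PS: number of records labeled as the positive (anti-inflammatory) class."""
        return sum(1 for r in self.records if r.label == 1)

    @property
    def negatives_count(self) -> int:
        """NS: number of records labeled as the negative class."""
        return sum(1 for r in self.records if r.label == 0)

    def is_labeled(self) -> bool:
        return len(self.records) > 0 and all(r.label is not None for r in self.records)

    def subset(self, indices: Sequence[int]) -> "PeptideDataset":
        return PeptideDataset([self.records[i] for i in indices])

    def with_labels(self, labels: Mapping[str, int]) -> "PeptideDataset":
        """Return a copy with labels joined by record id."""
        out = []
        for rec in self.records:
            lab = labels.get(rec.id, rec.label)
            out.append(PeptideRecord(rec.id, rec.sequence, lab))
        return PeptideDataset(out)


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a headerless two-column TSV of ``id<TAB>label`` (label in {0,1})."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SequenceError(f"{path}:{lineno}: expected 'id<TAB>label'")
        ident, lab = parts
        if lab not in ("0", "1"):
            raise SequenceError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
        if ident in labels:
            raise SequenceError(f"{path}:{lineno}: duplicate id {ident!r}")
        labels[ident] = int(lab)
    return labels


def write_label_table(dataset: PeptideDataset, path: str | Path) -> None:
    lines = [f"{r.id}\t{r.label}" for r in dataset if r.label is not None]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _parse_header_label(raw_id: str) -> tuple[str, int | None]:
    # ">id|label" convention: a trailing |0 or |1 is read as the class label
    if "|" in raw_id:
        stem, _, tail = raw_id.rpartition("|")
        if tail in ("0", "1") and stem:
            return stem, int(tail)
    return raw_id, None


def read_fasta(path: str | Path, labels: str | Path | None = None) -> PeptideDataset:
    """Read a (multi-)FASTA of peptides, validating every record.

    Parameters
    ----------
    path
        FASTA file; wrapped or unwrapped lines, ``>id`` or ``>id|label`` headers.
    labels
        Optional path to a two-column ``id<TAB>label`` TSV joined by id.
    """
    label_map = read_label_table(labels) if labels is not None else {}
    records: list[PeptideRecord] = []
    for bio_rec in _BioSeqIO.parse(str(path), "fasta"):
        ident, header_label = _parse_header_label(bio_rec.id)
        label = label_map.get(ident, header_label)
        records.append(PeptideRecord(ident, str(bio_rec.seq), label))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return PeptideDataset(records)


def write_fasta(dataset: PeptideDataset, path: str | Path) -> None:
    """Write a dataset as plain FASTA (labels are *not* embedded in headers)."""
    if len(dataset) == 0:
        raise SequenceError("refusing to write an empty dataset")
    bio_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in dataset
    ]
    with open(path, "w") as fh:
        _BioSeqIO.write(bio_records, fh, "fasta")


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global pairwise identity: max matches / shorter sequence length.

    With unit match score and free gaps/mismatches the optimal global
    alignment score equals the maximal number of aligned identical residues.
    """
    if aligner is None:
        aligner = _identity_aligner()
    matches = aligner.score(a, b)
    return matches / min(len(a), len(b))


def reduce_redundancy(
    dataset: PeptideDataset, identity_threshold: float = 0.8
) -> PeptideDataset:
    """Greedy longest-first redundancy reduction.

    Records are visited by (length descending, id ascending); a record is
    kept iff its identity to every previously kept record is strictly below
    ``identity_threshold``. Output preserves the original dataset order of
    the kept records. This is a documented stand-in for CD-HIT, not an exact
    reproduction of its word-filter heuristics.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ParameterError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    aligner = _identity_aligner()
    order = sorted(range(len(dataset)), key=lambda i: (-len(dataset[i]), dataset[i].id))
    kept_idx: list[int] = []
    for i in order:
        seq = dataset[i].sequence
        if all(
            pairwise_identity(seq, dataset[j].sequence, aligner) < identity_threshold
            for j in kept_idx
        ):
            kept_idx.append(i)
    kept_idx.sort()
    return dataset.subset(kept_idx)
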