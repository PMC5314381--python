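"""Sequence and interaction-table input/output.

The pipeline consumes two plain-text inputs:

* a multi-record FASTA of HLA class I protein sequences, and
* a tab-separated interaction table ``allele_id<TAB>peptide<TAB>ic50_nM``
  (header line required, ``#`` comment lines skipped).

Records are labelled ``high`` (IC50 <= 50 nM by default) or ``low``
(IC50 > 50 nM); the boundary value itself is high affinity. Only the 20
standard amino-acid letters are accepted — records containing ambiguity
codes (B, J, O, U, X, Z) are rejected with a warning rather than silently
substituted, because the downstream descriptors have no defined property
value for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .scales import ALPHABET

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"

#: Default IC50 cutoff (nM) separating high- from low-affinity binders.
DEFAULT_IC50_THRESHOLD = 50.0

#: Default accepted peptide lengths: HLA class I presents 8-10-mers.
DEFAULT_PEPTIDE_LENGTHS = (8, 10)

_VALID = set(ALPHABET)


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the 20 standard amino acids."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class InteractionRecord:
    """One (HLA allele, peptide, IC50) measurement with its affinity label."""

    allele_id: str
    peptide: str
    ic50: float
    label: str

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50}")
        if self.label not in (HIGH, LOW):
            raise ValueError(f"label must be {HIGH!r} or {LOW!r}, got {self.label!r}")


@dataclass
class Dataset:
    """Allele sequences plus an ordered list of labelled interactions.

    Record order is stable and defines the row order of any feature matrix
    derived from the dataset.
    """

    alleles: dict[str, ProteinSequence]
    records: list[InteractionRecord] = field(default_factory=list)

    def __post_init__(self):
        unresolved = {r.allele_id for r in self.records} - set(self.alleles)
        if unresolved:
            raise ValueError(f"records reference unknown alleles: {sorted(unresolved)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def count(self, label: str) -> int:
        return sum(1 for r in self.records if r.label == label)


def label_affinity(ic50: float, threshold: float = DEFAULT_IC50_THRESHOLD) -> str:
    """Assign the affinity class for an IC50 measurement in nM.

    ``high`` iff ``ic50 <= threshold`` (the boundary is inclusive on the
    high-affinity side); ``low`` otherwise.
    """
    if not ic50 > 0:
        raise ValueError(f"ic50 must be a positive concentration, got {ic50}")
    return HIGH if ic50 <= threshold else LOW


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Parse a (possibly line-wrapped) FASTA file of protein sequences.

    The header token before the first whitespace becomes the record id and
    sequences are uppercased. Records with non-standard residues are dropped
    with a warning.
    """
    path = Path(path)
    out: list[ProteinSequence] = []
    header: str | None = None
    chunks: list[str] = []

    def _flush():
        if header is None:
            return
        seq = "".join(chunks).upper()
        bad = set(seq) - _VALID
        if not seq:
            logger.warning("FASTA record %r is empty; skipped", header)
        elif bad:
            logger.warning(
                "FASTA record %r contains non-standard residues %s; skipped",
                header,
                sorted(bad),
            )
        else:
            out.append(ProteinSequence(header, seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line)
        _flush()
    return out


def write_fasta(path: str | Path, sequences: Iterable[ProteinSequence], width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def read_interactions(
    path: str | Path,
    alleles: Mapping[str, ProteinSequence],
    threshold: float = DEFAULT_IC50_THRESHOLD,
    peptide_lengths: tuple[int, int] | None = DEFAULT_PEPTIDE_LENGTHS,
) -> Dataset:
    """Read a TSV interaction table and assemble a labelled :class:`Dataset`.

    Expected columns: ``allele_id``, ``peptide``, ``ic50_nM`` (a fourth
    ``label`` column, as written by :func:`write_interactions`, is ignored
    and recomputed from the IC50). Rows with a non-positive or non-numeric
    IC50, a malformed peptide, or an out-of-bounds peptide length are
    rejected with a warning; an allele id missing from ``alleles`` is an
    error.

    Parameters
    ----------
    peptide_lengths : (min, max) or None
        Accepted peptide length range; ``None`` disables the length filter.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    unresolved: set[str] = set()
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # first non-comment line is the header
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("%s:%d: expected >=3 tab-separated fields; row rejected", path, lineno)
                continue
            allele_id, peptide = parts[0], parts[1].upper()
            try:
                ic50 = float(parts[2])
            except ValueError:
                logger.warning("%s:%d: non-numeric ic50 %r; row rejected", path, lineno, parts[2])
                continue
            if ic50 <= 0:
                logger.warning("%s:%d: non-positive ic50 %g; row rejected", path, lineno, ic50)
                continue
            bad = set(peptide) - _VALID
            if bad:
                logger.warning(
                    "%s:%d: peptide %r has non-standard residues %s; row rejected",
                    path, lineno, peptide, sorted(bad),
                )
                continue
            if peptide_lengths is not None and not (
                peptide_lengths[0] <= len(peptide) <= peptide_lengths[1]
            ):
                logger.warning(
                    "%s:%d: peptide length %d outside [%d, %d]; row rejected",
                    path, lineno, len(peptide), *peptide_lengths,
                )
                continue
            if allele_id not in alleles:
                unresolved.add(allele_id)
                continue
            records.append(
                InteractionRecord(allele_id, peptide, ic50, label_affinity(ic50, threshold))
            )
    if unresolved:
        raise ValueError(
            f"{path}: interaction table references alleles absent from the "
            f"sequence pool: {sorted(unresolved)}"
        )
    return Dataset(alleles=dict(alleles), records=records)


def write_interactions(path: str | Path, dataset: Dataset) -> None:
    """Write the labelled interaction table (4-column TSV with header)."""
    with open(path, "w") as fh:
        fh.write("allele_id\tpeptide\tic50_nM\tlabel\n")
        for r in dataset.records:
            fh.write(f"{r.allele_id}\t{r.peptide}\t{r.ic50:g}\t{r.label}\n")
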