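"""Map peptides back to their coding sequences and count codons.

Every retained peptide is located in its parsimony-assigned protein, the
matching codon window is sliced out of the in-frame CDS, and exact counts
over the 61-sense-codon universe are produced. Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, MappingError, ValidationError
from .genetics import CODON_INDEX, SENSE_CODONS, STOP_CODONS
from .simulate import CodingSequence

__all__ = [
    "PeptideCodonProfile",
    "locate_peptide",
    "extract_codons",
    "count_codons",
    "codon_frequencies",
    "profile_peptide",
    "build_codon_profiles",
]

logger = logging.getLogger(__name__)

PROFILE_META_COLUMNS = ["peptide", "protein_id", "start_aa", "length"]


def locate_peptide(peptide: str, protein_aa_seq: str) -> list[int]:
    """All 0-based offsets where ``peptide`` occurs in the protein, ascending.

    Raises :class:`MappingError` when the peptide does not occur at all.
    """
    if not peptide or not protein_aa_seq:
        raise ValidationError("peptide and protein sequences must be non-empty")
    hits = []
    pos = protein_aa_seq.find(peptide)
    while pos != -1:
        hits.append(pos)
        pos = protein_aa_seq.find(peptide, pos + 1)
    if not hits:
        raise MappingError(
            f"peptide {peptide!r} not found in protein", peptide=peptide)
    return hits


def extract_codons(cds: CodingSequence, start_aa: int, length_aa: int,
                   ) -> list[str]:
    """Codons of ``cds`` covering ``[start_aa, start_aa + length_aa)``.

    Validates that the extracted codons translate back to the matching
    stretch of the protein; a mismatch means the CDS and protein databases
    are out of sync.
    """
    if start_aa < 0 or length_aa < 0 or start_aa + length_aa > len(cds):
        raise ValidationError(
            f"{cds.id}: window [{start_aa}, {start_aa + length_aa}) outside "
            f"protein of length {len(cds)}")
    nt = cds.nt_seq[3 * start_aa: 3 * (start_aa + length_aa)]
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    from .genetics import CODON_TO_AA
    translated = "".join(CODON_TO_AA[c] for c in codons)
    expected = cds.aa_seq[start_aa:start_aa + length_aa]
    if translated != expected:
        raise IntegrityError(
            f"{cds.id}: codons at [{start_aa}, {start_aa + length_aa}) "
            f"translate to {translated!r}, expected {expected!r}")
    return codons


def count_codons(codons: Sequence[str]) -> pd.Series:
    """Exact counts of ``codons`` over the fixed 61-key universe.

    Absent codons count 0; a stop codon anywhere is a validation error.
    """
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for c in codons:
        idx = CODON_INDEX.get(c)
        if idx is None:
            if c in STOP_CODONS:
                raise ValidationError(f"stop codon {c} in codon list")
            raise ValidationError(f"invalid codon {c!r}")
        counts[idx] += 1
    return pd.Series(counts, index=list(SENSE_CODONS), name="count")


def codon_frequencies(counts: pd.Series) -> pd.Series | None:
    """Per-codon percentages (summing to 100), or None for an empty vector."""
    total = counts.sum()
    if total == 0:
        return None
    return 100.0 * counts / total


@dataclass(frozen=True)
class PeptideCodonProfile:
    """Codon composition of one peptide's coding region."""

    peptide: str
    protein_id: str
    start_aa: int
    codons: tuple[str, ...]
    counts: pd.Series

    def __post_init__(self):
        if len(self.codons) != len(self.peptide):
            raise ValidationError("codon list length must equal peptide length")

    @property
    def freq_percent(self) -> pd.Series | None:
        return codon_frequencies(self.counts)


def profile_peptide(peptide: str, cds: CodingSequence,
                    start_aa: int | None = None) -> PeptideCodonProfile:
    """Locate (first occurrence), extract and count codons for one peptide."""
    if start_aa is None:
        hits = locate_peptide(peptide, cds.aa_seq)
        if len(hits) > 1:
            logger.debug("peptide %r occurs %d times in %s; using first",
                         peptide, len(hits), cds.id)
        start_aa = hits[0]
    codons = extract_codons(cds, start_aa, len(peptide))
    return PeptideCodonProfile(peptide, cds.id, start_aa, tuple(codons),
                               count_codons(codons))


def build_codon_profiles(assignment: Mapping[str, str],
                         cds_index: Mapping[str, CodingSequence],
                         ) -> pd.DataFrame:
    """Codon-profile table for every assigned peptide.

    ``assignment`` maps peptide -> representative protein id (from parsimony
    inference). Peptides occurring multiple times in their protein use the
    first occurrence (multiplicity is logged). Columns: peptide, protein_id,
    start_aa, length, then the 61 codon counts in alphabetical order.

    Raises :class:`MappingError` if an assigned protein is absent from the
    CDS database or a peptide cannot be located in its protein.
    """
    rows = []
    count_rows = np.zeros((len(assignment), len(SENSE_CODONS)), dtype=np.int64)
    multi = 0
    for i, (pep, prot) in enumerate(sorted(assignment.items())):
        cds = cds_index.get(prot)
        if cds is None:
            raise MappingError(
                f"assigned protein {prot!r} absent from CDS database",
                peptide=pep, protein_id=prot)
        try:
            hits = locate_peptide(pep, cds.aa_seq)
        except MappingError as exc:
            raise MappingError(
                f"peptide {pep!r} not found in assigned protein {prot!r}",
                peptide=pep, protein_id=prot) from exc
        if len(hits) > 1:
            multi += 1
        start = hits[0]
        codons = extract_codons(cds, start, len(pep))
        for c in codons:
            count_rows[i, CODON_INDEX[c]] += 1
        rows.append((pep, prot, start, len(pep)))
    if multi:
        logger.info("%d peptides occur more than once in their protein; "
                    "first occurrence used", multi)
    meta = pd.DataFrame(rows, columns=PROFILE_META_COLUMNS)
    counts = pd.DataFrame(count_rows, columns=list(SENSE_CODONS))
    return pd.concat([meta, counts], axis=1)
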