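"""Standard genetic code: codon universe constants and CDS translation.

The codon universe used throughout the package is the 61 sense codons of the
standard genetic code, ordered alphabetically. Stop codons are excluded from
every counting and ranking operation but are tracked for heatmap layout.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, 61 entries
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: the three stop codons, alphabetical
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

#: the 61 sense codons, alphabetical — the fixed key order of every
#: codon count/frequency vector in this package
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

N_SENSE_CODONS: int = len(SENSE_CODONS)

#: codon -> position in SENSE_CODONS
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: base order used for codon-table (heatmap) layout
BASE_ORDER: str = "TCAG"


def split_codons(nt_seq: str) -> list[str]:
    """Split an in-frame nucleotide sequence into codons.

    Raises
    ------
    ValidationError
        If the length is not a multiple of 3.
    """
    from .errors import ValidationError

    if len(nt_seq) % 3 != 0:
        raise ValidationError(
            f"sequence length {len(nt_seq)} is not divisible by 3")
    return [nt_seq[i:i + 3] for i in range(0, len(nt_seq), 3)]


def translate(nt_seq: str) -> str:
    """Translate an in-frame CDS with the standard genetic code.

    Stop codons are not permitted anywhere, including the final position:
    coding sequences handled here are stop-trimmed by convention.

    Raises
    ------
    ValidationError
        If the length is not divisible by 3, a stop codon occurs (the
        message names the 0-based codon position), or a codon contains
        characters outside ACGT.
    """
    from .errors import ValidationError

    nt_seq = nt_seq.upper()
    aa = []
    for pos, codon in enumerate(split_codons(nt_seq)):
        if codon in STOP_CODONS:
            raise ValidationError(
                f"stop codon {codon} at codon position {pos}")
        try:
            aa.append(CODON_TO_AA[codon])
        except KeyError:
            raise ValidationError(
                f"invalid codon {codon!r} at codon position {pos}") from None
    return "".join(aa)
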