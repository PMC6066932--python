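"""Genetic code handling.

The standard (bacterial, NCBI table 11) code is used throughout: 61 sense
codons, 3 stops, and the common bacterial initiator set {ATG, GTG, TTG}.
Codons are represented internally on the RNA alphabet (ACGU); DNA input
(T) is accepted everywhere and canonicalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

RNA_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

STOP = "*"


class InvalidSequenceError(ValueError):
    """A codon or sequence contains symbols outside the nucleotide alphabet."""


def rna(seq: str) -> str:
    """Canonicalize a nucleotide string to the uppercase RNA alphabet."""
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    s = rna(seq)
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(s))
    except KeyError as exc:
        raise InvalidSequenceError(f"non-nucleotide symbol in {seq!r}") from exc


@dataclass(frozen=True)
class GeneticCode:
    """Mapping between codons and amino acids plus synonymous-family structure.

    Attributes
    ----------
    codon_to_aa:
        Maps all 64 RNA codons to a one-letter amino-acid symbol or ``"*"``.
    start_codons:
        Permitted initiator codons (RNA alphabet).
    families:
        Amino acid -> frozenset of synonymous sense codons. Six-fold
        degenerate amino acids (L, R, S) are each a single family.
    """

    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    families: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.families:
            fams: dict[str, set[str]] = {}
            for codon, aa in self.codon_to_aa.items():
                if aa != STOP:
                    fams.setdefault(aa, set()).add(codon)
            object.__setattr__(
                self, "families", {aa: frozenset(c) for aa, c in fams.items()}
            )

    @property
    def sense_codons(self) -> list[str]:
        return sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    def translate_codon(self, codon: str) -> str:
        c = rna(codon)
        try:
            return self.codon_to_aa[c]
        except KeyError as exc:
            raise InvalidSequenceError(f"unknown codon {codon!r}") from exc

    def family_of(self, codon: str) -> frozenset[str]:
        aa = self.translate_codon(codon)
        if aa == STOP:
            raise ValueError(f"{codon!r} is a stop codon and has no family")
        return self.families[aa]

    def is_stop(self, codon: str) -> bool:
        return self.translate_codon(codon) == STOP


def standard_code(start_codons=("ATG", "GTG", "TTG")) -> GeneticCode:
    """The bacterial genetic code (NCBI translation table 11).

    The sense/stop assignment is identical to the standard code; only the
    initiator set differs and is restricted here to the common bacterial
    starts ATG, GTG and TTG (configurable).
    """
    table = CodonTable.unambiguous_rna_by_id[11]
    codon_to_aa = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_to_aa[stop] = STOP
    return GeneticCode(
        codon_to_aa=codon_to_aa,
        start_codons=frozenset(rna(c) for c in start_codons),
    )


def split_codons(cds: str) -> list[str]:
    """Split a CDS into codons; length must be divisible by 3."""
    s = rna(cds)
    if len(s) % 3 != 0:
        raise InvalidSequenceError(
            f"sequence length {len(s)} is not divisible by 3"
        )
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise InvalidSequenceError(f"non-nucleotide symbols {sorted(bad)}")
    return [s[i : i + 3] for i in range(0, len(s), 3)]
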