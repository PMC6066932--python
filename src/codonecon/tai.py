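"""tRNA adaptation index (tAI).

The absolute decoding weight of a codon is

    W(c) = sum over anticodons j that can pair with c of (1 - s_j) * tGCN_j

where the sum runs over anticodons of the codon's box (same first two
codon positions) whose position-34 base can pair the codon's third base,
s_j is the wobble penalty of that pairing (0 for Watson-Crick) and tGCN_j
the anticodon's gene copy number. Weights are normalized two ways:
globally (w = W / max W over sense codons, the classical tAI weight) and
within each synonymous family (rel, the relative translational
efficiency). A gene's tAI is the geometric mean of w over its codons.

Default penalties: s(U:U) = 0.7 and s(U:C) = 0.95 (superwobble, applied in
all boxes); G:U = 0.41, I:C = 0.28, I:A = 0.9999, U:G = 0.68 follow the
classical eukaryote-derived defaults and are overridable since optimized
bacterial constants are not universally agreed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .code import STOP, GeneticCode, reverse_complement, split_codons
from .trna import TRNAInventory


class UntranslatableCodonError(ValueError):
    """A sense codon has zero decoding weight under the given inventory."""


@dataclass(frozen=True)
class WobbleRuleSet:
    """Pairing rules between anticodon position 34 and codon position 3.

    ``pairs`` maps (anticodon-34 base, codon-3 base) -> penalty s in [0, 1];
    Watson-Crick pairs carry s = 0. A34 acting on C3/A3 models inosine.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for (a, c), s in self.pairs.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"penalty s({a}:{c})={s} outside [0, 1]")


def default_rules(
    s_gu: float = 0.41,
    s_ic: float = 0.28,
    s_ia: float = 0.9999,
    s_ug: float = 0.68,
    s_uu: float = 0.7,
    s_uc: float = 0.95,
) -> WobbleRuleSet:
    return WobbleRuleSet(
        pairs={
            # Watson-Crick
            ("A", "U"): 0.0,
            ("C", "G"): 0.0,
            ("G", "C"): 0.0,
            ("U", "A"): 0.0,
            # wobble
            ("G", "U"): s_gu,
            ("A", "C"): s_ic,  # inosine:C
            ("A", "A"): s_ia,  # inosine:A
            ("U", "G"): s_ug,
            ("U", "U"): s_uu,  # superwobble
            ("U", "C"): s_uc,  # superwobble
        }
    )


@dataclass(frozen=True)
class TAITable:
    """Per-codon decoding weights: absolute W, global w, within-family rel."""

    W: dict[str, float]
    w: dict[str, float]
    rel: dict[str, float]
    source: str = ""


def decoding_anticodons(
    codon: str, rules: WobbleRuleSet
) -> list[tuple[str, float]]:
    """(anticodon, penalty) pairs able to read ``codon`` under ``rules``."""
    tail = reverse_complement(codon[:2])
    out = []
    for (a34, c3), s in rules.pairs.items():
        if c3 == codon[2]:
            out.append((a34 + tail, s))
    return out


def tai_table(
    inv: TRNAInventory,
    rules: WobbleRuleSet | None = None,
    code: GeneticCode | None = None,
) -> TAITable:
    """Compute absolute and normalized tAI weights for all sense codons."""
    from .code import standard_code

    rules = rules if rules is not None else default_rules()
    code = code if code is not None else standard_code()

    W: dict[str, float] = {}
    for codon in code.sense_codons:
        total = 0.0
        for anticodon, s in decoding_anticodons(codon, rules):
            total += (1.0 - s) * inv.counts.get(anticodon, 0)
        if codon == "AUA":
            total += float(inv.ile_aua)  # lysidine-modified Ile(CAU), s = 0
        W[codon] = total

    dead = sorted(c for c, v in W.items() if v == 0.0)
    if dead:
        raise UntranslatableCodonError(
            f"inventory {inv.source!r} cannot translate codons: {', '.join(dead)}"
        )

    w_max = max(W.values())
    w = {c: v / w_max for c, v in W.items()}
    rel = {}
    for fam in code.families.values():
        fam_max = max(W[c] for c in fam)
        for c in fam:
            rel[c] = W[c] / fam_max
    return TAITable(W=W, w=w, rel=rel, source=inv.source)


def relative_efficiency(codon: str, table: TAITable) -> float:
    return table.rel[codon]


def gene_tai(cds: str, table: TAITable, code: GeneticCode) -> float:
    """Gene-level tAI: geometric mean of w over codons (stop excluded)."""
    codons = split_codons(cds)
    if codons and code.translate_codon(codons[-1]) == STOP:
        codons = codons[:-1]
    if not codons:
        raise ValueError("gene has no sense codons")
    for i, c in enumerate(codons):
        if code.translate_codon(c) == STOP:
            raise ValueError(f"internal stop codon {c} at codon {i}")
    logs = [math.log(table.w[c]) for c in codons]
    return float(np.exp(np.mean(logs)))


def write_tai_table(table: TAITable, code: GeneticCode, path) -> None:
    """Export as TSV: codon, amino acid, W, w, rel."""
    lines = ["codon\taa\tW\tw\trel"]
    for codon in code.sense_codons:
        lines.append(
            f"{codon}\t{code.translate_codon(codon)}\t"
            f"{table.W[codon]:.6g}\t{table.w[codon]:.6g}\t{table.rel[codon]:.6g}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
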