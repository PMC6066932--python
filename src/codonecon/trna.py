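"""tRNA gene inventories.

An inventory maps anticodons (5'->3') to tRNA gene copy numbers (tGCN),
read either from tRNAscan-SE tabular output or from a plain two-column
TSV. Hypothetical inventories implement the classical bacterial tRNA
sparing strategies used to probe how tRNA content shapes the codon
cost-efficiency trade-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from .code import GeneticCode, reverse_complement, rna

logger = logging.getLogger(__name__)


class TRNAParseError(ValueError):
    pass


@dataclass(frozen=True)
class TRNAInventory:
    """Anticodon -> tRNA gene copy number (tGCN).

    ``ile_aua`` counts lysidine-modified tRNA-Ile(CAU) decoders, which read
    AUA and are booked separately from the CAU anticodon pool (whose
    unmodified members decode AUG). ``met_cau`` records the number of
    Met-annotated CAU genes when per-isotype annotation was available.
    """

    counts: dict[str, int]
    source: str = "unknown"
    ile_aua: int = 0
    met_cau: int | None = None

    def __post_init__(self):
        clean = {rna(ac): int(n) for ac, n in self.counts.items()}
        if any(n < 0 for n in clean.values()):
            raise ValueError("copy numbers must be non-negative")
        if not any(clean.values()) and self.ile_aua == 0:
            raise ValueError("inventory has no tRNA genes")
        object.__setattr__(self, "counts", clean)

    def total_genes(self) -> int:
        return sum(self.counts.values()) + self.ile_aua


def parse_trnascan(path: str | Path) -> TRNAInventory:
    """Parse tRNAscan-SE tabular output (the ``.out`` dialect).

    Three header lines are skipped; counts are aggregated per anticodon.
    Pseudogene-flagged rows and rows with undetermined ("NNN") anticodons
    contribute no decoding capacity and are excluded with a warning.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise TRNAParseError(f"{path}: empty file")
    counts: dict[str, int] = {}
    met_cau = 0
    n_rows = 0
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise TRNAParseError(
                f"{path}:{lineno}: expected >=6 tab-separated columns, "
                f"got {len(fields)}"
            )
        isotype = fields[4].strip()
        anticodon = fields[5].strip().upper()
        note = fields[9].strip().lower() if len(fields) > 9 else ""
        if isotype.lower().startswith("pseudo") or "pseudo" in note:
            logger.warning("%s:%d: skipping pseudogene row", path, lineno)
            continue
        if "N" in rna(anticodon).replace("U", ""):  # undetermined anticodon
            logger.warning(
                "%s:%d: skipping undetermined anticodon %r", path, lineno, anticodon
            )
            continue
        ac = rna(anticodon)
        if len(ac) != 3 or set(ac) - set("ACGU"):
            raise TRNAParseError(f"{path}:{lineno}: bad anticodon {anticodon!r}")
        counts[ac] = counts.get(ac, 0) + 1
        if ac == "CAU" and isotype == "Met":
            met_cau += 1
        n_rows += 1
    if n_rows == 0:
        raise TRNAParseError(f"{path}: no usable tRNA rows")
    return TRNAInventory(counts=counts, source=str(path), met_cau=met_cau or None)


def parse_anticodon_tsv(path: str | Path) -> TRNAInventory:
    """Read a plain TSV of ``anticodon<TAB>count`` rows ('#' comments allowed)."""
    counts: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            ac, n = line.split("\t")
            counts[rna(ac)] = counts.get(rna(ac), 0) + int(n)
        except ValueError as exc:
            raise TRNAParseError(f"{path}:{lineno}: bad row {line!r}") from exc
    if not counts:
        raise TRNAParseError(f"{path}: empty inventory")
    return TRNAInventory(counts=counts, source=str(path))


def ile_cat_correction(inv: TRNAInventory) -> TRNAInventory:
    """Compensate for tRNAscan's inability to call tRNA-Ile(CAU).

    If more than one Met(CAU) gene is present, one lysidine-modified
    Ile(CAU) decoder (which reads AUA) is added with copy number 1;
    otherwise the inventory is unchanged. When per-isotype annotation is
    unavailable the total CAU count is used as the Met(CAU) count.
    """
    met = inv.met_cau if inv.met_cau is not None else inv.counts.get("CAU", 0)
    if met > 1:
        return replace(inv, ile_aua=inv.ile_aua + 1)
    return inv


def hypothetical_inventory(kind: str, code: GeneticCode) -> TRNAInventory:
    """Hypothetical single-copy inventories for tRNA sparing strategies.

    ``full``
        One copy of each of the 61 Watson-Crick anticodons.
    ``strategy1``
        full minus all A34 anticodons (NNU codons read by G34 via G:U).
    ``strategy2``
        strategy1 minus C34 anticodons (NNG codons read by U34 via U:G),
        except where no U34 partner exists because the NNA codon is a stop
        (tRNA-Trp(CCA) is retained so UGG stays translatable).
    ``strategy3``
        strategy2 with G34 anticodons additionally dropped in four-codon
        boxes, leaving a single U34 anticodon reading the whole box via
        superwobble.
    """
    wc = {reverse_complement(c) for c in code.sense_codons}
    if kind == "full":
        keep = wc
    elif kind == "strategy1":
        keep = {ac for ac in wc if ac[0] != "A"}
    elif kind in ("strategy2", "strategy3"):
        s1 = {ac for ac in wc if ac[0] != "A"}
        keep = {
            ac
            for ac in s1
            if ac[0] != "C" or ("U" + ac[1:]) not in s1
        }
        if kind == "strategy3":
            four_boxes = {
                prefix
                for prefix in {c[:2] for c in code.sense_codons}
                if len({code.translate_codon(prefix + b) for b in "ACGU"}) == 1
                and all(prefix + b in code.codon_to_aa for b in "ACGU")
            }
            keep = {
                ac
                for ac in keep
                if not (ac[0] == "G" and reverse_complement(ac[1:]) in four_boxes)
            }
    else:
        raise ValueError(f"unknown hypothetical inventory kind {kind!r}")
    return TRNAInventory(
        counts={ac: 1 for ac in sorted(keep)}, source=f"hypothetical:{kind}"
    )
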