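"""Per-codon biosynthetic cost.

A codon's biosynthetic cost is defined additively: the sum of the costs of
its three nucleotides. The default metric is the nitrogen-atom cost of the
bases (A=5, C=3, G=5, U=2 ring nitrogens; the ribose-phosphate backbone
carries none), under which e.g. GCC costs 11 atoms and GCA/GCG cost 13.

Relative cost normalizes within a synonymous family so the most expensive
synonymous codon has relative cost exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .code import STOP, GeneticCode, InvalidSequenceError, rna


@dataclass(frozen=True)
class CostTable:
    """Per-nucleotide biosynthetic cost on the RNA alphabet.

    ``metric`` is a free label ("nitrogen", "energy", or custom); all four
    bases must be present with non-negative cost.
    """

    metric: str
    per_nucleotide: dict[str, float]

    def __post_init__(self):
        missing = {"A", "C", "G", "U"} - set(self.per_nucleotide)
        if missing:
            raise ValueError(f"cost table missing bases {sorted(missing)}")
        if any(v < 0 for v in self.per_nucleotide.values()):
            raise ValueError("nucleotide costs must be non-negative")


#: Nitrogen atoms per base: adenine and guanine carry 5 ring/exocyclic
#: nitrogens, cytosine 3, uracil 2.
NITROGEN = CostTable("nitrogen", {"A": 5.0, "C": 3.0, "G": 5.0, "U": 2.0})


def placeholder_energy_table() -> CostTable:
    """A PLACEHOLDER energetic (~P bond) cost table.

    No authoritative per-nucleotide high-energy-phosphate cost ships with
    this package; energetic analyses should supply a curated table via
    :func:`read_cost_table`. This placeholder is affine in the nitrogen
    cost and exists so energy-metric code paths can be exercised; outputs
    computed from it are labeled with the table's metric name.
    """
    return CostTable(
        "energy-placeholder",
        {b: 0.6 * c + 0.44 / 3 for b, c in NITROGEN.per_nucleotide.items()},
    )


def codon_cost(codon: str, table: CostTable = NITROGEN) -> float:
    """Biosynthetic cost of a codon: sum of its per-nucleotide costs."""
    c = rna(codon)
    if len(c) != 3:
        raise InvalidSequenceError(f"{codon!r} is not a 3-mer")
    try:
        return sum(table.per_nucleotide[b] for b in c)
    except KeyError as exc:
        raise InvalidSequenceError(f"unknown symbol in codon {codon!r}") from exc


def relative_cost(codon: str, table: CostTable, code: GeneticCode) -> float:
    """Cost relative to the most expensive synonymous codon (in (0, 1])."""
    c = rna(codon)
    aa = code.translate_codon(c)
    if aa == STOP:
        raise ValueError(f"{codon!r} is a stop codon; relative cost undefined")
    fam_max = max(codon_cost(x, table) for x in code.families[aa])
    return codon_cost(c, table) / fam_max


def family_cost_profile(
    aa: str, table: CostTable, code: GeneticCode
) -> list[tuple[str, float, float]]:
    """(codon, absolute cost, relative cost) for every codon of one family."""
    if aa not in code.families:
        raise KeyError(f"unknown amino-acid symbol {aa!r}")
    rows = []
    for codon in sorted(code.families[aa]):
        rows.append(
            (codon, codon_cost(codon, table), relative_cost(codon, table, code))
        )
    return rows


def read_cost_table(path: str | Path) -> CostTable:
    """Read a two-column TSV (nucleotide, cost); '# metric: NAME' header."""
    metric = "custom"
    per_nt: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("metric:"):
                metric = body.split(":", 1)[1].strip()
            continue
        nt, value = line.split("\t")
        per_nt[rna(nt)] = float(value)
    return CostTable(metric, per_nt)


def write_cost_table(table: CostTable, path: str | Path) -> None:
    lines = [f"# metric: {table.metric}"]
    for nt in "ACGU":
        lines.append(f"{nt}\t{table.per_nucleotide[nt]:g}")
    Path(path).write_text("\n".join(lines) + "\n")
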