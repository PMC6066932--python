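"""In-silico single-nucleotide mutagenesis.

Every position of a CDS is mutated to each alternative base; mutations are
classed as synonymous, non-synonymous, nonsense (creating a premature
stop), start-loss or stop-loss, and the change in cost-efficiency
optimality (delta score, mutant minus original) is computed for the
synonymous and non-synonymous classes. For a non-synonymous change the
frontier is rebuilt for the mutated amino-acid sequence, so each sequence
is scored against its own constraint set. The fraction of scorable
mutations with negative delta ("deleterious" in the cost-efficiency sense)
is summarized per gene and regressed on gene optimality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .code import STOP, GeneticCode, rna, split_codons
from .costs import CostTable, relative_cost
from .optimality import frontiers_from_composition, score_point, PointCE
from .tai import TAITable

BASES = "ACGU"


@dataclass(frozen=True)
class MutationRecord:
    position: int  # 0-based nucleotide index
    ref: str
    alt: str
    mut_class: str  # synonymous | nonsynonymous | nonsense | start_loss | stop_loss
    delta_score: float | None = None


@dataclass(frozen=True)
class ScanSummary:
    gene: str
    optimality: float
    syn_deleterious_frac: float
    nonsyn_deleterious_frac: float
    n_syn: int
    n_nonsyn: int


def _classify(codon_index, old_codon, new_codon, code: GeneticCode, n_codons) -> str:
    old_aa = code.translate_codon(old_codon)
    new_aa = code.translate_codon(new_codon)
    last = codon_index == n_codons - 1
    if codon_index == 0 and new_codon not in code.start_codons:
        return "start_loss"
    if last and old_aa == STOP:
        return "synonymous" if new_aa == STOP else "stop_loss"
    if new_aa == STOP:
        return "nonsense"
    if old_aa == new_aa:
        return "synonymous"
    return "nonsynonymous"


def enumerate_snvs(cds: str, code: GeneticCode) -> list[MutationRecord]:
    """All 3L single-nucleotide variants of a CDS, classified, no deltas."""
    seq = rna(cds)
    codons = split_codons(seq)
    records = []
    for pos, ref in enumerate(seq):
        ci, within = divmod(pos, 3)
        old_codon = codons[ci]
        for alt in BASES:
            if alt == ref:
                continue
            new_codon = old_codon[:within] + alt + old_codon[within + 1 :]
            records.append(
                MutationRecord(
                    position=pos,
                    ref=ref,
                    alt=alt,
                    mut_class=_classify(ci, old_codon, new_codon, code, len(codons)),
                )
            )
    return records


def sample_snvs(
    cds: str, m: int, seed: int, code: GeneticCode
) -> list[MutationRecord]:
    """Uniform sample of m SNVs without replacement; seeded and reproducible."""
    records = enumerate_snvs(cds, code)
    if m < 1 or m > len(records):
        raise ValueError(f"m={m} outside [1, {len(records)}]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=m, replace=False)
    return [records[i] for i in sorted(idx)]


def score_mutations(
    cds: str,
    records: list[MutationRecord],
    table: CostTable,
    tai: TAITable,
    code: GeneticCode,
) -> list[MutationRecord]:
    """Attach delta_score to synonymous and non-synonymous records.

    Mutations are applied one at a time to the original sequence. The
    original and mutant are each scored under their own amino-acid
    constraint; nonsense, start-loss and stop-loss records get no delta.
    """
    seq = rna(cds)
    codons = split_codons(seq)
    if code.translate_codon(codons[-1]) == STOP:
        sense = codons[:-1]
    else:
        sense = codons
    aa_counts: dict[str, int] = {}
    for c in sense:
        aa = code.translate_codon(c)
        aa_counts[aa] = aa_counts.get(aa, 0) + 1
    n_sense = len(sense)
    cost_sum = sum(relative_cost(c, table, code) for c in sense)
    eff_sum = sum(tai.rel[c] for c in sense)
    base_fronts = frontiers_from_composition(aa_counts, table, tai, code)
    base = score_point(
        PointCE(cost_sum / n_sense, eff_sum / n_sense), base_fronts
    )

    out = []
    for rec in records:
        if rec.mut_class not in ("synonymous", "nonsynonymous"):
            out.append(rec)
            continue
        ci, within = divmod(rec.position, 3)
        if ci >= n_sense:  # stop-codon synonymous change: no coordinate change
            out.append(replace(rec, delta_score=0.0))
            continue
        old_codon = sense[ci]
        new_codon = old_codon[:within] + rec.alt + old_codon[within + 1 :]
        old_aa = code.translate_codon(old_codon)
        new_aa = code.translate_codon(new_codon)
        new_cost = cost_sum - relative_cost(old_codon, table, code) + relative_cost(
            new_codon, table, code
        )
        new_eff = eff_sum - tai.rel[old_codon] + tai.rel[new_codon]
        point = PointCE(new_cost / n_sense, new_eff / n_sense)
        if new_aa == old_aa:
            res = score_point(point, base_fronts)
        else:
            counts = dict(aa_counts)
            counts[old_aa] -= 1
            counts[new_aa] = counts.get(new_aa, 0) + 1
            res = score_point(
                point, frontiers_from_composition(counts, table, tai, code)
            )
        out.append(replace(rec, delta_score=res.score - base.score))
    return out


def scan_gene(
    gene_id: str,
    cds: str,
    table: CostTable,
    tai: TAITable,
    code: GeneticCode,
    mode: str = "exhaustive",
    m: int = 1000,
    seed: int = 0,
) -> ScanSummary:
    """Deleterious-fraction summary for one gene."""
    from .optimality import optimality as _optimality

    if mode == "exhaustive":
        records = enumerate_snvs(cds, code)
    elif mode == "sample":
        records = sample_snvs(cds, m, seed, code)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scored = score_mutations(cds, records, table, tai, code)
    opt = _optimality(cds, table, tai, code).score

    def frac(cls: str) -> tuple[float, int]:
        deltas = [r.delta_score for r in scored if r.mut_class == cls]
        if not deltas:
            return (float("nan"), 0)
        neg = sum(1 for d in deltas if d < 0)
        return (100.0 * neg / len(deltas), len(deltas))

    syn, n_syn = frac("synonymous")
    nonsyn, n_nonsyn = frac("nonsynonymous")
    return ScanSummary(
        gene=gene_id,
        optimality=opt,
        syn_deleterious_frac=syn,
        nonsyn_deleterious_frac=nonsyn,
        n_syn=n_syn,
        n_nonsyn=n_nonsyn,
    )


def scan_genome(
    cds_set,
    table: CostTable,
    tai: TAITable,
    code: GeneticCode,
    ids=None,
    mode: str = "exhaustive",
    m: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene scan summaries plus OLS of deleterious fraction on optimality.

    Returns (summary table, {"synonymous": RegressionResult-dict,
    "nonsynonymous": ...}); regressions on constant optimality are flagged
    degenerate.
    """
    from .analyses import simple_ols

    ids = list(ids) if ids is not None else [f"gene_{i}" for i in range(len(cds_set))]
    rows = [
        scan_gene(gid, cds, table, tai, code, mode=mode, m=m, seed=seed + i)
        for i, (gid, cds) in enumerate(zip(ids, cds_set))
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df) < 3:
        raise ValueError("need at least 3 genes for the trend regression")
    regs = {}
    for cls, col in (
        ("synonymous", "syn_deleterious_frac"),
        ("nonsynonymous", "nonsyn_deleterious_frac"),
    ):
        sub = df.dropna(subset=[col, "optimality"])
        if sub["optimality"].nunique() < 2:
            regs[cls] = {"degenerate": True}
        else:
            res = simple_ols(sub["optimality"].values, sub[col].values)
            regs[cls] = {
                "slope": res.slope,
                "intercept": res.intercept,
                "r2": res.r2,
                "p": res.p,
                "n": res.n,
                "degenerate": False,
            }
    return df, regs
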