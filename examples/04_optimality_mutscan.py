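"""Pareto cost-efficiency optimality of a transcript and its mutational
robustness.

For a fixed protein, every synonymous recoding occupies a point in (mean
relative cost, mean relative efficiency) space. The optimality score
100*d4/(d1+d4) locates a transcript between the Pareto frontier (score
100) and the anti-frontier (score 0). The SNV scan then asks what fraction
of single-nucleotide changes would lower that score.
"""

from codonecon import (
    NITROGEN,
    default_rules,
    enumerate_snvs,
    hypothetical_inventory,
    optimality,
    scan_gene,
    standard_code,
    tai_table,
)

code = standard_code()
tai = tai_table(hypothetical_inventory("strategy2", code), default_rules(), code)

gene = "ATG" + "GGTAAAGTTGCAACCCATTGC" * 3 + "TAA"  # M (GKVATHC)x3 *
res = optimality(gene, NITROGEN, tai, code)
print(f"gene point: cost={res.point.cost:.3f}, efficiency={res.point.eff:.3f}")
print(f"d1 (to Pareto frontier) = {res.d1:.4f}, d4 (to anti-frontier) = {res.d4:.4f}")
print(f"optimality = {res.score:.1f}%  (100% = on the Pareto frontier)")

summary = scan_gene("example", gene, NITROGEN, tai, code)
n_records = len(enumerate_snvs(gene, code))
print(f"\nexhaustive SNV scan ({n_records} variants):")
print(f"  synonymous: {summary.n_syn} scorable, "
      f"{summary.syn_deleterious_frac:.1f}% reduce optimality")
print(f"  non-synonymous: {summary.n_nonsyn} scorable, "
      f"{summary.nonsyn_deleterious_frac:.1f}% reduce optimality")
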