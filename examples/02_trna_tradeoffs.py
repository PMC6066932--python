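"""How tRNA gene content shapes the codon cost-efficiency trade-off.

Builds three hypothetical species: a full complement of 61 Watson-Crick
anticodons, sparing strategy 1 (no A34 anticodons; NNU codons read by G34
wobble) and strategy 2 (additionally no C34; NNG codons read by U34).
For each, computes tAI decoding weights and regresses within-family
relative efficiency on relative nitrogen cost across multi-codon families.
A negative slope means cheap codons are also efficient; a positive slope
means cost and efficiency selection pull in opposite directions.
"""

from codonecon import (
    NITROGEN,
    default_rules,
    hypothetical_inventory,
    standard_code,
    tai_table,
    tradeoff_gradient,
)

code = standard_code()
for kind in ("full", "strategy1", "strategy2"):
    inv = hypothetical_inventory(kind, code)
    tai = tai_table(inv, default_rules(), code)
    reg = tradeoff_gradient(tai, NITROGEN, code)
    print(
        f"{kind:10s} ({len(inv.counts):2d} anticodons): "
        f"slope={reg.slope:+.2f}  R^2={reg.r2:.2f}  p={reg.p:.2g}"
        + ("  (no significant trade-off)" if reg.p >= 0.05 else "")
    )
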