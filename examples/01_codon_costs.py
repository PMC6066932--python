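"""Per-codon biosynthetic cost: absolute nitrogen atoms and within-family
relative cost.

Builds nothing external: uses the default nitrogen table (A=5, C=3, G=5,
U=2 atoms per base) and prints the alanine family profile. The relative
cost of a codon is its cost divided by the most expensive synonymous
codon, so the family maximum is exactly 1.
"""

from codonecon import NITROGEN, codon_cost, family_cost_profile, relative_cost, standard_code

code = standard_code()

print(f"nitrogen cost of GCC: {codon_cost('GCC', NITROGEN):.0f} atoms")
print(f"nitrogen cost of GCA: {codon_cost('GCA', NITROGEN):.0f} atoms")
print(f"relative cost of GCC: {relative_cost('GCC', NITROGEN, code):.2f} "
      "(= 11/13, cheapest-but-one alanine codon)")
print()
print("alanine family profile (codon, atoms, relative):")
for codon, cost, rel in family_cost_profile("A", NITROGEN, code):
    print(f"  {codon}  {cost:4.0f}  {rel:.3f}")
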