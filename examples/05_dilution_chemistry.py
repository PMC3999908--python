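"""Centesimal-dilution arithmetic: molarities, molecule counts, ethanol.

Walks the gelsemine potency chain from the mother tincture (6.5e-4 M)
through the centesimal dilutions used in the cell assays, including the
in-assay 1:10 step, and converts molarities to expected molecule numbers.
"""
from dosetx.dilution import (
    DilutionSpec,
    centesimal_molarity,
    chain_ethanol,
    molecule_count,
)

MT = 6.5e-4  # mol/L gelsemine in the mother tincture

print("potency   in-assay molarity      molecules / 10-ml plate")
for n in (2, 3, 4, 5, 9, 30):
    spec = DilutionSpec(MT, n, extra_factors=(10.0,))
    mol = centesimal_molarity(spec)
    mc = molecule_count(mol, volume_l=0.010)
    flag = "  (< 1: sub-molecular)" if mc.sub_molecular else ""
    print(f"  {n:>2}c     {mol:9.1e} M        {mc.count:9.3g}{flag}")

mc5 = molecule_count(centesimal_molarity(DilutionSpec(MT, 5, (10.0,))), 0.010,
                     cells=3_000_000)
print(f"\nat 5c a 10-ml plate holds ~{mc5.count:.2g} molecules, "
      f"about {mc5.per_cell:.0f} per seeded cell")

mc9 = molecule_count(centesimal_molarity(DilutionSpec(MT, 9)), 0.001)
print(f"at 9c, {mc9.count:.2f} molecules are expected per ml of working "
      "solution - a Poisson mean below one molecule")

eth = chain_ethanol(30.0, [(0.05, 5.0), (1.0, 10.0)])
print(f"\nethanol: 30% stock -> {chain_ethanol(30.0, [(0.05, 5.0)]):.2g}% in the "
      f"final dilution -> {eth:.2g}% in the assay (far below cytotoxic levels)")
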