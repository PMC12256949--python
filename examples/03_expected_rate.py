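"""Derive the expected loading rate from the bead dose and mean droplet volume.

mu = (beads per unit aqueous volume) x (mean droplet volume): no fitting,
just the concentration argument. Also shown: the ligand-coupling arithmetic
and the 37% single-occupancy ceiling of random encapsulation.
"""

import math

from beadpoisson import BeadDose, expected_mu, ligand_density, poisson_pmf

# mineral-oil/Abil EM 90 condition: 10^7 beads in 100 ul, 3.6 pL mean droplet
mu_abil = expected_mu(BeadDose(n_beads=1e7, aqueous_volume_ul=100), 3.6)
# fluorocarbon/FluoSurf condition: 10^7 beads in 200 ul, 8.9 pL mean droplet
mu_fluo = expected_mu(BeadDose(n_beads=1e7, aqueous_volume_ul=200), 8.9)
print(f"expected mu (Abil EM 90):  {mu_abil:.2f}")
print(f"expected mu (FluoSurf):    {mu_fluo:.3f} (~{mu_fluo:.2f})")

print(f"single-occupancy ceiling:  {100 * poisson_pmf(1, 1.0):.1f}% at mu = 1 (1/e)")

peptides = ligand_density(ligand_volume_ul=9.2, ligand_concentration_um=9.0, n_beads=5e7)
print(f"peptides per bead:         {peptides:.3g} (~10^{round(math.log10(peptides))})")
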