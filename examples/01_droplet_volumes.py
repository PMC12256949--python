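"""Convert measured in-plane droplet diameters to volumes under slab confinement.

An emulsion imaged between slide and coverslip forms a liquid layer of fixed
height; droplets wider than the layer are squeezed into pancakes, so their
in-plane diameter maps to volume through a cylinder rather than a sphere.
"""

from beadpoisson import ChamberGeometry, volume_from_diameter

geometry = ChamberGeometry(layer_height_um=8.4)  # mineral-oil/Abil EM 90 chamber

for d in (2.0, 8.4, 23.36, 40.0):
    dv = volume_from_diameter(d, geometry)
    print(f"diameter {d:6.2f} um -> {dv.volume_pl:9.4f} pL  ({dv.shape_regime})")

# The 23.36 um droplet holds ~3.6 pL, the mean bead-containing droplet volume
# of the mineral-oil condition; small droplets (d <= 8.4 um) stay spherical.
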