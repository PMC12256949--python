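"""Droplet volumes under slab confinement between slide and coverslip.

An emulsion aliquot imaged between a glass slide and a coverslip forms a
liquid layer of fixed height ``h``. Droplets smaller than the layer remain
spherical and their imaged in-plane diameter ``d`` is the true sphere
diameter; droplets larger than the layer are squeezed into pancakes, modelled
here as cylinders of height ``h`` and diameter ``d``. The volume rule is

    V(d) = (pi/6) d^3          if d <= h   (sphere)
    V(d) = pi (d/2)^2 h        if d >  h   (cylinder)

The rule is deliberately discontinuous at ``d == h`` (the cylinder formula
exceeds the sphere formula by a factor 1.5 there); the regime is reported
alongside every volume so boundary cases can be audited. A droplet whose
diameter exactly equals the layer height is treated as an undeformed sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import UM3_PER_PL

__all__ = [
    "ChamberGeometry",
    "DropletVolume",
    "volume_from_diameter",
    "diameter_from_volume",
    "volumes_from_diameters",
    "diameters_from_volumes",
]

SPHERE = "sphere"
CYLINDER = "cylinder"


@dataclass(frozen=True)
class ChamberGeometry:
    """Measurement chamber: the liquid layer height between slide and coverslip.

    Parameters
    ----------
    layer_height_um
        Height of the liquid layer in micrometres; must be strictly positive.
        Typical values for mineral-oil/Abil EM 90 and HFE-7500/FluoSurf
        emulsions are 8.4 and 7.2 um respectively.
    """

    layer_height_um: float

    def __post_init__(self) -> None:
        if not (self.layer_height_um > 0):
            raise ValueError(
                f"layer_height_um must be strictly positive, got {self.layer_height_um!r}"
            )

    @property
    def sphere_volume_max_pl(self) -> float:
        """Largest sphere-regime volume: (pi/6) h^3, in pL."""
        return math.pi / 6.0 * self.layer_height_um**3 / UM3_PER_PL

    @property
    def cylinder_volume_min_pl(self) -> float:
        """Cylinder-regime volume at d == h: (pi/4) h^3, in pL."""
        return math.pi / 4.0 * self.layer_height_um**3 / UM3_PER_PL


@dataclass(frozen=True)
class DropletVolume:
    """A droplet volume (pL) together with the confinement regime that produced it."""

    volume_pl: float
    shape_regime: str

    def __post_init__(self) -> None:
        if not (self.volume_pl > 0):
            raise ValueError(f"volume_pl must be strictly positive, got {self.volume_pl!r}")
        if self.shape_regime not in (SPHERE, CYLINDER):
            raise ValueError(f"shape_regime must be 'sphere' or 'cylinder', got {self.shape_regime!r}")


def volume_from_diameter(diameter_um: float, geometry: ChamberGeometry) -> DropletVolume:
    """Convert a measured in-plane diameter (um) to a droplet volume (pL).

    Diameters up to and including the layer height use the sphere formula;
    larger diameters use the cylinder formula with the layer height as the
    cylinder height.
    """
    if not (diameter_um > 0):
        raise ValueError(f"diameter_um must be strictly positive, got {diameter_um!r}")
    h = geometry.layer_height_um
    if diameter_um <= h:
        v_um3 = math.pi / 6.0 * diameter_um**3
        regime = SPHERE
    else:
        v_um3 = math.pi * (diameter_um / 2.0) ** 2 * h
        regime = CYLINDER
    return DropletVolume(v_um3 / UM3_PER_PL, regime)


def diameter_from_volume(volume_pl: float, geometry: ChamberGeometry) -> float:
    """Invert :func:`volume_from_diameter`: volume (pL) to in-plane diameter (um).

    Because the forward rule jumps by a factor 1.5 at ``d == h``, volumes in
    the open gap ``((pi/6) h^3, (pi/4) h^3]`` can never be produced by it.
    Such volumes are clamped to the boundary diameter ``d = h`` (the tie rule
    assigns the boundary to the sphere regime), which keeps the inverse
    monotone and total. Away from the gap the round trip d -> V -> d is exact
    to floating-point precision.
    """
    if not (volume_pl > 0):
        raise ValueError(f"volume_pl must be strictly positive, got {volume_pl!r}")
    h = geometry.layer_height_um
    v_um3 = volume_pl * UM3_PER_PL
    v_sphere_max = math.pi / 6.0 * h**3
    v_cyl_min = math.pi / 4.0 * h**3
    if v_um3 <= v_sphere_max:
        return (6.0 * v_um3 / math.pi) ** (1.0 / 3.0)
    if v_um3 > v_cyl_min:
        return 2.0 * math.sqrt(v_um3 / (math.pi * h))
    return h


def volumes_from_diameters(
    diameters_um: np.ndarray, geometry: ChamberGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`volume_from_diameter`.

    Returns
    -------
    volumes_pl, regimes
        Arrays of droplet volumes (pL) and regime labels ('sphere'/'cylinder').
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size and not np.all(d > 0):
        bad = np.flatnonzero(~(d > 0))
        raise ValueError(f"diameter_um must be strictly positive; offending indices: {bad.tolist()[:10]}")
    h = geometry.layer_height_um
    sphere = d <= h
    v_um3 = np.where(sphere, math.pi / 6.0 * d**3, math.pi * (d / 2.0) ** 2 * h)
    regimes = np.where(sphere, SPHERE, CYLINDER)
    return v_um3 / UM3_PER_PL, regimes


def diameters_from_volumes(volumes_pl: np.ndarray, geometry: ChamberGeometry) -> np.ndarray:
    """Vectorised :func:`diameter_from_volume`."""
    v = np.asarray(volumes_pl, dtype=float)
    if v.size and not np.all(v > 0):
        bad = np.flatnonzero(~(v > 0))
        raise ValueError(f"volume_pl must be strictly positive; offending indices: {bad.tolist()[:10]}")
    h = geometry.layer_height_um
    v_um3 = v * UM3_PER_PL
    v_sphere_max = math.pi / 6.0 * h**3
    v_cyl_min = math.pi / 4.0 * h**3
    with np.errstate(invalid="ignore"):
        d = np.select(
            [v_um3 <= v_sphere_max, v_um3 > v_cyl_min],
            [(6.0 * v_um3 / math.pi) ** (1.0 / 3.0), 2.0 * np.sqrt(v_um3 / (math.pi * h))],
            default=h,
        )
    return d
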