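import math

import numpy as np
import pytest

from beadpoisson import ChamberGeometry, SimulationParams


@pytest.fixture
def abil_geometry():
    """Chamber geometry of the mineral-oil/Abil EM 90 condition (8.4 um layer)."""
    return ChamberGeometry(8.4)


@pytest.fixture
def fluosurf_geometry():
    """Chamber geometry of the HFE-7500/FluoSurf condition (7.2 um layer)."""
    return ChamberGeometry(7.2)


@pytest.fixture
def small_emulsion_params():
    """Abil-condition emulsion scaled down 1000x at fixed bead concentration."""
    return SimulationParams.abil_em90(seed=11).scaled(1e-3)


def monodisperse_params(mu_true: float, n_bead_containing: int, seed: int) -> SimulationParams:
    """Monodisperse 3.6 pL emulsion sized to yield ~n_bead_containing loaded droplets."""
    frac = 1.0 - math.exp(-mu_true)
    n_droplets = int(n_bead_containing / frac)
    aq_pl = n_droplets * 3.6
    return SimulationParams(
        n_beads=int(round(mu_true / 3.6 * aq_pl)),
        aqueous_volume_ul=aq_pl / 1e6,
        log_mean_pl=math.log(3.6),
        log_sd_pl=0.0,
        cluster_p=1.0,
        layer_height_um=8.4,
        seed=seed,
    )
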