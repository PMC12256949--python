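"""Synthetic polydisperse emulsions with volume-proportional bead loading.

The generator emulates the statistical structure of a vortexed bulk
water-in-oil emulsion carrying functionalised microbeads:

1. droplet volumes are drawn from a lognormal (or gamma) distribution and
   accumulated until the total aqueous phase is exactly dispersed (the last
   droplet is trimmed, so droplet count is emergent, not fixed);
2. beads — or bead *clusters*, when aggregation is simulated — are placed
   into droplets independently with probability proportional to droplet
   volume, the stochastic model that yields Poisson occupancy in the
   dilute limit;
3. a measurement table of in-plane diameters is rendered through the
   slab-confinement geometry, optionally restricted to bead-containing
   droplets and subsampled, mimicking a manual microscopy campaign.

Aggregation is modelled by partitioning the beads into clusters with
shifted-geometric sizes (support >= 1, mean 1/p) that co-partition into one
droplet; ``cluster_p = 1`` recovers independent single beads. This cluster
model is synthetic: it stands in for qualitative descriptions of bead
clumping, not for any measured aggregate-size distribution.

Default parameters mirror the two study conditions this package analyses:
10^7 beads dispersed in 100 ul (mean bead-containing droplet volume ~3.6 pL,
layer height 8.4 um) or 200 ul (~8.9 pL, 7.2 um). At full scale that is
~10^7-10^8 droplets; use :meth:`SimulationParams.scaled` to shrink the
emulsion while keeping the bead concentration — and hence all occupancy
statistics — unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ChamberGeometry, diameters_from_volumes
from .units import PL_PER_UL

__all__ = [
    "SimulationParams",
    "SyntheticEmulsion",
    "sample_droplet_volumes",
    "sample_cluster_sizes",
    "load_beads",
    "simulate_emulsion",
    "render_measurements",
    "write_emulsion",
]

#: lognormal sigma (in log-volume space) used when no polydispersity is given;
#: chosen once as a realistic spread for vortexed bulk emulsions
DEFAULT_LOG_SD = 0.8


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of a synthetic emulsification run.

    Parameters
    ----------
    n_beads
        Total beads dispersed in the aqueous phase.
    aqueous_volume_ul
        Total aqueous volume (ul); fully dispersed into droplets.
    log_mean_pl, log_sd_pl
        Lognormal parameters of the droplet volume distribution, in log-pL.
        The distribution mean is ``exp(log_mean + log_sd^2 / 2)``.
    cluster_p
        Termination probability of the shifted-geometric cluster-size law,
        in (0, 1]; mean cluster size is 1/p, and p = 1 means no aggregation.
    layer_height_um
        Liquid layer height of the measurement chamber.
    seed
        Master seed; all randomness in a run flows from it.
    family
        'lognormal' (default) or 'gamma'; the gamma alternative is moment-
        matched to the lognormal's mean and variance.
    """

    n_beads: int = 10_000_000
    aqueous_volume_ul: float = 100.0
    log_mean_pl: float = math.log(3.6) - DEFAULT_LOG_SD**2 / 2
    log_sd_pl: float = DEFAULT_LOG_SD
    cluster_p: float = 1.0
    layer_height_um: float = 8.4
    seed: int = 0
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if not (self.n_beads > 0):
            raise ValueError(f"n_beads must be strictly positive, got {self.n_beads!r}")
        if not (self.aqueous_volume_ul > 0):
            raise ValueError(f"aqueous_volume_ul must be strictly positive, got {self.aqueous_volume_ul!r}")
        if not (0 < self.cluster_p <= 1):
            raise ValueError(f"cluster_p must lie in (0, 1], got {self.cluster_p!r}")
        if not (self.layer_height_um > 0):
            raise ValueError(f"layer_height_um must be strictly positive, got {self.layer_height_um!r}")
        if not (self.log_sd_pl >= 0) or not np.isfinite(self.log_mean_pl) or not np.isfinite(self.log_sd_pl):
            raise ValueError("volume distribution parameters must be finite with log_sd_pl >= 0")
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"family must be 'lognormal' or 'gamma', got {self.family!r}")

    @classmethod
    def abil_em90(cls, **overrides) -> "SimulationParams":
        """Mineral-oil/Abil EM 90 condition: 10^7 beads in 100 ul, ~3.6 pL droplets, h = 8.4 um."""
        defaults = dict(
            n_beads=10_000_000,
            aqueous_volume_ul=100.0,
            log_mean_pl=math.log(3.6) - DEFAULT_LOG_SD**2 / 2,
            log_sd_pl=DEFAULT_LOG_SD,
            layer_height_um=8.4,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def fluosurf(cls, **overrides) -> "SimulationParams":
        """HFE-7500/FluoSurf condition: 10^7 beads in 200 ul, ~8.9 pL droplets, h = 7.2 um."""
        defaults = dict(
            n_beads=10_000_000,
            aqueous_volume_ul=200.0,
            log_mean_pl=math.log(8.9) - DEFAULT_LOG_SD**2 / 2,
            log_sd_pl=DEFAULT_LOG_SD,
            layer_height_um=7.2,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def scaled(self, factor: float) -> "SimulationParams":
        """Shrink (or grow) the emulsion by ``factor`` at fixed bead concentration."""
        if not (factor > 0):
            raise ValueError(f"factor must be strictly positive, got {factor!r}")
        n = max(1, int(round(self.n_beads * factor)))
        return dataclasses.replace(self, n_beads=n, aqueous_volume_ul=self.aqueous_volume_ul * factor)

    @property
    def mean_volume_pl(self) -> float:
        """Mean of the droplet volume distribution (pL)."""
        return math.exp(self.log_mean_pl + self.log_sd_pl**2 / 2)

    @property
    def concentration_per_pl(self) -> float:
        return self.n_beads / (self.aqueous_volume_ul * PL_PER_UL)


@dataclass(frozen=True)
class SyntheticEmulsion:
    """A realised emulsion: true droplet volumes and per-droplet bead counts."""

    volumes_pl: np.ndarray
    bead_counts: np.ndarray
    params: SimulationParams

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_pl, dtype=float)
        b = np.asarray(self.bead_counts, dtype=int)
        if v.shape != b.shape or v.ndim != 1:
            raise ValueError("volumes_pl and bead_counts must be equal-length 1-D arrays")
        object.__setattr__(self, "volumes_pl", v)
        object.__setattr__(self, "bead_counts", b)

    @property
    def n_droplets(self) -> int:
        return int(self.volumes_pl.size)

    @property
    def bead_containing(self) -> np.ndarray:
        """Boolean mask of droplets holding at least one bead."""
        return self.bead_counts >= 1


def _draw_volumes(params: SimulationParams, rng: np.random.Generator, size: int) -> np.ndarray:
    if params.log_sd_pl == 0:
        return np.full(size, math.exp(params.log_mean_pl))
    if params.family == "lognormal":
        return rng.lognormal(params.log_mean_pl, params.log_sd_pl, size)
    # gamma, moment-matched to the lognormal's mean and variance
    m = params.mean_volume_pl
    var = m**2 * (math.exp(params.log_sd_pl**2) - 1.0)
    shape = m**2 / var
    scale = var / m
    return rng.gamma(shape, scale, size)


def sample_droplet_volumes(params: SimulationParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw droplet volumes until the aqueous phase is exhausted.

    Volumes are drawn sequentially from the configured distribution; the
    draw that first carries the cumulative volume past the total aqueous
    volume is trimmed so the sum matches exactly (volume conservation by
    construction). The droplet count is therefore emergent.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    target = params.aqueous_volume_ul * PL_PER_UL
    mean_v = params.mean_volume_pl
    if not np.isfinite(mean_v) or mean_v <= 0:
        raise ValueError("volume distribution has non-finite or non-positive mean")
    chunks: list[np.ndarray] = []
    total = 0.0
    est = max(16, int(target / mean_v * 1.1) + 16)
    while total < target:
        draw = _draw_volumes(params, rng, est)
        chunks.append(draw)
        total += float(draw.sum())
        est = max(16, int((target - total) / mean_v * 1.1) + 16)
    v = np.concatenate(chunks)
    cum = np.cumsum(v)
    last = int(np.searchsorted(cum, target))
    v = v[: last + 1].copy()
    v[-1] -= cum[last] - target  # trim the overshoot; remainder is positive
    return v


def sample_cluster_sizes(n_beads: int, p: float, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Partition ``n_beads`` into clusters with shifted-geometric(p) sizes.

    Sizes have support >= 1 and mean 1/p; the last cluster is trimmed so the
    sizes sum to ``n_beads`` exactly. ``p = 1`` yields all-singleton clusters.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p must lie in (0, 1], got {p!r}")
    if not (n_beads > 0):
        raise ValueError(f"n_beads must be strictly positive, got {n_beads!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if p == 1.0:
        return np.ones(n_beads, dtype=int)
    chunks: list[np.ndarray] = []
    total = 0
    est = max(16, int(n_beads * p * 1.1) + 16)
    while total < n_beads:
        draw = rng.geometric(p, est)
        chunks.append(draw)
        total += int(draw.sum())
        est = max(16, int((n_beads - total) * p * 1.1) + 16)
    s = np.concatenate(chunks)
    cum = np.cumsum(s)
    last = int(np.searchsorted(cum, n_beads))
    s = s[: last + 1].copy()
    s[-1] -= int(cum[last]) - n_beads
    return s


def load_beads(
    volumes_pl: np.ndarray,
    cluster_sizes: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Place each cluster into a droplet with probability proportional to volume.

    Returns per-droplet bead counts; total beads are conserved exactly. With
    singleton clusters this is multinomial thinning, whose per-droplet
    marginals approach Poisson(c * V_j) in the many-droplet limit.
    """
    v = np.asarray(volumes_pl, dtype=float)
    s = np.asarray(cluster_sizes, dtype=int)
    if v.ndim != 1 or v.size == 0 or not np.all(v > 0):
        raise ValueError("volumes_pl must be a non-empty 1-D array of positive volumes")
    if s.ndim != 1 or (s.size and not np.all(s >= 1)):
        raise ValueError("cluster_sizes must be a 1-D array of sizes >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = np.zeros(v.size, dtype=int)
    if s.size == 0:
        return counts
    probs = v / v.sum()
    assigned = rng.choice(v.size, size=s.size, p=probs)
    np.add.at(counts, assigned, s)
    return counts


def simulate_emulsion(params: SimulationParams) -> SyntheticEmulsion:
    """Run the full generator: volumes, clusters, volume-proportional loading."""
    rng = np.random.default_rng(params.seed)
    volumes = sample_droplet_volumes(params, rng)
    clusters = sample_cluster_sizes(params.n_beads, params.cluster_p, rng)
    counts = load_beads(volumes, clusters, rng)
    return SyntheticEmulsion(volumes_pl=volumes, bead_counts=counts, params=params)


def render_measurements(
    emulsion: SyntheticEmulsion,
    geometry: ChamberGeometry | None = None,
    only_bead_containing: bool = True,
    subsample_n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Render a microscopy-style measurement table from a synthetic emulsion.

    Volumes are converted to observed in-plane diameters through the slab
    geometry; optionally only bead-containing droplets are kept (as in a
    manual campaign that measures droplets harbouring beads) and a fixed
    number of rows is subsampled without replacement.

    Returns a DataFrame with columns ``droplet_id``, ``diameter_um``,
    ``n_beads``.
    """
    if geometry is None:
        geometry = ChamberGeometry(emulsion.params.layer_height_um)
    mask = emulsion.bead_containing if only_bead_containing else np.ones(emulsion.n_droplets, bool)
    ids = np.flatnonzero(mask)
    if subsample_n is not None:
        if subsample_n > ids.size:
            raise ValueError(
                f"subsample_n={subsample_n} exceeds the {ids.size} available droplets"
            )
        rng = np.random.default_rng(emulsion.params.seed + 1 if seed is None else seed)
        ids = np.sort(rng.choice(ids, size=subsample_n, replace=False))
    diameters = diameters_from_volumes(emulsion.volumes_pl[ids], geometry)
    return pd.DataFrame(
        {
            "droplet_id": ids,
            "diameter_um": diameters,
            "n_beads": emulsion.bead_counts[ids],
        }
    )


def write_emulsion(
    emulsion: SyntheticEmulsion,
    outdir: str | Path,
    measurements: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a simulated run to disk: droplets CSV, measurements CSV, metadata JSON.

    The metadata records every parameter including the seed, so a run is
    fully reproducible from its output directory alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    droplets = pd.DataFrame(
        {
            "droplet_id": np.arange(emulsion.n_droplets),
            "volume_pl": emulsion.volumes_pl,
            "n_beads": emulsion.bead_counts,
        }
    )
    paths = {
        "droplets": outdir / "droplets.csv",
        "measurements": outdir / "measurements.csv",
        "metadata": outdir / "run_metadata.json",
    }
    droplets.to_csv(paths["droplets"], index=False)
    if measurements is None:
        measurements = render_measurements(emulsion)
    measurements.to_csv(paths["measurements"], index=False)
    meta = dataclasses.asdict(emulsion.params)
    meta["n_droplets"] = emulsion.n_droplets
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return paths
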