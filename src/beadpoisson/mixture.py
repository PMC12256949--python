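"""Volume-binned Poisson mixtures: the polydispersity correction.

A single Poisson rate derived from the mean droplet volume ignores that, in a
polydisperse emulsion, large droplets capture beads at a higher rate than
small ones. The correction binned here: divide the full droplet volume
distribution (including empty droplets) into uniform volume bins (default
2 pL), assign each bin the Poisson rate ``mu_i = c * V_i`` implied by the
bead concentration ``c`` and a representative bin volume ``V_i``, and predict
occupancy as the weighted sum ``M(k) = sum_i w_i f(k; mu_i)``.

Two weighting conventions are provided:

- ``"aqueous_volume"`` (default): ``w_i`` is bin i's share of the total
  measured aqueous volume, ``n_i V_i / sum_j n_j V_j``. This describes the
  occupancy of the droplet containing a randomly chosen unit of aqueous
  phase (size-biased).
- ``"droplet_count"``: ``w_i = n_i / sum_j n_j``. This is the fraction of
  droplets per bin and is the exact generative model for per-droplet
  occupancy under volume-proportional bead loading.

Both are exposed because occupancy histograms are per-droplet quantities
while reagent-budget arguments are per-volume quantities; see the methods
note for the distinction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occupancy import BeadDose, poisson_pmf

__all__ = [
    "VolumeBinning",
    "VolumeBinnedMixture",
    "bin_droplet_volumes",
    "build_mixture",
    "mixture_occupancy",
    "truncated_mixture_occupancy",
]


@dataclass(frozen=True)
class VolumeBinning:
    """Uniform-width binning of droplet volumes.

    ``bin_edges`` has length ``n_bins + 1`` and starts at a multiple of the
    bin width; ``representative_volume_pl`` holds one volume per bin (the
    midpoint by default, or the within-bin mean when raw volumes were
    available), guaranteed to lie inside its bin.
    """

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    representative_volume_pl: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.bin_counts)
        rep = np.asarray(self.representative_volume_pl, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1-D array of at least two edges")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin_edges must be strictly increasing with uniform width")
        if counts.shape != (edges.size - 1,) or rep.shape != counts.shape:
            raise ValueError("bin_counts and representative_volume_pl must have one entry per bin")
        if np.any(counts < 0):
            raise ValueError("bin_counts must be non-negative")
        if np.any(rep < edges[:-1]) or np.any(rep > edges[1:]):
            raise ValueError("each representative volume must lie within its bin")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_counts", counts)
        object.__setattr__(self, "representative_volume_pl", rep)

    @property
    def bin_width_pl(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_binned(self) -> float:
        return float(self.bin_counts.sum())


@dataclass(frozen=True)
class VolumeBinnedMixture:
    """Per-bin mixture weights and Poisson rates; weights sum to one."""

    weights: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if w.shape != r.shape or w.ndim != 1 or w.size == 0:
            raise ValueError("weights and rates must be equal-length 1-D arrays")
        if np.any(w < 0) or np.any(r < 0):
            raise ValueError("weights and rates must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "rates", r)

    @property
    def mean_rate(self) -> float:
        """Weight-averaged rate sum_i w_i mu_i (the mixture's mean bead count)."""
        return float(np.sum(self.weights * self.rates))


def bin_droplet_volumes(
    volumes_pl, bin_width_pl: float = 2.0, representative: str = "midpoint"
) -> VolumeBinning:
    """Bin droplet volumes into half-open bins [m*w, (m+1)*w) anchored at 0.

    Empty droplets belong in ``volumes_pl`` too when available — the mixture
    corrects for the *full* volume distribution. Leading and trailing empty
    bins are dropped; interior empty bins are kept with zero weight.
    ``representative='mean'`` uses the within-bin mean volume instead of the
    midpoint (only meaningful when raw volumes are passed, as here).
    """
    v = np.asarray(volumes_pl, dtype=float)
    if v.size == 0:
        raise ValueError("volumes_pl must not be empty")
    if not np.all(v > 0):
        raise ValueError("all droplet volumes must be strictly positive")
    if not (bin_width_pl > 0):
        raise ValueError(f"bin_width_pl must be strictly positive, got {bin_width_pl!r}")
    if representative not in ("midpoint", "mean"):
        raise ValueError(f"representative must be 'midpoint' or 'mean', got {representative!r}")

    idx = np.floor(v / bin_width_pl).astype(int)
    lo, hi = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = np.arange(lo, hi + 2, dtype=float) * bin_width_pl
    mid = edges[:-1] + bin_width_pl / 2.0
    if representative == "mean":
        sums = np.bincount(idx - lo, weights=v, minlength=hi - lo + 1)
        rep = np.where(counts > 0, sums / np.maximum(counts, 1), mid)
    else:
        rep = mid
    return VolumeBinning(bin_edges=edges, bin_counts=counts, representative_volume_pl=rep)


def build_mixture(
    binning: VolumeBinning, dose: BeadDose, weighting: str = "aqueous_volume"
) -> VolumeBinnedMixture:
    """Assemble the Poisson mixture from a volume binning and the bead dose.

    Rates are ``mu_i = c * V_i`` with ``c`` the bulk bead concentration and
    ``V_i`` the representative bin volume; weights follow ``weighting``
    (see module docstring).
    """
    counts = binning.bin_counts.astype(float)
    if counts.sum() <= 0:
        raise ValueError("binning contains no droplets")
    rep = binning.representative_volume_pl
    if weighting == "aqueous_volume":
        share = counts * rep
    elif weighting == "droplet_count":
        share = counts
    else:
        raise ValueError(f"weighting must be 'aqueous_volume' or 'droplet_count', got {weighting!r}")
    weights = share / share.sum()
    rates = dose.concentration_per_pl * rep
    return VolumeBinnedMixture(weights=weights, rates=rates)


def mixture_occupancy(mixture: VolumeBinnedMixture, k):
    """Mixture occupancy M(k) = sum_i w_i f(k; mu_i); sums to 1 over k >= 0."""
    arr = np.atleast_1d(np.asarray(k))
    # pmf for every (component, k) pair
    grid = np.vstack([poisson_pmf(arr, float(mu)) for mu in mixture.rates])
    out = mixture.weights @ grid
    return float(out[0]) if np.isscalar(k) or np.asarray(k).ndim == 0 else out


def truncated_mixture_occupancy(mixture: VolumeBinnedMixture, k):
    """Zero-truncated mixture occupancy M(k) / (1 - M(0)) for k >= 1.

    The truncation is applied to the final weighted sum (not per component),
    matching a measurement protocol that records only bead-bearing droplets.
    """
    arr = np.atleast_1d(np.asarray(k))
    if np.any(_as_int(arr) < 1):
        raise ValueError("truncated mixture occupancy is defined for k >= 1 only")
    m0 = mixture_occupancy(mixture, 0)
    denom = 1.0 - m0
    if denom <= 1e-15:
        raise ValueError("all mixture rates are (numerically) zero: M(0) = 1, truncation undefined")
    out = mixture_occupancy(mixture, arr) / denom
    return float(out[0]) if np.isscalar(k) or np.asarray(k).ndim == 0 else out


def _as_int(arr: np.ndarray) -> np.ndarray:
    if not np.all(arr == np.floor(arr)):
        raise ValueError("k must be integer-valued")
    return arr.astype(int)
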