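"""Poisson occupancy statistics for bead encapsulation in droplets.

When particles are uniformly dispersed in the aqueous phase before
emulsification, the number of particles a droplet of volume ``V`` captures is
Poisson with rate ``mu = c * V``, where ``c`` is the bulk particle
concentration. Because microscopy campaigns typically record only droplets
that contain at least one bead, the observable quantity is the
*zero-truncated* occupancy ``P(k | k >= 1) = f(k; mu) / (1 - f(0; mu))``.

This module provides the pmf, its zero-truncated form, least-squares fitting
of the rate to an observed occupancy histogram (with the sum of squared
errors, SSE, as the fit metric), the concentration-derived expected rate, and
the Avogadro arithmetic for ligand loading per bead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.constants import Avogadro

from .units import PL_PER_UL

__all__ = [
    "BeadDose",
    "OccupancyHistogram",
    "PoissonFitResult",
    "poisson_pmf",
    "truncated_occupancy",
    "sse",
    "fit_occupancy_fractions",
    "fit_truncated_poisson",
    "expected_mu",
    "ligand_density",
]

#: default search bounds for the rate parameter during fitting
MU_BOUNDS: tuple[float, float] = (1e-6, 50.0)


@dataclass(frozen=True)
class BeadDose:
    """Total bead input of an experiment: bead count in a bulk aqueous volume.

    The implied concentration ``n_beads / aqueous_volume_ul`` is what links
    droplet volume to the expected Poisson rate.
    """

    n_beads: float
    aqueous_volume_ul: float

    def __post_init__(self) -> None:
        if not (self.n_beads > 0):
            raise ValueError(f"n_beads must be strictly positive, got {self.n_beads!r}")
        if not (self.aqueous_volume_ul > 0):
            raise ValueError(
                f"aqueous_volume_ul must be strictly positive, got {self.aqueous_volume_ul!r}"
            )

    @property
    def concentration_per_pl(self) -> float:
        """Bead concentration in beads per picolitre."""
        return self.n_beads / (self.aqueous_volume_ul * PL_PER_UL)


@dataclass(frozen=True)
class OccupancyHistogram:
    """Counts of droplets per bead number k.

    ``truncated=True`` (the usual case) means only bead-containing droplets
    (k >= 1) were recorded; a k = 0 entry is then rejected. Counts may be
    non-integer (e.g. averaged across emulsions) but must be non-negative
    with at least one positive entry.
    """

    counts: dict[int, float]
    truncated: bool = True

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("counts must not be empty")
        for k, n in self.counts.items():
            if not (isinstance(k, (int, np.integer)) and k >= 0):
                raise ValueError(f"bead numbers must be non-negative integers, got {k!r}")
            if n < 0:
                raise ValueError(f"count for k={k} must be non-negative, got {n!r}")
        if self.truncated and 0 in self.counts:
            raise ValueError("truncated histogram must not contain a k=0 entry")
        if not any(n > 0 for n in self.counts.values()):
            raise ValueError("at least one count must be positive")

    @classmethod
    def from_bead_counts(cls, bead_counts, truncated: bool = True) -> "OccupancyHistogram":
        """Build a histogram from per-droplet bead counts, dropping k=0 if truncated."""
        ks = np.asarray(bead_counts, dtype=int)
        if truncated:
            ks = ks[ks >= 1]
        if ks.size == 0:
            raise ValueError("no droplets left after truncation")
        vals, cnts = np.unique(ks, return_counts=True)
        return cls({int(k): int(n) for k, n in zip(vals, cnts)}, truncated=truncated)

    @property
    def n_total(self) -> float:
        return float(sum(self.counts.values()))

    def support(self) -> np.ndarray:
        """Contiguous k support: 1..max (truncated) or 0..max (untruncated)."""
        lo = 1 if self.truncated else 0
        return np.arange(lo, max(self.counts) + 1)

    def fractions(self) -> np.ndarray:
        """Observed occupancy fractions on :meth:`support` (zeros where unobserved)."""
        sup = self.support()
        total = self.n_total
        return np.array([self.counts.get(int(k), 0.0) / total for k in sup])


@dataclass(frozen=True)
class PoissonFitResult:
    """Fitted Poisson rate with its SSE, the support used, and boundary diagnostics."""

    mu: float
    sse: float
    support: tuple[int, ...]
    observed: tuple[float, ...]
    truncated: bool = True
    at_lower_bound: bool = False
    method: str = "sse"

    def model_fractions(self) -> np.ndarray:
        """Model occupancy fractions on the stored support at the fitted rate."""
        k = np.asarray(self.support)
        if self.truncated:
            return truncated_occupancy(k, self.mu)
        return poisson_pmf(k, self.mu)


def _validate_k(k) -> np.ndarray:
    arr = np.asarray(k)
    if not np.issubdtype(arr.dtype, np.number) or not np.all(arr == np.floor(arr)) or np.any(arr < 0):
        raise ValueError(f"k must be a non-negative integer (or array thereof), got {k!r}")
    return arr.astype(int)


def poisson_pmf(k, mu: float):
    """Poisson probability of k occurrences at rate mu: exp(-mu) mu^k / k!.

    Evaluated via scipy's log-space implementation; ``mu = 0`` yields the
    point mass at k = 0. Scalar in, scalar out; array in, array out.
    """
    arr = _validate_k(k)
    if not (mu >= 0):
        raise ValueError(f"mu must be non-negative, got {mu!r}")
    out = stats.poisson.pmf(arr, mu)
    return float(out) if np.isscalar(k) or arr.ndim == 0 else out


def truncated_occupancy(k, mu: float):
    """Zero-truncated occupancy P(k | k >= 1) = f(k; mu) / (1 - f(0; mu)).

    Defined only for k >= 1 and mu > 0 (as mu -> 0 the distribution collapses
    to a point mass at k = 1).
    """
    arr = _validate_k(k)
    if np.any(arr < 1):
        raise ValueError("truncated occupancy is defined for k >= 1 only")
    if not (mu > 0):
        raise ValueError(f"mu must be strictly positive for the truncated distribution, got {mu!r}")
    denom = -np.expm1(-mu)  # 1 - exp(-mu), stable for small mu
    out = stats.poisson.pmf(arr, mu) / denom
    return float(out) if np.isscalar(k) or arr.ndim == 0 else out


def sse(observed, model) -> float:
    """Sum of squared errors between observed and model fraction vectors."""
    obs = np.asarray(observed, dtype=float)
    mod = np.asarray(model, dtype=float)
    if obs.shape != mod.shape:
        raise ValueError(f"observed and model must share a support: shapes {obs.shape} vs {mod.shape}")
    return float(np.sum((obs - mod) ** 2))


def fit_occupancy_fractions(
    support,
    fractions,
    bounds: tuple[float, float] = MU_BOUNDS,
    truncated: bool = True,
) -> PoissonFitResult:
    """Least-squares fit of the Poisson rate to occupancy fractions.

    Minimises ``SSE(mu) = sum_k (obs_k - model_k(mu))^2`` over ``mu`` in
    ``bounds`` by deterministic bounded scalar minimisation (no random
    starts), where the model is the zero-truncated occupancy if
    ``truncated`` else the plain pmf. If the minimiser is pinned at the
    lower bound (e.g. all observed mass at k = 1), the result carries
    ``at_lower_bound=True`` and a warning is emitted.
    """
    sup = _validate_k(support)
    obs = np.asarray(fractions, dtype=float)
    if sup.shape != obs.shape or sup.size == 0:
        raise ValueError("support and fractions must be equal-length non-empty vectors")
    if truncated and np.any(sup < 1):
        raise ValueError("truncated fit requires support k >= 1")

    def objective(mu: float) -> float:
        model = truncated_occupancy(sup, mu) if truncated else poisson_pmf(sup, mu)
        return float(np.sum((obs - model) ** 2))

    # The SSE is flat at large mu (all model mass beyond the observed
    # support), so a single bounded search over wide bounds can stall on the
    # plateau. A deterministic coarse scan brackets the global minimum first;
    # bounded Brent then refines inside the bracket.
    grid = np.geomspace(bounds[0], bounds[1], 512)
    pmf_grid = stats.poisson.pmf(sup[:, None], grid[None, :])
    model_grid = pmf_grid / -np.expm1(-grid)[None, :] if truncated else pmf_grid
    i = int(np.argmin(np.sum((obs[:, None] - model_grid) ** 2, axis=0)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9}
    )
    mu_hat = float(res.x)
    at_lb = mu_hat <= bounds[0] + 1e-5
    if at_lb:
        warnings.warn(
            "fitted rate pinned at the lower bound; the truncated Poisson approaches "
            "a point mass at k=1 as mu -> 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return PoissonFitResult(
        mu=mu_hat,
        sse=objective(mu_hat),
        support=tuple(int(k) for k in sup),
        observed=tuple(float(f) for f in obs),
        truncated=truncated,
        at_lower_bound=at_lb,
        method="sse",
    )


def fit_truncated_poisson(
    hist: OccupancyHistogram,
    bounds: tuple[float, float] = MU_BOUNDS,
    method: str = "sse",
) -> PoissonFitResult:
    """Fit the Poisson rate to an occupancy histogram.

    ``method='sse'`` (default) minimises the sum of squared errors between
    observed and model occupancy fractions on the observed support
    (k = 1..max observed, no padding beyond), matching how occupancy data
    are conventionally plotted and scored. ``method='mle'`` instead solves
    the maximum-likelihood equation (for the truncated model,
    ``mu / (1 - exp(-mu)) = sample mean``); the reported SSE is then the SSE
    achieved at the ML estimate.
    """
    sup = hist.support()
    obs = hist.fractions()
    if method == "sse":
        return fit_occupancy_fractions(sup, obs, bounds=bounds, truncated=hist.truncated)
    if method != "mle":
        raise ValueError(f"method must be 'sse' or 'mle', got {method!r}")

    mean_k = float(np.sum(sup * obs))
    at_lb = False
    if hist.truncated:
        if mean_k <= 1.0 + 1e-12:
            mu_hat = bounds[0]
            at_lb = True
            warnings.warn(
                "sample mean <= 1: truncated-Poisson MLE is at the boundary mu -> 0",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            mu_hat = float(
                optimize.brentq(lambda m: m / -np.expm1(-m) - mean_k, 1e-12, max(bounds[1], mean_k * 2))
            )
        model = truncated_occupancy(sup, mu_hat)
    else:
        mu_hat = mean_k
        model = poisson_pmf(sup, mu_hat) if mu_hat > 0 else np.where(sup == 0, 1.0, 0.0)
    return PoissonFitResult(
        mu=mu_hat,
        sse=sse(obs, model),
        support=tuple(int(k) for k in sup),
        observed=tuple(float(f) for f in obs),
        truncated=hist.truncated,
        at_lower_bound=at_lb,
        method="mle",
    )


def expected_mu(dose: BeadDose, mean_droplet_volume_pl: float) -> float:
    """Concentration-derived expected rate: (beads per pL) x mean droplet volume.

    This is the a-priori rate implied by the bead dose and the mean volume of
    the analysed (bead-containing) droplets, as opposed to a rate fitted to
    the occupancy histogram.
    """
    if mean_droplet_volume_pl < 0:
        raise ValueError(
            f"mean_droplet_volume_pl must be non-negative, got {mean_droplet_volume_pl!r}"
        )
    return dose.concentration_per_pl * mean_droplet_volume_pl


def ligand_density(ligand_volume_ul: float, ligand_concentration_um: float, n_beads: float) -> float:
    """Ligand molecules per bead from a coupling reaction assuming lossless binding.

    ``volume (ul) x concentration (uM) x N_A / n_beads``; e.g. 9.2 ul of a
    9 uM peptide over 5x10^7 beads is ~10^6 molecules per bead.
    """
    if not (n_beads > 0):
        raise ValueError(f"n_beads must be strictly positive, got {n_beads!r}")
    if ligand_volume_ul < 0 or ligand_concentration_um < 0:
        raise ValueError("ligand volume and concentration must be non-negative")
    moles = ligand_volume_ul * 1e-6 * ligand_concentration_um * 1e-6
    return moles * Avogadro / n_beads
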