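"""End-to-end analysis of per-droplet measurement tables.

Ties the geometry, occupancy and mixture modules together: read a table of
measured in-plane diameters and bead counts, convert to volumes, build the
zero-truncated occupancy histogram, fit the Poisson rate (reporting SSE),
derive the concentration-expected rate from the mean bead-containing droplet
volume, and — when empty droplets were measured too — predict occupancy from
the volume-binned Poisson mixture. Reports are plain dictionaries/JSON and
deterministic given identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ChamberGeometry, volumes_from_diameters
from .mixture import bin_droplet_volumes, build_mixture, truncated_mixture_occupancy
from .occupancy import (
    BeadDose,
    PoissonFitResult,
    expected_mu,
    fit_occupancy_fractions,
    sse,
    truncated_occupancy,
)

__all__ = [
    "ExperimentConfig",
    "AnalysisReport",
    "BootstrapInterval",
    "read_droplet_table",
    "write_droplet_table",
    "analyze_emulsion",
    "bootstrap_mu",
    "format_report",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("diameter_um", "n_beads")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to analyse one emulsion experiment.

    Defaults reproduce the mineral-oil/Abil EM 90 study condition: 8.4 um
    liquid layer, 10^7 beads in 100 ul aqueous phase, 2 pL volume bins.
    """

    layer_height_um: float = 8.4
    n_beads: float = 10_000_000
    aqueous_volume_ul: float = 100.0
    bin_width_pl: float = 2.0
    truncated: bool = True
    mu_min: float = 1e-6
    mu_max: float = 50.0
    pooling: str = "per_emulsion"  # or "pooled"
    mixture_weighting: str = "aqueous_volume"  # or "droplet_count"

    def __post_init__(self) -> None:
        for name in ("layer_height_um", "n_beads", "aqueous_volume_ul", "bin_width_pl", "mu_min", "mu_max"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if self.mu_max <= self.mu_min:
            raise ValueError("mu_max must exceed mu_min")
        if self.pooling not in ("per_emulsion", "pooled"):
            raise ValueError(f"pooling must be 'per_emulsion' or 'pooled', got {self.pooling!r}")
        if self.mixture_weighting not in ("aqueous_volume", "droplet_count"):
            raise ValueError(f"unknown mixture_weighting {self.mixture_weighting!r}")

    @property
    def geometry(self) -> ChamberGeometry:
        return ChamberGeometry(self.layer_height_um)

    @property
    def dose(self) -> BeadDose:
        return BeadDose(self.n_beads, self.aqueous_volume_ul)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass(frozen=True)
class BootstrapInterval:
    """Percentile bootstrap interval for the fitted rate."""

    mu_hat: float
    lower: float
    upper: float
    n_boot: int
    level: float


@dataclass
class AnalysisReport:
    """Per-experiment summary mirroring how occupancy analyses are reported.

    Observed fractions (and their across-emulsion SD, the usual error bars)
    sit on ``support``; each stored SSE is recomputable from the stored
    vectors.
    """

    n_droplets_total: int
    n_bead_containing: int
    n_empty: int
    n_emulsions: int
    mean_bead_volume_pl: float
    mean_bead_volume_sd_pl: float | None
    support: list[int]
    observed_fractions: list[float]
    observed_fraction_sd: list[float] | None
    mu_hat: float
    fit_sse: float
    fit_at_lower_bound: bool
    expected_mu: float
    expected_fractions: list[float]
    expected_sse: float
    mixture_bin_mid_pl: list[float] | None
    mixture_weights: list[float] | None
    mixture_rates: list[float] | None
    mixture_fractions: list[float] | None
    mixture_sse: float | None
    config: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        """Deterministic JSON serialisation (sorted keys, fixed float repr)."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def read_droplet_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-droplet measurement CSV.

    Requires columns ``diameter_um`` and ``n_beads`` (an ``emulsion_id``
    column is optional). Rejects negative or zero diameters, negative or
    non-integer bead counts, and decimal-comma numbers (a common source of
    thousands-separator ambiguity in exported spreadsheets), naming the
    offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    for col in REQUIRED_COLUMNS:
        if df[col].dtype == object:
            commas = df[col].astype(str).str.contains(",")
            if commas.any():
                rows = df.index[commas].tolist()[:10]
                raise ValueError(
                    f"column {col!r} contains comma-formatted numbers (rows {rows}); "
                    "use a decimal point and no thousands separators"
                )
            df[col] = pd.to_numeric(df[col])
    bad_d = df.index[~(df["diameter_um"] > 0)].tolist()
    if bad_d:
        raise ValueError(f"non-positive diameter_um in rows {bad_d[:10]}")
    n = df["n_beads"].to_numpy()
    bad_k = df.index[(n < 0) | (n != np.floor(n))].tolist()
    if bad_k:
        raise ValueError(f"negative or non-integer n_beads in rows {bad_k[:10]}")
    df["n_beads"] = df["n_beads"].astype(int)
    logger.info("read %d droplet records from %s", len(df), path)
    return df


def write_droplet_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-droplet measurement table to CSV (round-trips with the reader)."""
    df.to_csv(path, index=False)


def _observed_fractions(
    bc: pd.DataFrame, support: np.ndarray, pooling: str
) -> tuple[np.ndarray, np.ndarray | None, int]:
    """Observed truncated occupancy fractions, optionally per emulsion then averaged."""
    groups = (
        [g for _, g in bc.groupby("emulsion_id")] if "emulsion_id" in bc.columns else [bc]
    )
    if pooling == "pooled" or len(groups) == 1:
        counts = np.array([(bc["n_beads"] == k).sum() for k in support], float)
        frac = counts / counts.sum()
        per = None
        if len(groups) > 1:
            per = np.vstack(
                [
                    np.array([(g["n_beads"] == k).mean() for k in support])
                    for g in groups
                ]
            )
        sd = per.std(axis=0, ddof=1) if per is not None else None
        return frac, sd, len(groups)
    per = np.vstack(
        [np.array([(g["n_beads"] == k).mean() for k in support]) for g in groups]
    )
    return per.mean(axis=0), per.std(axis=0, ddof=1), len(groups)


def analyze_emulsion(table: pd.DataFrame, config: ExperimentConfig) -> AnalysisReport:
    """Full occupancy analysis of a measurement table.

    Computes droplet volumes through the slab geometry, the zero-truncated
    occupancy histogram of bead-containing droplets, a least-squares Poisson
    fit (rate + SSE), the concentration-expected rate from the mean
    bead-containing droplet volume, and — if the table includes empty
    droplets — the volume-binned mixture prediction with its SSE against the
    observed fractions. With an ``emulsion_id`` column, observed fractions
    are computed per emulsion and averaged (matching across-replicate error
    bars); ``config.pooling='pooled'`` pools all droplets instead.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing required column(s): [{col!r}]")
    df = table.copy()
    volumes, regimes = volumes_from_diameters(df["diameter_um"].to_numpy(float), config.geometry)
    df["volume_pl"] = volumes
    df["shape_regime"] = regimes

    bc = df[df["n_beads"] >= 1]
    if bc.empty:
        raise ValueError("no bead-containing droplets in the table")
    n_empty = int((df["n_beads"] == 0).sum())
    logger.info(
        "analysing %d droplets (%d bead-containing, %d empty)", len(df), len(bc), n_empty
    )

    support = np.arange(1, int(bc["n_beads"].max()) + 1)
    observed, observed_sd, n_emulsions = _observed_fractions(bc, support, config.pooling)

    fit = fit_occupancy_fractions(
        support, observed, bounds=(config.mu_min, config.mu_max), truncated=config.truncated
    )

    mean_bc_vol = float(bc["volume_pl"].mean())
    if "emulsion_id" in bc.columns and bc["emulsion_id"].nunique() > 1:
        per_means = bc.groupby("emulsion_id")["volume_pl"].mean()
        mean_vol_sd = float(per_means.std(ddof=1))
    else:
        mean_vol_sd = None

    mu_exp = expected_mu(config.dose, mean_bc_vol)
    expected_model = truncated_occupancy(support, mu_exp)
    expected_sse = sse(observed, expected_model)

    mixture_fields: dict = dict(
        mixture_bin_mid_pl=None,
        mixture_weights=None,
        mixture_rates=None,
        mixture_fractions=None,
        mixture_sse=None,
    )
    if n_empty > 0:
        binning = bin_droplet_volumes(df["volume_pl"].to_numpy(), config.bin_width_pl)
        mix = build_mixture(binning, config.dose, weighting=config.mixture_weighting)
        mix_model = truncated_mixture_occupancy(mix, support)
        mixture_fields = dict(
            mixture_bin_mid_pl=binning.representative_volume_pl.tolist(),
            mixture_weights=mix.weights.tolist(),
            mixture_rates=mix.rates.tolist(),
            mixture_fractions=np.asarray(mix_model).tolist(),
            mixture_sse=sse(observed, mix_model),
        )

    return AnalysisReport(
        n_droplets_total=len(df),
        n_bead_containing=len(bc),
        n_empty=n_empty,
        n_emulsions=n_emulsions,
        mean_bead_volume_pl=mean_bc_vol,
        mean_bead_volume_sd_pl=mean_vol_sd,
        support=[int(k) for k in support],
        observed_fractions=[float(f) for f in observed],
        observed_fraction_sd=None if observed_sd is None else [float(s) for s in observed_sd],
        mu_hat=fit.mu,
        fit_sse=fit.sse,
        fit_at_lower_bound=fit.at_lower_bound,
        expected_mu=mu_exp,
        expected_fractions=np.asarray(expected_model).tolist(),
        expected_sse=expected_sse,
        config=dataclasses.asdict(config),
        **mixture_fields,
    )


def bootstrap_mu(
    table: pd.DataFrame,
    config: ExperimentConfig,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapInterval:
    """Nonparametric bootstrap interval for the fitted rate.

    Resamples bead-containing droplets with replacement, refits the
    zero-truncated Poisson to each resample, and returns the percentile
    interval. Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be at least 100, got {n_boot}")
    ks = table.loc[table["n_beads"] >= 1, "n_beads"].to_numpy(int)
    if ks.size < 10:
        raise ValueError(f"need at least 10 bead-containing droplets, got {ks.size}")
    bounds = (config.mu_min, config.mu_max)
    support_full = np.arange(1, ks.max() + 1)
    point = fit_occupancy_fractions(
        support_full, np.bincount(ks, minlength=ks.max() + 1)[1:] / ks.size, bounds=bounds
    )
    rng = np.random.default_rng(seed)
    mus = np.empty(n_boot)
    import warnings as _warnings

    for b in range(n_boot):
        resample = rng.choice(ks, size=ks.size, replace=True)
        kmax = resample.max()
        sup = np.arange(1, kmax + 1)
        frac = np.bincount(resample, minlength=kmax + 1)[1:] / resample.size
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mus[b] = fit_occupancy_fractions(sup, frac, bounds=bounds).mu
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(mus, [alpha, 1.0 - alpha])
    return BootstrapInterval(mu_hat=point.mu, lower=float(lo), upper=float(hi), n_boot=n_boot, level=level)


def format_report(report: AnalysisReport) -> str:
    """Human-readable summary; rates echoed at two significant figures."""
    lines = [
        f"droplets analysed: {report.n_droplets_total} "
        f"({report.n_bead_containing} bead-containing, {report.n_empty} empty, "
        f"{report.n_emulsions} emulsion(s))",
        f"mean bead-containing droplet volume: {report.mean_bead_volume_pl:.3g} pL",
        f"fitted rate mu = {report.mu_hat:.2g} (SSE {report.fit_sse:.2g})",
        f"expected rate mu = {report.expected_mu:.2g} from dose and mean volume "
        f"(SSE {report.expected_sse:.2g})",
    ]
    if report.mixture_sse is not None:
        lines.append(
            f"volume-binned mixture prediction: SSE {report.mixture_sse:.2g} "
            f"({len(report.mixture_weights)} bins)"
        )
    if report.fit_at_lower_bound:
        lines.append("warning: fitted rate pinned at the lower bound (all mass at k=1?)")
    return "\n".join(lines)
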