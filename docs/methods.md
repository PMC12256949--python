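# Methods

## Measurement geometry

Droplets are measured as in-plane diameters `d` (μm) in a chamber whose
liquid layer height `h` (μm) is known. The volume rule is piecewise:
`V = (π/6)d³` for `d ≤ h` (an undeformed sphere) and `V = π(d/2)²h` for
`d > h` (a droplet squeezed to a cylinder of height `h`). Lengths are μm
internally, volumes are pL at every public interface (1 pL = 1000 μm³), and
bulk volumes are μl (1 μl = 10⁶ pL); the two conversion constants live in
one module (`units`).

Three deliberate choices:

- **Tie rule.** `d == h` is assigned to the sphere regime: a droplet exactly
  fitting the gap is undeformed.
- **No smoothing.** The rule is discontinuous at `d = h` (the cylinder
  formula exceeds the sphere formula by exactly 3/2 there). We implement it
  verbatim rather than interpolating with a spherocylinder or spherical-cap
  correction, and return the regime with every volume so boundary cases can
  be audited. No surface-tension or 3-D reconstruction model is attempted.
- **Inversion gap.** Because of the jump, volumes in `((π/6)h³, (π/4)h³]`
  cannot be produced by the forward rule. The inverse (used by the
  simulator's measurement model) clamps them to `d = h`, which keeps
  volume→diameter monotone and total. Consequence: simulated droplets whose
  true volume falls in the gap are reported at the boundary diameter, and
  re-analysis assigns them `(π/6)h³` — an underestimate of at most a factor
  1.5 affecting only the narrow gap (0.31–0.47 pL at h = 8.4 μm, well below
  typical bead-containing droplet volumes). Away from the gap the round trip
  d → V → d is exact to ~1e-15 relative.

Measured diameters of sub-layer droplets are treated as true sphere
diameters (equatorial), not projections.

## Occupancy model and fitting

Bead counts per droplet follow `f(k; μ) = e^(−μ)μᵏ/k!` (evaluated through
scipy's log-space Poisson pmf). Since measurement campaigns record only
bead-bearing droplets, fits use the zero-truncated occupancy
`P(k|k≥1) = f(k;μ)/(1−f(0;μ))`.

- **Objective.** Least squares on occupancy fractions — the quantity
  actually plotted and reported for such experiments — with the SSE as the
  fit metric. A truncated-Poisson maximum-likelihood option exists
  (`method="mle"`, solving `μ/(1−e^(−μ)) = sample mean`) but is off by
  default, as is an untruncated fit (`truncated=False`) for tables that
  include empty droplets.
- **Support.** k = 1 … max observed k, unobserved interior k entering as
  zero fractions; no padding beyond the largest observed count.
- **Optimiser.** The SSE is flat in μ once the model mass has moved past the
  observed support, so a single bounded search over μ ∈ [10⁻⁶, 50] can stall
  on that plateau. The fit therefore scans a fixed 512-point geometric grid
  (vectorised), then refines inside the bracketing interval with bounded
  Brent at xatol = 1e-9. Fully deterministic; verified against a brute-force
  grid oracle in the tests.
- **Degenerate input.** A histogram with all mass at k = 1 drives μ̂ to the
  lower bound (the truncated Poisson tends to a point mass at 1 as μ → 0);
  the result is flagged `at_lower_bound` and a warning is emitted rather
  than failing.
- **Reporting.** Human-readable summaries echo μ and SSE at two significant
  figures; machine-readable output keeps full precision.

The concentration route needs no fitting: `expected_mu` returns
`(n_beads / aqueous_volume) × mean droplet volume`, the rate implied by the
bead dose and the mean volume of the analysed (bead-containing) droplets.
Note this mean is itself size-biased — larger droplets are more likely to
contain a bead — which is one reason the fitted and expected rates differ
on polydisperse emulsions.

## Volume-binned Poisson mixture

Polydispersity makes per-droplet rates heterogeneous. The correction bins
the *full* volume distribution (empty droplets included) into uniform
half-open bins `[m·w, (m+1)·w)` anchored at 0 (default width 2 pL), assigns
each bin the rate `μᵢ = c·Vᵢ` with `Vᵢ` the bin midpoint (or the within-bin
mean when raw volumes are available — midpoint is the default because it is
well-defined given only binned counts), and predicts
`M(k) = Σᵢ wᵢ f(k; μᵢ)`, truncating the *final* sum as `M(k)/(1−M(0))`
(truncation per component would model a different protocol in which empty
droplets of every size class were separately discarded).

Two weightings are implemented, and the distinction matters:

- `aqueous_volume` (default): `wᵢ ∝ nᵢVᵢ`, bin i's share of the total
  measured aqueous volume. This answers "in what occupancy environment does
  a random unit of reagent sit?" — the natural weighting for reagent-budget
  arguments.
- `droplet_count`: `wᵢ ∝ nᵢ`. This is the exact generative model for
  *per-droplet* occupancy fractions under volume-proportional loading, and
  is what an occupancy histogram (one entry per droplet) estimates.

The two disagree on polydisperse emulsions (the volume weighting is
size-biased: `μ f(k;μ) = (k+1) f(k+1;μ)` shifts mass to higher k), and the
simulation-oracle tests hold each to its own empirical counterpart: the
count-weighted mixture matches per-droplet occupancy fractions, the
volume-weighted mixture matches aqueous-volume-weighted occupancy fractions,
both within Monte-Carlo error. Analyses that compare a mixture SSE against a
per-droplet occupancy histogram should use `droplet_count`; the default
remains `aqueous_volume` for continuity with how polydispersity corrections
are usually quoted. Continuous (integral) mixtures over a fitted parametric
volume distribution are out of scope — binned only.

## Synthetic emulsion generator

The generator produces the statistical structure the analysis assumes, not
the fluid dynamics of emulsification (no nozzle shear physics, coalescence,
or time-resolved kinetics):

1. **Volumes.** Lognormal draws (pL) accumulated until the total aqueous
   volume is exactly dispersed; the overshooting draw is trimmed, so the
   droplet count is emergent and volume is conserved by construction —
   mirroring bulk emulsification, where the aqueous phase is fully
   dispersed. A moment-matched gamma family is available as an alternative.
2. **Aggregation.** Beads are partitioned into clusters with
   shifted-geometric sizes (support ≥ 1, mean 1/p, last cluster trimmed for
   exact bead conservation). `cluster_p = 1` means no aggregation. The
   cluster model is synthetic: real aggregate-size distributions are
   unknown, and simulator parameters must not be read as estimates of them.
3. **Loading.** Each cluster lands in droplet j with probability
   `Vⱼ/ΣV`, independently — multinomial thinning, whose per-droplet
   marginals approach Poisson(c·Vⱼ) in the dilute many-droplet limit. Total
   beads are conserved exactly.
4. **Rendering.** Volumes map to observed diameters through the inverse
   geometry; optionally only bead-containing droplets are kept and a fixed
   number subsampled, emulating a manual microscopy campaign.

All randomness flows from a single integer seed through one numpy
`Generator`; run metadata (parameters + seed) is written beside every
simulated dataset.

Default parameters are the two bench conditions the package is organised
around: 10⁷ beads in 100 μl (mean bead-containing droplet volume ≈ 3.6 pL,
layer height 8.4 μm) or in 200 μl (≈ 8.9 pL, 7.2 μm). The lognormal log-sd
defaults to 0.8, a realistic spread for vortexed bulk emulsions (volume CV
≈ 95 %); no measured spread is published for these conditions, so this is a
package choice, made once. Because occupancy statistics depend on the bead
*concentration* and the volume *distribution* but not on the total volume,
tests and examples run volume-scaled-down emulsions
(`SimulationParams.scaled`, typically 10³–10⁴ droplets, ~10⁴ bead-containing
droplets for recovery checks and 10⁵ droplets for mixture oracles) at the
full-scale concentration.

What passing tests show — and don't. The generator reproduces volume
polydispersity, volume-proportional loading, zero-truncated measurement and
cluster-induced overdispersion; it does not reproduce droplet coalescence,
measurement error in diameters, image-segmentation bias, droplets touching
field borders, or non-lognormal volume tails. Parameter recovery on
synthetic data therefore validates the estimators under the stated model,
not the microscopy pipeline that feeds them in a real experiment.

## Pipeline conventions

- Observed occupancy fractions are computed per emulsion and averaged
  (matching across-replicate error bars, reported as the per-emulsion SD);
  a pooled-droplets mode is available (`pooling="pooled"`). Error bars
  across droplets rather than emulsions are deliberately not the default.
- One row per droplet; no area weighting or border corrections.
- Config is a flat YAML file; every report embeds the full config for
  provenance, and report JSON is byte-deterministic given identical inputs
  (sorted keys, full-precision floats).
- The bootstrap (`bootstrap_mu`) resamples bead-containing droplets with
  replacement and returns a percentile interval — a simple uncertainty
  companion to the point fit; no profile-likelihood or Bayesian intervals.
- Input validation rejects non-positive diameters, non-integer bead counts
  and decimal-comma numbers (thousands-separator ambiguity), naming the
  offending rows.

## Known limitations

- The discontinuous geometry rule biases volumes near the regime boundary
  (see inversion gap above).
- The SSE fit weights all occupancy classes equally; rare high-k classes
  contribute little, so μ̂ is driven by the low-k fractions.
- The expected-rate method inherits the size bias of the mean
  bead-containing droplet volume and should be read as a consistency check,
  not an estimator.
- Aggregation is a one-parameter toy model; it produces overdispersion of a
  plausible shape but is not calibrated to any measured cluster-size data.
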