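# Methods

## The estimation problem

NMR chemical shifts of a disordered protein can be converted (e.g. by the
TALOS-N neural network) into a per-residue likelihood that the backbone
dihedral pair (φ, ψ) falls into each of the 324 voxels (20° × 20°) of the
Ramachandran map.  Given a pool of Q candidate conformations — each
contributing one (φ, ψ) pair per residue — the package estimates the
fractional population γ_q of each conformation in solution by fitting the
normalized maps with a finite mixture

p^n(φ, ψ) = Σ_q γ_q p_q^n(φ, ψ),   γ_q ≥ 0, Σ γ_q = 1,

where p_q^n is a probability density on the torus centered at the dihedrals
of conformation q at residue n.  A single population vector is shared by all
residues.

## Torus density

Each mode is a bivariate von Mises density of the sine type,

p(φ, ψ) ∝ exp(κ₁ cos(φ−φ₀) + κ₂ cos(ψ−ψ₀) + λ sin(φ−φ₀) sin(ψ−ψ₀)),

the periodic analogue of a correlated bivariate Gaussian, valid for
λ² < κ₁κ₂.  Internally modes carry (κ₁, κ₂, ρ) with ρ = λ/√(κ₁κ₂), so the
constraint is simply ρ² < 1.  The normalization constant

T = 4π² Σ_m C(2m, m) (λ²/4κ₁κ₂)^m I_m(κ₁) I_m(κ₂)

is evaluated in log space with exponentially scaled Bessel functions; each
term is rewritten with I_m(κ)/κ^m, whose κ→0 limit (1/2)^m/m! makes the
vanishing-concentration case exact.  The series is truncated when the last
term contributes less than 10⁻¹² of the running sum (hard cap 500 terms; at
the fitting bound |ρ| ≤ 0.99 the cap leaves a relative tail of order 10⁻⁴,
well below the fitting noise; at |ρ| ≤ 0.95 the tolerance is reached within
~270 terms).  Derivatives of ln T with respect to κ₁, κ₂ and λ use term-wise
differentiation via d/dκ [I_m(κ)/κ^m] = κ·I_{m+1}(κ)/κ^{m+1}.

For small angular variances the sine model matches a Gaussian with
σ₁² = κ₂/(κ₁κ₂−λ²), σ₂² = κ₁/(κ₁κ₂−λ²), ρ = λ/√(κ₁κ₂), and these maps are
exact mutual inverses; they are used to seed mode shapes from 2×2 dihedral
covariance matrices (e.g. from a torsional elastic-network model).  When no
covariance is available the default basin is isotropic with σ = 20°.

## Likelihood and optimization

The data are probability maps, not angle samples, so the fit maximizes the
voxel-weighted log-likelihood

L = Σ_n Σ_m w^n_m ln p^n(φ_m, ψ_m)

over the 324 voxel centers, with weights w^n_m equal to the normalized map
values.  Up to a model-independent constant this equals minus the summed
discrete Kullback–Leibler divergence between data and model.  The model
density is evaluated at voxel centers (midpoint rule); consistency of that
choice constrains how sharp a fitted mode may be (see bounds below).

Optimization is bounded quasi-Newton (L-BFGS-B) with a fully analytic
gradient:

- populations through a softmax reparameterization (the simplex constraint
  cannot be expressed as box bounds); the population gradient is accumulated
  directly in softmax space through the mixture responsibilities, which are
  bounded even when a population underflows;
- mode centers box-constrained within ± drift_limit (default 15°) of their
  initial, conformation-derived values — the drift limit keeps modes
  anchored to the conformations they represent;
- concentrations κ ∈ [2, 100] and |ρ| ≤ 0.99 by default.  The κ bounds are
  scientific, not cosmetic: with κ allowed near zero a single mode can
  flatten into a uniform torus density and absorb any diffuse background in
  the map, inflating its population arbitrarily; with κ ≫ 100 a mode becomes
  narrower than a voxel and, under the midpoint rule, can spike onto a
  single high-noise voxel.  κ ∈ [2, 100] corresponds to basin widths
  σ between roughly 6° and 41°, bracketing everything plausible for
  Ramachandran basins.

A run is converged when the optimizer reports success with a finite
objective; the iteration cap is 5000 (hard, strongly overlapping mode sets
need ~3000 iterations) and the relative-improvement tolerance is 10⁻⁷ —
overlapping modes create long, flat population ridges that are pointless to
polish beyond that.  The multi-start protocol repeats the fit from
populations drawn flat-Dirichlet with a seeded generator (default 100
starts), discards non-converged runs, and reports mean ± SD of γ over the
rest, renormalized to sum 1.

Residues for which a conformation has no defined dihedrals (termini, missing
atoms) exclude that conformation from the mixture at that residue; the
remaining populations are renormalized there, i.e. the residue informs only
the relative weights of the conformations it can see.  Residues with no map
are skipped.

## Synthetic validation

`synthetic_maps` generates maps with known ground truth: up to 15 modes
drawn uniformly inside three basin rectangles (β: φ ∈ [−180, −45],
ψ ∈ [90, 180]; α_R: φ ∈ [−160, −20], ψ ∈ [−120, 30]; α_L: φ ∈ [20, 100],
ψ ∈ [−20, 90]; basins chosen with probability proportional to area), with a
minimum pairwise circular center separation per scatter class (large ≥ 60°,
medium ≥ 30°, narrow ≥ 10°), basin widths σ uniform in [10°, 20°] per axis,
ρ uniform in [−0.3, 0.3], and flat-Dirichlet populations.  The mixture is
evaluated at voxel centers and the peak rescaled to 15, emulating a
histogram whose top voxel holds about 15 counts.

Noise emulates the counting fluctuations of that histogram: each voxel
receives zero-mean Gaussian noise with SD = noise_level · √(value/peak),
negatives are clipped and the map renormalized.  The scaling is deliberate.
A constant-variance alternative (available as `noise_model="flat"`),
clipped at zero, fabricates probability mass over the entire torus — at
noise level 5 over 80% of the normalized map is fabricated background — and
any background-free mixture model then transfers roughly
bg_fraction · |γ_q − 1/Q| of population between modes, drowning the signal
populations at the higher noise levels regardless of the estimator.
Signal-scaled noise perturbs the populated regions at full strength (SD 10
on a peak of 15 at the highest level) without inventing mass where the
density is zero, which keeps the population-recovery problem well posed at
every noise level while still degrading mode centers and shapes.

The validation experiment (`run_validation`) renders one map per
(template, noise, drift) cell with a cell-specific seed, runs a multi-start
fit initialized at the true mode centers and shapes with random populations,
matches fitted modes to the truth by nearest circular center distance
(Hungarian assignment), and records per parameter family (φ₀, ψ₀, γ, κ₁,
κ₂, ρ) the absolute deviation of the run-averaged estimate from truth and
the across-run SD.

The desk-scale reduced design uses three templates — large scatter with 3
modes, medium with 6, narrow with 10 — noise levels {0, 0.2, 1, 2, 3, 5},
drift limits {1°, 20°} and 25 starts per cell (36 cells, 900 fits, a few
minutes on one CPU).  The full design extends to noise 10 and drift limits
up to 50° with 100 starts.  Mode counts per template are a scaled-down
choice: the narrow class exercises heavy mode overlap without the runtime
of 15 modes.

What passing the synthetic suite does and does not show: the generator
draws data from the same parametric family the fit assumes, so recovery
bounds certify the estimator (likelihood, gradients, constraints,
multi-start protocol), not the adequacy of the sine-model mixture for real
TALOS-N maps, which are smoother, carry prediction bias, and are typically
multi-residue with shared populations.

## Geometric descriptors

For ensemble comparison the package computes, per conformation:

- the local gyration profile P(n): rms deviation of the backbone atoms
  (N, CA, C, O) of residues within ±N_win (default 5) of residue n from
  their centroid; windows are clamped at chain ends.  Profiles are compared
  by Euclidean distance, skipping positions undefined in either profile.
- global radius of gyration (unit masses) and maximum interatomic diameter,
  over all atoms by default (`backbone_only` restricts them);
- minimum cross-set RMSD / profile distances between two ensembles, with
  RMSD minimized over proper rototranslations (Kabsch);
- the resulting ensemble-level Rg from per-conformation radii and
  populations, linear (Σ γ_q Rg_q, default) or rms (√(Σ γ_q Rg_q²)) — the
  two differ by Jensen's inequality and both are exposed because the
  convention is not standardized.

Backbone dihedrals follow the IUPAC sign convention; termini and residues
with missing backbone atoms are undefined (NaN) and propagate as exclusions
rather than errors.

## Numerical and edge-case conventions

- Internal angles are radians; all file formats and user-facing parameters
  are degrees.
- Mixture densities are accumulated in log space; a voxel where the model
  underflows contributes the log-floor −745 and sets a flag rather than
  producing −inf.
- Box extraction thresholds the normalized probability map, groups voxels
  by 4-connectivity without periodic wrap (a basin crossing ±180° yields
  two boxes), and reports bounding rectangles sorted by contained mass.
- All stochastic entry points (multi-start draws, synthetic maps, the CLI)
  take explicit integer seeds; identical seeds give bit-identical outputs.

## Known limitations

- The midpoint-rule likelihood ignores within-voxel curvature; for κ near
  the upper bound the discretization error is visible but bounded by the
  κ ≤ 100 constraint.
- Populations of strongly overlapping modes (narrow scatter) are only
  jointly identified; the multi-start mean then reflects the ridge average,
  and per-mode errors of 0.1–0.3 are expected at high noise.
- The conditional-mixture treatment of missing dihedrals assumes
  missingness is unrelated to conformation identity.
- Series truncation at 500 terms limits partition-function accuracy to
  ~10⁻⁴ relative only in the extreme corner |ρ| > 0.95 with large κ.
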