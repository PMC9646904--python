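# ramamix

Population estimation for intrinsically disordered protein (IDP) ensembles
from Ramachandran probability maps, with local gyration-radius profiles for
comparing conformational ensembles.

## The problem

An IDP in solution is a mixture of many interconverting conformations.
Chemical-shift-based predictors (e.g. TALOS-N) provide, per residue, the
likelihood that the backbone dihedrals (φ, ψ) fall into each of the 324
voxels (20° × 20°) of the Ramachandran map.  Given a pool of Q candidate
conformations — from distance-geometry enumeration, MD, or a database —
this package estimates the fractional population γ_q of each conformation
by fitting the normalized maps with a finite mixture of torus densities:

    p^n(φ, ψ) = Σ_q γ_q p_q^n(φ, ψ),    γ_q ≥ 0,  Σ_q γ_q = 1,

where p_q^n is a bivariate von Mises density of the sine type,

    p(φ, ψ) ∝ exp(κ₁ cos(φ−φ₀) + κ₂ cos(ψ−ψ₀) + λ sin(φ−φ₀) sin(ψ−ψ₀)),

centered at the dihedrals of conformation q at residue n.  Fitting
maximizes the voxel-weighted log-likelihood (equivalently, minimizes the
Kullback–Leibler divergence between map and mixture) by L-BFGS-B with an
analytic gradient, a softmax parameterization of the population simplex, a
configurable drift limit on the mode centers, and a seeded multi-start
protocol that reports mean ± SD of the populations over converged runs.

Ensembles are additionally compared through local gyration profiles
P_q(n) — the rms spread of backbone atoms in a ±5-residue window — plus
R_g, D_max, optimal-superposition RMSD, and population-weighted ensemble
R_g.  See `docs/methods.md` for the model, parameter conventions and
numerical choices.

## Worked example

Simulate a three-mode synthetic map with known populations, then re-fit it:

```sh
ramamix simulate --class large --modes 3 --noise 1.0 --seed 42 --out map.csv
```

`map.csv.truth.json` records the generating truth:

```json
"true_gamma": [0.0818, 0.1907, 0.7275]
```

Fitting the map back (the library call mirrors `ramamix fit` for PDB
ensembles):

```python
import json, numpy as np
from ramamix import FitConfig, fit_multistart, read_rama_table, normalize_grid
from ramamix.synthetic_maps import SyntheticSpec, _truth_model
from ramamix.torus_model import BivariateSineParams

grids = [normalize_grid(g) for g in read_rama_table("map.csv")]
truth = json.load(open("map.csv.truth.json"))
modes = [BivariateSineParams(np.radians(m["phi0_deg"]), np.radians(m["psi0_deg"]),
                             m["kappa1"], m["kappa2"], m["rho"])
         for m in truth["modes"]]
spec = SyntheticSpec(modes=modes, true_gamma=np.array(truth["true_gamma"]))
result = fit_multistart(grids, _truth_model(spec),
                        FitConfig(drift_limit=15.0, n_starts=25, seed=7))
print(np.round(result.mean_gamma, 4), "+/-", np.round(result.sd_gamma, 4))
```

prints

```
[0.0866 0.1713 0.7421] +/- [0.0001 0.0001 0.0001]
```

i.e. at noise level 1 the three populations are recovered within 0.02 of
the generating values, with a negligible spread across the 25 random
population initializations (`result.n_failed == 0`).

For real data the entry point is

```sh
ramamix fit --maps maps.csv --ensemble confs.pdb --drift 15 --starts 100 \
            --seed 1 --out result.json
```

which reads a multi-model PDB ensemble, extracts backbone dihedrals, seeds
mode shapes from an optional covariance table (`--cov`), and writes per-run
and aggregate populations.  `ramamix profile` writes local gyration
profiles, `ramamix boxes` extracts high-likelihood angular boxes, and
`ramamix validate` runs the synthetic recovery experiment.

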