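# andesdiv

Diversification and biogeography analyses for mountain-dwelling clades,
built around the question of whether mountain uplift drives speciation.
The motivating system is the Andean orchid flora — mega-diverse epiphyte
radiations whose speciation appears to track the rise of the Northern
Andes — but every component is generic: it takes a dated phylogeny
(Newick), tip geographic-range states, per-species speciation rates,
occurrence records, and a palaeo-elevation history, all as plain-text
files.

The package implements four analyses on a shared chronogram data model,
plus seeded synthetic-data generators that make every stage testable
without any external download:

1. **Palaeo-elevation-dependent birth–death models** (`andesdiv.envbd`).
   Speciation and extinction rates follow a smoothed elevation curve
   E(t): λ(t) = λ₀·exp(α·E(t)), μ(t) = μ₀·exp(β·E(t)), with α in km⁻¹
   and a known tip sampling fraction f. The reconstructed-tree
   likelihood integrates the extinction probability
   dE/dt = μ − (λ+μ)E + λE² along the tree; ML fits are compared by
   AIC/AICc against constant-rate and time-exponential variants.
2. **Two-region GeoSSE** (`andesdiv.geosse`). Lineages occupy a focal
   region A, the complement B, or both (AB), with region speciation
   sA/sB, between-region speciation sAB, extirpation xA/xB, and range
   expansion dA/dB. Includes constrained ML fits (e.g. sA=sB), the
   free-vs-constrained ΔAIC statistic with a **reshuffled-states
   permutation null** (add-one p-value), and an adaptive MCMC reporting
   posterior summaries such as P(sA > sB).
3. **Speciation-rate mapping** (`andesdiv.ratemap`). Tip rates are
   joined to occurrences, records are thinned to one per 0.5° grid
   cell to blunt collection bias, and the rated points are interpolated
   by inverse distance weighting (haversine distances, p=2, k=12) onto
   a masked raster, with bootstrap regional summaries.
4. **Ancestral elevation and richness profiles**
   (`andesdiv.elevtraits`). Species mean elevations as a continuous
   character under Brownian motion (REML σ², two-pass pruning for node
   expectations and variances), the 1100 m montane/lowland
   classification, and richness-by-elevation profiles.

## Worked example

Simulate a clade whose speciation tracks a 4000 m logistic uplift
(inflection 6 Ma), fit the environment-dependent and constant models,
then run the GeoSSE asymmetry test on a second, region-labelled tree:

```python
import numpy as np
from andesdiv import envbd, geosse, simulate
from andesdiv.fitting import compare_models

spec = simulate.UpliftCurveSpec()          # 4000 m plateau, inflection 6 Ma
uplift = simulate.make_uplift_curve(spec, t_max=12, n=121)
env = envbd.build_env_function(uplift, smoothing=0.0)

gen = envbd.EnvBDParams(0.2, 0.5, 0.05, 0.0, 1.0, "env", "constant")
lam, mu = envbd.rate_functions(gen, env)
tree = simulate.simulate_bd_tree(lam, mu, crown_age=9.0, f=0.02, seed=7)

fit_env = envbd.fit_envbd(tree, env, lambda_form="env", f=0.02, seed=0)
fit_const = envbd.fit_envbd(tree, env, lambda_form="constant", f=0.02, seed=0)
print(compare_models([fit_env, fit_const]).to_string(index=False))

p = geosse.GeoSSEParams(sA=0.3, sB=0.15, sAB=0.1,
                        xA=0.05, xB=0.05, dA=0.05, dB=0.05)
gtree, ranges = simulate.simulate_geosse(p, root_state="AB", n_tips=120, seed=7)
null = geosse.permutation_null(gtree, ranges, constraints=("sA=sB",),
                               n_perm=99, seed=0)
free = geosse.fit_geosse(gtree, ranges, seed=0)
```

This prints (seed 7; a 141-tip tree):

```
                           model  k        logL        AIC       AICc     dAIC   weight  converged
     bd(lambda~env, mu~constant)  3 -247.096876 500.193753 500.368935 0.000000 0.918994       True
bd(lambda~constant, mu~constant)  2 -250.525637 505.051274 505.138231 4.857521 0.081006       True
```

so the elevation-dependent model is preferred by ΔAIC ≈ 4.9 (Akaike
weight 0.92): speciation on this tree rises with palaeo-elevation. The
fitted sensitivity is α̂ = 0.25 km⁻¹ (95% CI −0.07 to 0.57 — a single
~140-tip tree constrains α only loosely; the simulation studies below
quantify this), giving a present-day speciation rate λ(0) ≈ 1.9 Myr⁻¹
at the 4000 m plateau. The GeoSSE stage estimates ŝA = 0.29 vs
ŝB = 0.17 Myr⁻¹ (truth 0.30/0.15) with observed ΔAIC = 2.2 against the
sA=sB model and permutation p = 0.18 on this realization.

The same pipeline is scriptable from the shell:

```bash
andesdiv demo --seed 1 --outdir demo_out        # all stages + manifest
andesdiv simulate-geosse --rates 0.3,0.15,0.1,0.05,0.05,0.05,0.05 \
    --n-tips 120 --seed 7 --out-tree t.nwk --out-ranges r.csv
andesdiv geosse-null --tree t.nwk --ranges r.csv --n-perm 99 --seed 0 \
    --out null.csv
```

`andesdiv demo` writes every intermediate table plus `manifest.json`
with per-stage seeds and SHA-256 checksums; the same seed reproduces
every output byte for byte.

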