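# pricklemap

Spatial patterning of prickles on plant stems: measurement geometry,
an inhibitor-field model, and pattern fitting.

Prickles — the sharp epidermal outgrowths on rose and acacia stems — are
positioned non-randomly relative to the leaves. On *Rosa hybrida*
'Red Queen' shoots they concentrate around φ ≈ 90–135° away from the
leaf-connecting spiral at every height; species such as *Acacia seyal*
instead carry a prickle pair flanking each leaf base (h ≈ 0.95,
φ = ±60°). `pricklemap` is for developmental biologists and quantitative
botanists who measure organ positions on stems and want to (a) express
them in leaf-relative coordinates and (b) test whether an inhibitory
field emanating from leaf primordia explains the prickle pattern.

## The model

Leaf primordia appear around the shoot apex every plastochron *T* at
divergence Φ (golden angle by default) and secrete a diffusible inhibitor
of prickle initiation. The inhibitor from one primordium reaching the
circular priming zone follows an unnormalised von Mises profile, and only
the three primordia nearest in time contribute:

    f(φ, t) = k(t−T) e^{m(t−T) cos(φ−Φ)} + k(t) e^{m(t) cos φ}
            + k(t+T) e^{m(t+T) cos(φ+Φ)}

where k(t) is a piecewise-linear secretion schedule (zero outside
(T_a, T_c), peaking at 1 at T_b) and m(t) = max(αt + β, 0) is the von
Mises concentration, growing as the primordium recedes at velocity α.
Prickle density is proportional to f⁻¹, sampled on a 100 × 100 (φ, t)
lattice. The five free parameters (α, β, T_a, T_b, T_c) are estimated by
maximising the Pearson correlation between the model grid and a 2-D
Gaussian KDE of the observed (φ, h) points, using seeded multistart BFGS
under a smooth constraint-preserving reparameterisation. See
`docs/methods.md` for assumptions, reference frames and numerical details.

## Worked example

Fit the model to the built-in *A. seyal* pair pattern:

```python
from pricklemap import (PricklePatternModel, FitConfig, aseyal_pair_fixture,
                        RED_QUEEN_PARAMS, model_density_grid)

model = PricklePatternModel(aseyal_pair_fixture(),
                            config=FitConfig(n_starts=100, seed=0))
res = model.fit()
print(res.summary())

grid = model_density_grid(RED_QUEEN_PARAMS)
print(f"dispersed-pattern density peaks at phi = {grid.argmax_phi_deg():.1f} deg")
```

prints

```
Inhibitor-field prickle pattern fit
===================================================
No. observations:                    2
Multistart count:                  100
Converged starts:                  100
Distinct optima:                    94
Pearson correlation:            0.9794
---------------------------------------------------
param         estimate   constraint
alpha           0.1360   > 0
beta           -0.0841   (free)
T_a            -0.0105   >= -T, < T_b
T_b             0.0029   in (T_a, T_c)
T_c             1.7800   in (0, 2T]
===================================================
T = 1 (plastochron), Phi = 137.51 deg

dispersed-pattern density peaks at phi = 97.2 deg
```

The correlation of 0.979 says the fitted reciprocal-intensity surface
ranks density across the (φ, h) plane almost exactly as the smoothed
two-point pattern does (the KDE's h-axis bandwidth comes from the
documented degenerate-axis fallback, since both points share one h). The
small α and near-zero T_a/T_b say this pattern needs a weak, early-peaking
field — quite different from the dispersed-pattern reference set
`RED_QUEEN_PARAMS`, whose density peaks at φ = 97.2°, inside the measured
90–135° band. `res.plot_comparison()` draws the observed and fitted
densities side by side, and `res.basins` lists the distinct optima.

## Command line

```sh
pricklemap synth config.yaml stems.csv          # synthetic measurement CSV
pricklemap measure stems.csv prickles.csv       # (θ, H) -> (φ, h) + d_pp
pricklemap fit prickles.csv --output fit.json --starts 100 --seed 1
pricklemap simulate params.json grid.csv        # model density grid
pricklemap report prickles.csv --params params.json --output compare.png
```

Measurement CSVs have one row per organ (`stem_id, kind, theta_deg, H_mm,
prickle_height_mm`); prickles under 5 mm are filtered as immature.

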