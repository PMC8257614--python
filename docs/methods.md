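# Methods

## The problem

Prickles on rose-like stems are not scattered at random: on *Rosa hybrida*
'Red Queen' shoots they cluster at a characteristic angle of roughly
90–135° away from the leaf-connecting spiral at every height, while species
such as *Acacia seyal* and *Rosa hirtula* instead carry a pair of prickles
flanking each leaf base. `pricklemap` implements the measurement geometry
that makes such patterns visible, a mechanistic inhibitor-field model that
can generate both patterns, and the estimation machinery that fits the
model to an observed pattern.

## Measurement geometry

Raw data are per-organ pairs (θ, H): the angle around the stem in degrees
(θ = 0 toward the parent shoot) and the height along the shoot in mm, for
every leaf and every mature prickle (≥ 5 mm; shorter prickles are still
elongating and are dropped on input with a logged count).

1. **Chirality.** Spirals come in both hands. If the mean leaf-to-leaf
   divergence of the minimally unwrapped angles is ≥ 180°, all angles are
   reflected (θ → 360 − θ) so every stem is analysed right-handed. The
   operation is idempotent; a record carries a `mirrored` flag.
2. **Unwrapping.** Leaf angles become cumulative angles θc = θ + 360N with
   the smallest non-negative N making the sequence strictly increasing
   (ties broken by incrementing N). A float-edge guard enforces strictness
   when a candidate lands exactly on its predecessor.
3. **Phyllotaxis spline.** A natural cubic interpolating spline θ̂_sp(H)
   passes exactly through the (H, θc) leaf knots (a straight line for two
   leaves). Interpolation rather than smoothing: the reference curve must
   pass through the leaves by construction.
4. **Relative coordinates.** Each prickle gets φ = (θ + 360N) − θ̂_sp(H)
   with N chosen uniquely so φ ∈ [−90°, 270°), and h = (H − H_low)/(H_up −
   H_low) within its internode. A prickle exactly at a node belongs to the
   internode above (h = 0); at the topmost node, where none exists, it is
   reported as h = 1 of the top internode. Prickles outside the leaf span
   are excluded with a warning — the (φ, h) plane is only defined between
   nodes.
5. **Spacing.** d_pp is each prickle's nearest-neighbour distance on the
   stem cylinder, √(ΔH² + (r·Δθ_wrapped)²) with a user-supplied radius
   (default 5 mm). How such distances are best measured on a physical stem
   (surface vs chord) is not settled; the cylinder-surface choice is a
   documented assumption of this package.

## The inhibitor-field model

Leaf primordia appear around the shoot apical meristem every plastochron T
(set to 1) at a fixed divergence Φ (default: golden angle, ≈ 137.5°), and
are carried away from the apex by growth. Each secretes a diffusible
inhibitor of prickle initiation. At diffusive equilibrium the inhibitor
reaching the circular priming zone from one primordium follows an
unnormalised von Mises profile, giving the per-primordium intensity

    f_i(φ, t) = k(t) · exp(m(t) · cos(φ − φ_i))

with two ingredients:

* **Secretion schedule** k(t): piecewise linear, zero outside (T_a, T_c),
  rising to a peak of 1 at T_b. Constraints T_a < T_b < T_c, −T ≤ T_a,
  0 < T_c ≤ 2T mean only the three primordia nearest in time (n−1, n, n+1)
  ever reach the priming circle, so the total field is the three-term sum
  f(φ, t) = k(t−T)e^{m(t−T)cos(φ−Φ)} + k(t)e^{m(t)cos φ} +
  k(t+T)e^{m(t+T)cos(φ+Φ)}.
* **Concentration** m(t) = max(αt + β, 0): the angular footprint sharpens
  linearly as the source recedes at velocity α > 0; β is the offset at
  t = 0. The von Mises normalising constant is deliberately omitted — the
  Pearson cost below is scale-invariant, so it could not change a fit.

Prickle density is proportional to 1/f, sampled on an N_d × N_d lattice
(default 100) with φ_i = 2πi/N_d and t_j = jT/N_d; t is identified with the
relative height h (t = 0 at the lower node). Entries are floored at
f ≥ ε = 1e−12 before the reciprocal so the grid stays finite even where all
secretion windows are closed; ε is far below any attainable intensity, so
occupied regions are unaffected.

**Reference frame.** The data's φ is measured from the leaf-connecting
spline, which rotates by Φ across each internode, whereas the model's
natural origin is the fixed direction of the n-th primordium. The package
therefore evaluates the field at φ + Φ·t/T by default (`corotating_frame`),
placing model and data in the same spline-relative frame. This choice is
what makes the model's density peak sit at a height-independent φ ≈ 90–105°
for the dispersed-pattern reference parameters, matching the measured
pattern; in the fixed-primordium frame (available via
`corotating_frame=False`) the peak would drift by ≈ Φ per internode.

Two published reference parameter sets ship as constants:
`RED_QUEEN_PARAMS` (α = 0.267, β = 0.139, T_a = −0.909, T_b = 0.071,
T_c = 1.661; dispersed single-peak pattern) and `PAIRED_PATTERN_PARAMS`
(α = 0.044, β = 0.102, T_a = 0.109, T_b = 1.419, T_c = 1.925; leaf-flanking
pair pattern). Their α ratio is 6.068, i.e. 6.06 after truncation to three
significant figures — the form in which the ratio is usually quoted; the β
ratio is 1.363 (sometimes quoted as 1.35). Both roundings are preserved
here as documented discrepancies rather than silently reconciled.

## Density estimation and fitting

**KDE.** The observed (φ, h) points are smoothed with an axis-aligned
product-Gaussian kernel evaluated on the same lattice as the model. Each
axis uses the normal-reference bandwidth 1.06·min(sd, IQR/1.34)·n^(−1/5).
When that rule degenerates (n < 2, or zero spread — e.g. the two-point pair
fixture shares one h value) the axis falls back to 0.25 × the axis range
(2π for φ, T for h), with a loud warning: the fallback is a pragmatic
choice, not a statistical optimum, and fits of near-degenerate patterns
should be read with that in mind. The estimate is planar (non-periodic in
φ) by default, matching a plain 2-D KDE; `periodic_phi=True` replicates
points at φ ± 360° for a circular-correct estimate.

**Cost.** Negative Pearson correlation between the flattened model and KDE
grids. Correlation is invariant to positive affine rescaling of either
grid, so neither the KDE's truncation losses at the rectangle edge nor the
model's arbitrary intensity scale bias the fit.

**Optimisation.** BFGS (scipy) from many random feasible starts. The
constraint set is enforced by a smooth bijection: α = e^a, T_c = 2T·σ(u₃),
T_a = −T + (T_c + T)·σ(u₁), T_b = T_a + (T_c − T_a)·σ(u₂) with σ the
logistic function; β is free. Every iterate is feasible, no penalty tuning
is needed, and feasible parameter sets map losslessly into the raw space.
Starts draw α ∈ (0, 1], β ∈ [−1, 1] and an ordered triple uniform over
[−T, 2T] (re-drawn until T_c > 0), from a seeded generator — identical
seed and configuration give a bit-identical result. Converged optima are
clustered into distinct basins (> 1e−2 difference in any coordinate); the
cost surface has flat directions (e.g. window edges outside the observable
t ∈ [0, 1)), so many "distinct" optima with equal correlation are normal.
The default budget is 10⁴ starts; the test suite and the bundled
reproduction script use 100–200 starts, which reach the same optimum for
these small problems in well under a minute on one CPU. Exponents m·cos φ
are clamped at 700 before exponentiation so extreme line-search iterates
cannot overflow; the clamp is unreachable for printed-scale parameters.

## Synthetic data

The generator emulates the structure the analysis assumes, so every stage
is testable without measured stems:

* leaves with divergence ~ Normal(137.5°, 10°), replaced with probability
  0.05 by a uniform draw in (270°, 330°) — occasional extreme internodes of
  the kind real shoots show (with the mixture on, the expected mean
  divergence is 145.6°, not 137.5°);
* internode lengths ~ Normal(30 mm, 8 mm) truncated above 1 mm — a
  plausible scale for a flowering lateral shoot, where neither a canonical
  value nor a deposited dataset exists;
* about 3 prickles per internode (Poisson), positions drawn from the model
  density grid by cell-level inverse CDF (multinomial over cells, uniform
  jitter within the cell) and mapped to (θ, H) through the stem's own
  spline — exactly inverting the measurement transform, so a noise-free
  stem round-trips through the geometry pipeline to float precision;
* a 5 mm hard core: candidates closer than the minimum spacing to an
  accepted prickle are re-drawn up to 100 times, then dropped with a
  warning. Real close pairs are rare; the hard core lives only in the
  generator, not in the field model.

What the generator does **not** emulate: measurement error in θ and H,
autocorrelated divergence noise along the stem, stem taper (a single radius
is used for all heights), and any leafstalk-derived local exclusion around
φ = 0, h ≈ 1. Passing tests therefore demonstrate internal consistency of
the pipeline and identifiability of the model under its own assumptions,
not field-measurement robustness.

Two fixtures are built in: `aseyal_pair_fixture()` — the literature-derived
pair pattern, two points at h = 0.95, φ = ±60° (also shipped as
`data/aseyal_pair.csv`) — and `redqueen_fixture(seed, n)`, a reproducible
sample from the dispersed-pattern reference density standing in for
unreleased multi-stem measurements.

## Numerical choices and limitations

* Degenerate secretion limbs (T_b → T_a or T_c → T_b under saturated
  reparameterisation) are treated as empty rather than dividing by zero.
* A two-point pattern with co-located h values exercises the bandwidth
  fallback; the resulting correlation depends materially on that fallback.
  Fitting such patterns is supported, but the achieved correlation should
  be compared across bandwidth choices before being interpreted.
* The model is deterministic and equilibrium-based: no transient diffusion,
  no prickle–prickle inhibition, no growth mechanics.
* No uncertainty quantification on fitted parameters (no bootstrap or
  profile intervals); the multistart basin list is the only spread
  diagnostic reported.
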