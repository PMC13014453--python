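# Methods

## Scope and model

`hbpmf` quantifies how much a bound molecular glue strengthens individual
protein–protein hydrogen bonds, and aggregates per-bond rupture free
energies into a complex-level stability score.  The analysis layer (rupture
rule, Jarzynski estimation, bootstrap errors, significance and independence
screening, ΣPMF tables) is exact and data-source-agnostic: it consumes work
traces from any constant-velocity pulling protocol.  The data layer is a toy
simulator: all-atom steered MD of real complexes is far beyond desk scale,
so the package generates work traces from a one-dimensional surrogate whose
statistical structure matches what the analysis assumes.  Everything
quantitative about real systems enters only through the shipped reference
tables of published per-interaction values.

## Pulling protocol

A replicate is simulated in three stages, mirroring standard steered-MD
practice:

1. **Hold** (default 0.1 ns): the coordinate relaxes inside a flat-bottom
   window (2.5–3.5 Å, 60 kcal/mol·Å²) with no pulling spring.
2. **Approach** (default 0.05 ns): the harmonic spring (500 kcal/mol·Å²)
   switches on and its centre moves linearly to `pull_start` = 2.5 Å,
   bringing donor and acceptor to close proximity.
3. **Ramp**: the centre λ(t) moves from 2.5 to 5.0 Å at 0.5 Å/ns.  External
   work accumulates per step as k·(λ−x)·Δλ, with W = 0 at ramp start.

The hold and approach durations are configurable desk-scale stand-ins for
the much longer equilibration used with explicit-solvent systems; only the
ramp-stage work enters the analysis.  Temperature is 298 K
(k_B = 0.0019872041 kcal/mol/K).  When the steered coordinate is a
centre-of-mass distance over a symmetric group, the pulling window is
shifted outward by 0.5 Å (`com_adjustment`); the outward direction is chosen
so that the full rupture event is still spanned.

## Toy bond model

The coordinate x (donor–acceptor separation, Å) follows overdamped
Euler–Maruyama dynamics, dx = −V′(x)/γ dt + √(2 k_BT dt/γ) ξ.  Overdamped
rather than inertial dynamics: rupture-work statistics only require
configurational sampling, and this avoids mass and thermostat parameters the
surrogate cannot meaningfully constrain.  The stability contract
k_spring·dt/γ < 1 is enforced; integration aborts with advice to reduce the
timestep if the coordinate diverges.

The bond is a Morse well V(x) = D_eff (1 − e^{−a(x−r_eq)})² with
D_eff = D·(1 + shielding).  The `shielding` knob (0 = binary complex,
default 0.6 = ternary) emulates glue-induced hydrophobic shielding as a
deepened well.  Beyond the outer wall (r_eq + 2/a) a smooth outward force of
magnitude `release_frac`·D switches on, emulating post-rupture relaxation of
the freed interface; without it the viscous drag of the tracking spring
makes the work profile creep upward forever and the rupture maximum loses
its meaning.  The release force scales with the bare depth D, not D_eff —
the glue shields the intact bond, not the separated fragments — which keeps
the rupture free energy strictly increasing in `shielding`.  A zero-depth
potential therefore has no release force and behaves as a free particle.

Defaults, chosen once so the toy reproduces the qualitative features of
measured work profiles (a dip near equilibrium followed by a rupture
maximum, unshielded rupture free energies of roughly 2 kcal/mol with
bootstrap sds of 0.1–0.3, and clean binary/ternary separation at N = 25):

| parameter | default | units | role |
|---|---|---|---|
| D (`well_depth`) | 3.5 | kcal/mol | unshielded bond strength |
| a (`width`) | 2.0 | 1/Å | inverse well width |
| r_eq | 2.7 | Å | equilibrium separation |
| shielding | 0 / 0.6 | — | binary / ternary deepening |
| γ (`friction`) | 800 | kcal/mol·ps/Å² | overdamped friction |
| `release_frac` | 0.5 | 1/Å | post-rupture relaxation force per unit D |
| dt | 0.05 | ps | Euler–Maruyama step |

With r_eq = 2.7 Å and a = 2/Å the compression strain at the 2.5 Å ramp
start (≈ 0.68 D) stays below the outward barrier, so rupture works are
positive; a wider or farther well would let the released compression energy
swamp the climb.  All parameters live in the run configuration, not in code.

Noise is pre-generated from `numpy.random.default_rng` streams (seeded per
replicate) and consumed by a numba-compiled integrator, so identical inputs
give bit-identical traces.  Traces are recorded at ≤ 750 samples per ramp;
work is accumulated every step.

### What the toy does and does not emulate

It reproduces: N = 25 replicates per interaction; work profiles with a
minimum near equilibrium and a rupture maximum; condition-dependent well
depth; dissipation that vanishes in the slow-pulling limit; and optional
cross-interaction correlation of rupture distances.  It does not contain
explicit solvent, three-dimensional geometry, force-field realism, or any
mapping from a real complex's chemistry to toy parameters.  Tests passing on
the toy therefore validate the *analysis machinery* (estimators, screens,
aggregation) and the simulator's own statistical contracts — they say
nothing about any particular protein system.  Published per-system values
are validated only through the fixture-driven aggregation checks.

### Correlated bond pairs

The correlation screen needs pairs of interactions whose ruptures are
correlated to a controllable degree.  Mechanism (shared latent noise
fraction): for a target correlation ρ, `round(|ρ|·n)` of the n replicate
pairs share their entire Brownian forcing; the rest are independent.
Identically parameterised bonds driven by the same forcing rupture at
exactly the same separation, so the population Pearson correlation of
rupture distances equals the shared fraction and the sample correlation at
n = 25 concentrates within ±0.15 of ρ.  A continuous per-step noise mixture
was tried first and rejected: the rupture event is a chaotic functional of
the path, which attenuates mixed-noise correlations unpredictably.  Negative
ρ uses antithetic shared forcing and only weakly anticorrelates; the
magnitude contract is stated for ρ ≥ 0.

## Estimation

* **Rupture work**: the maximum of W(t) at or after the *global* minimum of
  the ramp-stage profile.  The global (not first local) minimum is used for
  robustness to early noise; the alternative reading is a one-line change at
  the call site since the rule is a pure function of the trace.
* **Jarzynski estimate**: −k_BT·logsumexp(−W/k_BT, mean), exact and
  overflow-safe.  Jensen's inequality (estimate ≤ mean work) is asserted on
  every estimate the pipeline produces.
* **Bootstrap (B = 50)**: resampling units are whole replicates — for
  scalar estimates the replicate rupture works, for profiles whole replicate
  columns — preserving within-trace correlation along the coordinate.
  Whether the original analysis resampled raw values or replicates is not
  deducible from its description ("bootstrapping 50 times at each distance
  point"); replicate-level resampling is the defensible choice.
* **Profiles**: the estimator applied per distance-grid point across
  replicates; traces with differing schedules are linearly interpolated onto
  the first trace's grid.
* Temperature always comes from the protocol, never from data.  Reported
  values are rounded half-away-from-zero to one decimal at the rendering
  layer only.

## Screening and aggregation

* **Significance**: two-sided Mann–Whitney U on the binary vs ternary
  rupture-work samples; exact null for ≤ 8 per side without ties,
  tie-corrected normal approximation otherwise; significant ⇔ p ≤ 0.05.  The
  U convention is the first sample's statistic.  No multiple-testing
  correction is applied, matching the original screening rule.
* **Independence**: Pearson correlation of rupture-distance vectors for all
  interaction pairs on matched replicates.  For each pair with |r| > 0.5,
  exactly one member is dropped — the smaller |ΔPMF| (tie: lexicographically
  later id) — cascading from the largest |r| until no retained pair exceeds
  the threshold.  Which member the original analysis dropped is not stated;
  retaining the larger effect is the conservative choice for the total, and
  the rule is a parameter of `correlation_screen`.
* **Totals**: ΣPMF per condition sums the retained rows; uncertainties
  combine in quadrature, as do the ΔΣPMF uncertainties from the two footer
  sds.  Quadrature is justified empirically: applied to the published
  per-interaction values it reproduces all nine published footer
  uncertainties and every parenthesised per-row delta after one-decimal
  rounding.

## Solvent RDF

g(r) around pooled interaction-site centres, 0–10 Å in 0.1 Å bins; exact
spherical-shell volumes (4π/3)(r_o³−r_i³); minimum-image distances when a
periodic box is given; bulk density explicit or (with a box) automatic from
the mean solvent count.  Pooled-centre averaging is used (per-centre
averaging would only differ for heterogeneous centre sets).  The shielding
diagnostic integrates g_binary − g_ternary over a window with trapezoids,
interpolating at the window edges so the integral covers exactly [r_lo,
r_hi]; positive values mean the glue dries the interface.

## Numerical choices and degenerate inputs

* Coordination-count terms are evaluated as 1/(1+(r/r₀)⁶), algebraically
  identical to the 6-12 rational form wherever the latter is defined and
  equal to its limit 1/2 at r = r₀.  r₀ has no default — no published value
  exists for the phosphate coordination count — and must be configured.
* All-tied Mann–Whitney samples give p = 1; zero-variance rupture-distance
  vectors make the pair's correlation undefined and the pair is skipped with
  a warning; an aggregation with zero retained rows renders an explicit
  notice instead of a zero footer.
* Missing values in trace files are rejected, not imputed; file validation
  reports the offending line.
* The quasi-static oracle `reversible_free_energy` computes
  G(λ) = −k_BT ln ∫ e^{−(V+k/2(x−λ)²)/k_BT} dx by trapezoidal quadrature on
  a dense grid; for a harmonic well it agrees with the closed form
  κk/(κ+k)·Δλ²/2 to better than 0.1 %.

## Problem sizes

Default study conditions are used throughout: 25 replicates, 50 bootstrap
resamples, 2.5 Å ramp at 0.5 Å/ns.  Monte-Carlo checks use 2 000 null
repeats for the Mann–Whitney type-I rate and 100 seed batches per operating
point of the correlation screen; the quasi-static ladder uses 8 replicates
at 1×, 0.1× and 0.01× the standard pulling rate; the ideal-gas RDF check
uses 10⁴ solvent points × 20 frames.

## Known limitations

* The toy's parameter scale is phenomenological; ΔΣPMF magnitudes from the
  simulator are not comparable to published per-system values.
* The Jarzynski estimator is biased low at finite N when work spreads are
  large (its exponential average is dominated by rare low-work replicates);
  the bootstrap quantifies variance, not this bias.
* Negative target correlations in the pair generator are only weakly
  realised (antithetic forcing).
* The exclusion rule reproduces retained-set *logic*, not the original
  per-system exclusion lists, whose pairwise correlation matrices are not
  part of the shipped tables.
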