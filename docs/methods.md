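# Methods

## Model

`recflip` studies resource competition between two reporter modules and its
mitigation by recombinase-mediated promoter inversion, using a deterministic
mean-field ODE. The state is `(G, R, X, I, C, P_LR)`: GFP, RFP, free
excisionase, free integrase, integrase–excisionase complex (all in arbitrary
concentration units), and the fraction of plasmid promoters in the
RFP-driving LR orientation.

Assumptions baked into the formulation:

* **Single lumped resource pool.** All synthesis fluxes are multiplied by one
  shared availability factor `phi = 1/(1 + Σ w·u)`, where each promoter
  activity `u` carries a dimensionless demand weight `w`. This collapses
  RNAP/ribosome/charged-tRNA competition into a single saturating factor;
  it reproduces the hallmark phenomenology (one module's induction depresses
  the other's output) without tracking machinery species explicitly.
* **Mean-field promoter orientation.** `P_LR ∈ [0, 1]` is a continuous
  fraction over plasmid copies, not a discrete copy-state distribution. This
  is the right object for deterministic steady-state heatmaps; it cannot
  describe cell-to-cell bimodality.
* **Mass-action recombination kinetics.** The complex forms by
  `k_on·X·I − k_off·C` and decays at `d_C`; flipping is first order in its
  catalyst: LR→BP at `V_off·C`, BP→LR at `V_on·I`. No cooperativity, no
  explicit DNA-bound intermediates.
* **Bicistronic excisionase.** X is synthesized from the same promoter
  activity as RFP (`u_R`), with its own rate constant `k_X` — this is what
  closes the negative-feedback loop.
* **Induction.** A Hill function
  `leak + (1−leak)·dose^n/(K_L^n + dose^n)` of the L-arabinose dose in
  % w/v. Growth/dilution effects are folded into the first-order removal
  rates; burden-induced growth feedback is out of scope.

Four topologies share this right-hand side bit-exactly under parameter pins:
`RE_NF_FF` (full controller), `RE_NF` (`beta_FF` term dropped),
`OPEN_LOOP_MUT` (flip rates zeroed, `P_LR` pinned — the experimental analogue
is an attR central-dinucleotide mutation that blocks re-ligation), and
`NO_CONTROLLER` (additionally no recombinase synthesis or load). The test
suite asserts these reductions exactly.

## Default parameters

All concentrations are in arbitrary units (a.u.), times in hours. Defaults
are chosen so that (i) half-activation `K_L = 6.25e-4 %` sits inside the
6-point induction ladder `(0, 1.25e-4, 2.5e-4, 6.25e-4, 2.5e-3, 5e-3) %`,
(ii) the flip-disabled open loop shows strong visible negative coupling
(CI ≈ −0.15), and (iii) the feedforward controller traverses both its
overcompensating and undercompensating regimes inside the swept brackets.

| parameter | default | meaning |
|---|---|---|
| `k_G`, `k_R` | 100 a.u./h | reporter synthesis capacity |
| `k_X`, `k_I` | 50, 10 a.u./h | excisionase / integrase synthesis |
| `d_G`, `d_R`, `d_I`, `d_C` | 1 /h | removal (degradation + dilution) |
| `d_X` | 1 /h | excisionase removal — the feedforward tuning knob |
| `K_L`, `n_H`, `leak` | 6.25e-4 %, 2, 0 | induction curve |
| `w_G`, `w_R`, `w_I` | 1, 1, 0.2 | resource demand weights |
| `k_on`, `k_off` | 10 /(a.u.·h), 1 /h | complex association/dissociation |
| `V_on` | 1.0 /(a.u.·h) | BP→LR reset per free integrase |
| `V_off` | 0.75 /(a.u.·h) | LR→BP flip per complex — feedback strength |
| `beta_FF` | 1 | flipped-promoter read-through toward GFP |
| `copy_gain` | 1 | plasmid copy-number scalar (5 ≈ high-copy) |

`V_on = 1.0` deserves a note: with a much weaker reset (e.g. 0.1) the
integrase–excisionase complex keeps most promoters flipped even at very fast
excisionase degradation, so the feedforward controller never re-enters its
undercompensating (negative-CI) regime inside the two-decade `d_X` bracket
and the zero crossing that makes the controller *tunable* disappears. The
chosen value balances the two flip directions so that both regimes — and
exactly one sign change between them — occur inside `d_X ∈ [1e-2, 1e2] /h`.

A structural consequence of modeling the BP→LR reset as first order in
*free* integrase: at very high integrase synthesis the reset outruns
complex-driven flipping (complex formation saturates once excisionase is
depleted), so high `k_I` ends in the unflipped, negative-CI regime and low
`k_I` in the flipped, positive-CI regime. A formulation in which reset
competes less effectively would reverse that direction; the single-crossing
tunability is the robust statement.

## Steady states

`integrate_to_steady_state` integrates with LSODA in geometrically growing
time chunks and declares convergence when
`max_i |f_i| / (1 + |y_i|) < ss_tol` (default 1e-9), with a model-time
budget of `t_max = 1e4 h` — promoter-orientation relaxation can be ~100× slower
than protein turnover at the weak-integrase end of the sweeps.
Non-convergence is always reported (flag + diagnostic), and dose scans raise
listing the offending doses. Dose scans warm-start each dose from the
previous steady state; tests assert warm/cold agreement to 1e-6 and
insensitivity to 100× tighter tolerances, which is the practical uniqueness
check for the regimes swept here. Tiny integrator undershoots (≲1e-7) below
zero or above `P_LR = 1` are snapped back onto the invariant box; larger
excursions raise.

## Coupling index

Normalization: `g_norm = G/G(dose 0)`, `r_norm = R/max(R)`, points sorted by
`r_norm` with exact ties averaged. Two estimators are exposed because the
averaging measure is a genuine design choice:

* `pchip_fit` (default): fit the monotone piecewise-cubic Hermite
  interpolant and average `curve(r) − 1` over a uniform grid (default 201
  points) on `r ∈ [0, 1]`. This makes the CI a property of the response
  *curve*, independent of where the dose ladder happens to place its points.
* `direct`: average `g_norm − 1` over the points themselves — appropriate
  for dense simulated curves, and equal to `pchip_fit` to ~1e-3 when the
  points cover `r` near-uniformly (asserted in the tests).

Sign classification uses a configurable decoupled band, default
`|CI| ≤ 0.02`. An all-zero RFP channel makes `r_norm` undefined and raises a
dedicated error rather than silently returning 0. Replicates are averaged
per dose before normalization; a bootstrap-over-replicates CI standard error
is provided as a utility.

## Synthetic plate data

`generate_dataset` emulates a bulk fluorescence induction experiment: the
6-dose ladder × 3 replicates, each read drawn as
`max(0, S·ε + bg)` with `ε` lognormal with mean exactly 1 and coefficient of
variation `cv_mult` (default 0.10), `bg ~ Normal(bg_mean, bg_sd)` (default
0). What it deliberately does **not** emulate: growth/OD readouts,
plate-position effects, channel bleed-through, autofluorescence drift, or
cell-to-cell heterogeneity. Passing recovery tests therefore demonstrate
pipeline self-consistency and parameter identifiability under well-behaved
multiplicative noise — not robustness to real plate-reader artifacts.

## Tuning and recovery

`find_decoupling_value` brackets the zero of `value ↦ CI(value)` on a log
scale (Brent's method; `d_X` and `k_I` act over decades) and requires an
actual sign change — the plain negative-feedback controller, whose CI is
never positive, correctly raises a no-root error. `fit_parameters` minimizes
squared residuals of `log(signal + 1)` between replicate-mean fluorescence
and model steady states over log-transformed parameters in bounds
(`scipy.optimize.least_squares`, trust-region reflective), with a
deterministic multi-start scheme (geometric bound midpoint plus seeded
log-uniform starts). The +1 a.u. floor keeps uninduced zero-RFP channels
finite and mimics a detector background count. The recovery study
(`6 doses × 3 reps`, 20 seeds per noise level) recovers `{V_off, d_X}` of
the feedforward controller essentially exactly from noiseless data and with
~8–13% median relative error at 5% multiplicative noise.

## Numerical edge cases

* `dose = 0` with `leak = 0` gives exactly zero RFP and excisionase
  synthesis; the zero-dose steady state then has `P_LR = 1` (free integrase
  resets any flipped promoters), which anchors the GFP baseline.
* `hill_activation` is computed via `(dose/K_L)^n / (1 + (dose/K_L)^n)` to
  avoid overflow at large doses.
* CSV output carries 12 significant digits and round-trips within text
  precision; every CLI run writes a manifest echoing all effective settings
  and seeds.

## Known limitations

Deterministic mean-field only (no stochastic single-cell simulation); no
sequence-level recombination detail; plasmid copy number is a scalar gain;
no bifurcation/continuation analysis — steady-state uniqueness is checked
numerically, not proven; the fit machinery is validation tooling for
synthetic data, not a calibrated inference pipeline for real measurements.
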