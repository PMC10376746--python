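# Methods

## Model and assumptions

The Planche is treated as a purely static, planar problem: the body is a
chain of eight rigid segments on a single straight line at angle β above
horizontal, mirror-symmetric in the medio-lateral direction, supported at the
wrists by massless hands. Balance is the vanishing of the summed
gravitational torques about the wrist. Because every segment torque is
affine in the shoulder coordinate x with a strictly positive combined slope
W·g, the equilibrium x* = −cos β·N/W is unique and computed in closed form;
no iteration or tolerance enters the solution itself (the test suite verifies
the closed form against an independent Brent root finder to 1e-9 m).

Assumptions worth keeping in mind:

- **Straight body line.** Hip or shoulder pike/arch is not modelled; β is the
  single posture parameter besides the solved x.
- **Arm torques are lever ratios.** The upper- and lower-arm torques depend
  on x only, through the ratios (D7+L8)/(L7+L8) and D8/(L7+L8); they carry no
  β dependence. This follows the printed equation forms literally; no
  mechanical re-derivation is attempted.
- **Strict feasibility.** |x*| = L7+L8 counts as infeasible (the boundary is
  the fully extended degenerate posture). The wrist angle
  α = 180° − arccos(x*/(L7+L8)) is computed with the arccos argument clamped
  at ±1 within 1e-12 to absorb floating-point rounding, and only reported for
  feasible solutions.
- **Sign convention.** Positive x points toward the head. For normal bodies
  the leg-side mass dominates (N > 0), so x* < 0: the shoulders shift away
  from the head side to counterbalance the legs, and α < 90°.
- **No strength, no dynamics.** The model ranks anthropometric (innate)
  difficulty only; muscle strength, joint moments and movement into/out of
  the hold are out of scope.

## Anthropometry defaults

The provider converts (BM, BH, gender, race) into segment parameters. The
published race–gender regression equations behind the original analysis are
not publicly available, so the default provider is a documented
approximation built from group-mean proportion tables, and every number in it
is configuration:

| quantity | default | rationale |
|---|---|---|
| trunk/legs/arms %BH | per race–gender table (e.g. Asian male trunk 39.53 %BH, European male legs 49.83 %BH) | published group means for young Chinese and German adults; preserves the key ordering (European legs longer, trunks shorter at equal BH) |
| trunk split | 50/50 upper/lower by length | no published value; transparent neutral choice |
| leg split | thigh 53 % / shank 47 % | classical proportion tables |
| arm chain split | upper 42.5 % / lower 33 % / hand 24.5 % | classical proportion tables; the %BH arm value is taken to include the hand, so the torque-bearing reach L7+L8 is 75.5 % of the chain |
| head, foot length | 13 %BH, 15.2 %BH | classical proportion tables |
| mass fractions of BM | head 8.1 %, upper trunk 27.4 %, lower trunk 22.3 %, thighs 20 %, shanks 9.3 %, feet 2.9 %, upper arms 5.6 %, lower arms 3.2 % | Dempster-style fractions, trunk split thorax-heavy (~55/45); the ~1.2 % hand mass is deliberately unassigned since hands are the massless support |
| COG fractions Di/Li | 0.5 (midpoint) | no published per-segment values; the midpoint is the neutral choice, and at 0.5 the proximal/distal reference conventions of the printed torque forms coincide |
| g | 9.81 m/s² | standard gravity; g cancels in x*, so it never affects feasibility or ranking |

A single mass-fraction table is applied to all four groups (group-specific
tables are accepted via config). Units are kg, m and degrees everywhere;
radians exist only inside the trigonometry.

Consequences of these defaults that differ from analyses based on the
unpublished regressions — and are expected to: because the default
proportions are constant %BH within a group, x*/(L7+L8) is scale-free, so
all 20 bodies of a group share one α(β) curve and one feasibility verdict.
Under the defaults the European groups are feasible over all β ∈ [0°, 20°],
Asian males only for β ≥ 7° and Asian females only for β ≥ 18°, and no
default-grid body is Planche-impossible. Difficulty orderings and ratio
values reported by this package are therefore always labelled with the
provider that produced them and are not claims about the original regression
results; BM/BH-dependent proportions (which break the within-group ties)
enter through the synthetic provider or a user-supplied config.

## Simulation and ranking

The default grid crosses the five weight classes and four height groups per
gender (male 44/54/63/73/83 kg × 1.57/1.66/1.74/1.82 m; female
39/48/56/65/74 kg × 1.45/1.53/1.62/1.70 m) with the four race–gender groups:
80 body types. β is swept over [0°, 20°] — the range is prescribed by the
FIG body-line rule; the 1° step is this package's default and configurable.
Ranking sorts by α at a reference β (default 0°, the strictest posture),
descending; bodies infeasible at the reference rank last, bodies feasible at
no β are flagged "Planche impossible", and ties break on the body identifier
so output is deterministic. The Olympic comparison evaluates the
gender-matched reference bodies (male 1.66 m/63 kg, female 1.53 m/48 kg)
under all four groups' proportions, isolating the pure race–gender effect.

## Ratio post-exploration

Per body: TL = L2+L3, LL = L4+L5, AL = L7+L8, all ratios in percent, and the
difference TL/AL − TL/LL. Two conventions are deliberately configurable
because the length definitions admit both readings: AL with or without the
hand (default without: the wrist is the support point and the %BH arm chain
is hand-inclusive, which also keeps AL/LL near the observed ~61 % rather than
the hand-inclusive ~84 %), and LL with or without the foot (default without:
leg length conventionally ends at the ankle). Group summaries are mean ± SD
over the group's bodies; the SD is the sample SD (ddof = 1) by default and
switchable, since the flavor used originally is unstated. Groups are ranked
by mean difference, descending, ties alphabetical. Note that under the
default constant-proportion provider the within-group SDs are exactly zero
and the diff ranking (Asian female > Asian male > European male > European
female) is a property of the default proportion tables, not a reproduction of
the published ratio table.

## Synthetic anthropometry and what a green recovery test establishes

The generator emulates the *structure* of the unavailable regressions:
chain proportion = group base + group offset + bh_slope·(BH − 1.60 m) +
bm_slope·(BM − 60 kg) + N(0, noise_sd²), clipped to (0, 1). Noise applies to
proportions, not absolute lengths, preserving the scale invariance of α.
Draws are keyed on (seed, group, BM, BH), so a seed reproduces a dataset
independent of evaluation order, and every dataset carries its ground truth
(offsets, slopes, the group ordering of the injected diff statistic).

The recovery experiments are power-designed, with parameters fixed before
any test was run:

- **Group-ranking recovery** (ratio pipeline): trunk offsets of
  +0.012/+0.004/−0.004/−0.012 %BH-fraction stagger the group diff means by
  ≥ 1.7 percent-points; at noise_sd = 0.001 the group-mean standard error is
  ≈ 0.08, a ≥ 20 SD margin.
- **Body-ranking recovery** (sweep/ranking pipeline, 20 bodies, all ranks
  exact): arm-proportion slopes (−0.12 per m BH, −0.0002 per kg BM, +0.08
  offset to keep every body feasible at β = 0°) give a smallest adjacent-rank
  gap ≥ 4.5 SD of the noise-induced perturbation at noise_sd = 0.0002. The
  smaller noise here reflects that an exact 20-way ordering is a much harder
  recovery target than a 4-way group ordering; recovery degrades gracefully
  as noise grows.

A green recovery test establishes that the pipelines propagate injected
anthropometric structure into the correct orderings. It does not establish
realism of the synthetic populations: the generator makes no attempt to
mimic real covariance between BM, BH and proportions, measurement error
structure, or age effects — only the linear-in-BM/BH, group-offset,
Gaussian-noise skeleton the analysis assumes.

## Known limitations

- Rankings and feasibility patterns depend entirely on the anthropometry
  provider; the shipped defaults are group means, so within-group variation
  is absent unless a regression-backed or synthetic provider is supplied.
- The arm-torque lever forms ignore any β dependence of the arm geometry.
- No validation against measured Planche kinematics is included; the model's
  value is comparative (between body types), not predictive of an
  individual's absolute capability, which muscle strength dominates.
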