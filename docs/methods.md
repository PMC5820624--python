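# Methods

## Constitutive model

Every tissue is treated as isotropic, nonlinear elastic and incompressible
— the load-carrying response of pelvic connective tissue under a single
pressure event, not its active or time-dependent behaviour. A constituent
`i` carries the three-term polynomial energy
`Wᵢ = C₁₀ⁱ(I₁−3) + C₀₁ⁱ(I₂−3) + C₂₀ⁱ(I₁−3)²` (MPa). Missing coefficients
in the bundled tables are structural zeros: a single-term material is
evaluated with the other terms exactly zero, and the fitting module only
frees the terms a caller selects.

The endopelvic fascia is too thin (≈1.5 mm) to resolve as a separate body;
it is modelled as a composite "organ" of fibre compound, adipose tissue and
smooth muscle with volume fractions (0.10, 0.85, 0.05). Homogenization uses
the Voigt isostrain rule: all phases share `C`, so the effective energy and
every stress measure are volume-fraction-weighted sums. The weighted-sum
identity is exact by construction and asserted to 1e−12 in tests. Smooth
muscle contributes only passively (no active stress anywhere in the
package). Fractions are validated to sum to one within 1e−12 — the
admissible parametrization requires a closed composition, and the
constructor rejects anything else.

Incompressibility introduces a hydrostatic pressure multiplier `p`. At the
constitutive level `p` is not an independent unknown: it is resolved per
deformation state from a traction condition (zero lateral traction for
uniaxial tension, stress-free reference for `F = I`, the volumetric penalty
in the FE solver). The closed-form uniaxial nominal stress `P(λ)` follows
from `λ₂ = λ₃ = λ^(−1/2)` and is the workhorse for fitting, truss elements
and verification; it is checked against numeric differentiation of the
isochoric uniaxial energy to 1e−6 relative on λ ∈ [1.001, 1.7] for every
bundled material.

### Parameters

Two bundled CSV tables (`name,c10_mpa,c01_mpa,c20_mpa`) hold the fitted
coefficients of the fascia constituents and of the whole pelvic structures
(organs, ligaments, fascia regions, muscle), collected from published
uniaxial tensile experiments. Two derived conventions:

* the elastin-rich (proximal) fascia region is the collagen-rich set with
  every coefficient reduced by 75% — the adopted average stiffness contrast
  between collagen- and elastin-dominated connective tissue (digestion
  experiments suggest >90% for complete removal; 75% avoids overstating
  the contrast when only the ratio changes). `derive_elastin_rich`
  reproduces the bundled row exactly (0.64785 → 0.1619625 MPa).
* the cardinal-ligament and uterosacral coefficients are shipped as
  constants (porcine-comparison and left/right-average procedures behind
  them are not reproducible from the published record).

Units package-wide: stress MPa, length mm, force N. Clinical pressures are
converted with the exact water-column constant 1 cm H₂O = 98.0665 Pa; note
that a commonly quoted shorthand 60 cm H₂O = 0.0058 MPa rounds the exact
0.005884 MPa low, which the consistency table reports explicitly.

### Impairment

Tissue laxity is modelled as stiffness loss: all coefficients of the
affected tissues are multiplied by `(1 − impairment)` with impairment in
[0, 0.95] (multiplier never below 0.05). Because `P(λ)` is linear in the
coefficients, impairment scales the whole stress-stretch curve; this
linearity is exact and tested.

## Coefficient fitting

`P(λ)` is linear in (C₁₀, C₀₁, C₂₀), so fitting is unweighted linear least
squares on nominal stress (no weighting is applied because none is implied
by the data sources). Default stretch range for synthetic studies is
[1.0, 1.3] (physiological soft-tissue working range). Coefficients are
unconstrained in sign; negative results are logged as warnings since they
usually indicate an ill-chosen term subset. Noiseless synthetic curves are
recovered to well below 0.1%. Under 2%-of-max-stress Gaussian noise the
*response* is recovered to ≤5% (L2 over the fit range) across seeds, and
the dominant coefficient individually; a very small coefficient that
contributes only a few percent of the signal (adipose C₁₀ ≈ 0.0008 MPa
against C₂₀-driven stresses) is not individually identifiable at that
noise level, which is a property of the estimation problem, not of the
implementation.

## Finite elements

Total-Lagrangian, quasi-static, deterministic:

* **Bulk**: 4-node constant-strain tetrahedra. Exact incompressibility is
  replaced by a decoupled law — the polynomial energy evaluated on
  isochoric invariants `Ī₁ = J^(−2/3) I₁`, `Ī₂ = J^(−4/3) I₂` plus the
  volumetric penalty `κ/2 (J−1)²`. Default `κ` is 10³ × the largest
  effective deviatoric coefficient of the element's material (per region,
  so impairment scales `κ` consistently and the closed-form scaling
  survives discretization). On the verification cube this keeps |J−1|
  below 2e−4 and the stress error against the closed form below 0.1%;
  doubling κ moves the reaction by <0.5%.
* **Tangent**: the first Piola-Kirchhoff stress is analytic; the
  first-elasticity tensor dP/dF is formed by batched central finite
  differences (step 1e−6 on F components, all 18 perturbed states in one
  vectorized stress call). Agreement with a dof-wise finite difference of
  the element force is ~1e−9 relative.
* **Ligaments**: 2-node trusses carrying `A₀ · P(λ)` along the current
  axis, tension-only by default. The slack-to-taut transition is smoothed
  with a C¹ cubic over λ ∈ [0.99, 1.01]: a hard cut leaves a tangent
  discontinuity exactly where a ligament rests at its natural length and
  makes Newton chatter. The smoothing admits a negligible compressive
  force inside the window (stress there is O(window)).
* **Loads**: face pressures are follower loads (re-evaluated on the
  deformed surface) with their exact, unsymmetric load stiffness
  assembled; this matters once tissues are heavily impaired and the load
  stiffness rivals the material stiffness. Dead-load pressures remain
  available for verification. Point muscle forces are dead loads.
* **Solution**: incremental loading (10 equal steps by default) with full
  Newton iterations (relative residual ≤ 1e−9), step bisection on
  divergence or element inversion with step-size recovery after two
  successes, and step halving inside an iteration only when a trial step
  would invert an element. Sparse unsymmetric direct solves
  (`scipy.sparse.linalg.spsolve`). Identical inputs give bitwise-identical
  histories.

Global equilibrium (reactions balancing applied loads) is asserted in
tests, as is the patch-style verification: a cube stretched to λ = 1.1
reproduces the closed-form nominal stress within 1%.

## Idealized pelvic model

The original cadaver-derived geometry is not reproducible, so the package
builds a parametrized idealized stand-in designed to preserve the
load-path structure, not patient anatomy:

* a fascia **hammock** (default 80 × 100 × 3 mm, 8 × 10 × 1 cells) fixed at
  its lateral margins (pelvic sidewall / arcus analogue), posterior margin
  (sacrum) and anterior margin (pubis / perineal membrane — distal Level
  III fusion; leaving the anterior edge free makes the pubourethral
  ligament the de-facto anterior suspension, which contradicts the hammock
  mechanism the model exists to study);
* a **collagen-rich distal strip** (anterior 25 mm, motivated by the
  distal 2–3 cm of the vaginal fascia being collagen-rich) and an
  elastin-rich proximal remainder, each a Voigt mixture whose fibre phase
  is the corresponding Table entry;
* an **organ block** (bladder analogue, 40 × 40 × 30 mm of vesica
  material) resting conformally on the hammock;
* **ligament trusses** with fixed bone anchors: pubourethral (10 mm²,
  anchored anterior-superior of the bladder neck), uterosacral (15 mm²,
  posterior), cardinal (2 × 10 mm², lateral). Anchors sit nearly level
  with their attachments: pelvic ligaments stabilize the organs
  horizontally while the hammock bears the vertical pressure — the
  anatomical reading under which the published fascia-dominance mechanism
  is reproducible;
* a **urethra truss** from the bladder neck (UVJ) to a fixed meatus node
  placed so the resting urethral axis is 22° from the vertical;
* **loads**: 40 cm H₂O intra-abdominal pressure on all upward-facing
  surfaces (follower), plus small constant muscle forces — levator plate
  0.5 N posterior at the bladder neck, longitudinal anal muscle 0.5 N
  caudal at the anorectal landmark — sized so the healthy urethral angle
  stays within 10° of rest (measured: +5.5°). A bladder-neck fluid
  pressure (60 cm H₂O at the neck, linear to zero at the exit, applied as
  an equivalent axial force) is available for micturition load cases and
  off by default.

Measurement conventions (mid-sagittal plane, degrees): Ur from the
vertical in [0°, 90°]; α at the pubic reference point between the fixed
midpubic line (tilted 20° so the resting α is 110°) and the displaced
bladder neck; LPA from the horizontal with caudal inclination positive
(flat hammock ⇒ resting LPA 0°, so LPA values are read as changes);
inferior and posterior UVJ displacements are reported positive.

**Impairment sweeps** re-solve the model per level with the target set
("fasciae", "ligaments", "all", or one named ligament) scaled by
`(1 − level)`, warm-starting each level from the previous one
(continuation in the impairment parameter, with bounded bisection of the
impairment interval on failure). The cold 95%-all case sits near a limit
point of the discretized model; the homotopy passes through it reliably.
A level that still fails is flagged in the output table and the sweep
continues.

What the default model shows (and tests assert): UVJ mobility is
non-decreasing in combined impairment (5.26 → 22.6 mm at 95%);
fascia-only impairment displaces the UVJ strictly more than all-ligament
impairment at every level ≥ 50% (9.3 vs 6.5 mm at 95%); the urethral
angle crosses the 30° Q-tip threshold under fascia impairment (level 0.65
on the default 5% grid, 0.40 when everything is impaired together) but
never under ligament impairment. Absolute millimetre values are
geometry-bound and are not comparable to patient or cadaver numbers; only
orderings, monotonicities and threshold structure carry over.

## Synthetic data

The curve generator samples the closed-form `P(λ)` on an even grid and
adds Gaussian noise (additive, standard deviation expressed as a fraction
of the curve's maximum absolute stress; multiplicative noise behind a
flag). One integer seed per call, no global state. It emulates digitized
uniaxial tensile experiments only: no biaxial states, no hysteresis or
rate effects, no digitization bias, no specimen-to-specimen variability.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated noise model, not robustness to real
experimental artefacts. Fixture meshes are structured boxes split into six
tetrahedra per cell (Kuhn subdivision — translation-invariant, hence
conforming, with orientation fixed programmatically).

## Problem sizes and tolerances

Defaults were chosen so a full default pipeline (three sweeps × twenty
levels) runs in minutes on one CPU: the idealized model has 672 tetrahedra,
6 trusses and ≈760 free dofs; the verification cube 48 tetrahedra; curve
studies use 50 points and 100 seeds. Key tolerances: Newton relative
residual 1e−9; mixture-sum validation 1e−12; isochoric assertion 1e−8;
uniaxial-oracle agreement 1e−6; FE-vs-closed-form 1%.

## Known limitations

* Isotropic only — no fibre-reinforced (Holzapfel/Itskov-type) anisotropy.
* No contact: vaginal wall self-contact and organ-organ contact are out of
  scope, which caps the realism of large-impairment shapes.
* No viscoelasticity, no active muscle contraction, no coccyx flexion.
* Constant-strain tetrahedra are stiff in bending; the hammock response is
  membrane-dominated, where they are adequate, but thin-plate bending
  regimes would need a finer or higher-order discretization.
* The idealized geometry is a mechanism model. Its displacement magnitudes
  have no clinical calibration, and conclusions should be drawn from the
  comparative quantities only.
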