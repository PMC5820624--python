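# pelvifem

Soft-tissue mechanics of the female pelvic floor: hyperelastic mixture
modelling of the endopelvic fascia, coefficient identification from uniaxial
experiments, and a compact nonlinear finite-element model of an idealized
pelvic floor used to study stress urinary incontinence (SUI) as a
tissue-laxity phenomenon.

## Who this is for

Biomechanics researchers who want a small, fully scripted pipeline for
studying how stiffness loss in the pelvic suspension system (endopelvic
fascia vs. ligaments) displaces the urethrovesical junction (UVJ, the
bladder neck) and rotates the urethral axis during a Valsalva manoeuvre —
the mechanical signature of SUI.

## The model

Each tissue constituent is an isotropic, incompressible hyperelastic solid
with a three-term polynomial (Mooney–Rivlin type) strain-energy function of
the principal invariants of `C = FᵀF`:

    Wᵢ = C₁₀ⁱ (I₁ − 3) + C₀₁ⁱ (I₂ − 3) + C₂₀ⁱ (I₁ − 3)²

The endopelvic fascia is a composite of an elastin–collagen fibre compound
(10%), adipose tissue (85%) and passive smooth muscle (5%), homogenized by
the Voigt isostrain rule: all constituents share the same `C` and the
effective energy is the volume-fraction-weighted sum

    W = Σᵢ fᵢ Wᵢ(C),   f_fas + f_ad + f_sm = 1.

Stresses follow the standard chain `S = 2 ∂W/∂C − p C⁻¹`, `P = F S`,
`σ = J⁻¹ F S Fᵀ`; in incompressible uniaxial tension
(`λ₂ = λ₃ = λ^(−1/2)`) the nominal stress has the closed form

    P(λ) = Σᵢ fᵢ [ 2C₁₀ⁱ(λ − λ⁻²) + 2C₀₁ⁱ(1 − λ⁻³) + 4C₂₀ⁱ(λ − λ⁻²)(λ² + 2/λ − 3) ]

which is linear in the coefficients, so fitting tensile data is a linear
least-squares problem. Tissue laxity ("impairment") multiplies all
coefficients of the affected tissues by `(1 − impairment)`, up to 95%.

The FE model is total-Lagrangian: 4-node tetrahedra with a nearly
incompressible decoupled law (isochoric invariants plus a volumetric
penalty `κ/2 (J−1)²`), tension-only truss elements for the ligaments,
follower intra-abdominal pressure (40 cm H₂O by default) and Newton
iteration with load stepping. The idealized geometry is a fascia hammock
(collagen-rich distal strip, elastin-rich proximal region) fixed at the
pelvic sidewalls, sacrum and pubis, carrying a bladder block suspended by
pubourethral, uterosacral and cardinal ligament trusses.

Measurements reproduce the clinical quantities: vertical/horizontal/resultant
UVJ mobility (`UVJ = √(VUVJ² + HUVJ²)`), urethral axis angle **Ur** from the
vertical (> 30° ≈ positive Q-tip test), angle **α** from the midpubic line
to the bladder neck, and the levator plate angle **LPA**.

## Worked example

Solve the healthy idealized pelvic floor under 40 cm H₂O Valsalva:

```bash
$ pelvifem solve
   vuvj_mm:    5.234
   huvj_mm:    0.509
    uvj_mm:    5.258
    ur_deg:   27.501
 alpha_deg:  121.589
   lpa_deg:   29.301
```

The bladder neck moves 5.26 mm (mostly inferiorly), the urethral axis tilts
from its 22° resting angle to 27.5° (still a negative Q-tip analogue), and
the levator line inclines 29.3° caudally. The same model through Python:

```python
from pelvifem import build_idealized_pelvis, impairment_sweep

model = build_idealized_pelvis()
sweep = impairment_sweep(model, "fasciae", [0.0, 0.5, 0.95])
print(sweep[["impairment", "uvj_mm", "ur_deg"]])
#    impairment    uvj_mm     ur_deg
# 0        0.00  5.258293  27.500554
# 1        0.50  7.204729  29.420168
# 2        0.95  9.295701  28.688552
```

Weakening the fascia by 95% moves the UVJ 9.3 mm, against 6.5 mm when all
three ligament groups are weakened instead — the hammock, not the
ligaments, is the primary pressure-bearing support, and fascia impairment
is what first drives the urethral angle past the 30° Q-tip threshold.
(Absolute millimetre values are specific to this idealized geometry; the
orderings and trends are the scientific content.)

The full pipeline (healthy solve, 0–95% impairment sweeps of fasciae /
ligaments / all, consistency table, plots, VTK displacement fields,
machine-readable summary):

```bash
pelvifem report --out runs/default
```

## Layout

| Module | Contents |
| --- | --- |
| `pelvifem.constitutive` | invariants, strain energies, PK1/PK2/Cauchy stress, uniaxial closed form, impairment |
| `pelvifem.materials` | bundled tissue parameter tables (CSV), elastin-rich derivation |
| `pelvifem.fitting` | least-squares coefficient identification |
| `pelvifem.fem` | tet + truss total-Lagrangian solver |
| `pelvifem.pelvic` | idealized pelvic model, clinical measurements, sweeps |
| `pelvifem.synthetic` | stress–stretch curve generator, fixture meshes |
| `pelvifem.pipeline` / `pelvifem.cli` | staged runs, consistency checks, `pelvifem` CLI |

See `docs/methods.md` for modelling assumptions, parameter choices and
numerical details.
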