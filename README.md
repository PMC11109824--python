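# ampscat

Quantitative membrane biophysics of antimicrobial peptides (AMPs):
a Python library covering the full analysis chain used to characterise
how short cationic amphipathic peptides interact with lipid model
membranes, from sequence descriptors and MIC statistics to X-ray and
neutron scattering model fits.

It is aimed at membrane-biophysics groups who collect circular dichroism
(CD), low- and wide-angle X-ray scattering, solution SAXS and neutron
reflectometry (NR) data on peptide/lipid systems and want a tested,
scriptable replacement for the usual patchwork of one-off analysis
programs. Every stage can also be exercised end-to-end on synthetic data
with known ground truth.

## What it computes

| stage | model | output |
|---|---|---|
| `ampscat.descriptors` | Fauchère–Pliska mean hydrophobicity H, integer net charge, MIC group means with σ_Ave = √(Σσ_i²)/N | peptide tables, MIC summaries |
| `ampscat.cd` | MRE(λ) = Σ_i f_i B_i(λ), f_i ≥ 0, Σf_i = 1 (NNLS on an augmented system) | α-helix/β-sheet/β-turn/random-coil fractions |
| `ampscat.caille` | discrete smectic free energy F = ½Σ_n∫[K_C(∇²u_n)² + B(u_{n+1}−u_n)²]; diffuse S(q_z,q_r) from height correlations; I = s·S·\|F\|²/q_z | bending modulus K_C, compression modulus B |
| `ampscat.waxs` | Maier–Saupe tilted-rod arc, f(β) ∝ exp(m cos²β) sinβ; S_xray = (3⟨cos²β⟩−1)/2 | acyl-chain order parameter S_xray |
| `ampscat.sdp` | scattering-density-profile bilayer (Gaussian headgroups, erf chain slab, peptide envelope); F(q_z) = ∫(ρ−ρ_w)cos(q_z z)dz | A_L, D_HH, 2D_C, peptide placement by χ² |
| `ampscat.saxs` | Bragg orders q_n = 2πn/D; Scherrer L = 2πK/Δq, n = L/D | D-spacing, lamellarity, ULV/MLV/mixed class |
| `ampscat.nr` | volume-occupancy composition space; Parratt/Abelès dynamical reflectivity; joint H₂O/D₂O MCMC | component profiles with 68% credible intervals |
| `ampscat.synth` | seeded generators for every modality | synthetic data + JSON ground truth |

Fitting follows the Model/Results idiom: construct a model object from
data, call `fit()`, get a results object with estimates, uncertainties
and a `summary()` table.

## Worked example

```python
from ampscat.descriptors import PeptideRecord
from ampscat import synth, caille
from ampscat.saxs import LamellarModel

for rec in (PeptideRecord("LE-53", "RRRRRRWWWWVV"),
            PeptideRecord("LE-55", "RRRRRRRRWWWWVVVV")):
    print(f"{rec.id}: {rec.n_residues} aa, charge {rec.net_charge:+d}, "
          f"H = {rec.hydrophobicity_H:.3f}")

# lamellar analysis of a synthetic fused-vesicle (MLV) curve
curve, truth = synth.gen_saxs(D=51.1, n_layers=30, noise=0.005, seed=1)
print(LamellarModel(curve).fit().summary())

# bending-modulus fit of a synthetic diffuse pattern
stack = synth.default_stack()                     # K_C = 20 k_BT ground truth
pattern, _ = synth.gen_xds(stack, noise=0.05, seed=0)
init = caille.StackModel(K_C=12.0, B=5e-7, N_layers=stack.N_layers,
                         L_r=stack.L_r, D=stack.D)
fit = caille.fit_elasticity(pattern, synth.default_formfactor, init,
                            fit_window=[(0.08, 0.33, 0.02, 0.25)])
print(fit.summary())
```

prints

```
LE-53: 12 aa, charge +6, H = 0.448
LE-55: 16 aa, charge +8, H = 0.362

Lamellar SAXS analysis
------------------------------
class: MLV
  q=0.1230 A^-1  order=1  FWHM=0.003404
  q=0.3686 A^-1  order=3  FWHM=0.004007
  q=0.4918 A^-1  order=4  FWHM=0.004674
  q=0.6150 A^-1  order=5  FWHM=0.00514
D spacing   = 51.10 A
Scherrer L  = 1661.1 A -> n = 33

Smectic elasticity fit (diffuse lobe fall-off)
----------------------------------------------
K_C  =      19.83 k_BT   68% CI [19.71, 19.94]
     =       84.9 x 1e-21 J
B    =  2.138e-07 k_BT/A^4 68% CI [2.044e-07, 2.237e-07]
scale=      1.003
reduced chi^2 = 1.008
status: ok
```

The two peptides differ only in length: dropping two arginines and two
valines raises the mean hydrophobicity from 0.362 to 0.448. The SAXS
curve generated with a 51.1 Å repeat and 30 correlated bilayers is
classified as multilamellar with its repeat spacing and lamellarity
recovered (n = 33 vs 30 generated; the Scherrer constant K = 0.9 makes
this a ±10% estimate). The elasticity fit recovers the generating
bending modulus (20 k_BT ≈ 86 × 10⁻²¹ J at 37 °C) within 1% from a
pattern carrying 5% multiplicative noise.

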