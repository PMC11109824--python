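# Methods

This note records the models implemented in `ampscat`, the defaults and
numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Peptide descriptors and MIC statistics

Mean hydrophobicity H is the arithmetic mean of per-residue values on
the Fauchère–Pliska octanol/water scale (the scale the HeliQuest server
uses), bundled as `data/fauchere_pliska_1983.csv`. Net charge is integer
counting at pH 7: +1 per Arg/Lys, −1 per Asp/Glu, His neutral, termini
ignored. This convention is deliberate — for Arg-rich designed peptides
the printed charges equal the arginine count, which identifies the
counting rule; pKa-based partial charges are out of scope.

MIC panels are summarised by unweighted means over species. When
per-species standard deviations are available the group SEM is the
quadrature combination √(Σσ_i²)/N; otherwise it is the sample (N−1)
standard deviation of the species means over √N. A single-species group
reports SEM 0 by convention. The mean residue ellipticity conversion
MRE = ε·10⁴/N bakes in fixed acquisition conditions (10 μM peptide,
3 mL cell) and is documented as valid only there.

## CD decomposition

The far-UV trace is modelled as a convex combination of four motif
reference spectra. The constrained problem (f ≥ 0, Σf = 1) is solved by
non-negative least squares on a system augmented with a sum-to-one row
weighted 10⁶ above the data scale — deterministic, convex, no tuning.
Because the solve is convex, "perturbed restarts" are a no-op; per-motif
uncertainties instead come from a small number (default 4, matching the
usual practice of quoting 3–4 repeated fits) of seeded refits on data
perturbed by the residual RMS.

The bundled basis (`data/cd_motif_basis_synthetic.csv`) is a **synthetic
stand-in**: Gaussian bands whose centres and magnitudes follow the
canonical poly-peptide reference shapes (helix: −33 000 at 222 nm,
−31 000 at 208 nm, positive lobe below 200 nm; sheet: −20 000 at 217 nm,
+33 000 at 196 nm; turn: +15 000 at 203 nm, −10 000 at 224 nm; coil:
−45 000 at 197 nm, +5 000 at 217 nm; all deg·cm²·dmol⁻¹), tabulated at
0.5 nm pitch over 200–240 nm (the standard instrument data pitch and
scan window). Decompositions of *real* spectra are basis-dependent;
only synthetic-recovery accuracy is asserted by the tests, and users
should supply a measured basis for quantitative work. The tryptophan
side-chain correction is exposed as `subtract_reference` with a default
scale of n_W/N; the identity and scaling of the reference trace is an
input, not a guess.

## Smectic elasticity (diffuse low-angle scattering)

The stack of N bilayers carries the discrete smectic free energy

    F = ½ Σ_n ∫ d²r [ K_C (∇²u_n)² + B (u_{n+1} − u_n)² ]

with periodic boundary conditions in the layer index. Units are reduced
(k_BT at T = 310.15 K, Å); K_C is reported both in k_BT and 10⁻²¹ J.
Equipartition gives per-mode amplitudes 1/[A(K_C q_r⁴ + 2B(1 −
cos 2πm/N))]; height-difference correlations δ_k(r) follow by a mode sum
and a quadrature over q_r on a log-spaced grid between the finite-size
cutoff π/L_r and a molecular cutoff 2π/5 Å⁻¹ (default 256 nodes;
`height_correlation` doubles the grid until stable to 0.1%, raising
with diagnostics otherwise). The structure factor

    S(q_z, q_r) = Σ_k (N − |k|) cos(q_z k D) · (2/L_r²) ∫₀^{L_r} r J₀(q_r r) e^{−q_z² δ_k(r)/2} dr

is normalised so a frozen stack reproduces the ideal finite-lattice
interference function. The r-integral uses a uniform 800-node grid
(spacing L_r/800 ≈ 3 Å, resolving the J₀ oscillation up to q_r ≈ 0.3
Å⁻¹). The truncation at L_r produces small finite-size fringes, which
can make S marginally negative in dark regions far from the lobes; this
is a known property of the sharp-domain approximation and is irrelevant
inside any sensible fit window.

The observation model is I = scale·S·|F(q_z)|²/q_z with the 1/q_z
Lorentz factor for oriented flat samples, an optional Gaussian q_r
resolution, and a masked beam region below a configurable q_z cutoff.
Fits run over (log K_C, log B, log scale) with N, L_r, D fixed at
configuration values; default N = 16 and L_r = 2500 Å are effective
coherence values chosen for desk-scale tractability, not the physical
stack size (~10³ bilayers). Confidence intervals are multiplicative,
from the Jacobian covariance at the optimum scaled by the reduced χ².
Per-pixel uncertainties are floored at 10⁻⁴ of the peak intensity so
near-empty pixels cannot dominate the weighted fit. A higher fitted K_C
means a stiffer membrane.

Degenerate inputs: a laterally *flat* pattern is genuinely explained by
vanishing stiffness (white-noise heights), while a *frozen* pattern
drives the moduli to the upper bound — the fit flags any bound hit in
its status rather than guessing.

## WAXS chain order

Chains are modelled as thin rods tilted by β from the local director
with the Maier–Saupe density f(β) ∝ exp(m cos²β) sinβ on [0, π/2].
⟨cos²β⟩ has the closed form 1/(2√m·D(√m)) − 1/(2m) with D the Dawson
function (series about 1/3 below m = 10⁻⁶), from which
S_xray = (3⟨cos²β⟩ − 1)/2. The arc intensity is the exact angular
projection of the rod distribution onto the detector arc; substituting
cos β = cos φ sin θ removes the endpoint singularity and leaves

    I(φ) = scale · ∫₀^{π/2} exp(m cos²φ sin²θ) dθ + background,

evaluated by 48-node Gauss–Legendre quadrature (the small-angle
approximation is not needed; the exact mapping is cheap). The flat
additive background reflects that the ±incidence-angle subtraction
removes structured background. A flat profile lies on a degenerate
ridge (m = 0 with finite amplitude vs any m with vanishing amplitude);
the fit prefers the isotropic reading whenever it explains the data
equally well and flags it in the status.

## SDP form-factor model

Component groups per lipid: Phos and CG as Gaussian pairs at ±z_P,
±z_CG; the hydrocarbon core as an error-function slab of half-width
D_C = V_chain/A_L with edge roughness σ_HC; the terminal-methyl trough
as a central Gaussian carved from the slab; water filling the remainder.
Default component volumes and electron counts
(`data/lipid_components_310K.csv`) are literature-informed round
numbers representative of the fluid-phase PE/PG-rich mixtures at 37 °C;
they are user-overridable and their absolute accuracy is not asserted —
all quantitative tests are synthetic round trips.

A peptide envelope is one Gaussian pair placed in the headgroup region
(displacing water, contrast ρ_pep − ρ_w), in the hydrocarbon core
(displacing methylenes, contrast ρ_pep − ρ_CH2), or one of each sharing
a fitted amplitude split. Displacement keeps total occupancy at one;
the small tail of a core-placed Gaussian beyond the slab edge is
clipped, making the closed-form F exact to ~10⁻⁵ relative — negligible
against any realistic uncertainty. Peptide electrons come from residue
composition (+10 for the termini), volumes from standard partial
residue volumes, scaled by the lipid:peptide mole ratio (default 75:1).

Fits are weighted least squares on |F| with one free multiplicative
scale per dataset (F(0) is not constrained by arbitrary-unit data),
volume-packing violations penalised softly, and envelope widths bounded
at 7 Å so a Gaussian nominally in one region cannot spread across the
leaflet and mimic the other. Placement is scanned over the three modes
and selected by the Akaike-corrected score χ² + 2p: the two-Gaussian
mode nests the single placements, so raw χ² alone would always prefer
it. For peptide-containing samples the four width parameters are best
held at the values fitted to the control (peptide-free) sample — the
scan is only weakly identifiable otherwise, since seven lipid shape
parameters can absorb a 75:1 peptide's contribution. Structural
readouts: D_HH is twice the (parabolically refined) peak position of
the summed Phos+CG electron density; 2D_C is the FWHM of the
hydrocarbon occupancy, which for the erf slab equals 2V_chain/A_L
independent of σ_HC.

## Lamellar SAXS

Bragg candidates are local maxima of the background-subtracted curve
(rolling median, 15-point window) at ≥4 pointwise σ, where the noise
scale is the larger of the declared σ(q) and a local robust MAD —
the data are strongly heteroscedastic across the diffuse lobes. Three
vetoes remove artifacts: single-pixel spikes (neighbours must also sit
above the noise), features broader than min(0.025 Å⁻¹, 0.55 window)
(diffuse-lobe undulations), and candidates that fail to rise above a
parabola through flanking windows by max(4σ, 5% of the local intensity)
(the rolling median's own sag at a smooth lobe maximum). Orders are
assigned by integer ratio to the lowest peak (tolerance 0.08) with
warnings for inconsistent peaks; widths come from a local Gaussian+
linear fit. D is the 1/FWHM²-weighted mean of 2πn/q_n. Scherrer
lamellarity uses K = 0.9 and quadrature deconvolution of an optional
instrumental width; with the finite-stack generator this recovers the
layer count to ~±10% (the Laue-function FWHM is 2π·0.886/ND).
Classification: no assigned order → ULV; otherwise MLV when the Bragg
power (background-subtracted, integrated over ±FWHM) exceeds 5% of the
diffuse power, else mixed.

The generator uses a paracrystalline finite-N structure factor with
cumulative Gaussian disorder (default 0.8 Å) times a smooth bilayer
envelope, plus an uncorrelated (ULV) channel weighted by
`diffuse_fraction` — chosen because it gives analytic control of both
peak position and width for round-trip tests.

## Neutron reflectometry

The interface is a volume-occupancy composition profile on a 2 Å grid:
native oxide, ~140 Å gold (4–9 Å r.m.s. roughness typical; 5 Å
default), tether/SAM (14 Å at 60% density), inner/outer headgroups
(8 Å at 55% of bilayer completeness), hydrocarbon core (29 Å default at
95% completeness), and a free-form peptide profile — a monotone cubic
Hermite (PCHIP) spline with control points 15 Å apart (spacings below
5 Å rejected as over-parameterisation), clamped to [0, 1] and zero
outside its support. The peptide displaces the soft components and
solvent proportionally, so occupancies sum to one by construction.
Neutron SLDs for Si, SiO₂, Au, tether, headgroups, chains, protein
(with labile-H exchange in D₂O) and the two buffers are bundled nominal
literature values, overridable per profile.

Reflectivity is the exact Parratt/Abelès recursion through the slab
stack, vectorised over q; Nevot–Croce factors are available but profile
roughness is normally encoded in the slab discretisation (2 Å,
converged versus 1 Å to well below the data uncertainty in the tested
configurations). Closed-form Fresnel and single-slab solutions are
reproduced to 10⁻¹⁰ and the kinematic (Born) limit to within 5% above
five critical edges on smooth profiles.

Both isotopic contrasts share every structural parameter; only the
solvent (and exchange-dependent) SLDs switch. The joint fit is a seeded
affine-invariant ensemble MCMC (emcee; default 14 walkers × 500 steps,
200 burn-in) started in a tight ball around the Nelder–Mead
maximum-likelihood point, with uniform priors, split-chain R̂ < 1.2 as
the mixing criterion, and equal-tailed 68% credible intervals. In
repeated synthetic experiments at 5% relative noise the intervals show
mild undercoverage for the peptide amplitude (a ~0.5σ finite-noise
estimator bias from the nonlinearity of the parameter-to-reflectivity
map); the nominal-coverage test therefore checks per-parameter coverage
against a 60% floor rather than the asymptotic 68%.

## Synthetic data and what passing tests show

Each generator draws from the forward model of its consuming module
with explicit seeds (identical seed ⇒ byte-identical output) and
returns a JSON-serialisable ground-truth dict. Noise models: additive
Gaussian for CD, |F| and NR; multiplicative Gaussian with a 0.1%
additive floor (read noise) or √I counting noise for detector patterns;
log-normal strain dispersion for MIC panels with optional two-fold
dilution quantisation. Default study sizes — 64×52 diffuse patterns,
120-point WAXS arcs, 150-point |F| curves, 500-point SAXS curves,
52-point two-contrast NR curves, 10–100 seeded replicates — are desk-
scale choices that keep the full suite to minutes.

The generators deliberately do **not** emulate beamstop shadows,
detector gaps, mosaic spread, absolute intensity scales, absorption
flattening (CD), resolution smearing beyond a Gaussian, or model
misspecification: analysing generated data with the same forward model
is a *consistency* check. Passing round-trip tests therefore
demonstrates correctness of the estimators and their uncertainty
bookkeeping under the stated noise, not robustness to the systematic
errors of real instruments — that is what the documented degenerate-
input behaviours (bound flags, isotropic tie-breaks, unassigned-order
warnings) are for.

## Known limitations

* The CD basis is synthetic; real-data decompositions are only as good
  as the basis supplied.
* The smectic model fixes N and L_r per fit; they trade off against
  (K_C, B) if floated, and the defaults are effective coherence sizes.
* The SDP placement scan needs control-constrained widths to be
  reliably identifiable at 75:1; at much higher lipid:peptide ratios
  the placement signal vanishes into the noise.
* Scherrer lamellarity inherits the arbitrariness of K (0.9 default);
  absolute layer counts are ±10% at best.
* The NR architecture is a fixed stBLM stack; arbitrary layer
  sequences require building a custom profile, and the tether
  sub-layer parameterisation is a single homogeneous slab.
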