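# Methods

This note documents the models, numerical choices and limitations behind
`sansemble`. It is written for a reader who wants to know exactly what the
package computes and what passing its tests does and does not demonstrate.

## Scientific setting

CorA-family magnesium channels are homopentamers: a transmembrane domain
(TMD) ring above a large funnel-shaped intracellular domain (ICD). Solution
small-angle neutron scattering (SANS) of such a channel in a
contrast-matched carrier measures the orientation-averaged intensity I(q) of
the protein alone, and is sensitive to whether the pentamer is C5-symmetric
or has displaced/tilted protomers: the two architectures differ most in the
mid-q band (roughly q ≈ 0.08–0.15 Å⁻¹). The package implements the full
computational chain used to interpret such data as a conformational
*mixture*: forward scattering from structures, curve analysis, structure
refinement, ensemble generation and reweighting with an explicit symmetric
population fraction f, plus the two companion analyses (pore-radius
profiling and solid-state-NMR relaxation fitting).

All lengths are Å and momentum transfer Å⁻¹, except inside the
metadynamics module, where the collective variable and bias are in nm and
kJ/mol (the units of the production bias parameters).

## Forward SANS model

One bead per residue, placed at the residue's scattering-length-weighted
atom centroid (weights |b_element|; for single-atom toy residues the bead is
the atom). The excess scattering length of a residue is

    b_i = b_res(x_D2O, f_exch) − ρ_solv · V_res,

where b_res sums the atomic coherent lengths with the residue's labile
hydrogens exchanged to deuterium at fraction `exchange_fraction × d2o_fraction`,
ρ_solv is the solvent scattering-length density
(19.145 fm / 29.9 Å³ for pure D₂O) and V_res the residue dry volume.
The per-residue table (Σb in H₂O, labile-H count, volume) holds the
standard literature values for the 20 amino acids. Defaults: 100% D₂O,
exchange fraction 0.9 (common practice for a membrane protein measured
within hours of buffer exchange; exposed as a parameter).

Hydration layer: residues outside the membrane slab whose bead has fewer
than 14 neighbours within 7 Å receive one shell bead 3 Å outward from the
protein centroid with b = 0.06 · ρ_solv · 30 Å³ — a 6% excess-density water
layer applied only to the solvent-exposed, non-membrane surface. The slab
defaults to the z-range of the TMD annotation.

Intensities use the Debye double sum I(q) = Σᵢⱼ bᵢbⱼ sinc(q·rᵢⱼ), exact up
to 2000 beads. Above that a pair-distance histogram is used with 0.1 Å bins
whose representative distance is the b-weighted mean distance within the
bin; this cancels the leading-order binning error and keeps the
approximation below ~6·10⁻⁴ relative on 500-bead models even where the
coherent term is small. p(r) is the b-weighted pair histogram normalised so
that 4π∫p(r)dr = I(0) − Σbᵢ² (self terms excluded).

## Curve analysis

*Guinier*: weighted straight-line fit of ln I vs q², with the window grown
from the first positive-intensity point and iterated until q_max·Rg ≤ 1.3
self-consistently. Window choice is therefore algorithmic and reproducible
rather than human.

*Bayesian IFT*: p(r) on an interior r grid with p(0) = p(Dmax) = 0, solved
from min_p χ² + α‖Lp‖² where L is the second-difference operator of the
zero-padded vector (full column rank, hence a proper smoothness prior).
(α, Dmax) are chosen by maximising the Gaussian-approximation log evidence
½ln det(αLᵀL) − ½ln det(AᵀΣ⁻¹A + αLᵀL) − ½χ² − ½α‖Lp‖². Positivity is not
enforced (small negative excursions are allowed, matching common IFT
practice). Known behaviour: when a minority component extends the true
support by a few Å with negligible pair mass, the evidence prefers the
compact support — Dmax tracks the majority population.

*χ²*: χ² = Σ[(a·I_model + c − I_data)/σ]² with scale a and background c
solved by weighted linear least squares when enabled. The raw statistic is
used inside optimisers; reduced χ² appears only in reports.

## Normal-mode refinement

Elastic network: Cα nodes, uniform springs within a 10 Å cutoff (standard
anisotropic-network choice), assembled in a rotation–translation-block
basis — each annotated secondary-structure segment is a rigid block, loop
residues are single-residue (translation-only) blocks. A connected network
has exactly six zero modes; disconnection is an error, not a warning.

Finite deformations are applied as per-block screws: the linear
displacement field of each block is decomposed into its generating rigid
motion (t, ω) and applied as a finite rotation about the block centroid
plus translation. Intra-block geometry is preserved exactly at any
amplitude, and the motion agrees with linear normal-mode extrapolation to
first order. Amplitudes are expressed in Å of root-mean-square node
displacement (eigenvectors are kept orthonormal internally), so "amplitude
5" is a 5 Å-RMS deformation — a scale SANS can constrain.

Refinement minimises T = χ² + α·S over the amplitudes of the lowest
internal modes (default 10). S is the mean squared deviation of all
intra-segment Cα–Cα distances from the reference (Å²) — a declared stand-in
for "secondary-structure deviation"; note it does not penalise
inter-segment motion, so α → ∞ restores intra-segment geometry without
necessarily restoring the global conformation. The objective is cast as a
least-squares residual vector and solved with trust-region least squares
from zero amplitudes (optionally with seeded random restarts). α is chosen
at the maximum-curvature point of the (log S, log χ²) L-curve, computed by
discrete Menger curvature on axis-normalised coordinates; the chosen α is
reported so a human can override it.

## Well-tempered metadynamics

The bias protocol is standard well-tempered metadynamics: Gaussians of
width σ_G deposited every `stride` steps with heights h·exp(−V(s)/k_BΔT),
ΔT = (γ−1)T, plus an upper wall κ((s−s_wall)/rescale)^e. The default
parameter set is the production protocol used for CorA-scale pentamer
sampling: σ_G = 0.05 nm, h = 2.1 kJ/mol, stride 100, γ = 15, wall at an
Rg of 4.0 nm with κ = 10000, e = 4, offset 0, rescale 1, T = 303.15 K
(width and height quoted in the conventional PLUMED units, nm and
kJ/mol).

The dynamics engine is deliberately a toy: overdamped Langevin on either an
analytic 1-D potential (the coordinate is the CV) or a harmonic
elastic-network pentamer with an Rg collective variable over the ICD beads.
Coarse-grained force-field dynamics are out of scope; the bias algorithm
and its parameters are what is reproduced. Numerical safeguards: the bias
is accumulated on a grid for O(1) force lookups (Gaussian-sum evaluation
remains available and the grid tracks it to ~10⁻⁴ relative); the
deterministic drift per step is clipped at 5× the thermal noise amplitude,
which never binds in the sampled basin but prevents the quartic wall from
destabilising the explicit Euler step.

Free energies are estimated as F(s) = −γ/(γ−1)·V(s), averaged over bias
snapshots from the second half of the run (the instantaneous well-tempered
estimate oscillates; snapshot averaging is standard practice and reduced
seed-to-seed spread from ~0.9 to ≤0.2 k_BT on the double-well benchmark).
The benchmark itself uses bias parameters sized to the 1-D well (σ_G = 0.1,
h = 1.2 kJ/mol ≈ 0.5 k_BT): the production widths/heights are calibrated to
a pentamer-Rg CV, not to a unit-width toy potential. Unbiasing weights are
w ∝ exp(V_final(s_i)/k_BT) with the first 10% of frames discarded as
equilibration (configurable).

## BME reweighting and the symmetric fraction

Posterior weights minimise Γ(w) = ½χ²(w) − θ·S_rel(w) with
S_rel = −Σ wᵢ ln(wᵢ/w⁰ᵢ) ≤ 0. The problem is solved in its convex dual —
one multiplier per q point, weights w ∝ w⁰ exp(−Σⱼ λⱼIⱼ/θ) — with
σ-normalised variables and analytic gradients (L-BFGS). φ_eff = exp(S_rel)
reports the effective retained frame fraction. θ is selected on the
(S_rel, χ²) L-curve at one grid step *below* the maximum-curvature kink,
encoding deliberately lower trust in the simulation prior; a featureless
trace falls back to the smallest θ with φ_eff ≥ 0.1 and is flagged.

A fixed symmetric fraction f enters through the differential scheme: the
symmetric model curve is scaled so its Guinier-extrapolated I(0) matches
the data's, the residual I_diff = I_exp − f·I_sym is formed with σ
unchanged (the subtracted model is treated as noise-free — a declared
choice), and the (1−f)-scaled frame curves are reweighted against the
residual. `scan_symmetric_fraction` profiles χ²(f) over a grid (default
step 0.05, θ re-selected per f), reports argmin and the Δχ² = 1 interval
{f : χ²(f) ≤ χ²_min + 1} as the uncertainty. On synthetic two-population
data at f_true = 0.4 with 1% noise this interval covers the truth in ≈95%
of seeded repeats.

## Pore profile

HOLE-style: coordinates are rotated so the channel axis is z; at each slice
the largest sphere centred in the plane that avoids all atom vdW spheres is
found. The centre may move at most one slice-step from the previous
slice's centre (the pore path is continuous — without this constraint the
probe escapes into bulk solvent where the radius is unbounded). Per slice,
a deterministic 0.5 Å grid locates the optimum and seeded simulated
annealing polishes it, so the result always dominates a grid search. vdW
radii are Bondi values; coarse bead models (detected as one atom per
residue, or forced with `vdw_set="bead"`) use a 3.0 Å bead radius. A
channel is conducting for hydrated Mg²⁺ when the minimum profile radius is
≥ 2.4 Å; equality counts as conducting (fixed, documented convention).

## Relaxation fitting

Per-residue decays are fit with I(t) = I₀e^{−Rt} by non-linear least
squares (log-linearisation is used only for the starting guess — the
non-linear form is robust to near-zero long-delay points). Errors are
Monte-Carlo: the series is refit on replicates with Gaussian noise σ added,
and the replicate standard deviation is reported (default 1000 replicates;
error-on-error below ~3%). The default delay schedule is the 15 kHz
spin-lock R₁ρ experiment (0.05, 1, 5, 15, 50, 100, 200 ms); the R₁
schedule is also bundled. Intensity ratios between conditions carry
propagated errors and are flagged unreliable when the denominator is below
3σ.

## Synthetic data: what it emulates, what it does not

The toy pentamer (70 beads per protomer: 42 ICD + 28 TMD, TMD ring radius
11 Å, assembled by 72° rotations) reproduces the *architecture* that
matters to the analyses: a C5-symmetric reference, protomer-displaced
asymmetric states whose SANS curves differ in the mid-q band (the default
5 Å displacement / 8° tilt gives a ≈16σ peak difference at 1% noise,
located near q ≈ 0.11 Å⁻¹), a membrane slab, helical segment annotations
and a real pore. The builder verifies the ≥3σ mid-q separation and scales
the perturbation up with a warning if a user's parameters fall below it.

Noise is counting-statistics-like: σ(q) = 10⁻⁴·I(0) + 0.01·I(q)·(1+(q/0.2)²),
i.e. ~1% relative at low q growing toward high q above a small absolute
floor. Scale: 350 beads keeps a full Debye evaluation at ~40 ms, so
refinements and 100-repeat scans run on one CPU in minutes; ensembles of
8–10 frames stand in for clustered trajectory frames.

What the toys do *not* emulate: side-chain geometry and real sequence
composition (residue names cycle through a fixed set), carrier/detergent
residuals, instrument smearing, inter-protomer binding-site chemistry, and
force-field realism in the sampler. Passing tests therefore demonstrate
the *correctness of the algorithms* (forward model, inversions, optimisers,
estimators, recovery of known ground truth) — not that any particular real
dataset would yield a particular fraction.

## Degenerate inputs and tie-breaks

Constant L-curve traces are flagged degenerate (first index returned).
Ties in the pore constriction return the first z and set a tie flag.
KMeans centroids are the real frames nearest each cluster mean, so reported
centroids are always actual conformations. All stochastic stages take
explicit seeds and are bit-reproducible; the pipeline derives per-stage
seeds from one global seed.

## Known limitations

- The structure penalty S does not constrain inter-segment geometry; very
  soft S-free torsions exist in the toy pentamer and are only restrained by
  the data.
- The evidence-selected IFT Dmax is biased toward compact support when the
  p(r) tail mass is small (documented above).
- The Δχ² = 1 interval for f is a profile-likelihood construction around a
  θ-regularised fit; its ≈95% measured coverage is a property of the
  synthetic conditions, not a guaranteed confidence level.
- The metadynamics engine is first-order Euler with drift clipping; it is
  a sampler for toy landscapes, not a molecular-dynamics integrator.
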