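# Methods

This note records the models, the defaults and the judgment calls behind
them — what a maintainer needs to know before changing a constant or
trusting a number.

## Relaxation model and the simultaneous Bayesian fit

The 3Q/SQ intensity pair is modelled with a shared amplitude A0, a shared
N-exponential relaxation envelope (N = 1 or 2; default 2, which in our
experience is needed for biphasic decays while a monophasic dataset simply
drives one fraction toward 0 or the two rates together) and the closed-form
build-up factors in η and δ. The two curves get independent homoscedastic
Gaussian noise scales, which is what makes the ratio's growing late-delay
uncertainty emerge naturally in posterior-predictive space: constant
absolute noise divided by a decaying SQ mean.

Normalization: both curves are divided by max |SQ| — one common positive
scale. η is exactly invariant under a common rescaling (A0 absorbs it), and
a *single* scale is required for the shared-amplitude model to stay
self-consistent; normalizing each curve by its own maximum would silently
introduce a second, unmodelled scale between the coherence types. (Raw 3Q
and SQ data acquired with different scan counts should be corrected to a
common scale before input.)

Priors are weakly informative half-normals: η, δ ~ HN(100 s⁻¹),
R1, ΔR ~ HN(300 s⁻¹), A0 ~ N(1, 1) truncated positive (data are
normalized), noise scales ~ HN(0.2) on the normalized intensity scale,
fractions uniform on [0, 1]. Rates are parameterized as (R1, R1 + ΔR) with
ΔR ≥ 0, so every retained draw is ordered and exponential label switching
cannot occur. η ≥ 0 by default (build-up phase positive); a flag allows
signed η.

Sampling uses the affine-invariant ensemble sampler (emcee), vectorized
over walkers, initialized in a tight ball around a crude simultaneous
least-squares fit. Defaults (32 walkers × 1200 steps, 400 burn-in) are
sized so one peak fits in well under a second while posterior means on
noiseless data land within a fraction of a percent of truth; the
acceptance fraction is reported and flagged outside (0.05, 0.95). All
sampling is seeded and reproducible.

## τc and the η ↔ O² conversion

τc = 4π η_visc R³ / (3 k_B T) with R = Rg from the Guinier fit (the
self-consistent window q·Rg ≤ 1.3, iterated to a fixpoint). Two published
renderings of this relation differ by the factor 3; the standard
isotropic-rotor form is the default and a config switch
(`denominator_3=False`) exposes the other. A second switch substitutes the
hydrodynamic radius of the equivalent sphere, Rh = Rg/√(3/5). Rg is
interpreted in Å: the validator warns when a config declares tens of
nanometres, which would be an implausibly large receptor–micelle particle.
At Rg = 37.85 Å, η_visc = 1.099 cP, 298.15 K the default form gives
τc ≈ 60.6 ns. Rg uncertainty propagates by Monte Carlo over a positively
truncated Gaussian (a warning fires when sd ≥ mean/3, where truncation
distorts the distribution materially).

The conversion η = (9/10) P₂(cos θ_HH)² O² τc k² is implemented in SI
units, which requires the dipolar prefactor k = (μ₀/4π) γ_H² ħ / r_HH³;
formulations quoted in cgs-style unit systems omit the (μ₀/4π)². Defaults:
r_HH = 1.813 Å, θ_HH = 90° (geometric factor −1/2), γ_H = 2.6752×10⁸
rad s⁻¹ T⁻¹. With these values a J′-class methionine (O² = 0.25) at
τc = 65 ns corresponds to η ≈ 59 s⁻¹. O² samples outside [0, 1] are
counted and reported but never clipped on the way to reweighting targets —
the target σ must reflect the real spread; clipping happens only for
motional-class assignment. Class edges (centers are what the literature
quotes): O² < 0.30 → J′, < 0.50 → J, ≤ 0.80 → α, above → ω; configurable.

## Ensemble order parameters

P₂(x) = (3x² − 1)/2 throughout (the normalization is forced by
C_int(0) = 1). The tensor expansion and the TCF plateau are two routes to
the same quantity and are cross-asserted within 0.02 on converged
synthetic trajectories. TCF origins are dense (every frame) by default
with a configurable stride; the plateau estimator defaults to the last
point, with a tail-mean alternative. The weighted tensor expansion is one
code path shared by the uniform-weight and reweighted cases, so the
reweighting observable reduces *exactly* to the plain order parameter at
uniform weights.

Two bond-vector parameterizations are carried: Cartesian vectors in the
Cα-superposed molecular frame, and vectors rebuilt from the internal
(θ = Cγ–Sδ–Cε angle, φ = χ3 dihedral) coordinates. The internal route is
immune to residual global motion by construction and therefore bounds the
Cartesian estimate from above on real trajectories. Dihedrals follow the
IUPAC signed convention (cis = 0°), verified against MDAnalysis.
Superposition is the closed-form optimal orthogonal fit (proper rotations
only) per frame.

## Reweighting

L(w) = χ²(w) + θ S_REL(w) with squared residuals in χ² (required for
non-negativity and for χ² semantics) and S_REL the KL divergence from the
prior (uniform 1/N unless supplied). Optimization runs over unnormalized
weights u ≥ 0 under box constraints with analytic gradients; for any
objective term F with simplex gradient g = ∂F/∂w, the unnormalized
gradient is (g − Σ w g)/Σu. The w ln w term uses the 0·ln 0 = 0 limit; its
one-sided derivative at w = 0 diverges, so boundary frames receive a
bounded subgradient surrogate. This keeps the L-BFGS-B line search stable
— with the divergent form the optimizer stalls on a spurious
relative-reduction stop long before the weakly curved directions are
resolved — and frames parked at the boundary are reported.

θ is scanned on a log grid from large to small with warm starts, i.e. the
continuation path of the regularized problem. This matters beyond speed:
at very small θ the objective has a nearly flat valley (many weight
vectors fit the targets equally well, and only the entropy term
discriminates), and entering it from the well-conditioned solution above
reaches the minimum-divergence point in a handful of iterations, whereas a
cold start can terminate far along the valley. Single-θ cold solves are
still supported (tolerances: gradient 1e-8, function 1e-12, 5000
iterations, all configurable).

N_eff defaults to exp(−S_REL) — the standard effective-sample fraction in
maximum-entropy ensemble refinement — with the Kish ratio (Σw)²/(N Σw²)
selectable; both are 1 iff the weights equal the prior, and the choice is
recorded in output metadata. Elbow selection maximizes discrete curvature
on (log θ, log χ²); a plateau criterion (largest θ within 10% of the
small-θ χ²) is the alternative; flat curves return the largest θ with a
`no_elbow` flag.

## Entropy

10° bins anchored at −180°, right-closed, wrap-consistent (−180° ≡ +180°);
a half-bin-offset option exists for rotamer-boundary sensitivity checks.
Per-residue S_SC averages the marginal per-dihedral Shannon entropies over
Nχ, giving values in [0, ln 36] per residue. The alternative reading — one
joint histogram over the full χ space, divided by Nχ — is implemented but
flagged experimental: it needs vastly more sampling (36^Nχ bins) and is
not the default because per-residue magnitudes up to ~ln 36 are the
internally consistent scale for the marginal sum. k_B ≡ 1 (dimensionless
entropies); a flag multiplies by the gas constant for J mol⁻¹ K⁻¹.
Eligibility is by χ count: 1–3 included, Ala/Gly (0) and Lys/Arg (4)
excluded. Residues whose effective frame count N_eff·N falls below 100 are
flagged low-confidence but still computed. Build-up curves recompute S_SC
on growing prefixes with renormalized weights; an optional block bootstrap
(clearly labelled an extension) gives a spread where a single build-up
cannot.

## Synthetic data: what it does and does not emulate

The decay generator draws Gaussian noise around the exact closed-form
curves — by construction their quotient satisfies the ratio model
pointwise — and so tests the fitting machinery, not baseline distortions,
peak overlap or NUS-reconstruction artifacts of real spectra.

The rotamer generator runs a Markov chain over χ wells (default: the
methionine χ3 trans/gauche± wells 120° apart at the tetrahedral polar
angle θ = 109.47°, arccos(−1/3)) with Gaussian intra-well libration
(default 10°) wrapped on the circle. Kinetics are either Metropolis
proposals to a random other well gated by an exchange probability (used
when TCF decay matters) or i.i.d. draws from the stationary law (used for
reweighting/entropy fixtures, where only the stationary distribution is
contractual and frame correlation just inflates estimator noise). The
stationary mixture's order parameter has a closed form — the circular
moments E[e^{ikχ}] of a Gaussian-librating well are cos/sin(k c)·e^{−k²σ²/2}
— as does its binned entropy (wrapped-normal CDF masses), so every
downstream stage has an exact oracle. None of this emulates force-field
physics, anisotropic tumbling, or coupling between χ angles.

A consequence worth knowing when interpreting recovery tests: with
120°-spaced wells, a single scalar O² per residue is invariant under
relabeling which well carries which population (the well permutation is a
rotation about the symmetry axis). Population recovery through reweighting
is therefore assessed on the *sorted* population vector — the observable
cannot identify more, and no optimizer choice could change that. Passing
recovery tests show the machinery finds the minimum-divergence ensemble
consistent with the data; on real systems, where the targets are sparser
and the ensemble richer, the same non-uniqueness applies more broadly.

## Problem sizes and numerical choices

Fixture sizes are chosen where the estimators' sampling error is
comfortably below the assertion tolerances: 10⁵ frames for order-parameter
convergence (sampling sd ≈ 0.005 against a 0.02 band), 2×10⁴ frames × 10
residues for reweighting recovery (population recovery to ≈0.02 against a
0.03 band), 50 replicates at 2% noise for fit-calibration rates. Gradient
checks use central differences with step 1e-6 at interior points.
Determinism is treated as a contract: every stochastic stage takes an
explicit seed, the pipeline manifest records seeds, constants and SHA-256
checksums of every output, and a rerun of the demo config is byte-identical.

## Known limitations

* Relaxation fitting assumes the intensity table is already extracted;
  no spectral processing, peak picking or lineshape modelling.
* Isotropic tumbling only; no anisotropic diffusion tensor, and the SAXS
  side does no buffer subtraction or structure-factor correction.
* Reweighting targets are order parameters only (no time-dependent
  observables), and the Lagrange-dual fast path for linear observables is
  deliberately out of scope.
* Entropies are marginal per dihedral (no χ–χ correlation corrections) and
  are not converted to binding free energies.
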