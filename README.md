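# methylscape

Integrative analysis of methyl side-chain dynamics for large membrane-protein
systems: estimate methyl-axis order parameters from triple-quantum (3Q) NMR
relaxation data, compute matching order parameters from conformational
ensembles, reweight the ensemble to the NMR values with a maximum-entropy
scheme, and map the resulting side-chain conformational entropy changes
between ligand states.

It is aimed at NMR spectroscopists and simulators working on
methyl-TROSY-scale systems (e.g. a ¹³C-methionine-labelled GPCR in a
detergent micelle) where relaxation data are noisy and sparse, and where MD
ensembles need experimental restraint before thermodynamic quantities are
read off them.

## What it computes

**η and δ from interleaved 3Q/SQ decay series.** The forbidden 3Q coherence
builds up relative to the allowed SQ coherence at the intra-methyl
cross-correlated rate η; δ collects external-proton dipolar contributions.
With s = √(η² + δ²) and an N-exponential relaxation envelope,

```
I3Q(T) = 3 η tanh(sT) · A0 · Σᵢ fᵢ e^(−RᵢT)
ISQ(T) = 4 (s − δ tanh(sT)) · A0 · Σᵢ fᵢ e^(−RᵢT)
```

are fitted **simultaneously** with shared parameters and per-coherence noise
scales (affine-invariant ensemble MCMC), alongside the classical non-linear
least-squares fit of the ratio I3Q/ISQ. The simultaneous fit stays stable on
data too noisy for the ratio fit, because it never divides by small
late-delay SQ intensities.

**η → O²axis.** η = (9/10) P₂(cos θ_HH)² O²axis τc k², with
k = (μ₀/4π) γ_H² ħ / r_HH³, inverted exactly for O²axis. The rotational
correlation time τc comes from the SAXS radius of gyration via Guinier
analysis and the Stokes–Einstein relation τc = 4π η_visc R³ / (3 k_B T),
with Rg and viscosity uncertainty propagated by Monte Carlo. O² means are
binned into the empirical motional classes J′ / J / α / ω.

**O²axis from ensembles.** The static second-rank tensor expansion
O² = (3/2)(⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²) − 1/2 over
unit Sδ–Cε bond vectors (Cartesian, after Cα superposition, or rebuilt from
the internal (θ, χ3) spherical parameterization), cross-validated against
the long-time plateau of the internal TCF C(τ) = ⟨P₂(μ̂(t)·μ̂(t+τ))⟩.

**Maximum-entropy reweighting.** Because O² is quadratic in the weighted
moments, frame weights are found by direct box-constrained L-BFGS-B
minimization of L(w) = χ²(w) + θ·S_REL(w) over unnormalized weights with
analytic gradients, rather than the Lagrange-dual solution that applies
only to linear observables. θ is chosen at the elbow of the χ²-vs-θ
L-curve; N_eff = exp(−S_REL) tracks how much of the prior ensemble
survives.

**Side-chain conformational entropy.** Reweighted χ-angle histograms on
10° bins give the dimensionless per-residue entropy
S_SC = (1/Nχ) Σ_χ [−Σ_k P(k) ln P(k)] for residues with 1–3 χ angles
(Ala/Gly excluded: no χ; Lys/Arg excluded: 4 χ), plus build-up convergence
curves and ΔS maps between ligand states.

## Worked example

The bundled demo simulates two ligand states of a three-methionine system
(rotamer-jump ensembles with known populations, noisy 3Q/SQ curves with η
set consistently from the state's true O² and the configured τc), then runs
every stage:

```
$ methylscape run-all --demo
... INFO tau_c = 60.66 ± 1.94 ns
{
  "Apo":     {"eta_true": 32.77, "o2_true": 0.150, "theta_selected": 10.0,
              "neff": 0.965, "chi2": 25.29, "entropy_total": 7.641},
  "agonist": {"eta_true": 78.11, "o2_true": 0.357, "theta_selected": 100.0,
              "neff": 0.582, "chi2": 9.16, "entropy_total": 7.102}
}
```

Reading the numbers: the Stokes–Einstein τc from Rg = 37.85 Å and
η_visc = 1.099 cP at 298 K is 60.7 ns; the agonist state was simulated with
a more concentrated χ3 rotamer distribution (0.70/0.15/0.15 vs
0.45/0.35/0.20), so its true O² is higher (0.357 vs 0.150), the reweighting
has to move further from the uniform prior (N_eff 0.58 vs 0.96), and its
total side-chain entropy ends lower (7.10 vs 7.64). The per-residue ΔS
table written to `runs/demo/delta_entropy_Apo_vs_agonist.tsv` is negative
for every methionine:

```
residue_id  s_a        s_b        delta_s
M100        2.587105   2.376262   -0.210843
M101        2.495842   2.357335   -0.138507
M102        2.558379   2.367966   -0.190413
```

Library use mirrors the statsmodels pattern — a model built from data whose
`fit()` returns a results object:

```python
from methylscape import RelaxationModel, read_intensity_table

sq, tq = read_intensity_table("peaks.tsv")["M244"]
res = RelaxationModel(sq, tq).fit_bayes(n_exp=2, seed=7)
print(res.summary())          # posterior mean/sd/CI for eta, delta, rates
res.plot_fit()                # data + 100 posterior build-up curves
```

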