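# ccrama

Residue-level Ramachandran distributions from cross-correlated NMR spin
relaxation.

Intrinsically disordered proteins exist as ensembles of interconverting
conformations, so a single structure cannot describe them; what is
experimentally accessible and biologically meaningful is the per-residue
distribution of backbone dihedrals p(φ, ψ).  Cross-correlated relaxation
(CCR) rates — interference effects between pairs of relaxation mechanisms
(dipole–dipole, dipole–CSA, CSA–CSA) — encode the relative orientation of
interaction vectors spanning a residue and therefore carry exactly this
information, but convoluted with local dynamics.  `ccrama` implements the
full deconvolution and inversion pipeline for structural biologists and
NMR spectroscopists working with such data, and a synthetic-ensemble
framework to validate it self-consistently.

## The method

Each CCR rate factorizes into structure and dynamics,

    Γ = A · τ,      A = Σ_k K_k · P2(cos θ_k(φ, ψ)),

where `A` is the structural amplitude of a rigid model backbone (P2 of
the projection angles between the two interaction vectors, times physical
prefactors) and `τ` the effective correlation time (integral of the
amplitude-normalized time correlation function).  Two rates whose
interactions share one rigid peptide plane have known, conformation-
independent amplitudes; their measured values yield local correlation
times (dynamical proxies) `τ_NNH` and `τ_CCCA`.  Dividing each of the
eight *remote* rates by a proxy approximates its ensemble-averaged
amplitude, which is linear in the dihedral distribution:

    Γ_j(p) = τ_j · Σ_{φ,ψ} p_{φ,ψ} A_j(φ, ψ).

The distribution is then inferred as the maximum-a-posteriori point of a
Gaussian likelihood with an entropy prior,

    min_p   T · D_KL(p ‖ q)  +  ½ Σ_j (Γ_j(p) − Γ_j)² / σ_j²,

over the probability simplex, with a strictly positive coil-like prior
grid q, temperature T = 1 by default (or selected on an L-curve), and
σ_j = 1.  Predicted and reference distributions are compared with the
Jensen–Shannon divergence (log2, bounded [0, 1]) at 10° graining.

## Worked example

Forward-generate noiseless rates from a known two-basin distribution
(60% α-helical, 40% β-extended) and invert them against the built-in
synthetic coil prior:

```python
from ccrama import (build_rate_surfaces, REMOTE_RATE_IDS, standin_coil_prior,
                    Basin, true_grid, synthetic_rates, InversionProblem,
                    maxent_map, coarsen, js_divergence)

surfaces = build_rate_surfaces(resolution=1.0)
remote = {rid: surfaces[rid] for rid in REMOTE_RATE_IDS}

truth = true_grid([Basin(-63, -43, spread=15, weight=0.6),
                   Basin(-135, 135, spread=15, weight=0.4)], resolution=1.0)
taus = {rid: 3e-9 for rid in remote}
rates, _ = synthetic_rates(truth, taus, remote, noise_sigma=0.0)

prior = standin_coil_prior(resolution=1.0)
result = maxent_map(InversionProblem(rates, remote, taus, prior))
posterior = coarsen(result.grid, 10.0)
```

This prints, with the rates listed first:

```
CAHA_C     Gamma =   +4.384 s^-1
CAHA_Cm1   Gamma =   -5.778 s^-1
CAHA_NHN1  Gamma =   -3.480 s^-1
Cm1_C      Gamma =   -7.752 s^-1
HAHN1_C    Gamma =   +3.905 s^-1
NHN_C      Gamma =   -0.702 s^-1
NHN_CAHA   Gamma =   -4.833 s^-1
NHN_NHN1   Gamma =   +4.940 s^-1
chi2 = 0.145   D_KL(p||q) = 0.597
JS(posterior, truth) at 10 deg = 0.089
alpha-basin mass = 0.554  (true 0.600)
beta-basin mass  = 0.367  (true 0.400)
```

The eight remote rates (a few s⁻¹ at 800 MHz, signed by the
gyromagnetic-ratio convention) suffice to recover the basin weights to
within 0.05 and the full 36×36 distribution to a Jensen–Shannon
divergence of 0.09 — i.e. the posterior is much closer to the truth than
the coil prior it started from.

## Command line

The same pipeline is exposed as subcommands operating on files
(HDF5 containers for trajectories/surfaces/grids, CSV rate tables):

    ccrama simulate --n-residues 10 --seed 1 --out chain.h5 --truth ref.h5
    ccrama rates    --traj chain.h5 --out rates.csv
    ccrama infer    --rates rates.csv --out posterior.h5
    ccrama compare  --pred posterior.h5 --ref ref.h5 --out js.tsv

Angles are degrees, times nanoseconds, rates s⁻¹ at the file boundaries;
every run writes a provenance sidecar (config hash, version, seed).

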