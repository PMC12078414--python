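# Methods

## The model

A cross-correlated relaxation (CCR) rate reports the interference between
two relaxation mechanisms of equal tensor rank — two dipolar couplings, a
dipolar coupling and a chemical shift anisotropy (CSA), or two CSAs.  In
isotropic solution the observable rate is proportional to the
zero-frequency spectral density of the time correlation function (TCF)

    C_ab(t) = < P2( a(0) . b(t) ) >,        P2(x) = 1.5 x^2 - 0.5,

where `a` and `b` are the unit vectors of the two interactions (dipolar
bond vectors or CSA principal axes).  Factorizing J(0) = C(0) * tau
separates a **structural amplitude** — the population average of P2 of the
projection angle, times physical prefactors — from an **effective
correlation time** tau, the integral of the amplitude-normalized TCF.

With a rigid model backbone whose only degrees of freedom are the central
residue's dihedrals (phi, psi), each rate's amplitude becomes a surface

    A(phi, psi) = sum_k  K_k * P2( cos theta_k(phi, psi) ),

tabulated on a 1-degree grid.  The ensemble-averaged amplitude of a
dihedral distribution p is linear in p: `A(p) = sum p(phi,psi) A(phi,psi)`.

Prefactors per mechanism class (SI units; sigma in ppm converted once
inside the prefactor; gyromagnetic ratios signed, so rate signs follow the
physical convention):

* DD/DD: (2/5) (mu0 hbar / 4 pi)^2 g_a g_b g_c g_d / (r_ab^3 r_cd^3)
* DD/CSA: (4/15) (mu0 hbar / 4 pi) g_a g_b g_u B0 (sigma_kk - sigma_zz) /
  r_ab^3, summed over the in-plane axes k = x, y
* CSA/CSA: (8/45) g_u g_v B0^2 (sigma_kk - sigma_zz)(sigma_ll - sigma_zz),
  double sum over k, l = x, y

## The rate registry

Ten interferences are registered declaratively (mechanism class, atom
names with residue offsets, distance mode, amplitude-known flag), so a
correction to an entry never touches math code.  Eight are *remote* (no
shared spin; their amplitudes depend on phi_i, psi_i of the central
residue): three DD/DD pairs among N_iH_i, C_a_iH_a_i and N_{i+1}H_{i+1};
four DD/CSA pairs of those dipoles (plus the sequential H_a_i–H_{i+1}
dipole) with the carbonyl CSAs C'_{i-1} and C'_i; and the C'_{i-1}/C'_i
CSA/CSA interference.  Two have conformation-independent (known)
amplitudes because both interactions sit in one rigid peptide plane:
N-CSA with the NH dipole, and C'-CSA with the C'CA dipole.  Only the
H_a_i–H_{i+1} dipole keeps its instantaneous r(t)^-3 inside the TCF; all
bonded dipoles use trajectory-mean distances in the prefactor.

## Geometry and CSA conventions

The rigid backbone uses standard peptide internal coordinates (trans
omega = 180 deg, N–CA 1.458 A, CA–C' 1.525 A, C'–N 1.329 A, C'=O 1.231 A,
tetrahedral H_a placement at phi + 120 deg) with amide and alpha proton
distances 1.01 and 1.09 A; all values are overridable from a TOML config.

CSA tensors are residue-type-independent averages: carbonyl
(249.4, 191.1, 87.9) ppm with the xx axis 37 deg from the C'–N bond, and
amide nitrogen stored as principal-value *differences* (170, 0) ppm —
the tensor is effectively axial (sigma_yy ~ sigma_zz), so the y-component
drops out of every sum — with xx 20 deg from the N–H bond.  Frame
convention: zz is the normal of the plane spanned by the two frame bonds
(C'N/C'O for C', NH/NC' for N); xx is obtained by rotating the reference
bond by +alpha *toward the second bond*; yy completes a right-handed
triad.  The sign of alpha is not determined by the magnitude-only tensor
specification; the toward-the-second-bond choice is declared once here and
used consistently, which is all the self-consistent validation requires.

Known-amplitude rates carry the same dipolar 1/r^3 factor as the general
DD/CSA prefactor, so that tau = Gamma / A is a time.

## TCF estimation

`P2(a.b)` is decomposed into the six symmetric products of vector
components, and each channel is cross-correlated with FFTs (zero-padded to
at least n + max_lag, so no circular wrap contaminates the used lags).
Normalization is unbiased: every lag is divided by its number of
contributing origins, because the long tail matters for J(0).  Each TCF is
additionally symmetrized as the mean of the forward and reversed-order
correlations.  Distance weighting multiplies the channels by r(t)^-3 on
the weighted side only.

J(0) is a plain trapezoidal integral at the native 1 ps spacing —
multi-exponential fitting is deliberately avoided as artifact-prone.
Default integration bounds: 10 ns (disordered systems) and 20 ns (folded);
a TCF whose tail retains more than 1% of C(0) at the bound is flagged
non-converged through the warning channel.

A per-residue spectrum cache makes the marginal cost of one rate a single
inverse FFT; the cache holds references to its key objects (ids must stay
unique) and is cleared after each residue to bound memory.

## Dynamical proxies

The two known-amplitude rates give peptide-plane correlation times
`tau = Gamma / A`.  A residue's proxy averages the two encompassing
planes: tau_NNH from the amide rates of planes i and i+1, tau_CCCA from
the carbonyl rates of planes i-1 and i.  Terminal residues missing one
plane fall back to the single available plane and are flagged (and
excluded from default reporting).  The blended proxy
tau_opt = 0.7 tau_CCCA + 0.3 tau_NNH is applied, when selected, only to
remote rates that involve the amide proton; the weights are configurable
because their transferability across protein systems is not established.
Dividing each remote rate by its proxy approximates the structural
amplitude; the carbonyl-plane proxy is the default.

## MaxEnt inversion

The MAP estimate minimizes over the probability simplex

    T * D_KL(p || q)  +  (1/2) sum_j (Gamma_j(p) - Gamma_j)^2 / sigma_j^2

with Gamma_j(p) = tau_j * sum p * A_j linear in p, sigma_j = 1 by default,
and q a strictly positive prior grid (bins below 1e-12 are floored before
normalization so D_KL stays finite).  D_KL uses natural logarithms; the
temperature absorbs any base change.  Stationarity confines the optimum to
the exponential family p(c) ~ q exp(-(1/T) sum_j c_j tau_j A_j) whose
dimension equals the number of rates, not the grid size; the solver
iterates the damped fixed point c_j <- (Gamma_j(p) - Gamma_j)/sigma_j^2
(damping 0.5, at most 500 iterations) and polishes c with BFGS using the
closed-form gradient Cov_p(F)(c - r/sigma^2)/T.  The objective is convex
in p, so independent initializations meet at the same optimum; the default
start is the prior (c = 0) and the returned point is never worse than the
prior.  Optimization runs at 1-degree resolution; reporting coarsens to
10 degrees.

Temperature: T = 1 by default.  An optional L-curve solves across a
temperature ladder and picks the maximum-Menger-curvature corner of the
(log10 chi2, log10 D_KL) curve; a flat curve falls back to T = 1 with a
warning.  Automatic corner detection replaces visual inspection, which is
the only practical choice for an unattended pipeline.

## Synthetic ensembles

The generator emulates the *statistical* structure of disordered-protein
trajectories, not molecular mechanics: no force field, solvent or
thermostat.  Per residue, basin occupancy follows a continuous-time Markov
jump process (destination drawn from the stationary weights) among
canonical basins (alpha (-63,-43), beta (-135,135), polyproline-II
(-75,150), left-handed helix (60,45)); within a basin the angles relax as
a wrapped Ornstein-Uhlenbeck jitter.  Chains are built frame by frame from
rigid internal coordinates, and global tumbling is an isotropic
rotational-diffusion quaternion walk with D_r = 1/(6 tau_rot), composed
with a vectorized prefix scan.  Defaults: dt = 1 ps, 1e6 frames (1 us),
basin exchange 5 ns, jitter 50 ps, spread 15 deg, tau_rot 3 ns — sized so
TCFs converge well inside the 10 ns integration bound.

The "true" reference grid is the analytic wrapped-Gaussian mixture, so
recovery targets are independent of sampling noise; the empirical
histogram path (10 x 10 deg bins, optional 100 ps graining) is also
provided.  The shipped coil prior is a synthetic stand-in: a broad
four-basin mixture with a 5% uniform floor, strictly positive everywhere.
Any strictly positive prior grid on the same resolution is accepted in its
place.

What the generator does **not** emulate — and hence what passing
benchmarks do not show about real data: anisotropic overall tumbling,
correlated phi/psi dynamics within and between residues beyond the shared
jump process, side-chain and neighbor-sequence effects on basin geometry,
residue-specific CSA tensors, chemical exchange, and experimental noise
structure beyond independent Gaussians.

## Benchmark designs and their statistics

* **Estimator equivalence** — FFT vs. direct O(N^2) correlation on 2048
  random frames; agreement to 1e-9 absolute.
* **Rigid rotor** — one frozen conformer tumbling at tau_rot = 2 ns for
  1 us.  The conformer is chosen by a deterministic rule: the grid point
  maximizing the weakest rate's normalized amplitude, so no rate sits near
  a magic-angle null where relative error diverges.  Note the statistical
  floor: an origin-averaged TCF integrated over a 10 ns window from a
  T = 1000 tau record carries a Monte-Carlo error of roughly 6% (one
  sigma) on each J(0), measured over independent seeds.  Individual rates
  therefore scatter by several percent to tens of percent around the
  closed form A * tau_rot at this trajectory length; the
  structure/dynamics *separation* Gamma/tau_Gamma = A is exact to
  floating-point precision because both factors come from the same TCF.
* **Uniform-dynamics proxy diagnostic** — 12 scored frozen conformers
  spread over the four basins, sharing one 2 ns tumbling walk, 2 us long;
  the regression of Gamma/tau_CCCA against the true amplitudes pools 96
  points whose common-mode tumbling noise cancels in the ratio.  The 2 us
  length sets the residual per-point scatter near 3%, which the slope
  (through the origin) and R^2 of the pooled cloud average down further.
* **Two-basin recovery** — noiseless forward rates from alpha/beta
  mixtures (weights 0.1–0.9, spread 15 deg), inverted at T = 1 against
  the stand-in coil prior; basin weights are read back as probability
  mass in ±45 deg windows around the basin centers.
* **End-to-end miniature** — a 10-residue disordered chain (four-basin
  mixtures with per-residue weights, 5 ns exchange, 3 ns tumbling, 1 us),
  full rates → proxies → inversion → Jensen-Shannon comparison against
  the analytic truth at 10 deg; the 8 interior residues with both peptide
  planes are scored.

## Numerical choices and degenerate inputs

* Grid convention everywhere: bin centers at -180 + res/2 + k res on
  [-180, 180); +180 deg wraps to -180.
* Jensen-Shannon divergence uses log2 (bounded [0, 1]); 0 log 0 = 0 by
  convention.
* Zero-anisotropy CSA interference: the rate is exactly 0 and the
  correlation time is undefined (NaN) rather than an error.
* Colinear CSA frame bonds raise a degenerate-frame error; missing atoms
  name the atom in the error.
* Integration beyond the available lag range raises a truncation error
  (the CLI clamps to the trajectory span with a warning).
* All stochastic operations take explicit seeds; the MaxEnt path is
  deterministic.

## Limitations

* The amplitude model is a rigid single-conformer backbone per (phi,
  psi); correlated internal motions that modulate the interaction
  geometry beyond (phi, psi) are absorbed into the effective correlation
  times and bias proxies at the few-percent level.
* The exact identities and internal geometry of published CCR experiment
  sets vary; the registry ships a canonical set and is meant to be edited
  declaratively to match a given experimental battery.
* Proxy blend weights (0.7/0.3) are system-dependent; treat them as a
  starting point, not a constant of nature.
* Glycine, proline and chain termini need special treatment that this
  package does not attempt; terminal residues are flagged and excluded
  from default reporting.
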