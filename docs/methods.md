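# Methods

## Model

The package integrates the ground state of a mixed quantum system: an
explicit electronic subsystem (nuclei with charges `Z_i`, `N_e` electrons)
coupled to an environment of `N_Q` quantum Drude oscillators (QDOs) and
`N_pc` fixed point charges. Each QDO is a fixed center of charge `+q` and
a drudon of charge `-q`, mass `mu`, bound by a harmonic well
`1/2 mu omega^2 |r_d - R_c|^2`. Drudons are distinguishable, spinless
quantum particles.

Interaction rules:

* electronic subsystem internal terms (e–e, e–n, n–n): bare Coulomb;
* a drudon interacts by Coulomb with every other charged particle except
  its own center (harmonic well instead) and the point charges of its
  parental QDO (omitted);
* center–own-point-charge terms are rigid intramolecular constants and
  excluded by default (`include_center_own_pc=True` restores them);
* every pair with at least one environment member (drudon, center, point
  charge) is damped: `q_i q_j m(r)/r` with pair length
  `sigma_ij = sqrt(sigma_i sigma_j)`. Electrons and nuclei carry the
  system-wide `sigma_e` for these cross terms. The electronic Hamiltonian
  itself is never damped.

All fixed-charge constants (n–n, n–center, n–pc, center–center,
center–pc, pc–pc) are computed once and cached on the system; they cancel
in interaction energies only when compositions match, so they are always
included in totals.

Damping kernels (`x = r/sigma`): `erf(x)`, `1-exp(-x^2)`, `1-exp(-x^4)`,
and the Slater 1s charge-smearing form `1-exp(-2x)(1+x)`. All satisfy
`0 <= m <= 1`, monotone growth to 1, and a finite `m(r)/r` at contact;
`sigma=0` reproduces bare Coulomb bit-exactly. The geometric-mean
combination rule is symmetric and propagates an undamped particle to
undamped pairs.

The TIP4P-style water QDO places `+0.605 e` on each hydrogen and
`-1.21 e` on the M site, 0.2667 angstrom from O on the HOH bisector; O is
chargeless. The oscillator parameters are `(q, omega, mu) = (1.1973,
0.6287, 0.3656)` a.u. (argon: `1.3314, 0.7272, 0.3020`). The oscillator
center defaults to the M site; `center_site="O"` is available because the
attachment point is a modelling choice with visible short-range
consequences (see the overpolarization discussion below).

Internal units are hartree/bohr; geometry files are angstrom
(1 A = 1.8897259886 bohr).

## Trial wave function

`Psi = Psi_e * Psi_Q * J_eQ`:

* `Psi_e = det(S_up) det(S_dn) exp(J2 + J3)`. Molecular orbitals are
  linear combinations of contracted Cartesian Gaussians or hydrogenic
  `exp(-zeta r)` functions centered on nuclei only. The two-body Jastrow
  uses the Pade cusp form `u(r) = c r/(1+b r)` with `c = 1/4` for parallel
  and `1/2` for antiparallel spins — the Kato cusp conditions — plus a
  Gaussian remodulation `sum_n g_n exp(-zeta_n r^2)` per spin channel.
  The three/four-body term is `sum_{i<j} chi(r_i)^T gamma chi(r_j)` over an
  uncontracted Gaussian Jastrow basis with symmetric `gamma`; it is
  evaluated as `(V gamma) V^T` summed over the strict upper triangle, so a
  walker-scale evaluation costs O(N_e^2 Q_J) multiplications after the
  O(N_e Q_J) basis projection (measured wall-time exponent ~2 over
  N_e = 8..64 at fixed Q_J).
* `Psi_Q = exp(-1/2 d^T A d)` over the stacked drudon displacements, with
  `A` symmetric positive definite (`3N_Q(3N_Q+1)/2` parameters). The 1/2
  convention makes `A = mu omega I` the exact ground state of uncoupled
  oscillators. Nodeless.
* `J_eQ = exp(mu_e^T B d)` with `mu_e = sum_i Z_i R_i - sum_j r_j` (the
  nuclear-charge-weighted dipole origin; any fixed origin is equivalent up
  to a constant absorbed into the optimum of `B`). Strictly positive.

No one-body electron–nucleus Jastrow is used: the hydrogenic orbitals of
the all-electron test atoms carry their nuclear cusps exactly.

Local energies are assembled per particle from analytic log-derivatives,
`lap Psi/Psi = lap log|Psi| + |grad log|Psi||^2`, with drudon kinetic
terms weighted by `1/(2 mu_i)`; all factor gradients, Laplacians and the
parameter derivatives `O_k = d log|Psi|/d p_k` are verified against
central finite differences to 1e-6 relative in the tests. `|det| <
1e-300` is treated as a node and reported via a zero sign, never an
exception.

## Variational Monte Carlo

Particle-by-particle Metropolis: per sweep, all electrons first and then
all drudons, each block in a fresh random order; trial moves are isotropic
Gaussians of width `delta/sqrt(m)` (`m_e = 1`, drudon mass `mu_i`), which
equalizes kinetic sampling across species. Acceptance uses
`min(1, |Psi'/Psi|^2)`; the ratio recomputes only the factors touching the
moved particle. Amplitudes are tuned before production by multiplicative
feedback `delta <- delta * clip(acc/0.5, 0.5, 2)` over measurement windows
until each species sits at 50% +/- 2%.

Estimators: per-sweep population means form a time series; the error bar
comes from a blocking analysis (block-size doubling until at least 16
blocks remain, taking the largest stderr on the way — a plateau detector
that needs no autocorrelation fit). A 50-seed calibration test keeps the
reported stderr within [0.7, 1.4] of the empirical scatter of means.

Optimization is stochastic reconfiguration: `dp = -lr (S + eps I)^{-1} g`
with `S` the covariance of the `O_k` and `g_k = 2 cov(E_L, O_k)`,
`eps = 1e-3` doubling on failed solves, learning rate 0.3 by default.
Orbital coefficients are excluded (the determinant stays fixed). After an
update `A` is re-symmetrized and eigenvalue-floored back to positive
definite if needed. Between updates the current sample is reused with
weights `|Psi_new/Psi_old|^2`; it is redrawn when the overlap proxy
`<w>^2/<w^2>` drops below 0.95 (the threshold is a package default, kept
configurable). Starting from `A = 2 mu omega I` on one argon oscillator,
the optimizer reaches the exact energy to 1e-3 hartree and `A` to 2% in
well under 200 iterations.

One master `numpy` Generator drives each run with fully vectorised draws
over the walker axis, so results are bit-reproducible given
`(seed, n_walkers)`.

## Diffusion Monte Carlo

Importance-sampled fixed-node DMC with a particle-by-particle update.
Each particle carries `tau_i = dtau/m_i` (mirroring the VMC mass
scaling): drift `v_bar tau_i` plus Gaussian diffusion of variance
`tau_i`, where `v_bar` is the Umrigar-rescaled velocity
`v (-1 + sqrt(1 + 2 v^2 tau_i))/(v^2 tau_i)` (→ `v` for small steps,
saturating at `sqrt(2/tau_i)` near nodes). Every single-particle move is
accepted or rejected against the importance-sampled Green's function;
electron moves that change the determinant sign are rejected (fixed
node), drudon moves are never node-checked (the drudon factor is
nodeless, so the environment sector carries no fixed-node error).

Branching uses continuous weights
`w *= exp(-tau_eff (E_L_bar - E_ref))` with the symmetrized capped local
energy: deviations from the running estimate are hard-clipped at
`alpha sqrt(N/tau)` with `alpha = 0.2` (branching only — the energy
estimator always uses the uncapped local energy). `tau_eff` is `dtau`
scaled by the accepted-to-proposed squared-displacement ratio. Population
control is a stochastic comb (systematic resampling) every step: it
preserves total weight exactly and keeps the walker count constant; the
reference energy relaxes as
`E_ref = E_est - ln(W_tot/W_target)/(10 dtau)` per step, a damping that
holds the total weight within a few percent of target.

Defaults `dtau = 0.005` a.u., 100+ walkers. For a deliberately wrong
drudon Gaussian the fixed-node energy is exact up to time-step bias; the
suite checks recovery at `dtau = 0.005` and a linear extrapolation over
`{0.02, 0.01, 0.005}`. Note a practical interaction: for very poor trial
functions on few-particle systems the `alpha sqrt(N/tau)` cap half-width
can reach the bulk of the local-energy distribution and the clipping
itself biases the branching (an effect that vanishes as `tau -> 0` or as
the ansatz improves); validation systems are chosen so the cap is inert,
and the cap parameter is exposed for sensitivity checks.

## Reference oracles

Independent of the sampling code paths: `(3/2) omega` isolated-oscillator
energies; `alpha = q^2/(mu omega^2)` polarizabilities; exact
diagonalization of the mass-weighted dynamical matrix of dipole-coupled
oscillators (`E_0 = 1/2 sum_k omega_k`, raising a polarization-catastrophe
error on non-positive modes), whose long-range interaction reproduces
`-C6/R^6` with `C6 = (3/4) alpha^2 omega`; and a 1D/radial
finite-difference eigensolver with Richardson extrapolation (for radial
problems the grid is `x_j = j h` so the ghost Dirichlet point sits exactly
at `r = 0`, which restores clean `h^2` convergence for Coulomb-like
wells). The dipole-truncated coupling is also available inside the
sampler (`qdo_coupling="dipole"`, pure-QDO systems only) so DMC can be
benchmarked against the closed form on identical Hamiltonians.

## Observables

Interaction, solvation and environment-induced binding-energy changes are
supermolecular differences of independently seeded runs with quadrature
error propagation; inputs tagged with a configuration or cage-deformation
label must match, otherwise the combination is refused. Scans
(`pes_scan`) tabulate points (CSV/JSON, hartree and meV at
1 hartree = 27211.386245988 meV), record failed points without aborting,
and flag a point as overpolarization-unstable when its raw local-energy
variance exceeds 10x the scan median. The raw weighted variance of the
mixed-distribution local energy was chosen as the flag input after
experiments showed block-energy variance depends on when (not whether) a
bare-Coulomb run collapses, whereas the mixed-estimator variance of a
collapsed population is reproducibly an order of magnitude above the
stable baseline.

Cage machinery: `deform_cage` moves every water's oxygen by `dR` along
the unit vector from the geometric center of the subsystem nuclei,
translating the hydrogens rigidly (intramolecular geometry preserved to
machine precision). `generate_fixture_cage` builds synthetic rigid-water
cages (r_OH = 0.9572 A, HOH = 104.52 deg) with oxygens on a sphere,
random orientations, O–O > 2.4 A, reproducible by seed. It emulates the
geometry and packing of a solvation shell but none of the hydrogen-bond
network structure of a real snapshot, so tests built on it validate the
machinery (deformation, solvation bookkeeping, stability flags), not the
energetics of any particular liquid structure.

## Validation systems and what they show

Desk-scale, all-electron systems anchor every stochastic path:

* one argon-parameter QDO with the exact Gaussian (zero-variance VMC,
  variance < 1e-18 hartree^2) and with wrong Gaussians (variational
  ordering, SR recovery, DMC exactness and time-step extrapolation);
* hydrogen with the exact and a `zeta = 0.8` 1s orbital (VMC exact /
  variational at the analytic `zeta^2/2 - zeta`; DMC projects to -1/2);
* two dipole-coupled argon QDOs at 20 and 40 bohr against the normal-mode
  solution;
* an overpolarization toy — a hydrogen atom facing one TIP4P water QDO
  with the oscillator on the O site so the bare system exposes a naked
  supercritical `+q` center while the damped system is screened by the
  M-site charge. A DMC scan over center distances {0.8, 3, 4, 6} bohr
  triggers the variance flag at short range with bare Coulomb and at no
  point with erf damping at sigma = 0.5 bohr.

These verify the estimators, the samplers and the interaction rules.
They do not probe large-`N_e` electronic structure (no pseudopotentials,
no orbital generation, no multideterminant nodes) — production-scale
embedding runs would add those ingredients on top of the machinery tested
here.

## Known limitations

* No pseudopotentials (and hence no locality/T-move/DLA channels), no
  periodic boundary conditions, no environment flexibility, no forces.
* The dipolar `J_eQ` cannot represent short-range electron–environment
  correlation; at contact distances the residual local-energy variance is
  visibly larger even for damped interactions.
* Orbitals are inputs (JSON basis + MO coefficients or built-in
  hydrogenics); the package does not generate them.
* The hard-clip form of the local-energy cap is one member of the family
  of bounded-rewweighting schemes; its `alpha sqrt(N/tau)` scale is the
  documented default.
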