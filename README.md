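# elqdo

Quantum Monte Carlo for an explicit electronic subsystem embedded in an
environment of **quantum Drude oscillators** (QDOs) and point charges, with
short-range **damped Coulomb coupling**.

## The problem

Simulating a molecule inside a large environment (a solvation shell, a
molecular cage) at full electronic-structure accuracy is prohibitively
expensive. A quantum Drude oscillator replaces each environment molecule by
a fixed center of charge `+q` and a single light quantum particle (the
*drudon*, charge `-q`, mass `mu`) bound by a harmonic well of frequency
`omega`. The three parameters reproduce the molecule's leading response
properties — dipole polarizability `alpha = q^2/(mu omega^2)` and
dispersion coefficients — so a bath of QDOs delivers polarization and
dispersion at a cost that grows only quadratically with its size. Polar
molecules additionally carry fixed point charges (for water, the TIP4P
arrangement: `+0.605 e` on each hydrogen and `-1.21 e` on an M site
0.2667 A from the oxygen along the HOH bisector).

The joint Hamiltonian

```
H = H_e  +  H_Q  +  V_coupling
```

couples the standard Born–Oppenheimer electronic Hamiltonian `H_e`
(electrons + nuclei, bare Coulomb) to the oscillator bath `H_Q` and to the
electron–environment Coulomb terms. Every pair involving an environment
member is damped, `q_i q_j m(r)/r`, with a kernel `m(r)` (erf, Gaussian,
fourth-power exponential, or Slater s-wave smearing) that is finite at
contact and recovers `1/r` beyond a few damping lengths `sigma`. Without
damping, electrons drift onto positive environment charges and the energy
diverges — the polarization catastrophe known from QM/MM embeddings.

The joint ground state is integrated by variational Monte Carlo (VMC) with
stochastic-reconfiguration parameter optimization, and by fixed-node
diffusion Monte Carlo (DMC). The trial wave function is a product

```
Psi = det(S_up) det(S_dn) e^{J_ee} * e^{-1/2 d^T A d} * e^{mu_e^T B d}
```

of a Slater–Jastrow electronic factor, a correlated Gaussian over the
stacked drudon displacements `d` (symmetric positive-definite `A`), and a
positive dipolar electron–drudon coupling (`mu_e` the electronic dipole,
`B` a `3 x 3N_Q` matrix). Drudons are distinguishable and nodeless, so DMC
is exact for the environment sector regardless of `A`.

## Worked example

```python
import numpy as np
from elqdo import (ElQdoSystem, make_qdo, AnsatzParameters,
                   VmcSettings, run_vmc, DmcSettings, run_dmc,
                   DipoleSystem, coupled_dipole_energy)

# one argon-parameter oscillator (q=1.3314, omega=0.7272, mu=0.3020 a.u.)
system = ElQdoSystem(qdos=[make_qdo("Ar", [0.0, 0.0, 0.0])])

# exact Gaussian ground state: zero-variance check
exact = AnsatzParameters.qdo_ground_state(system)
est = run_vmc(exact, system, VmcSettings(n_steps=300, n_walkers=32, seed=1))
print(est.mean, est.variance)   # 1.0908 2.12e-32

# deliberately wrong Gaussian: VMC is variational, DMC projects it out
wrong = AnsatzParameters.qdo_ground_state(system, scale=1.5)
print(run_vmc(wrong, system, VmcSettings(n_steps=400, n_walkers=64, seed=2)).mean)
# 1.1850  (exact VMC value (3 omega/4)(s + 1/s) = 1.1817; above 1.0908)
print(run_dmc(wrong, system, DmcSettings(target_population=200, seed=2)).mean)
# 1.0925 +/- 0.0088  (nodeless, hence exact up to time-step bias)

# two dipole-coupled oscillators vs the closed-form normal-mode energy
pair = (make_qdo("Ar", [0, 0, 0]), make_qdo("Ar", [0, 0, 20.0]))
print(coupled_dipole_energy(DipoleSystem(qdos=pair)))   # 2.181599
dim = ElQdoSystem(qdos=pair, qdo_coupling="dipole")
print(run_dmc(AnsatzParameters.qdo_ground_state(dim), dim,
              DmcSettings(target_population=200, seed=5)).mean)  # 2.181601(13)
```

The first number is `(3/2) omega` for argon; the VMC energy of the wrong
ansatz sits above it (variational principle) while DMC recovers it because
the drudon sector has no nodes. The coupled-dipole energies agree with the
exact diagonalization of the `3N x 3N` mass-weighted dynamical matrix, and
at large separation their interaction follows `-C6/R^6` with
`C6 = (3/4) alpha^2 omega`.

A thin CLI wraps the library: `elqdo run config.yaml`, `elqdo scan`,
`elqdo solvation`, `elqdo fixtures --n-waters 8 --radius 4.5 --seed 1
--out cage.xyz`.

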