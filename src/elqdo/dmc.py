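"""Fixed-node diffusion Monte Carlo for the mixed electron-drudon system.

Importance-sampled drift-diffusion with a particle-by-particle update:
each particle carries its own effective time step ``tau_i = dtau / m_i``
(mirroring the VMC mass scaling), the drift velocity is rescaled near
nodes following Umrigar's scheme, and each single-particle move is
accepted or rejected against the importance-sampled Green's function.
Electron moves that flip the trial-wave-function sign are rejected
(fixed node); the drudon Gaussian is nodeless, so drudon moves are never
node-checked and the drudon sector carries no fixed-node error.

Branching uses continuous weights with a local-energy cap of half-width
``alpha * sqrt(N / tau)`` (hard clip) and a stochastic-comb population
control every step that preserves total weight exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import RunError
from .model import ElQdoSystem, potential_energy
from .vmc import (
    EnergyEstimate,
    VmcSettings,
    blocked_statistics,
    initialize_walkers,
    metropolis_sweep,
    tune_amplitudes,
)
from .wavefunction import AnsatzParameters, evaluate

__all__ = [
    "DmcSettings",
    "rescaled_drift",
    "capped_local_energy",
    "population_comb",
    "dmc_step",
    "run_dmc",
    "run_dmc_tau_series",
]


@dataclass
class DmcSettings:
    """Run-control parameters for DMC."""

    dtau: float = 0.005
    alpha_cut: float = 0.2
    target_population: int = 100
    n_blocks: int = 40
    steps_per_block: int = 100
    n_equil_blocks: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.dtau <= 0:
            raise RunError("dtau must be > 0")
        if self.alpha_cut <= 0:
            raise RunError("alpha_cut must be > 0")
        if self.target_population < 10:
            raise RunError("population must be >= 10")


def rescaled_drift(v, tau):
    """Umrigar-rescaled drift velocity, batched over (..., 3).

    ``v_bar = v (-1 + sqrt(1 + 2 v^2 tau)) / (v^2 tau)``; smoothly equals
    ``v`` for small ``v^2 tau`` and saturates at ``sqrt(2/tau)`` near a
    node, where the raw quantum velocity diverges.
    """
    v = np.asarray(v, dtype=float)
    v2 = np.sum(v * v, axis=-1, keepdims=True)
    x = v2 * tau
    small = x < 1e-10
    safe = np.where(small, 1.0, x)
    factor = np.where(small, 1.0 - x / 2.0, (-1.0 + np.sqrt(1.0 + 2.0 * safe)) / safe)
    return v * factor


def capped_local_energy(eloc, e_est, alpha, n_particles, tau):
    """Clip the deviation E_L - E_est to +/- alpha sqrt(N/tau) (Zen-style cap)."""
    half_width = alpha * np.sqrt(n_particles / tau)
    return e_est + np.clip(np.asarray(eloc, float) - e_est, -half_width, half_width)


def population_comb(weights, rng):
    """Systematic resampling ('comb') to equal weights.

    Returns ``(indices, new_weight)`` such that taking ``walker[indices]``
    with uniform weight ``new_weight`` preserves the total weight exactly.
    """
    w = np.asarray(weights, dtype=float)
    n = len(w)
    total = float(np.sum(w))
    if total <= 0:
        raise RunError("population collapse: total weight is zero")
    cum = np.cumsum(w)
    u = (rng.uniform() + np.arange(n)) / n * total
    idx = np.searchsorted(cum, u, side="left")
    return np.clip(idx, 0, n - 1), total / n


def _masses(system: ElQdoSystem):
    order = [("e", i, 1.0) for i in range(system.n_electrons)]
    order += [("d", i, float(system.qdo_mu[i])) for i in range(system.n_qdos)]
    return order


def dmc_step(params, system, electrons, drudons, weights, e_ref, e_est, settings, rng,
             state=None):
    """Advance the whole population one DMC time step (in place).

    Returns ``(block_energy_contrib, eloc_moments, state)`` where the
    contribution is the weighted mean (uncapped) local energy after the
    step, ``eloc_moments = (sum_w, sum_w_E, sum_w_E2)`` feeds the raw
    local-energy variance (the overpolarization diagnostic), and ``state``
    caches the wave-function evaluation between steps.
    """
    nw = electrons.shape[0]
    tau = settings.dtau
    n_particles = system.n_electrons + system.n_qdos
    if state is None:
        state = evaluate(params, system, electrons, drudons)
    eloc_old = _local_from_state(system, state, electrons, drudons)

    acc_disp2 = np.zeros(nw)
    prop_disp2 = np.zeros(nw)
    for species, idx, mass in _masses(system):
        tau_i = tau / mass
        coords = electrons if species == "e" else drudons
        gkey = "grad_e" if species == "e" else "grad_d"
        v = state[gkey][:, idx, :]
        vbar = rescaled_drift(v, tau_i)
        eta = rng.standard_normal((nw, 3))
        r_old = coords[:, idx, :].copy()
        r_new = r_old + vbar * tau_i + np.sqrt(tau_i) * eta
        coords[:, idx, :] = r_new
        new_state = evaluate(params, system, electrons, drudons)
        # fixed node for electrons: reject sign flips and nodes
        if species == "e":
            node_ok = (new_state["sign"] == state["sign"]) & (new_state["sign"] != 0)
        else:
            node_ok = np.ones(nw, dtype=bool)
        v_new = new_state[gkey][:, idx, :]
        vbar_new = rescaled_drift(v_new, tau_i)
        fwd = r_new - r_old - vbar * tau_i
        bwd = r_old - r_new - vbar_new * tau_i
        log_g = (np.sum(fwd * fwd, axis=-1) - np.sum(bwd * bwd, axis=-1)) / (2.0 * tau_i)
        log_ratio = 2.0 * (new_state["log_psi"] - state["log_psi"]) + log_g
        accept = node_ok & (np.log(rng.uniform(size=nw)) < log_ratio)
        disp2 = np.sum((r_new - r_old) ** 2, axis=-1)
        prop_disp2 += disp2
        acc_disp2 += np.where(accept, disp2, 0.0)
        coords[~accept, idx, :] = r_old[~accept]
        for key in state:
            state[key] = np.where(
                accept.reshape((-1,) + (1,) * (state[key].ndim - 1)),
                new_state[key],
                state[key],
            )

    eloc_new = _local_from_state(system, state, electrons, drudons)
    with np.errstate(invalid="ignore"):
        frac = np.where(prop_disp2 > 0, acc_disp2 / np.where(prop_disp2 > 0, prop_disp2, 1.0), 1.0)
    tau_eff = tau * frac
    ecap_old = capped_local_energy(eloc_old, e_est, settings.alpha_cut, n_particles, tau)
    ecap_new = capped_local_energy(eloc_new, e_est, settings.alpha_cut, n_particles, tau)
    weights *= np.exp(np.clip(-tau_eff * (0.5 * (ecap_old + ecap_new) - e_ref), -50.0, 50.0))

    total = float(np.sum(weights))
    if not np.isfinite(total) or total <= 0:
        raise RunError("population collapse: non-finite or zero total weight")
    energy = float(np.sum(weights * eloc_new) / total)
    moments = (total, float(np.sum(weights * eloc_new)),
               float(np.sum(weights * eloc_new**2)))
    idx, w_new = population_comb(weights, rng)
    electrons[...] = electrons[idx]
    drudons[...] = drudons[idx]
    for key in state:
        state[key] = state[key][idx]
    weights[...] = w_new
    return energy, moments, state


def _local_from_state(system, state, electrons, drudons):
    kin = 0.0
    if system.n_electrons:
        kin = kin - 0.5 * np.sum(
            state["laplog_e"] + np.sum(state["grad_e"] ** 2, axis=-1), axis=-1
        )
    if system.n_qdos:
        kin = kin - np.sum(
            (state["laplog_d"] + np.sum(state["grad_d"] ** 2, axis=-1))
            / (2.0 * system.qdo_mu),
            axis=-1,
        )
    return kin + potential_energy(system, electrons, drudons)


def run_dmc(params, system, settings: DmcSettings, rng=None, warn_unoptimized=False):
    """Fixed-node DMC mixed-estimator energy with blocked error bars.

    Walkers are first thermalized by a short tuned VMC run, then propagated
    for ``n_blocks`` blocks of ``steps_per_block`` steps; the first
    ``n_equil_blocks`` blocks are discarded.  The reference energy is
    relaxed toward ``E_est - ln(W_tot / W_target) / dtau`` each block.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    vset = VmcSettings(n_walkers=settings.target_population, n_steps=1,
                       n_tune_steps=20, seed=settings.seed)
    electrons, drudons = initialize_walkers(system, settings.target_population, rng)
    de, dd = tune_amplitudes(params, system, vset, rng, electrons, drudons)
    vset = replace(vset, delta_e=de, delta_d=dd)
    for _ in range(100):
        metropolis_sweep(params, system, electrons, drudons, vset, rng)
    weights = np.ones(settings.target_population)

    state = evaluate(params, system, electrons, drudons)
    e_est = float(np.mean(_local_from_state(system, state, electrons, drudons)))
    e_ref = e_est
    block_energies = []
    populations = []
    m0 = m1 = m2 = 0.0
    for block in range(settings.n_blocks + settings.n_equil_blocks):
        block_acc = []
        for _ in range(settings.steps_per_block):
            energy, moments, state = dmc_step(
                params, system, electrons, drudons, weights, e_ref, e_est,
                settings, rng, state=state,
            )
            block_acc.append(energy)
            if block >= settings.n_equil_blocks:
                m0 += moments[0]
                m1 += moments[1]
                m2 += moments[2]
            # population feedback, damped over ~10 time steps
            w_tot = float(np.sum(weights))
            e_ref = e_est - np.log(w_tot / settings.target_population) / (10.0 * settings.dtau)
        be = float(np.mean(block_acc))
        e_est = 0.5 * (e_est + be)
        populations.append(float(np.sum(weights)))
        if block >= settings.n_equil_blocks:
            block_energies.append(be)

    est = blocked_statistics(block_energies)
    est.extra["block_energies"] = list(block_energies)
    # variance of block energies: drift-sensitive overpolarization diagnostic
    est.extra["block_variance"] = float(np.var(block_energies))
    # secular-drift z-score between run halves: a collapsing (overpolarized)
    # run never reaches stationarity, so its halves disagree strongly
    half = len(block_energies) // 2
    if half >= 4:
        h1 = blocked_statistics(block_energies[:half])
        h2 = blocked_statistics(block_energies[half:])
        denom = np.sqrt(h1.stderr**2 + h2.stderr**2)
        est.extra["drift_z"] = float(abs(h2.mean - h1.mean) / denom) if denom > 0 else 0.0
    # raw (uncapped) local-energy variance
    if m0 > 0:
        est.variance = max(m2 / m0 - (m1 / m0) ** 2, 0.0)
    est.extra["populations"] = populations
    est.extra["tau"] = settings.dtau
    return est


def run_dmc_tau_series(params, system, settings: DmcSettings, taus: Sequence[float],
                       rng=None):
    """Repeat :func:`run_dmc` over a list of time steps (for extrapolation).

    The number of steps per block is scaled inversely with tau so each run
    covers a comparable total imaginary time.
    """
    out = []
    for tau in taus:
        scale = settings.dtau / tau
        s = replace(
            settings,
            dtau=tau,
            steps_per_block=max(10, int(round(settings.steps_per_block * scale))),
        )
        out.append(run_dmc(params, system, s, rng=rng))
    return out
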