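"""Variational Monte Carlo sampling and stochastic-reconfiguration optimization.

Sampling follows the particle-by-particle Metropolis scheme: within each
sweep all electrons are proposed first and then all drudons, each block in
random order, with isotropic Gaussian trial moves of amplitude
``delta / sqrt(mass)`` so the diffusion length is species-balanced.  The
move amplitudes are auto-tuned to a 50% acceptance rate before production.

All walker-level operations are vectorised over the walker axis; a run is
bit-reproducible given ``(seed, n_walkers)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, RunError
from .model import ElQdoSystem
from .wavefunction import (
    AnsatzParameters,
    apply_parameter_update,
    delta_log_psi,
    local_energy,
    log_abs_psi,
    parameter_log_derivatives,
)

__all__ = [
    "VmcSettings",
    "EnergyEstimate",
    "initialize_walkers",
    "propose_move",
    "metropolis_sweep",
    "tune_amplitudes",
    "run_vmc",
    "sr_step",
    "correlated_energy_delta",
    "optimize_ansatz",
    "blocked_statistics",
]


@dataclass
class VmcSettings:
    """Run-control parameters for VMC."""

    delta_e: float = 1.0
    delta_d: float = 1.0
    n_steps: int = 1000
    n_walkers: int = 32
    n_tune_steps: int = 40
    n_equil_steps: int = 100
    block_size: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.delta_e <= 0 or self.delta_d <= 0:
            raise ConfigurationError("move amplitudes must be > 0")
        for name in ("n_steps", "n_walkers", "n_tune_steps", "block_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


@dataclass
class EnergyEstimate:
    """A Monte Carlo energy with blocked error bar.

    ``stderr`` comes from a blocking analysis (block-size doubling until
    the estimate plateaus), so it accounts for autocorrelation; ``n_eff``
    is the implied number of effectively independent samples.
    """

    mean: float
    stderr: float
    variance: float
    n_eff: float
    extra: dict = field(default_factory=dict)

    def __repr__(self):
        return f"EnergyEstimate(mean={self.mean:.6f}, stderr={self.stderr:.2e})"


def blocked_statistics(series) -> EnergyEstimate:
    """Blocking analysis of a (possibly autocorrelated) scalar time series."""
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    mean = float(np.mean(x))
    var = float(np.var(x))
    if var == 0.0 or n < 4:
        return EnergyEstimate(mean=mean, stderr=np.sqrt(var / max(n, 1)), variance=var, n_eff=n)
    best = 0.0
    y = x.copy()
    while len(y) >= 16:
        se = np.sqrt(np.var(y, ddof=1) / len(y))
        best = max(best, se)
        y = y[: 2 * (len(y) // 2)].reshape(-1, 2).mean(axis=1)
    n_eff = var / best**2 if best > 0 else float(n)
    return EnergyEstimate(mean=mean, stderr=best, variance=var, n_eff=n_eff)


def initialize_walkers(system: ElQdoSystem, n_walkers: int, rng: np.random.Generator):
    """Electrons scattered around the nuclei, drudons around their centers."""
    ne, nq = system.n_electrons, system.n_qdos
    electrons = np.zeros((n_walkers, ne, 3))
    if ne:
        if system.n_nuclei == 0:
            raise ConfigurationError("electrons require at least one nucleus")
        anchors = system.nuclei_pos[np.arange(ne) % system.n_nuclei]
        electrons = anchors + 0.7 * rng.standard_normal((n_walkers, ne, 3))
    drudons = np.zeros((n_walkers, nq, 3))
    if nq:
        width = 1.0 / np.sqrt(2.0 * system.qdo_mu * system.qdo_omega)
        drudons = system.centers + width[:, None] * rng.standard_normal((n_walkers, nq, 3))
    return electrons, drudons


def move_amplitude(system: ElQdoSystem, settings: VmcSettings, species: str, index: int) -> float:
    """Gaussian proposal width Delta_i = delta / sqrt(mass_i)."""
    if species == "e":
        return settings.delta_e  # m_e = 1
    return settings.delta_d / np.sqrt(system.qdo_mu[index])


def propose_move(system, settings, species, index, position, rng):
    """Trial position r' = r + Delta_i eta with eta ~ N(0, 1)^3."""
    amp = move_amplitude(system, settings, species, index)
    position = np.asarray(position, dtype=float)
    return position + amp * rng.standard_normal(position.shape)


def metropolis_sweep(params, system, electrons, drudons, settings, rng):
    """One particle-by-particle Metropolis sweep over all walkers (in place).

    Electrons first, then drudons, each block in random order; the
    acceptance ratio |Psi'/Psi|^2 is evaluated by recomputing only the
    factors the moved particle touches.  Returns per-species
    ``{(accepted, proposed)}`` counts.
    """
    counts = {"e": [0, 0], "d": [0, 0]}
    nw = electrons.shape[0]
    order = [("e", i) for i in rng.permutation(system.n_electrons)]
    order += [("d", i) for i in rng.permutation(system.n_qdos)]
    for species, idx in order:
        coords = electrons if species == "e" else drudons
        trial = propose_move(system, settings, species, idx, coords[:, idx, :], rng)
        dlog, sign_new = delta_log_psi(params, system, electrons, drudons, species, idx, trial)
        logu = np.log(rng.uniform(size=nw))
        accept = (logu < 2.0 * dlog) & (sign_new != 0)
        coords[accept, idx, :] = trial[accept]
        counts[species][0] += int(np.sum(accept))
        counts[species][1] += nw
    return counts


def tune_amplitudes(params, system, settings, rng, electrons=None, drudons=None,
                    target: float = 0.5, tol: float = 0.02, max_windows: int = 60):
    """Converge per-species acceptance to 50% by multiplicative feedback.

    Each window runs ``n_tune_steps`` sweeps; amplitudes are scaled by
    ``clip(acc / target, 0.5, 2)`` until all species with particles sit
    within ``target +/- tol``.  Returns the frozen ``(delta_e, delta_d)``.
    """
    import dataclasses

    s = dataclasses.replace(settings)
    if electrons is None or drudons is None:
        electrons, drudons = initialize_walkers(system, s.n_walkers, rng)
    converged = False
    for _ in range(max_windows):
        acc = {"e": [0, 0], "d": [0, 0]}
        for _ in range(s.n_tune_steps):
            c = metropolis_sweep(params, system, electrons, drudons, s, rng)
            for k in acc:
                acc[k][0] += c[k][0]
                acc[k][1] += c[k][1]
        ok = True
        for k, delta_name in (("e", "delta_e"), ("d", "delta_d")):
            if acc[k][1] == 0:
                continue
            rate = acc[k][0] / acc[k][1]
            if abs(rate - target) > tol:
                ok = False
                factor = float(np.clip(rate / target, 0.5, 2.0))
                setattr(s, delta_name, getattr(s, delta_name) * factor)
        if ok:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("amplitude tuning did not converge; using best amplitudes")
    return s.delta_e, s.delta_d


def run_vmc(params, system, settings, rng=None, tune=True, return_samples=False,
            sample_every: int = 1, log_path=None):
    """Sample |Psi|^2 and return the blocked energy estimate.

    With ``return_samples`` the walker configurations collected every
    ``sample_every`` sweeps are attached to ``extra["samples"]`` (used by
    the optimizer).  ``log_path`` appends one JSON line per block.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    electrons, drudons = initialize_walkers(system, settings.n_walkers, rng)
    if tune:
        de, dd = tune_amplitudes(params, system, settings, rng, electrons, drudons)
        import dataclasses

        settings = dataclasses.replace(settings, delta_e=de, delta_d=dd)
    for _ in range(settings.n_equil_steps):
        metropolis_sweep(params, system, electrons, drudons, settings, rng)

    series = np.empty(settings.n_steps)
    all_eloc = []
    acc = {"e": [0, 0], "d": [0, 0]}
    samples_e, samples_d = [], []
    for step in range(settings.n_steps):
        c = metropolis_sweep(params, system, electrons, drudons, settings, rng)
        for k in acc:
            acc[k][0] += c[k][0]
            acc[k][1] += c[k][1]
        eloc = local_energy(params, system, electrons, drudons)
        if not np.all(np.isfinite(eloc)):
            bad = ~np.isfinite(eloc)
            if np.all(bad):
                raise RunError("all walkers produced non-finite local energies")
            eloc = np.where(bad, np.nanmean(eloc[~bad]), eloc)
        series[step] = np.mean(eloc)
        all_eloc.append(eloc.copy())
        if return_samples and step % sample_every == 0:
            samples_e.append(electrons.copy())
            samples_d.append(drudons.copy())

    est = blocked_statistics(series)
    flat = np.concatenate(all_eloc)
    est.variance = float(np.var(flat))
    nb = settings.n_steps // settings.block_size
    if nb >= 2:
        bm = series[: nb * settings.block_size].reshape(nb, -1).mean(axis=1)
        est.extra["block_variance"] = float(np.var(bm))
    est.extra["acceptance"] = {
        k: (v[0] / v[1] if v[1] else None) for k, v in acc.items()
    }
    est.extra["amplitudes"] = (settings.delta_e, settings.delta_d)
    est.extra["final_walkers"] = (electrons, drudons)
    if return_samples:
        est.extra["samples"] = (
            np.concatenate(samples_e) if samples_e else np.zeros((0, system.n_electrons, 3)),
            np.concatenate(samples_d) if samples_d else np.zeros((0, system.n_qdos, 3)),
        )
    if log_path is not None:
        nb = max(1, settings.n_steps // settings.block_size)
        with open(log_path, "a") as fh:
            for b in range(nb):
                chunk = series[b * settings.block_size : (b + 1) * settings.block_size]
                if len(chunk):
                    fh.write(json.dumps({"block": b, "energy": float(np.mean(chunk))}) + "\n")
    return est


# ----------------------------------------------------------------------
# stochastic reconfiguration
# ----------------------------------------------------------------------

def sr_step(params, system, electrons, drudons, eloc, learning_rate=0.3, eps=1e-3,
            max_eps_escalations=8):
    """One stochastic-reconfiguration update from a |Psi|^2 sample.

    Solves ``(S + eps I) dp = -lr * g`` with ``S_kl = <O_k O_l> - <O_k><O_l>``
    and ``g_k = 2 (<E_L O_k> - <E_L><O_k>)``; determinant parameters are
    excluded, and A is projected back to symmetric positive definite if the
    step breaks it.  Badly conditioned S escalates eps.
    """
    O = parameter_log_derivatives(params, system, electrons, drudons)
    if O.shape[-1] == 0:
        return params, {"gradient_norm": 0.0, "eps": eps}
    O = O.reshape(-1, O.shape[-1])
    eloc = np.asarray(eloc, float).ravel()
    Obar = O.mean(axis=0)
    Oc = O - Obar
    S = (Oc.T @ Oc) / len(eloc)
    g = 2.0 * (Oc.T @ (eloc - eloc.mean())) / len(eloc)
    for _ in range(max_eps_escalations):
        try:
            dp = np.linalg.solve(S + eps * np.eye(len(g)), -learning_rate * g)
        except np.linalg.LinAlgError:
            eps *= 2.0
            continue
        if np.all(np.isfinite(dp)):
            break
        eps *= 2.0
    else:
        raise RunError("stochastic reconfiguration step failed: S irreparably conditioned")
    new = apply_parameter_update(params, system, dp)
    return new, {"gradient_norm": float(np.linalg.norm(g)), "eps": eps, "step": dp}


def correlated_energy_delta(params_old, params_new, system, electrons, drudons,
                            eloc_old=None):
    """Reweighted energy change between two parameter sets on one sample.

    Weights ``w = |Psi_new / Psi_old|^2`` on a sample drawn from
    ``|Psi_old|^2``; returns ``(delta_energy, overlap)`` where the overlap
    proxy is ``<w>^2 / <w^2> in (0, 1]``.  The caller resamples when the
    overlap drops below its threshold.
    """
    lo, _ = log_abs_psi(params_old, system, electrons, drudons)
    ln, _ = log_abs_psi(params_new, system, electrons, drudons)
    logw = 2.0 * (ln - lo)
    logw -= np.max(logw)
    w = np.exp(logw)
    if not np.any(w > 0):
        raise RunError("total loss of overlap between consecutive wave functions")
    overlap = float(np.mean(w) ** 2 / np.mean(w**2))
    e_new = float(np.sum(w * local_energy(params_new, system, electrons, drudons)) / np.sum(w))
    if eloc_old is None:
        eloc_old = local_energy(params_old, system, electrons, drudons)
    return e_new - float(np.mean(eloc_old)), overlap


def optimize_ansatz(params, system, settings, n_iterations=100, learning_rate=0.3,
                    eps=1e-3, overlap_threshold=0.95, rng=None, sample_every=2,
                    target_tol=None, target_energy=None):
    """Energy minimization by stochastic reconfiguration with correlated sampling.

    Each iteration draws (or reuses) a |Psi|^2 sample, applies
    :func:`sr_step`, and only resamples when the correlated-sampling
    overlap with the sampling wave function drops below
    ``overlap_threshold``.  Returns ``(params, history)`` where history
    rows carry the iteration energy and overlap.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    history = []
    sample = None
    sampling_params = params
    for it in range(n_iterations):
        if sample is None:
            est = run_vmc(sampling_params, system, settings, rng=rng, tune=(it == 0),
                          return_samples=True, sample_every=sample_every)
            if it == 0:
                import dataclasses

                settings = dataclasses.replace(
                    settings,
                    delta_e=est.extra["amplitudes"][0],
                    delta_d=est.extra["amplitudes"][1],
                )
            sample = est.extra["samples"]
        se, sd = sample
        eloc = local_energy(params, system, se, sd)
        # reweight onto the current parameters if the sample is stale
        if params is not sampling_params:
            lo, _ = log_abs_psi(sampling_params, system, se, sd)
            ln, _ = log_abs_psi(params, system, se, sd)
            w = np.exp(2.0 * (ln - lo - np.max(ln - lo)))
            energy = float(np.sum(w * eloc) / np.sum(w))
        else:
            w = None
            energy = float(np.mean(eloc))
        new_params, info = sr_step(params, system, se, sd, eloc,
                                   learning_rate=learning_rate, eps=eps)
        _, overlap = correlated_energy_delta(params, new_params, system, se, sd, eloc)
        history.append({"iteration": it, "energy": energy, "overlap": overlap,
                        "gradient_norm": info["gradient_norm"]})
        params = new_params
        if overlap < overlap_threshold:
            sample = None
            sampling_params = params
        if target_energy is not None and target_tol is not None and \
                abs(energy - target_energy) < target_tol and it >= 5:
            break
    return params, history
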