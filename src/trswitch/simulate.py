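"""Seeded generators for the two simulation studies and an exact-model sampler.

Both study generators produce deterministic profiles Omega*h(t) (Omega=1e3)
plus i.i.d. Gaussian measurement noise, observed in several experimental
conditions with replicated, irregularly spaced sampling (spacings drawn
uniformly from [0.5, 1.5] time units, shared across replicates within an
experiment).  The target gene is driven by a steep Hill-type transcription
ODE of the regulator profiles, which the piecewise-constant switch model
approximates closely.

``simulate_repressed_activation`` emulates a two-experiment repressed
activation: candidate f1 activates the target, f2 suppresses that
activation, and four decoys (a condition-invariant copy of f2, a
constant-shift candidate, a reflected repressor, and a small-range copy of
f1) probe the selection machinery.

``simulate_soc1`` emulates the Arabidopsis flowering-time network around
SOC1: activators FT and AGL24, repressors FLC and SVP, positive
autoregulation by SOC1 itself, and three non-regulator network genes
(FD, AP1, LFY) plus CO as decoys, observed in four conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import StatePartition, TargetData, solve_trs_ode

__all__ = [
    "SimulationDesign",
    "simulate_repressed_activation",
    "simulate_soc1",
    "simulate_from_trs",
]

OMEGA = 1_000.0


@dataclass
class SimulationDesign:
    """Shared design knobs of the study generators."""

    n_replicates: int = 4
    horizon: float = 10.0
    omega: float = OMEGA
    noise_sd: float = OMEGA / 20.0  # 50 units
    spacing: tuple = (0.5, 1.5)
    delta: float = 0.345  # target mRNA degradation rate
    hill_n: float = 150.0  # steepness of the Hill activation terms
    profile_k: float = 3.5  # logistic steepness of the TF profiles (per time unit)
    extra_noise: dict = field(default_factory=dict)  # per-gene noise multipliers


def _logistic(t, t0, k=2.0, lo=0.1, hi=0.9, rising=True):
    s = 1.0 / (1.0 + np.exp(-(k if rising else -k) * (t - t0)))
    return lo + (hi - lo) * s


def _hill(p, thr, n):
    p = np.maximum(p, 0.0)
    return p**n / (p**n + thr**n)


def _sample_times(L, spacing, rng):
    times = [0.0]
    while True:
        t = times[-1] + rng.uniform(*spacing)
        if t > L:
            break
        times.append(t)
    return np.array(times)


def _emit_long(rows, profiles_det, times, reps, sd, extra, rng):
    """Observe deterministic per-gene curves with i.i.d. Gaussian noise."""
    for exp, tvec in times.items():
        for gene, curve in profiles_det[exp].items():
            mean = curve(tvec)
            mult = extra.get(gene, 1.0)
            for r in range(reps):
                noisy = np.maximum(mean + rng.normal(0.0, sd * mult, tvec.size), 0.0)
                for t, v in zip(tvec, noisy):
                    rows.append((exp, f"r{r + 1}", float(t), gene, float(v)))


def _to_frame(rows):
    return pd.DataFrame(rows, columns=["experiment", "replicate", "time", "gene", "value"])


# ---------------------------------------------------------------------------
# study 1: repressed activation, six candidates, two experiments
# ---------------------------------------------------------------------------


def simulate_repressed_activation(
    design: SimulationDesign | None = None,
    rng: np.random.Generator | int | None = None,
    include_target_candidate: bool = False,
):
    """Two-experiment repressed-activation study.

    Returns ``(df, truth)`` — the long-format dataset and a truth manifest.
    Candidate shapes (unit scale, multiplied by Omega):

    * f1 — the activator: rises through 0.5 at t=2 in experiment 1; starts
      high and falls through 0.5 at t=7 in experiment 2.
    * f2 — the repressor of f1's activation: rises through 0.5 at t=6
      (exp 1) and t=3 (exp 2).
    * f3 — f2's experiment-2 shape in *both* experiments.
    * f4 — constant low (exp 1) / constant high (exp 2).
    * f5 — an imperfect reflection of f2 (an AND-activation alternative):
      mirrored shape with slightly offset transition times, a low-amplitude
      wobble and a noisier observation process.
    * f6 — f1's shape compressed to a smaller range.

    The target's transcription rate is a steep Hill gate
    ``basal + amp * H(f1) * (1 - H(f2))`` so only the (f1 on, f2 off) state
    transcribes fast.
    """
    design = design or SimulationDesign()
    rng = np.random.default_rng(rng)
    if not design.extra_noise:
        design.extra_noise = {"f5": 3.0}
    k = design.profile_k
    shapes = {
        "exp1": {
            "f1": lambda t: _logistic(t, 2.0, k),
            "f2": lambda t: _logistic(t, 6.0, k),
            "f3": lambda t: _logistic(t, 3.0, k),
            "f4": lambda t: np.full_like(np.asarray(t, float), 0.15),
            "f5": lambda t: _logistic(t, 6.8, k, lo=0.15, hi=0.95, rising=False)
            + 0.06 * np.sin(2 * np.pi * np.asarray(t, float) / 2.2),
            "f6": lambda t: _logistic(t, 2.0, k, lo=0.35, hi=0.65),
        },
        "exp2": {
            "f1": lambda t: _logistic(t, 7.0, k, rising=False),
            "f2": lambda t: _logistic(t, 3.0, k),
            "f3": lambda t: _logistic(t, 3.0, k),
            "f4": lambda t: np.full_like(np.asarray(t, float), 0.85),
            "f5": lambda t: _logistic(t, 2.3, k, lo=0.15, hi=0.95, rising=False)
            + 0.06 * np.sin(2 * np.pi * np.asarray(t, float) / 2.2 - 0.72),
            "f6": lambda t: _logistic(t, 7.0, k, lo=0.35, hi=0.65, rising=False),
        },
    }
    thr, n = 0.5, design.hill_n
    basal, amp = 0.02, 0.1
    delta = design.delta
    profiles_det = {}
    for exp, sh in shapes.items():
        def rate(t, sh=sh):
            return basal + amp * _hill(sh["f1"](t), thr, n) * (1.0 - _hill(sh["f2"](t), thr, n))

        h0 = basal / delta  # basal steady state
        sol = solve_ivp(
            lambda t, m, rate=rate: rate(t) - delta * m,
            (0.0, design.horizon),
            [h0],
            dense_output=True,
            rtol=1e-8,
            atol=1e-10,
        )
        target_curve = sol.sol
        curves = {g: (lambda t, f=f: design.omega * f(t)) for g, f in sh.items()}
        curves["target"] = lambda t, s=target_curve: design.omega * s(np.atleast_1d(t))[0]
        profiles_det[exp] = curves

    times = {exp: _sample_times(design.horizon, design.spacing, rng) for exp in shapes}
    rows: list = []
    _emit_long(rows, profiles_det, times, design.n_replicates, design.noise_sd,
               design.extra_noise, rng)
    df = _to_frame(rows)
    candidates = ["f1", "f2", "f3", "f4", "f5", "f6"]
    if include_target_candidate:
        candidates.append("target")
    truth = {
        "target": "target",
        "candidates": candidates,
        "true_set": ["f1", "f2"],
        "thresholds": {"f1": 0.5 * design.omega, "f2": 0.5 * design.omega},
        "logic": {"f1": "activator", "f2": "repressor-of-activation"},
        "delta": delta,
        "omega": design.omega,
        "noise_sd": design.noise_sd,
        "basal_rate": basal * design.omega,
        "active_rate": (basal + amp) * design.omega,
    }
    return df, truth


# ---------------------------------------------------------------------------
# study 2: SOC1 flowering-time network, four experiments
# ---------------------------------------------------------------------------


def simulate_soc1(
    design: SimulationDesign | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Four-condition SOC1 study (time in days).

    SOC1 transcription requires FT active with both repressors FLC and SVP
    inactive; AGL24 and SOC1 itself (positive feedback) each multiply the
    open-gate rate.  FD, AP1, LFY and CO are network genes that never gate
    SOC1 transcription directly; their profiles are condition-invariant
    (the same curve in every experiment), so any regulatory role ascribed
    to them in the permissive condition is contradicted in the others.
    The four conditions are designed so that every true TF is needed:

    * exp1 — permissive: the gate opens when SVP clears (day 4) and closes
      when the FT pulse ends (day 8), with AGL24- and self-boosts raising
      the rate inside the window — a staircase whose onset and offset edges
      are tied to different regulators.
    * exp2 — pre-induced SOC1 (high initial level), FLC stays high: the
      target decays despite the same FT pulse — only FLC can explain this.
    * exp3 — pre-induced, SVP stays high: decay again, forcing SVP.
    * exp4 — pre-induced, FT low: decay although SOC1 starts above its own
      feedback threshold, ruling out autoregulation alone and forcing FT.
    """
    design = design or SimulationDesign(hill_n=50.0, profile_k=2.0)
    rng = np.random.default_rng(rng)
    k = design.profile_k
    lo_c, hi_c = 0.12, 0.88

    def const(level):
        return lambda t: np.full_like(np.asarray(t, float), level)

    def pulse(t, t_on, t_off, lo=0.1, hi=0.9):
        t = np.asarray(t, float)
        s = 1.0 / (1.0 + np.exp(-k * (t - t_on))) / (1.0 + np.exp(k * (t - t_off)))
        return lo + (hi - lo) * s

    # network genes that are not regulators: identical curve in every
    # condition (condition-invariant housekeeping-like dynamics)
    decoys = {
        "FD": lambda t: _logistic(t, 2.8, k, rising=False),
        "AP1": lambda t: _logistic(t, 2.0, k, rising=False),
        "LFY": lambda t: _logistic(t, 2.5, k),
        "CO": lambda t: _logistic(t, 1.5, k),
    }
    shapes = {
        "exp1": {
            "FT": lambda t: pulse(t, 2.5, 8.0),
            "FLC": lambda t: _logistic(t, 1.2, k, rising=False),
            "SVP": lambda t: _logistic(t, 4.0, k, rising=False),
            "AGL24": lambda t: _logistic(t, 5.0, k),
            **decoys,
        },
        "exp2": {
            "FT": lambda t: pulse(t, 2.5, 8.0),
            "FLC": const(hi_c),
            "SVP": lambda t: _logistic(t, 2.0, k, rising=False),
            "AGL24": lambda t: _logistic(t, 5.0, k),
            **decoys,
        },
        "exp3": {
            "FT": lambda t: _logistic(t, 2.0, k),
            "FLC": lambda t: _logistic(t, 3.5, k, rising=False),
            "SVP": const(hi_c),
            "AGL24": lambda t: _logistic(t, 5.0, k),
            **decoys,
        },
        "exp4": {
            "FT": const(lo_c),
            "FLC": lambda t: _logistic(t, 2.0, k, rising=False),
            "SVP": lambda t: _logistic(t, 3.5, k, rising=False),
            "AGL24": lambda t: _logistic(t, 5.0, k),
            **decoys,
        },
    }
    thr, n = 0.5, design.hill_n
    basal, amp = 0.02, 0.4
    self_thr = 0.40  # SOC1 positive feedback engages at this level
    agl_floor, soc_floor = 0.1, 0.5  # rate multipliers with the booster off
    delta = design.delta
    # experiments 2-4 start pre-induced: SOC1 high, decaying under the
    # non-permissive condition
    init_level = {"exp2": 0.55, "exp3": 0.55, "exp4": 0.55}
    profiles_det = {}
    for exp, sh in shapes.items():
        def rate(t, m, sh=sh):
            gate = (
                _hill(sh["FT"](t), thr, n)
                * (1.0 - _hill(sh["FLC"](t), thr, n))
                * (1.0 - _hill(sh["SVP"](t), thr, n))
            )
            boost = (agl_floor + (1 - agl_floor) * _hill(sh["AGL24"](t), thr, n)) * (
                soc_floor + (1 - soc_floor) * _hill(m, self_thr, n)
            )
            return basal + amp * gate * boost

        h0 = init_level.get(exp, basal / delta)
        sol = solve_ivp(
            lambda t, m, rate=rate: rate(t, m[0]) - delta * m[0],
            (0.0, design.horizon),
            [h0],
            dense_output=True,
            rtol=1e-8,
            atol=1e-10,
        )
        curves = {g: (lambda t, f=f: design.omega * f(t)) for g, f in sh.items()}
        curves["SOC1"] = lambda t, s=sol.sol: design.omega * s(np.atleast_1d(t))[0]
        profiles_det[exp] = curves

    times = {exp: _sample_times(design.horizon, design.spacing, rng) for exp in shapes}
    rows: list = []
    _emit_long(rows, profiles_det, times, design.n_replicates, design.noise_sd,
               design.extra_noise, rng)
    df = _to_frame(rows)
    genes = ["FT", "FLC", "SVP", "AGL24", "FD", "AP1", "LFY", "CO", "SOC1"]
    truth = {
        "target": "SOC1",
        "candidates": genes,  # the target itself is a candidate (autoregulation)
        "true_set": ["AGL24", "FLC", "FT", "SOC1", "SVP"],
        "thresholds": {
            **{g: 0.5 * design.omega for g in ["FT", "FLC", "SVP", "AGL24"]},
            "SOC1": 0.40 * design.omega,
        },
        "logic": {
            "FT": "activator",
            "AGL24": "activator",
            "SOC1": "activator",
            "FLC": "repressor",
            "SVP": "repressor",
        },
        "delta": delta,
        "omega": design.omega,
        "noise_sd": design.noise_sd,
    }
    return df, truth


# ---------------------------------------------------------------------------
# exact-model generator
# ---------------------------------------------------------------------------


def simulate_from_trs(
    partition: StatePartition,
    tau: np.ndarray,
    delta: float,
    M0: dict,
    times: dict,
    n_replicates: int = 1,
    sigma: dict | float = 0.0,
    psi: dict | float = 0.0,
    log_v_base: dict | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Sample observations exactly from the switch model.

    Evaluates the closed-form ODE solution at the given per-experiment
    sampling times and adds Gaussian noise with sd sigma_k * v_k(t),
    v_k = exp(psi_k * log_v_base).  Returns (df, TargetData of the
    noiseless means).
    """
    rng = np.random.default_rng(rng)
    exps = list(times)
    if not isinstance(sigma, dict):
        sigma = {k: float(sigma) for k in exps}
    if not isinstance(psi, dict):
        psi = {k: float(psi) for k in exps}
    rows = []
    mean_times, mean_vals = {}, {}
    for exp in exps:
        t = np.asarray(times[exp], float)
        m = solve_trs_ode(delta, M0[exp], partition.segments[exp], tau, t)
        logv = psi[exp] * (log_v_base[exp] if log_v_base else np.zeros(t.size))
        sd = sigma[exp] * np.exp(logv)
        for r in range(n_replicates):
            noisy = m + rng.normal(0.0, 1.0, t.size) * sd
            for ti, vi in zip(t, noisy):
                rows.append((exp, f"r{r + 1}", float(ti), "target", float(vi)))
        mean_times[exp] = np.tile(t, n_replicates)
        mean_vals[exp] = np.tile(m, n_replicates)
    df = _to_frame(rows)
    return df, TargetData(mean_times, mean_vals)
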