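"""Posterior summaries: set ranking, inclusion marginals, threshold
densities, fitted profiles and regulation-logic classification."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TargetData, fit_given_structure, solve_trs_ode
from .mcmc import SampleTrace

__all__ = ["PosteriorSummary", "summarize", "classify_logic", "fitted_profiles"]


@dataclass
class PosteriorSummary:
    """Monte-Carlo summaries of a sampled trace."""

    n_draws: int
    nu_distribution: dict  # nu -> posterior probability
    inclusion: dict  # tf -> marginal inclusion probability
    set_probabilities: list  # [(sorted tf tuple, probability)], ranked
    threshold_histograms: dict  # tf -> (bin edges, densities), given inclusion
    top_sets: list = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "nu_distribution": {str(k): v for k, v in self.nu_distribution.items()},
            "inclusion": self.inclusion,
            "set_probabilities": [
                {"set": list(s), "probability": p} for s, p in self.set_probabilities
            ],
            "threshold_histograms": {
                tf: {"edges": list(map(float, e)), "density": list(map(float, d))}
                for tf, (e, d) in self.threshold_histograms.items()
            },
            "top_sets": [list(s) for s in self.top_sets],
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_jsonable(), fh, indent=1)

    def set_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"set": "+".join(s), "size": len(s), "probability": p}
             for s, p in self.set_probabilities]
        )


def summarize(
    trace: SampleTrace,
    min_set_probability: float = 0.05,
    max_sets: int = 10,
    threshold_bins: int = 30,
) -> PosteriorSummary:
    """Monte-Carlo frequencies over the retained draws.

    Sets are keyed by unordered regulator-id tuples; threshold histograms
    are conditional on the regulator being included.
    """
    n = len(trace)
    if n == 0:
        raise ValueError("empty trace")
    nu_counts: dict[int, int] = {}
    set_counts: dict[tuple, int] = {}
    incl_counts: dict[str, int] = {}
    thr_draws: dict[str, list] = {}
    for phi, rho in zip(trace.phi, trace.rho):
        key = tuple(sorted(phi))
        nu_counts[len(key)] = nu_counts.get(len(key), 0) + 1
        set_counts[key] = set_counts.get(key, 0) + 1
        for tf in key:
            incl_counts[tf] = incl_counts.get(tf, 0) + 1
            thr_draws.setdefault(tf, []).append(rho[tf])
    nu_dist = {k: c / n for k, c in sorted(nu_counts.items())}
    sets = sorted(set_counts.items(), key=lambda kv: -kv[1])
    set_probs = [(s, c / n) for s, c in sets]
    inclusion = {tf: c / n for tf, c in sorted(incl_counts.items())}
    histograms = {}
    for tf, draws in thr_draws.items():
        dens, edges = np.histogram(draws, bins=threshold_bins, density=True)
        histograms[tf] = (edges, dens)
    top = [s for s, p in set_probs if p >= min_set_probability][:max_sets]
    if not top:
        top = [set_probs[0][0]]
    return PosteriorSummary(
        n_draws=n,
        nu_distribution=nu_dist,
        inclusion=inclusion,
        set_probabilities=set_probs,
        threshold_histograms=histograms,
        top_sets=top,
    )


# ---------------------------------------------------------------------------
# regulation-logic classification
# ---------------------------------------------------------------------------


def _interval(draws, level=0.90):
    a = (1 - level) / 2
    return np.quantile(draws, [a, 0.5, 1 - a])


def classify_logic(trace: SampleTrace, model_set: tuple, level: float = 0.90) -> dict:
    """Label each regulator of one sampled model as activator / repressor /
    conditional / no-effect.

    For regulator j, every pair of observed states differing only in
    coordinate j defines a contrast between the posterior draws of the two
    transcription rates (conditioned on draws of exactly this model).
    Disjoint equal-tailed credible intervals mean an effect in the direction
    of the medians; overlapping intervals that each contain the other's
    median mean no effect at that co-state.  A regulator with effects of one
    sign only is an (possibly conditional) activator or repressor; mixed
    signs give "conditional"; no observed contrast gives "undetermined".
    """
    key = tuple(sorted(model_set))
    idx = [i for i, p in enumerate(trace.phi) if tuple(sorted(p)) == key]
    if not idx:
        raise ValueError(f"model {key} never sampled")
    # collect tau draws per state label (states can differ slightly across
    # draws if switch structure changes; key by state tuple)
    tau_draws: dict[tuple, list] = {}
    order = list(key)
    for i in idx:
        # state coordinates follow the phi order of the draw
        perm = [list(trace.phi[i]).index(tf) for tf in order]
        for s, t in zip(trace.states[i], trace.tau[i]):
            lab = tuple(s[p] for p in perm)
            tau_draws.setdefault(lab, []).append(t)
    result = {}
    for j, tf in enumerate(order):
        contrasts = []
        for lab, draws in tau_draws.items():
            if lab[j] == 1:
                continue
            on = tuple(1 if jj == j else x for jj, x in enumerate(lab))
            if on not in tau_draws:
                continue
            off_d = np.asarray(draws)
            on_d = np.asarray(tau_draws[on])
            lo0, med0, hi0 = _interval(off_d, level)
            lo1, med1, hi1 = _interval(on_d, level)
            co_state = tuple(x for jj, x in enumerate(lab) if jj != j)
            if hi0 < lo1:
                contrasts.append((co_state, "up"))
            elif hi1 < lo0:
                contrasts.append((co_state, "down"))
            elif lo1 <= med0 <= hi1 and lo0 <= med1 <= hi0:
                contrasts.append((co_state, "none"))
            else:
                contrasts.append((co_state, "uncertain"))
        effects = {d for _, d in contrasts}
        if not contrasts:
            label = "undetermined"
        elif "up" in effects and "down" in effects:
            label = "conditional"
        elif "up" in effects:
            label = "activator"
        elif "down" in effects:
            label = "repressor"
        elif effects <= {"none"}:
            label = "no-effect"
        else:
            label = "undetermined"
        # which co-regulator states nullify the effect (repressed activation)
        nullified_by = []
        if label in ("activator", "repressor"):
            others = [tff for tff in order if tff != tf]
            for co_state, d in contrasts:
                if d == "none":
                    for tff, bit in zip(others, co_state):
                        if bit == 1 and tff not in nullified_by:
                            nullified_by.append(tff)
        result[tf] = {
            "label": label,
            "contrasts": [
                {"co_state": list(cs), "effect": d} for cs, d in contrasts
            ],
            "nullified_by": nullified_by,
        }
    return result


# ---------------------------------------------------------------------------
# fitted curves
# ---------------------------------------------------------------------------


def fitted_profiles(
    trace: SampleTrace,
    model_set: tuple,
    profiles: dict,
    data: TargetData,
    n_grid: int = 201,
) -> dict:
    """Posterior-mean refit of one model: dense fitted mRNA curve M_k(t)
    and piecewise-constant transcription profile tau_k(t) per experiment."""
    key = tuple(sorted(model_set))
    idx = [i for i, p in enumerate(trace.phi) if tuple(sorted(p)) == key]
    if not idx:
        raise ValueError(f"model {key} never sampled")
    rho = {tf: float(np.mean([trace.rho[i][tf] for i in idx])) for tf in key}
    delta = float(np.mean([trace.delta[i] for i in idx]))
    psi = {
        k: float(np.mean([trace.psi[i][k] for i in idx])) for k in data.experiments
    }
    fit = fit_given_structure(profiles, key, rho, delta, data, psi)
    out = {"set": key, "rho": rho, "delta": delta, "experiments": {}}
    K = len(data.experiments)
    for j, exp in enumerate(data.experiments):
        tg = np.linspace(0.0, data.horizons[exp], n_grid)
        segs = fit.partition.segments[exp]
        M = solve_trs_ode(delta, fit.coef[j], segs, fit.tau, tg)
        left, right, sidx = segs
        tau_curve = [
            {"left": float(l), "right": float(r), "tau": float(fit.tau[i])}
            for l, r, i in zip(left, right, sidx)
        ]
        out["experiments"][exp] = {
            "t": tg,
            "M": M,
            "tau_segments": tau_curve,
        }
    return out
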