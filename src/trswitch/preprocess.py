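"""Turn raw candidate-TF mRNA time series into continuous regulator proxies.

Regulator activity enters the switch model as a continuous curve per
experiment.  Raw mRNA observations (with replicates, possibly at irregular
times) are smoothed with a cross-validated smoothing spline; a wild
bootstrap characterizes the noise envelope around the smoothed curve; and a
protein proxy is constructed from the smoothed mRNA — by default the
identity (smoothed mRNA as activity), optionally an affine map, a time
delay, or a linear translation/degradation ODE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import make_smoothing_spline

from .model import RegulatorProfile, TargetData

__all__ = [
    "SmoothedProfile",
    "smooth_profile",
    "wild_bootstrap",
    "protein_proxy",
    "build_profiles",
    "attach_target_weights",
]

GRID_POINTS = 121  # piecewise-linear resolution of smoothed curves


@dataclass
class SmoothedProfile:
    """Smoothing-spline fit of one gene: per experiment a spline, its
    evaluation grid, and the residuals at the observation times."""

    gene: str
    splines: dict  # experiment -> BSpline
    grids: dict  # experiment -> (t_grid, values)
    obs: dict  # experiment -> (times, values, residuals)
    horizons: dict

    def curve(self, experiment, t):
        return self.splines[experiment](np.clip(t, 0.0, self.horizons[experiment]))


def _pooled(times, values):
    """Average replicate observations at shared time points; returns
    (unique times, means, counts)."""
    order = np.argsort(times)
    t, v = np.asarray(times, float)[order], np.asarray(values, float)[order]
    ut, inv, counts = np.unique(t, return_inverse=True, return_counts=True)
    sums = np.zeros_like(ut)
    np.add.at(sums, inv, v)
    return ut, sums / counts, counts


def smooth_profile(
    df: pd.DataFrame, gene: str, lam: float | None = None
) -> SmoothedProfile:
    """Cross-validated smoothing-spline fit per experiment, pooling
    replicates.  ``lam=None`` selects the penalty by generalized
    cross-validation; pass a value to override."""
    sub = df[df["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not present")
    splines, grids, obs, horizons = {}, {}, {}, {}
    for exp, g in sub.groupby("experiment", sort=True):
        exp = str(exp)
        t, v = g["time"].to_numpy(float), g["value"].to_numpy(float)
        ut, mv, counts = _pooled(t, v)
        if ut.size < 4:
            raise ValueError(
                f"gene {gene!r}, experiment {exp}: need >= 4 distinct time points"
            )
        spl = make_smoothing_spline(ut, mv, w=counts.astype(float), lam=lam)
        L = float(ut.max())
        tg = np.linspace(0.0, L, GRID_POINTS)
        splines[exp] = spl
        grids[exp] = (tg, np.asarray(spl(tg), float))
        obs[exp] = (t, v, v - np.asarray(spl(t), float))
        horizons[exp] = L
    return SmoothedProfile(gene=gene, splines=splines, grids=grids, obs=obs, horizons=horizons)


# Mammen's two-point wild-bootstrap weights
_MAMMEN_LO = -(np.sqrt(5.0) - 1.0) / 2.0
_MAMMEN_HI = (np.sqrt(5.0) + 1.0) / 2.0
_MAMMEN_P_LO = (np.sqrt(5.0) + 1.0) / (2.0 * np.sqrt(5.0))


def wild_bootstrap(
    profile: SmoothedProfile,
    B: int = 200,
    rng: np.random.Generator | None = None,
    quantiles=(0.025, 0.975),
):
    """Pointwise bootstrap envelope around the smoothed curve.

    Each replicate refits the spline to y* = fitted + residual * xi with xi
    drawn from Mammen's two-point law (mean 0, variance 1), preserving the
    per-point residual scale.  Returns {experiment: (t_grid, lo, hi)}.
    """
    rng = rng or np.random.default_rng()
    if B < 50:
        warnings.warn("wild bootstrap with B < 50 replicates is unreliable", stacklevel=2)
    env = {}
    for exp, (t, v, r) in profile.obs.items():
        fitted = v - r
        tg, _ = profile.grids[exp]
        curves = np.empty((B, tg.size))
        for b in range(B):
            xi = np.where(
                rng.random(r.size) < _MAMMEN_P_LO, _MAMMEN_LO, _MAMMEN_HI
            )
            ystar = fitted + r * xi
            ut, mv, counts = _pooled(t, ystar)
            spl = make_smoothing_spline(ut, mv, w=counts.astype(float))
            curves[b] = spl(tg)
        lo, hi = np.quantile(curves, quantiles, axis=0)
        env[exp] = (tg, lo, hi)
    return env


def protein_proxy(
    profile: SmoothedProfile, mode: str = "identity", **params
) -> RegulatorProfile:
    """Construct the regulator-activity curve from the smoothed mRNA.

    Modes: ``identity`` (smoothed mRNA), ``linear`` (a*M + b),
    ``delay`` (M(t - lag), edge-held), ``translation-ode``
    (dP/dt = k_tl*M - delta_p*P integrated from P0, default steady state).
    """
    curves = {}
    for exp, (tg, vg) in profile.grids.items():
        if mode == "identity":
            v = vg.copy()
        elif mode == "linear":
            try:
                a, b = params["a"], params["b"]
            except KeyError as e:
                raise ValueError("linear proxy requires a and b") from e
            v = a * vg + b
        elif mode == "delay":
            if "lag" not in params:
                raise ValueError("delay proxy requires lag")
            v = np.asarray(profile.curve(exp, tg - params["lag"]), float)
        elif mode == "translation-ode":
            try:
                k_tl, delta_p = params["k_tl"], params["delta_p"]
            except KeyError as e:
                raise ValueError("translation-ode proxy requires k_tl and delta_p") from e
            spl = profile.splines[exp]
            P0 = params.get("P0", k_tl * float(spl(0.0)) / delta_p)
            sol = solve_ivp(
                lambda t, p: k_tl * float(spl(t)) - delta_p * p,
                (tg[0], tg[-1]),
                [P0],
                t_eval=tg,
                rtol=1e-8,
                atol=1e-10,
            )
            v = sol.y[0]
        else:
            raise ValueError(f"unknown proxy mode {mode!r}")
        curves[exp] = (tg.copy(), v)
    return RegulatorProfile(tf_id=profile.gene, curves=curves)


def build_profiles(
    df: pd.DataFrame,
    genes,
    mode: str = "identity",
    lam: float | None = None,
    **proxy_params,
) -> dict:
    """Smooth each candidate gene and return its regulator proxy."""
    return {
        g: protein_proxy(smooth_profile(df, g, lam=lam), mode, **proxy_params)
        for g in genes
    }


def attach_target_weights(data: TargetData, df: pd.DataFrame, target: str):
    """Attach the variance weight function w_k(t) — the inverse of a
    smoothing-spline estimate of the target expression — to the data."""
    sm = smooth_profile(df, target)
    smoothed = {k: np.asarray(sm.curve(k, data.times[k]), float) for k in data.experiments}
    data.set_weight_curve(smoothed)
    return data
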