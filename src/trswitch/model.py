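"""Core generative model for the transcriptional regulation switch (TRS).

A target gene's mRNA follows the piecewise-linear ODE

    dM/dt = tau(t) - delta * M(t),          t in [0, L_k],

where the transcription rate tau(t) is piecewise constant: it jumps only
when one of the regulators in the current set crosses its activation
threshold.  Each *observed* joint activation state ``a_i`` of the regulator
set owns a single rate ``tau_{a_i}`` shared across all experiments and over
time — the cross-experiment consistency constraint that makes the logic of
the regulation identifiable.

For fixed thresholds and degradation rate the ODE solution is linear in the
initial conditions ``M_k(0)`` and the rates ``tau_{a_i}``, so those
coefficients are estimated by (weighted) least squares and plugged into a
Gaussian log-likelihood with per-experiment heteroscedastic variance
``sigma_k(t) = sigma_k * v_k(t)``, ``v_k(t) = w_k(t)**(-psi_k)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegulatorProfile",
    "TargetData",
    "StatePartition",
    "FitResult",
    "RedundantThresholdError",
    "compute_activation",
    "activation_trajectory",
    "enumerate_states",
    "solve_trs_ode",
    "build_design",
    "wls_fit",
    "log_likelihood",
    "fit_given_structure",
    "states_without_observations",
]


class RedundantThresholdError(ValueError):
    """Threshold outside the profile's range: the regulator never switches."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulatorProfile:
    """Continuous regulator activity curve, one piecewise-linear branch per
    experiment, with its level range taken jointly across experiments."""

    tf_id: str
    curves: dict  # experiment_id -> (times, values), both 1-d float arrays

    def __post_init__(self):
        for exp, (t, v) in self.curves.items():
            t = np.asarray(t, float)
            v = np.asarray(v, float)
            if t.ndim != 1 or t.shape != v.shape or t.size < 2:
                raise ValueError(f"profile {self.tf_id}/{exp}: malformed knots")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"profile {self.tf_id}/{exp}: times not increasing")
            self.curves[exp] = (t, v)

    @property
    def range_(self) -> tuple[float, float]:
        lo = min(v.min() for _, v in self.curves.values())
        hi = max(v.max() for _, v in self.curves.values())
        return float(lo), float(hi)

    @property
    def range_width(self) -> float:
        lo, hi = self.range_
        return hi - lo

    @property
    def dynamic_range(self) -> float:
        """Mean over experiments of the within-experiment level range —
        the candidate's 'overall dynamics'.  A profile that is constant in
        every condition has no dynamics even if its level differs between
        conditions."""
        widths = [float(v.max() - v.min()) for _, v in self.curves.values()]
        return float(np.mean(widths))

    def value(self, experiment_id: str, t):
        tk, vk = self.curves[experiment_id]
        return np.interp(t, tk, vk)

    def gradient_mean_level(self) -> float:
        """Mean absolute level across experiments (used for scale normalization)."""
        tot, n = 0.0, 0
        for t, v in self.curves.values():
            tot += float(np.abs(v).sum())
            n += v.size
        return tot / max(n, 1)


class TargetData:
    """Observed target-gene expression across experiments and replicates.

    Observations are stored concatenated in a fixed experiment order so a
    single design matrix covers the whole dataset; replicate structure only
    matters through the observation times.
    """

    def __init__(self, times: dict, values: dict, horizons: dict | None = None):
        self.experiments = list(times)
        self.times = {k: np.asarray(t, float) for k, t in times.items()}
        self.values = {k: np.asarray(v, float) for k, v in values.items()}
        for k in self.experiments:
            if self.times[k].shape != self.values[k].shape:
                raise ValueError(f"experiment {k}: times/values length mismatch")
            if np.any(self.times[k] < 0):
                raise ValueError(f"experiment {k}: negative times")
        self.horizons = {
            k: float(horizons[k]) if horizons else float(self.times[k].max())
            for k in self.experiments
        }
        for k in self.experiments:
            if self.times[k].max() > self.horizons[k] + 1e-12:
                raise ValueError(f"experiment {k}: observation beyond horizon")
        self.n_obs = {k: self.times[k].size for k in self.experiments}
        self.y = np.concatenate([self.values[k] for k in self.experiments])
        # per-experiment slices into the concatenated observation vector
        self.slices = {}
        start = 0
        for k in self.experiments:
            self.slices[k] = slice(start, start + self.n_obs[k])
            start += self.n_obs[k]
        self.n_total = start
        # log of the variance base: v_k(t) = exp(psi_k * log_v_base); defaults
        # to the homoscedastic model until a weight curve is attached.
        self.log_v_base = {k: np.zeros(self.n_obs[k]) for k in self.experiments}

    @classmethod
    def from_long(cls, df: pd.DataFrame, gene: str, horizons: dict | None = None):
        """Build from a long-format table with columns
        (experiment, replicate, time, gene, value)."""
        sub = df[df["gene"] == gene]
        if sub.empty:
            raise ValueError(f"gene {gene!r} not present in the data")
        times, values = {}, {}
        for exp, g in sub.groupby("experiment", sort=True):
            g = g.sort_values(["replicate", "time"])
            times[str(exp)] = g["time"].to_numpy(float)
            values[str(exp)] = g["value"].to_numpy(float)
        return cls(times, values, horizons)

    def set_weight_curve(self, smoothed: dict, floor_frac: float = 1e-6):
        """Attach the fixed weight function w_k(t) = 1 / Mhat_k(t).

        ``smoothed`` maps experiment -> smoothed target values at the
        observation times.  The estimate is floored at ``floor_frac`` of its
        maximum before inversion, and w is normalized to geometric mean 1 per
        experiment so that psi_k is decoupled from the overall noise scale.
        """
        for k in self.experiments:
            m = np.asarray(smoothed[k], float)
            if m.shape != self.times[k].shape:
                raise ValueError(f"experiment {k}: weight curve length mismatch")
            m = np.maximum(m, floor_frac * m.max())
            logw = -np.log(m)
            logw -= logw.mean()  # geometric-mean-1 normalization
            # v = w**(-psi) => log v = -psi * log w
            self.log_v_base[k] = -logw

    def v_of_psi(self, psi: dict) -> np.ndarray:
        """Concatenated v_k(t_i) = w_k(t_i)**(-psi_k)."""
        return np.concatenate(
            [np.exp(psi[k] * self.log_v_base[k]) for k in self.experiments]
        )


@dataclass
class StatePartition:
    """Observed joint activation states and their time-interval unions.

    ``states`` lists the distinct observed binary state vectors (in order of
    first appearance); per experiment, ``segments[exp]`` holds arrays
    (left, right, state_index) of half-open intervals [l, r) that tile
    [0, L_k] exactly.  A state observed in several experiments maps to the
    same index — this is what ties one tau to each state across experiments.
    """

    states: list
    segments: dict

    @property
    def q(self) -> int:
        return len(self.states)

    def to_jsonable(self) -> dict:
        return {
            "states": [list(map(int, s)) for s in self.states],
            "segments": {
                k: [[float(l), float(r), int(i)] for l, r, i in zip(*segs)]
                for k, segs in self.segments.items()
            },
        }


# ---------------------------------------------------------------------------
# activation and state enumeration
# ---------------------------------------------------------------------------


def compute_activation(t: np.ndarray, v: np.ndarray, threshold: float):
    """Switch times of a piecewise-linear curve against a threshold.

    Returns ``(initial_state, switch_times)`` where the state is 1 exactly
    where the curve is >= threshold (closed on the active side); crossing
    times are found by linear interpolation within each knot segment.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    above = v >= threshold
    flips = np.nonzero(above[1:] != above[:-1])[0]
    if flips.size == 0:
        return int(above[0]), np.empty(0)
    dv = v[flips + 1] - v[flips]
    s = t[flips] + (threshold - v[flips]) * (t[flips + 1] - t[flips]) / dv
    return int(above[0]), s


def activation_trajectory(profile: RegulatorProfile, threshold: float) -> dict:
    """Per-experiment activation of one regulator at a given threshold.

    Raises :class:`RedundantThresholdError` when the threshold lies outside
    the profile's joint range, in which case the regulator could never
    change state in any experiment.
    """
    lo, hi = profile.range_
    if not (lo <= threshold <= hi):
        raise RedundantThresholdError(
            f"threshold {threshold} outside range [{lo}, {hi}] of {profile.tf_id}"
        )
    return {
        exp: compute_activation(t, v, threshold)
        for exp, (t, v) in profile.curves.items()
    }


def enumerate_states(trajectories: dict, horizons: dict) -> StatePartition:
    """Merge per-regulator switch times into the joint state partition.

    ``trajectories`` maps tf_id -> {experiment -> (initial_state,
    switch_times)}; regulator order in the joint state vector follows the
    dict order of ``trajectories``.
    """
    tfs = list(trajectories)
    state_index: dict[tuple, int] = {}
    states: list[tuple] = []
    segments = {}
    for exp, L in horizons.items():
        cuts = [np.array([0.0, L])]
        for tf in tfs:
            _, s = trajectories[tf][exp]
            if len(s):
                s = np.asarray(s, float)
                cuts.append(s[(s > 0) & (s < L)])
        bounds = np.unique(np.concatenate(cuts))
        left, right = bounds[:-1], bounds[1:]
        keep = right - left > 1e-12
        left, right = left[keep], right[keep]
        mids = 0.5 * (left + right)
        # state of each tf on each segment: initial state flipped once per
        # switch time before the segment midpoint
        cols = []
        for tf in tfs:
            s0, s = trajectories[tf][exp]
            nflip = np.searchsorted(np.sort(np.asarray(s, float)), mids)
            cols.append((s0 + nflip) % 2)
        joint = np.stack(cols, axis=1) if tfs else np.zeros((mids.size, 0), int)
        idx = np.empty(mids.size, int)
        for i, row in enumerate(joint):
            key = tuple(int(x) for x in row)
            if key not in state_index:
                state_index[key] = len(states)
                states.append(key)
            idx[i] = state_index[key]
        segments[exp] = (left, right, idx)
    return StatePartition(states=states, segments=segments)


# ---------------------------------------------------------------------------
# closed-form ODE solution and the induced linear design
# ---------------------------------------------------------------------------


def _segment_factors(delta, left, right, t):
    """exp(-delta t) * (exp(delta*min(r,t)) - exp(delta*l)) / delta for l < t,
    computed in overflow-safe shifted form.  Shapes: t (n,), left/right (m,)
    -> (n, m)."""
    tt = t[:, None]
    lo = left[None, :]
    hi = np.minimum(right[None, :], tt)
    out = np.where(
        hi > lo,
        (np.exp(delta * (hi - tt)) - np.exp(delta * (lo - tt))) / delta,
        0.0,
    )
    return out


def solve_trs_ode(delta: float, M0: float, segments, tau: np.ndarray, t):
    """Exact solution of dM/dt = tau(t) - delta*M on one experiment.

    ``segments`` is the (left, right, idx) triple of that experiment's
    partition; ``tau`` the per-state rates.
    """
    if delta <= 0:
        raise ValueError("degradation rate delta must be positive")
    t = np.atleast_1d(np.asarray(t, float))
    left, right, idx = segments
    fac = _segment_factors(delta, left, right, t)  # (n, m)
    contrib = fac @ np.asarray(tau, float)[idx]
    return M0 * np.exp(-delta * t) + contrib


def build_design(partition: StatePartition, delta: float, data: TargetData):
    """Design matrix of the linear regression implied by the ODE solution.

    Columns: one exp(-delta t) initial-condition column per experiment
    (nonzero only in its own block), followed by q shared tau columns whose
    entries are the closed-form integral factors.  Returns (X, column
    labels).
    """
    if delta <= 0:
        raise ValueError("degradation rate delta must be positive")
    K = len(data.experiments)
    q = partition.q
    X = np.zeros((data.n_total, K + q))
    for j, exp in enumerate(data.experiments):
        sl = data.slices[exp]
        t = data.times[exp]
        X[sl, j] = np.exp(-delta * t)
        left, right, idx = partition.segments[exp]
        fac = _segment_factors(delta, left, right, t)
        # accumulate segment factors into their state columns
        for s in range(q):
            m = idx == s
            if m.any():
                X[sl, K + s] += fac[:, m].sum(axis=1)
    labels = [f"M0[{exp}]" for exp in data.experiments] + [
        f"tau{tuple(s)}" for s in partition.states
    ]
    return X, labels


def wls_fit(X: np.ndarray, y: np.ndarray, v: np.ndarray | None = None):
    """Weighted least squares minimizing sum((y - X b)^2 / v^2).

    v is the per-observation standard-deviation multiplier; v = 1 gives OLS.
    Singular designs fall back to the minimum-norm solution with a warning.
    Returns (coef, residuals, rank_deficient).
    """
    if v is None:
        v = np.ones_like(y)
    Xw = X / v[:, None]
    yw = y / v
    coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    deficient = rank < X.shape[1]
    if deficient:
        warnings.warn(
            "rank-deficient design: a state lacks supporting observations; "
            "minimum-norm solution used",
            RuntimeWarning,
            stacklevel=2,
        )
    resid = y - X @ coef
    return coef, resid, deficient


def log_likelihood(residuals: np.ndarray, data: TargetData, sigma: dict, psi: dict):
    """Gaussian log-likelihood with sd sigma_k * v_k(t), summed over
    experiments and replicates."""
    total = 0.0
    for k in data.experiments:
        s = sigma[k]
        if s <= 0:
            raise ValueError("sigma must be positive")
        sl = data.slices[k]
        logv = psi[k] * data.log_v_base[k]
        var = (s * np.exp(logv)) ** 2
        r = residuals[sl]
        total += -0.5 * np.sum(np.log(2 * np.pi * var) + r * r / var)
    return float(total)


# ---------------------------------------------------------------------------
# plug-in fit for a given structure
# ---------------------------------------------------------------------------


def states_without_observations(partition: StatePartition, data: TargetData) -> list:
    """Indices of observed states whose interval unions contain no
    observation time in any experiment.

    Such states own a transcription rate that no data point directly
    informs (a near-free parameter), which the sampler treats as an invalid
    structure; direct fits fall back to minimum-norm least squares."""
    counts = np.zeros(partition.q, int)
    for exp in data.experiments:
        left, right, idx = partition.segments[exp]
        t = data.times[exp]
        seg_of_obs = np.clip(np.searchsorted(left, t, side="right") - 1, 0, left.size - 1)
        inside = (t >= left[seg_of_obs]) & (t < right[seg_of_obs] + 1e-12)
        np.add.at(counts, idx[seg_of_obs[inside]], 1)
    return [i for i in range(partition.q) if counts[i] == 0]


@dataclass
class FitResult:
    """Cached plug-in fit of a candidate structure (Phi, rho, delta)."""

    partition: StatePartition
    X: np.ndarray
    coef: np.ndarray
    residuals: np.ndarray
    rank_deficient: bool
    unsupported_states: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    @property
    def M0(self) -> np.ndarray:
        K = self.X.shape[1] - self.partition.q
        return self.coef[:K]

    @property
    def tau(self) -> np.ndarray:
        K = self.X.shape[1] - self.partition.q
        return self.coef[K:]

    def weighted_rss(self, data: TargetData, psi: dict) -> dict:
        """Per-experiment sum of squared residuals on the 1/v scale."""
        out = {}
        for k in data.experiments:
            sl = data.slices[k]
            v = np.exp(psi[k] * data.log_v_base[k])
            r = self.residuals[sl] / v
            out[k] = float(r @ r)
        return out


def fit_given_structure(
    profiles: dict,
    phi: tuple,
    rho: dict,
    delta: float,
    data: TargetData,
    psi: dict | None = None,
    partition: StatePartition | None = None,
    X: np.ndarray | None = None,
) -> FitResult:
    """Compose activation -> state enumeration -> design -> WLS.

    ``profiles`` maps tf_id -> RegulatorProfile; ``phi`` the current
    regulator set (ordered); ``rho`` thresholds per tf.  ``partition``/``X``
    allow reuse when only downstream pieces changed (partition is
    delta-independent; X is psi-independent).
    """
    psi = psi or {k: 0.0 for k in data.experiments}
    if partition is None:
        traj = {f: activation_trajectory(profiles[f], rho[f]) for f in phi}
        partition = enumerate_states(traj, data.horizons)
    if X is None:
        X, labels = build_design(partition, delta, data)
    else:
        labels = []
    v = data.v_of_psi(psi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        coef, resid, deficient = wls_fit(X, data.y, v)
    return FitResult(
        partition=partition,
        X=X,
        coef=coef,
        residuals=resid,
        rank_deficient=deficient,
        unsupported_states=states_without_observations(partition, data),
        labels=labels,
    )
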