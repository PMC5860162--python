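"""Prior distributions and the trans-dimensional move-probability schedule.

The number of regulators nu carries a (truncated, renormalized) Poisson
prior; the mRNA degradation rate a Gamma prior parameterized by mean and sd;
the noise variances scaled inverse-chi-square priors; the variance exponents
psi_k are uniform on [0, 1].  For the regulator set and its thresholds two
modes are available: a non-informative uniform mode, and an informative mode
in which a candidate's prior weight grows with the dynamic range of its
(scale-normalized) profile and its threshold density concentrates on levels
the profile actually traverses, weighted by how often they are crossed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import RegulatorProfile

__all__ = [
    "PriorSpec",
    "MoveSchedule",
    "move_probabilities",
    "informative_tf_weights",
    "informative_threshold_density",
    "PriorModel",
]


@dataclass
class PriorSpec:
    """Hyperparameters of all prior blocks (defaults follow the method's
    Arabidopsis application: lambda=0.15, delta ~ Gamma(mean 0.345/h,
    sd 0.1543/h) for a ~2 h half-life, vague scaled-inv-chi2(0.001, 0.001)
    on sigma_k^2)."""

    lam: float = 0.15
    nu_max: int | None = None  # default min(N, 8), resolved at build time
    nu_min: int = 1
    delta_mean: float = 0.345
    delta_sd: float = 0.1543
    sigma2_df: float = 0.001  # n_{k,0}
    sigma2_scale: float = 0.001  # sigma_{k,0}^2
    tf_prior: str = "informative"  # or "uniform"
    threshold_prior: str = "informative"  # or "uniform"
    pi_bd: float = 0.5
    pi_tilde: float = 0.5
    threshold_grid_cells: int = 512
    threshold_floor: float = 0.05  # uniform mixture weight in the informative density

    @property
    def delta_shape(self) -> float:
        return (self.delta_mean / self.delta_sd) ** 2

    @property
    def delta_rate(self) -> float:
        return self.delta_mean / self.delta_sd**2

    def to_jsonable(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# move schedule
# ---------------------------------------------------------------------------


@dataclass
class MoveSchedule:
    """Per-dimension probabilities of the four structure moves.

    Rows are indexed by nu in [nu_min, nu_max]; each row (pi_M, pi_S, pi_B,
    pi_D) is a categorical distribution.  Birth/death satisfy the balance
    equation pi(nu) pi_B(nu) = pi(nu+1) pi_D(nu+1) under the Poisson prior.
    """

    nu_min: int
    nu_max: int
    pi_M: np.ndarray
    pi_S: np.ndarray
    pi_B: np.ndarray
    pi_D: np.ndarray
    c: float

    def row(self, nu: int) -> np.ndarray:
        i = nu - self.nu_min
        return np.array([self.pi_M[i], self.pi_S[i], self.pi_B[i], self.pi_D[i]])


def move_probabilities(
    lam: float,
    nu_min: int = 1,
    nu_max: int = 8,
    pi_bd: float = 0.5,
    pi_tilde: float = 0.5,
    n_candidates: int | None = None,
) -> MoveSchedule:
    """Build the move schedule from the Poisson(lambda) prior on nu.

    pi_B(nu) = c*min{1, pi(nu+1)/pi(nu)} = c*min{1, lambda/(nu+1)},
    pi_D(nu) = c*min{1, pi(nu-1)/pi(nu)} = c*min{1, nu/lambda},
    with birth disabled at nu_max, death at nu_min, and c as large as
    possible subject to pi_B + pi_D <= pi_bd at every nu.  When nu equals
    the number of candidates no swap is possible and its probability is
    folded into the threshold move (proposal ratios stay consistent).
    """
    if not (0 < pi_bd < 1) or not (0 < pi_tilde < 1):
        raise ValueError("pi_bd and pi_tilde must lie in (0, 1)")
    nus = np.arange(nu_min, nu_max + 1)
    b = np.minimum(1.0, lam / (nus + 1.0))
    d = np.minimum(1.0, nus / lam)
    b[-1] = 0.0  # no birth at nu_max
    d[0] = 0.0  # no death at nu_min
    denom = (b + d).max()
    if denom <= 0:
        # single feasible dimension: no birth/death moves at all
        c = 0.0
    else:
        c = pi_bd / denom
    pi_B = c * b
    pi_D = c * d
    rest = 1.0 - pi_B - pi_D
    if np.any(rest <= 0):
        raise ValueError("infeasible schedule: c leaves no room for M/S moves")
    pi_M = pi_tilde * rest
    pi_S = (1 - pi_tilde) * rest
    if n_candidates is not None:
        full = nus >= n_candidates  # no regulator left to swap in
        pi_M = np.where(full, rest, pi_M)
        pi_S = np.where(full, 0.0, pi_S)
    return MoveSchedule(
        nu_min=nu_min,
        nu_max=nu_max,
        pi_M=pi_M,
        pi_S=pi_S,
        pi_B=pi_B,
        pi_D=pi_D,
        c=c,
    )


# ---------------------------------------------------------------------------
# informative constructions
# ---------------------------------------------------------------------------


def informative_tf_weights(profiles: dict) -> dict:
    """Prior inclusion weights proportional to each candidate's dynamic
    range (mean within-experiment level range) after per-gene scale
    normalization (divide by the mean absolute level across experiments),
    normalized to sum 1."""
    widths = {}
    for tf, p in profiles.items():
        scale = p.gradient_mean_level()
        if scale <= 0:
            raise ValueError(f"candidate {tf} has an all-zero profile")
        widths[tf] = p.dynamic_range / scale
    total = sum(widths.values())
    if total <= 0:
        raise ValueError("all candidate profiles are degenerate (zero range)")
    return {tf: w / total for tf, w in widths.items()}


def informative_threshold_density(
    profile: RegulatorProfile, n_cells: int = 512, floor: float = 0.05
):
    """Threshold prior density over the profile range R_phi.

    Switches are a priori more likely at levels the profile traverses
    quickly: every monotone traversal of a level band contributes mass
    proportional to the gradient |dP/dt| at the crossing, so the density
    peaks where the profile changes fastest and vanishes (up to a
    ``floor`` fraction of the uniform density, kept for full support) at
    levels never crossed.  Returns (edges, pdf) with pdf constant on each
    of the ``n_cells`` grid cells, integrating to 1.
    """
    lo, hi = profile.range_
    if hi <= lo:
        raise ValueError(f"degenerate profile range for {profile.tf_id}")
    edges = np.linspace(lo, hi, n_cells + 1)
    mass = np.zeros(n_cells)
    width = (hi - lo) / n_cells
    for t, v in profile.curves.values():
        seg_lo = np.minimum(v[:-1], v[1:])
        seg_hi = np.maximum(v[:-1], v[1:])
        slopes = np.abs(np.diff(v)) / np.diff(t)
        for a, b, m in zip(seg_lo, seg_hi, slopes):
            if b <= a:
                continue  # flat segment traverses no levels
            i0 = np.searchsorted(edges, a, side="right") - 1
            i1 = np.searchsorted(edges, b, side="left")
            i0 = max(i0, 0)
            i1 = min(i1, n_cells)
            # fraction of each cell covered by the traversed band [a, b]
            cell_lo = edges[i0:i1]
            cell_hi = edges[i0 + 1 : i1 + 1]
            frac = (np.minimum(cell_hi, b) - np.maximum(cell_lo, a)) / width
            mass[i0:i1] += m * np.clip(frac, 0.0, 1.0)
    total = mass.sum() * width
    if total > 0:
        pdf = (1 - floor) * mass / total + floor / (hi - lo)
    else:
        pdf = np.full(n_cells, 1.0 / (hi - lo))
    return edges, pdf


def _elementary_symmetric(weights: np.ndarray, kmax: int) -> np.ndarray:
    """e_0..e_kmax of the weight vector (normalizers of the size-nu set
    prior under independent per-TF weights)."""
    e = np.zeros(kmax + 1)
    e[0] = 1.0
    for w in weights:
        upper = min(kmax, 1 + np.nonzero(e)[0].max())
        e[1 : upper + 1] = e[1 : upper + 1] + w * e[:upper]
    return e


# ---------------------------------------------------------------------------
# assembled prior model
# ---------------------------------------------------------------------------


class PriorModel:
    """Prior densities bound to a concrete candidate set and its profiles."""

    def __init__(self, spec: PriorSpec, profiles: dict):
        self.spec = spec
        self.profiles = profiles
        self.candidates = list(profiles)
        N = len(self.candidates)
        if N == 0:
            raise ValueError("no candidate regulators")
        self.nu_max = min(spec.nu_max or min(N, 8), N)
        self.nu_min = spec.nu_min
        if not (1 <= self.nu_min <= self.nu_max):
            raise ValueError("invalid nu range")
        # truncated Poisson log-pmf over [nu_min, nu_max], renormalized
        nus = np.arange(self.nu_min, self.nu_max + 1)
        logp = stats.poisson.logpmf(nus, spec.lam)
        self._log_nu = dict(zip(nus.tolist(), (logp - _logsumexp(logp)).tolist()))
        # set prior
        if spec.tf_prior == "informative":
            self.tf_weights = informative_tf_weights(profiles)
        elif spec.tf_prior == "uniform":
            self.tf_weights = {tf: 1.0 / N for tf in self.candidates}
        else:
            raise ValueError(f"unknown tf_prior {spec.tf_prior!r}")
        w = np.array([self.tf_weights[tf] for tf in self.candidates])
        self._esp = _elementary_symmetric(w, self.nu_max)
        # threshold priors
        self._thr = {}
        for tf, p in profiles.items():
            if spec.threshold_prior == "informative":
                edges, pdf = informative_threshold_density(
                    p, spec.threshold_grid_cells, spec.threshold_floor
                )
            elif spec.threshold_prior == "uniform":
                lo, hi = p.range_
                edges = np.array([lo, hi])
                pdf = np.array([1.0 / (hi - lo)])
            else:
                raise ValueError(f"unknown threshold_prior {spec.threshold_prior!r}")
            self._thr[tf] = (edges, np.log(pdf))
        self.schedule = move_probabilities(
            spec.lam, self.nu_min, self.nu_max, spec.pi_bd, spec.pi_tilde,
            n_candidates=N,
        )

    # -- component log-densities ------------------------------------------

    def log_nu(self, nu: int) -> float:
        return self._log_nu.get(nu, -np.inf)

    def log_set(self, phi) -> float:
        """log P(Phi | nu): product of per-TF weights over the elementary
        symmetric normalizer (uniform weights reduce to 1/C(N, nu))."""
        nu = len(phi)
        if not (self.nu_min <= nu <= self.nu_max):
            return -np.inf
        lw = sum(np.log(self.tf_weights[tf]) for tf in phi)
        return float(lw - np.log(self._esp[nu]))

    def log_threshold(self, tf: str, rho: float) -> float:
        edges, logpdf = self._thr[tf]
        if rho < edges[0] or rho > edges[-1]:
            return -np.inf
        i = min(np.searchsorted(edges, rho, side="right") - 1, logpdf.size - 1)
        return float(logpdf[max(i, 0)])

    def log_delta(self, delta: float) -> float:
        if delta <= 0:
            return -np.inf
        return float(
            stats.gamma.logpdf(delta, a=self.spec.delta_shape, scale=1 / self.spec.delta_rate)
        )

    def log_sigma2(self, sigma2: float) -> float:
        # scaled-inv-chi2(n0, s0) == InvGamma(n0/2, n0*s0/2)
        n0, s0 = self.spec.sigma2_df, self.spec.sigma2_scale
        if sigma2 <= 0:
            return -np.inf
        return float(stats.invgamma.logpdf(sigma2, a=n0 / 2, scale=n0 * s0 / 2))

    def log_structure(self, phi, rho: dict) -> float:
        """Joint log-prior of (nu, Phi, rho_Phi) — the part that moves in
        trans-dimensional steps."""
        lp = self.log_nu(len(phi)) + self.log_set(phi)
        for tf in phi:
            lp += self.log_threshold(tf, rho[tf])
        return lp

    def log_prior(self, phi, rho: dict, delta: float, sigma2: dict) -> float:
        """Full log-prior of Theta (psi terms are constant on [0,1])."""
        lp = self.log_structure(phi, rho) + self.log_delta(delta)
        for s2 in sigma2.values():
            lp += self.log_sigma2(s2)
        return lp

    # -- analytic marginals used by tests ---------------------------------

    def inclusion_prior(self, tf: str) -> float:
        """P(tf in Phi) under the prior — exact, via symmetric polynomials."""
        w = np.array([self.tf_weights[f] for f in self.candidates if f != tf])
        e_minus = _elementary_symmetric(w, self.nu_max)
        total = 0.0
        for nu in range(self.nu_min, self.nu_max + 1):
            p_incl = self.tf_weights[tf] * e_minus[nu - 1] / self._esp[nu]
            total += np.exp(self.log_nu(nu)) * p_incl
        return float(total)


def _logsumexp(x):
    m = np.max(x)
    return m + np.log(np.sum(np.exp(x - m)))
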