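"""Trans-dimensional MCMC over regulator sets, thresholds and rates.

Each iteration performs, in order:

1. one structure move — move a threshold (M), swap a regulator (S), add one
   (Birth) or remove one (Death) — accepted by a Metropolis-Hastings-Green
   ratio of structure prior, plug-in likelihood and proposal probabilities;
2. a Gaussian random-walk Metropolis update of the degradation rate delta;
3. conjugate Gibbs draws of the noise variances sigma_k^2 (scaled
   inverse-chi-square full conditionals);
4. grid-based inverse-CDF draws of the variance exponents psi_k from their
   numerically computed full conditionals.

The likelihood is always the plug-in likelihood: the linear coefficients
(initial conditions and per-state transcription rates) are profiled out by
weighted least squares rather than integrated, following the Denison-style
shortcut, so trans-dimensional moves need no Jacobian beyond the proposal
densities of the thresholds.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .model import FitResult, TargetData, build_design, fit_given_structure, log_likelihood
from .priors import PriorModel

__all__ = ["MCMCConfig", "ChainState", "SampleTrace", "run_chain"]

_MOVES = ("M", "S", "B", "D")


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``sigma_rho_frac`` scales the truncated-normal threshold proposal sd as
    a fraction of each regulator's profile range; ``flat_likelihood``
    replaces the likelihood by a constant (prior-recovery diagnostics).
    """

    n_iter: int = 200_000
    burn_in: int | None = None  # default: 10% of n_iter
    thin: int | None = None  # default: keep <= 10_000 draws
    seed: int | None = None
    sigma_rho_frac: float = 0.1
    delta_prop_sd: float = 0.05
    update_structure: bool = True
    update_delta: bool = True
    update_sigma: bool = True
    update_psi: bool = True
    psi_grid: int = 201
    flat_likelihood: bool = False
    init_phi: tuple | None = None
    init_rho: dict | None = None
    init_delta: float | None = None
    init_sigma2: float | None = None
    init_psi: float = 0.5
    max_retained: int = 10_000

    def resolve(self):
        burn = self.burn_in if self.burn_in is not None else self.n_iter // 10
        if not (0 <= burn < self.n_iter):
            raise ValueError("need n_iter > burn_in >= 0")
        thin = self.thin or max(1, (self.n_iter - burn) // self.max_retained)
        return burn, thin

    def to_jsonable(self):
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items() if not isinstance(v, dict)}


@dataclass
class ChainState:
    """Current parameter vector Theta plus its cached plug-in fit."""

    phi: tuple
    rho: dict
    delta: float
    sigma2: dict
    psi: dict
    fit: FitResult | None
    loglik: float
    log_structure_prior: float


class SampleTrace:
    """Thinned posterior draws plus per-move acceptance bookkeeping."""

    def __init__(self):
        self.iterations: list[int] = []
        self.phi: list[tuple] = []
        self.rho: list[dict] = []
        self.delta: list[float] = []
        self.sigma: list[dict] = []
        self.psi: list[dict] = []
        self.states: list[list] = []
        self.tau: list[list] = []
        self.M0: list[dict] = []
        self.loglik: list[float] = []
        self.move: list[str] = []
        self.accepted: list[bool] = []

    def __len__(self):
        return len(self.iterations)

    def append(self, it, state: ChainState, move, accepted, experiments):
        self.iterations.append(it)
        self.phi.append(state.phi)
        self.rho.append(dict(state.rho))
        self.delta.append(state.delta)
        self.sigma.append({k: float(np.sqrt(state.sigma2[k])) for k in experiments})
        self.psi.append(dict(state.psi))
        if state.fit is not None:
            self.states.append([list(s) for s in state.fit.partition.states])
            self.tau.append([float(x) for x in state.fit.tau])
            K = len(experiments)
            self.M0.append({k: float(m) for k, m in zip(experiments, state.fit.coef[:K])})
        else:
            self.states.append([])
            self.tau.append([])
            self.M0.append({})
        self.loglik.append(state.loglik)
        self.move.append(move)
        self.accepted.append(bool(accepted))

    def scalars(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self)):
            row = {
                "iteration": self.iterations[i],
                "nu": len(self.phi[i]),
                "delta": self.delta[i],
                "loglik": self.loglik[i],
                "move": self.move[i],
                "accepted": self.accepted[i],
            }
            for k, v in self.sigma[i].items():
                row[f"sigma[{k}]"] = v
            for k, v in self.psi[i].items():
                row[f"psi[{k}]"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, directory):
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.scalars().to_csv(d / "trace_scalars.csv", index=False)
        with open(d / "trace_models.jsonl", "w") as fh:
            for i in range(len(self)):
                fh.write(
                    json.dumps(
                        {
                            "iteration": self.iterations[i],
                            "phi": list(self.phi[i]),
                            "rho": self.rho[i],
                            "states": self.states[i],
                            "tau": self.tau[i],
                            "M0": self.M0[i],
                        }
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, directory):
        import pathlib

        d = pathlib.Path(directory)
        tr = cls()
        sc = pd.read_csv(d / "trace_scalars.csv")
        sigma_cols = [c for c in sc.columns if c.startswith("sigma[")]
        psi_cols = [c for c in sc.columns if c.startswith("psi[")]
        with open(d / "trace_models.jsonl") as fh:
            for lineno, line in enumerate(fh):
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as e:
                    raise ValueError(
                        f"corrupt trace file {d / 'trace_models.jsonl'} at line "
                        f"{lineno + 1}: {e}"
                    ) from e
                i = lineno
                tr.iterations.append(int(sc["iteration"][i]))
                tr.phi.append(tuple(rec["phi"]))
                tr.rho.append(rec["rho"])
                tr.delta.append(float(sc["delta"][i]))
                tr.sigma.append({c[6:-1]: float(sc[c][i]) for c in sigma_cols})
                tr.psi.append({c[4:-1]: float(sc[c][i]) for c in psi_cols})
                tr.states.append(rec["states"])
                tr.tau.append(rec["tau"])
                tr.M0.append(rec["M0"])
                tr.loglik.append(float(sc["loglik"][i]))
                tr.move.append(str(sc["move"][i]))
                tr.accepted.append(bool(sc["accepted"][i]))
        return tr


# ---------------------------------------------------------------------------
# proposal machinery
# ---------------------------------------------------------------------------


def _truncnorm_sample(rng, mu, sd, lo, hi):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    pa, pb = ndtr(a), ndtr(b)
    u = rng.random()
    return mu + sd * ndtri(pa + u * (pb - pa))


def _truncnorm_logpdf(x, mu, sd, lo, hi):
    if not (lo <= x <= hi):
        return -np.inf
    z = (x - mu) / sd
    norm = ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd)
    return -0.5 * z * z - np.log(sd) - 0.5 * np.log(2 * np.pi) - np.log(norm)


def propose_structure_move(state: ChainState, prior: PriorModel, config: MCMCConfig, rng):
    """Draw a move type from the schedule at the current dimension and build
    the proposed (phi', rho') with its log proposal ratio
    log q(Theta|Theta') - log q(Theta'|Theta)."""
    cands = prior.candidates
    N = len(cands)
    phi, rho = state.phi, state.rho
    nu = len(phi)
    probs = prior.schedule.row(nu)
    for _ in range(100):
        move = _MOVES[rng.choice(4, p=probs)]
        if move == "S" and nu >= N:
            continue  # no regulator outside Phi to swap in; redraw
        break
    else:
        move = "M"

    if move == "M":
        tf = phi[int(rng.integers(nu))]
        lo, hi = prior.profiles[tf].range_
        sd = config.sigma_rho_frac * (hi - lo)
        cur = rho[tf]
        new = _truncnorm_sample(rng, cur, sd, lo, hi)
        ratio = _truncnorm_logpdf(cur, new, sd, lo, hi) - _truncnorm_logpdf(
            new, cur, sd, lo, hi
        )
        rho2 = dict(rho)
        rho2[tf] = new
        return move, phi, rho2, ratio

    if move == "S":
        out = phi[int(rng.integers(nu))]
        pool = [f for f in cands if f not in phi]
        new_tf = pool[int(rng.integers(len(pool)))]
        lo, hi = prior.profiles[new_tf].range_
        rho2 = {f: rho[f] for f in phi if f != out}
        rho2[new_tf] = rng.uniform(lo, hi)
        phi2 = tuple(sorted(rho2))
        lo0, hi0 = prior.profiles[out].range_
        # forward density 1/|R_new|, reverse density 1/|R_out|
        ratio = np.log(hi - lo) - np.log(hi0 - lo0)
        return move, phi2, rho2, ratio

    if move == "B":
        pool = [f for f in cands if f not in phi]
        new_tf = pool[int(rng.integers(len(pool)))]
        lo, hi = prior.profiles[new_tf].range_
        rho2 = dict(rho)
        rho2[new_tf] = rng.uniform(lo, hi)
        phi2 = tuple(sorted(rho2))
        pD_next = prior.schedule.row(nu + 1)[3]
        pB = probs[2]
        ratio = (
            np.log(pD_next)
            - np.log(nu + 1)
            - np.log(pB)
            + np.log(len(pool))
            + np.log(hi - lo)
        )
        return move, phi2, rho2, ratio

    # Death
    out = phi[int(rng.integers(nu))]
    rho2 = {f: rho[f] for f in phi if f != out}
    phi2 = tuple(sorted(rho2))
    lo, hi = prior.profiles[out].range_
    pB_prev = prior.schedule.row(nu - 1)[2]
    pD = probs[3]
    ratio = (
        np.log(pB_prev)
        - np.log(N - nu + 1)
        - np.log(hi - lo)
        - np.log(pD)
        + np.log(nu)
    )
    return move, phi2, rho2, ratio


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------


def _refit(profiles, phi, rho, delta, data, psi, partition=None, X=None) -> FitResult:
    return fit_given_structure(
        profiles, phi, rho, delta, data, psi, partition=partition, X=X
    )


def _ll(state_fit, data, sigma2, psi):
    sigma = {k: float(np.sqrt(s2)) for k, s2 in sigma2.items()}
    return log_likelihood(state_fit.residuals, data, sigma, psi)


def _init_state(data, profiles, prior, config, rng) -> ChainState:
    if config.init_phi is not None:
        phi = tuple(sorted(config.init_phi))
    else:
        phi = (prior.candidates[int(rng.integers(len(prior.candidates)))],)
    rho = dict(config.init_rho) if config.init_rho else {}
    for tf in phi:
        if tf not in rho:
            lo, hi = profiles[tf].range_
            rho[tf] = rng.uniform(lo, hi)
    delta = config.init_delta if config.init_delta is not None else prior.spec.delta_mean
    psi = {k: float(config.init_psi) for k in data.experiments}
    if config.init_sigma2 is not None:
        sigma2 = {k: float(config.init_sigma2) for k in data.experiments}
    else:
        sigma2 = {
            k: float(np.var(data.values[k]) + 1e-12) for k in data.experiments
        }
    if config.flat_likelihood:
        fit, ll = None, 0.0
    else:
        fit = _refit(profiles, phi, rho, delta, data, psi)
        ll = _ll(fit, data, sigma2, psi)
    return ChainState(
        phi=phi,
        rho=rho,
        delta=delta,
        sigma2=sigma2,
        psi=psi,
        fit=fit,
        loglik=ll,
        log_structure_prior=prior.log_structure(phi, rho),
    )


def run_chain(
    data: TargetData,
    profiles: dict,
    prior: PriorModel,
    config: MCMCConfig,
    rng: np.random.Generator | None = None,
    initial_state: ChainState | None = None,
):
    """Run the sampler; returns (SampleTrace, manifest dict, final state)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    burn, thin = config.resolve()
    state = initial_state or _init_state(data, profiles, prior, config, rng)
    trace = SampleTrace()
    proposed = dict.fromkeys(_MOVES, 0)
    accepted = dict.fromkeys(_MOVES, 0)
    delta_prop = delta_acc = 0
    flat = config.flat_likelihood
    n0, s0 = prior.spec.sigma2_df, prior.spec.sigma2_scale
    psi_grid = np.linspace(0.0, 1.0, config.psi_grid)
    # v(psi) on the grid is iteration-independent: precompute exp(-2*psi*b)
    psi_W = {
        k: np.exp(-2.0 * np.outer(psi_grid, data.log_v_base[k]))
        for k in data.experiments
    }
    # note b = log_v_base; residual weight is w^{2psi} = exp(-2 psi b)
    t_start = time.perf_counter()

    for it in range(config.n_iter):
        # -- 1. structure move ------------------------------------------
        move, last_accepted = "-", False
        if not config.update_structure:
            lp2 = -np.inf
        else:
            move, phi2, rho2, log_q = propose_structure_move(state, prior, config, rng)
            proposed[move] += 1
            lp2 = prior.log_structure(phi2, rho2)
        if np.isfinite(lp2):
            if flat:
                fit2, ll2 = None, 0.0
            else:
                fit2 = _refit(profiles, phi2, rho2, state.delta, data, state.psi)
                ll2 = _ll(fit2, data, state.sigma2, state.psi)
                if fit2.unsupported_states:
                    # a state with no supporting observation: invalid structure
                    ll2 = -np.inf
            log_a = (lp2 - state.log_structure_prior) + (ll2 - state.loglik) + log_q
            if np.isfinite(log_a) and np.log(rng.random()) < log_a:
                accepted[move] += 1
                last_accepted = True
                state.phi, state.rho = phi2, rho2
                state.fit, state.loglik = fit2, ll2
                state.log_structure_prior = lp2

        # -- 2. delta random walk ---------------------------------------
        if config.update_delta:
            delta_prop += 1
            d2 = state.delta + config.delta_prop_sd * rng.standard_normal()
            if d2 > 0:
                if flat:
                    fit2, ll2 = None, 0.0
                else:
                    fit2 = _refit(
                        profiles, state.phi, state.rho, d2, data, state.psi,
                        partition=state.fit.partition,
                    )
                    ll2 = _ll(fit2, data, state.sigma2, state.psi)
                log_a = (
                    prior.log_delta(d2)
                    - prior.log_delta(state.delta)
                    + (ll2 - state.loglik)
                )
                if np.isfinite(log_a) and np.log(rng.random()) < log_a:
                    delta_acc += 1
                    state.delta = d2
                    state.fit, state.loglik = fit2, ll2

        # -- 3. sigma_k^2 Gibbs -----------------------------------------
        if config.update_sigma and not flat:
            rss = state.fit.weighted_rss(data, state.psi)
            for k in data.experiments:
                n_k = data.n_obs[k]
                df_post = n0 + n_k
                scale_post = (n0 * s0 + rss[k]) / df_post
                state.sigma2[k] = df_post * scale_post / rng.chisquare(df_post)
            state.loglik = _ll(state.fit, data, state.sigma2, state.psi)

        # -- 4. psi_k grid Gibbs ----------------------------------------
        if config.update_psi and not flat:
            changed = False
            for k in data.experiments:
                sl = data.slices[k]
                r2 = state.fit.residuals[sl] ** 2
                # log full conditional on the grid (b sums to zero, so the
                # normalization term is constant in psi)
                logp = -(psi_W[k] @ r2) / (2.0 * state.sigma2[k])
                b = data.log_v_base[k]
                logp = logp - psi_grid * b.sum()
                logp -= logp.max()
                p = np.exp(logp)
                p /= p.sum()
                idx = int(np.searchsorted(np.cumsum(p), rng.random()))
                new_psi = float(psi_grid[min(idx, psi_grid.size - 1)])
                if new_psi != state.psi[k]:
                    changed = True
                state.psi[k] = new_psi
            if changed:
                state.fit = _refit(
                    profiles, state.phi, state.rho, state.delta, data, state.psi,
                    partition=state.fit.partition, X=state.fit.X,
                )
            state.loglik = _ll(state.fit, data, state.sigma2, state.psi)

        if it >= burn and (it - burn) % thin == 0:
            trace.append(it, state, move, last_accepted, data.experiments)

    elapsed = time.perf_counter() - t_start
    manifest = {
        "config": config.to_jsonable(),
        "prior": prior.spec.to_jsonable(),
        "candidates": prior.candidates,
        "n_iterations": config.n_iter,
        "burn_in": burn,
        "thin": thin,
        "retained": len(trace),
        "acceptance_rates": {
            m: (accepted[m] / proposed[m] if proposed[m] else None) for m in _MOVES
        },
        "delta_acceptance": (delta_acc / delta_prop if delta_prop else None),
        "move_counts": proposed,
        "elapsed_seconds": elapsed,
    }
    return trace, manifest, state
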