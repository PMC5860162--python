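"""Independent oracles shared by the sampler tests and acceptance checks."""

import itertools

import numpy as np

from trswitch.model import TargetData, fit_given_structure, log_likelihood
from trswitch.priors import PriorModel


def grid_enumeration_posterior(
    data: TargetData,
    profiles: dict,
    prior: PriorModel,
    sigma: dict,
    psi: dict,
    delta: float,
    n_cells: int = 20,
    sub: int = 6,
):
    """Exhaustive plug-in posterior over (regulator set, threshold grid cell)
    with delta, sigma and psi held fixed.

    Thresholds are integrated numerically: each of the ``n_cells`` coarse
    cells of every regulator's range is subdivided into ``sub`` quadrature
    points; the joint (set, cell combination) mass is the prior-weighted
    average of exp(log-likelihood) over the sub-grid, normalized over all
    nonempty sets up to the prior's nu_max.

    Returns {(phi tuple, cell index tuple): probability}.
    """
    cands = prior.candidates
    log_terms = {}
    for nu in range(prior.nu_min, prior.nu_max + 1):
        for phi in itertools.combinations(cands, nu):
            grids = {}
            log_cell_volume = 0.0
            for tf in phi:
                lo, hi = profiles[tf].range_
                log_cell_volume += np.log((hi - lo) / n_cells)
                edges = np.linspace(lo, hi, n_cells + 1)
                pts = np.stack(
                    [
                        edges[:-1] + (j + 0.5) * (edges[1] - edges[0]) / sub
                        for j in range(sub)
                    ],
                    axis=1,
                )  # (n_cells, sub)
                grids[tf] = pts
            for cells in itertools.product(range(n_cells), repeat=nu):
                vals = []
                for subpt in itertools.product(range(sub), repeat=nu):
                    rho = {
                        tf: float(grids[tf][c, j])
                        for tf, c, j in zip(phi, cells, subpt)
                    }
                    fit = fit_given_structure(profiles, phi, rho, delta, data, psi)
                    if fit.unsupported_states:
                        vals.append(-np.inf)
                        continue
                    ll = log_likelihood(fit.residuals, data, sigma, psi)
                    lp = prior.log_structure(phi, rho)
                    vals.append(ll + lp)
                vals = np.asarray(vals)
                m = vals.max()
                log_terms[(phi, cells)] = (
                    -np.inf
                    if not np.isfinite(m)
                    else m + np.log(np.mean(np.exp(vals - m))) + log_cell_volume
                )
    keys = list(log_terms)
    logv = np.array([log_terms[k] for k in keys])
    mx = logv.max()
    w = np.exp(logv - mx)
    w /= w.sum()
    return dict(zip(keys, w))


def bin_trace_draws(trace, profiles, n_cells=20):
    """Map sampled (set, thresholds) draws onto the enumeration grid cells."""
    counts = {}
    for phi, rho in zip(trace.phi, trace.rho):
        key = tuple(sorted(phi))
        cells = []
        for tf in key:
            lo, hi = profiles[tf].range_
            c = int((rho[tf] - lo) / (hi - lo) * n_cells)
            cells.append(min(max(c, 0), n_cells - 1))
        k = (key, tuple(cells))
        counts[k] = counts.get(k, 0) + 1
    n = len(trace.phi)
    return {k: v / n for k, v in counts.items()}
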