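"""Scikit-learn-style estimator wrapping the full inference pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mcmc import MCMCConfig, run_chain
from .model import TargetData
from .preprocess import attach_target_weights, build_profiles
from .priors import PriorModel, PriorSpec
from .summary import classify_logic, summarize

__all__ = ["TRSRegulatorInference"]


class TRSRegulatorInference(BaseEstimator):
    """Infer the regulator set and regulation logic of one target gene.

    Fit on a long-format expression table (columns ``experiment``,
    ``replicate``, ``time``, ``gene``, ``value``) containing the target and
    all candidate regulators.  Candidate mRNA profiles are smoothed into
    continuous activity proxies; the reversible-jump sampler then explores
    regulator sets, activation thresholds, the degradation rate and noise
    parameters, and the fitted attributes expose the ranked posterior.

    Parameters mirror the prior and sampler blocks; see
    :class:`trswitch.priors.PriorSpec` and :class:`trswitch.mcmc.MCMCConfig`.

    Attributes (after ``fit``)
    --------------------------
    summary_ : PosteriorSummary
    trace_ : SampleTrace
    manifest_ : dict
    inclusion_probabilities_ : dict mapping candidate -> P(in regulator set | y)
    nu_distribution_ : dict mapping set size -> posterior probability
    posterior_sets_ : list of (regulator tuple, probability), ranked
    logic_ : per-regulator logic labels of the top-ranked model
    """

    def __init__(
        self,
        target: str = "target",
        candidates: list | None = None,
        n_iter: int = 200_000,
        burn_in: int | None = None,
        thin: int | None = None,
        lam: float = 0.15,
        nu_max: int | None = None,
        tf_prior: str = "informative",
        threshold_prior: str = "informative",
        delta_prior_mean: float = 0.345,
        delta_prior_sd: float = 0.1543,
        sigma2_df: float = 0.001,
        sigma2_scale: float = 0.001,
        sigma_rho_frac: float = 0.1,
        delta_prop_sd: float = 0.05,
        proxy_mode: str = "identity",
        random_state: int | None = None,
    ):
        self.target = target
        self.candidates = candidates
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.lam = lam
        self.nu_max = nu_max
        self.tf_prior = tf_prior
        self.threshold_prior = threshold_prior
        self.delta_prior_mean = delta_prior_mean
        self.delta_prior_sd = delta_prior_sd
        self.sigma2_df = sigma2_df
        self.sigma2_scale = sigma2_scale
        self.sigma_rho_frac = sigma_rho_frac
        self.delta_prop_sd = delta_prop_sd
        self.proxy_mode = proxy_mode
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        df = X
        if not isinstance(df, pd.DataFrame):
            raise TypeError("X must be a long-format DataFrame")
        required = {"experiment", "replicate", "time", "gene", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        genes = set(df["gene"])
        if self.target not in genes:
            raise ValueError(f"target gene {self.target!r} not in data")
        candidates = self.candidates or sorted(g for g in genes if g != self.target)
        absent = [c for c in candidates if c not in genes]
        if absent:
            raise ValueError(f"candidate genes not in data: {absent}")

        data = TargetData.from_long(df, self.target)
        attach_target_weights(data, df, self.target)
        profiles = build_profiles(df, candidates, mode=self.proxy_mode)
        spec = PriorSpec(
            lam=self.lam,
            nu_max=self.nu_max,
            delta_mean=self.delta_prior_mean,
            delta_sd=self.delta_prior_sd,
            sigma2_df=self.sigma2_df,
            sigma2_scale=self.sigma2_scale,
            tf_prior=self.tf_prior,
            threshold_prior=self.threshold_prior,
        )
        prior = PriorModel(spec, profiles)
        config = MCMCConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
            sigma_rho_frac=self.sigma_rho_frac,
            delta_prop_sd=self.delta_prop_sd,
        )
        trace, manifest, _ = run_chain(data, profiles, prior, config)
        self.data_ = data
        self.profiles_ = profiles
        self.prior_ = prior
        self.trace_ = trace
        self.manifest_ = manifest
        self.summary_ = summarize(trace)
        self.posterior_sets_ = self.summary_.set_probabilities
        self.inclusion_probabilities_ = self.summary_.inclusion
        self.nu_distribution_ = self.summary_.nu_distribution
        top = self.posterior_sets_[0][0]
        self.logic_ = classify_logic(trace, top)
        return self

    def score(self, X=None, y=None):
        """Posterior mean log-likelihood of the retained draws."""
        self._check_fitted()
        return float(np.mean(self.trace_.loglik))

    def _check_fitted(self):
        if not hasattr(self, "trace_"):
            raise RuntimeError("estimator is not fitted")
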