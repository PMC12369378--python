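"""One-sample Bayesian estimation with a Student-t model ("BEST").

The data are modelled as t(nu, mu, sigma) with the method's standard vague
priors: mu ~ Normal(sample mean, 1000 * sample sd), sigma ~ Uniform(sd/1000,
1000 * sd), nu - 1 ~ Exponential(1/29). The posterior is sampled with an
affine-invariant ensemble sampler; the walkers are grouped into chains for a
split-R-hat convergence check and the 95% highest-density interval for mu is
returned.
"""
from __future__ import annotations

import arviz as az
import emcee
import numpy as np
from scipy import stats


def best_one_sample_interval(
    values: np.ndarray,
    seed: int,
    chains: int = 4,
    draws: int = 10_000,
    rhat_limit: float = 1.05,
    return_posterior: bool = False,
):
    """95% HDI for the location mu of a one-sample Student-t model.

    ``draws`` is the total number of retained posterior draws across all
    walkers (after burn-in). Raises if split-R-hat for mu exceeds
    ``rhat_limit``.
    """
    x = np.asarray(values, float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    m, s = float(np.mean(x)), float(np.std(x, ddof=1))
    if s == 0:
        raise ValueError("zero-variance sample")
    mu_sd = 1000.0 * s
    sig_lo, sig_hi = s / 1000.0, 1000.0 * s

    def log_prob(theta: np.ndarray) -> np.ndarray:
        # theta columns: mu, log sigma, log(nu - 1)
        mu, log_sig, log_num1 = theta[:, 0], theta[:, 1], theta[:, 2]
        sig = np.exp(log_sig)
        nu = 1.0 + np.exp(log_num1)
        lp = np.full(len(theta), -np.inf)
        ok = (sig > sig_lo) & (sig < sig_hi) & np.isfinite(nu)
        if not ok.any():
            return lp
        mu_o, sig_o, nu_o = mu[ok], sig[ok], nu[ok]
        ll = stats.t.logpdf(x[:, None], df=nu_o, loc=mu_o, scale=sig_o).sum(axis=0)
        prior = (
            stats.norm.logpdf(mu_o, m, mu_sd)
            + log_sig[ok]  # Jacobian of sigma ~ Uniform under log-sigma
            - (nu_o - 1.0) / 29.0 + log_num1[ok]  # Exp(1/29) + Jacobian
        )
        lp[ok] = ll + prior
        return lp

    nwalkers = max(8, 2 * chains)
    rng = np.random.default_rng(seed)
    p0 = np.column_stack([
        m + rng.normal(0, s / np.sqrt(n), nwalkers),
        np.log(s) + rng.normal(0, 0.05, nwalkers),
        np.log(29.0) + rng.normal(0, 0.5, nwalkers),
    ])
    steps = max(200, int(np.ceil(draws / nwalkers)))
    burn = max(200, steps // 2)
    sampler = emcee.EnsembleSampler(nwalkers, 3, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, burn + steps, progress=False)
    mu_chain = sampler.get_chain()[burn:, :, 0]  # (steps, walkers)
    # group walkers into `chains` pseudo-chains for split-R-hat
    grouped = mu_chain.T.reshape(chains, -1)
    rhat = float(az.rhat(az.convert_to_dataset(grouped))["x"])
    if not np.isfinite(rhat) or rhat > rhat_limit:
        raise RuntimeError(f"posterior did not converge: split-R-hat = {rhat:.3f}")
    flat = mu_chain.reshape(-1)
    hdi = az.hdi(flat, hdi_prob=0.95)
    if return_posterior:
        return float(hdi[0]), float(hdi[1]), flat
    return float(hdi[0]), float(hdi[1])
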