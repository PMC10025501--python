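"""Shared independent oracles for the test suite."""

import numpy as np


def grid_posterior_means(y, theta, loc, scale, mu, sd, n_grid=401):
    """Brute-force 2-D grid integration of one 2PL item's posterior.

    Sampling coordinates are (log alpha, b) with independent normal priors
    N(loc, scale) and N(mu, sd); the likelihood is Bernoulli with success
    probability sigmoid(alpha*theta + alpha*b).  Returns posterior means of
    (alpha, b, d = alpha*b).  Deliberately independent of the MCMC code path.
    """
    loga = np.linspace(loc - 5 * scale, loc + 5 * scale, n_grid)
    b = np.linspace(mu - 5 * sd, mu + 5 * sd, n_grid)
    LA, B = np.meshgrid(loga, b, indexing="ij")
    alpha = np.exp(LA)
    z = alpha[None] * theta[:, None, None] + (alpha * B)[None]
    loglik = (y[:, None, None] * z - np.logaddexp(0.0, z)).sum(axis=0)
    logprior = -0.5 * ((LA - loc) / scale) ** 2 - 0.5 * ((B - mu) / sd) ** 2
    w = np.exp(loglik + logprior - (loglik + logprior).max())
    w /= w.sum()
    return (
        float((alpha * w).sum()),
        float((B * w).sum()),
        float((alpha * B * w).sum()),
    )
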