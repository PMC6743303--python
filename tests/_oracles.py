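"""Independent brute-force oracles used to validate the statistical core.

These deliberately re-derive each quantity from first principles (explicit
loops, full enumeration) and share no code with the implementation paths
they check.
"""

import numpy as np
from scipy import stats
from scipy.special import comb


def oracle_partial_loglik(beta, time, event, x, ties="efron"):
    """Naive Cox partial log-likelihood with explicit loops."""
    ll = 0.0
    for ut in sorted(set(time[event == 1])):
        at_risk = time >= ut
        dead = (time == ut) & (event == 1)
        m = dead.sum()
        ll += beta * x[dead].sum()
        s_risk = np.exp(beta * x[at_risk]).sum()
        s_dead = np.exp(beta * x[dead]).sum()
        for l in range(m):
            f = l / m if ties == "efron" else 0.0
            ll -= np.log(s_risk - f * s_dead)
    return ll


def binomial_oracle(k, n, p0, sidedness):
    """Exact binomial p-value by direct pmf enumeration."""
    pmf = [comb(n, i, exact=True) * p0 ** i * (1 - p0) ** (n - i)
           for i in range(n + 1)]
    if sidedness == "one-sided":
        return sum(pmf[k:])
    if sidedness == "less":
        return sum(pmf[:k + 1])
    p_obs = pmf[k]
    return sum(p for p in pmf if p <= p_obs * (1 + 1e-7))


def fisher_two_sided_oracle(a, b, c, d):
    """Minimum-likelihood two-sided Fisher p by full hypergeometric
    enumeration over all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    probs = []
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((aa, stats.hypergeom.pmf(aa, n, r1, c1)))
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-7))
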