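"""Numba inner loops for the collapsed Gibbs sampler.

The sweep functions mutate the count state in place, visiting tokens in a
fixed order (document order, then token position).  Randomness enters only
through the pre-drawn ``uniforms`` array, one variate per token, so a run
is bitwise reproducible for a given seed regardless of compilation."""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweep(doc_of, word_of, z, n_dk, n_kw, n_k, alpha, beta, uniforms, cum):
    """One full collapsed-Gibbs sweep.

    Each token's topic is resampled from
    P(z_i = k | z_-i, w) propto (n_dk + alpha) (n_kw + beta) / (n_k + V beta)
    with the token itself removed from all counts.
    """
    K = n_k.shape[0]
    V = n_kw.shape[1]
    v_beta = V * beta
    for i in range(z.shape[0]):
        d = doc_of[i]
        w = word_of[i]
        k_old = z[i]
        n_dk[d, k_old] -= 1
        n_kw[k_old, w] -= 1
        n_k[k_old] -= 1
        total = 0.0
        for k in range(K):
            total += (n_dk[d, k] + alpha) * (n_kw[k, w] + beta) / (n_k[k] + v_beta)
            cum[k] = total
        u = uniforms[i] * total
        k_new = K - 1
        for k in range(K):
            if u <= cum[k]:
                k_new = k
                break
        z[i] = k_new
        n_dk[d, k_new] += 1
        n_kw[k_new, w] += 1
        n_k[k_new] += 1


@njit(cache=True)
def foldin_sweep(doc_of, word_of, z, n_dk, phi, alpha, uniforms, cum):
    """Fold-in sweep for held-out documents: phi held fixed, only the
    document-topic counts resampled (P propto (n_dk + alpha) * phi[k, w])."""
    K = phi.shape[0]
    for i in range(z.shape[0]):
        d = doc_of[i]
        w = word_of[i]
        k_old = z[i]
        n_dk[d, k_old] -= 1
        total = 0.0
        for k in range(K):
            total += (n_dk[d, k] + alpha) * phi[k, w]
            cum[k] = total
        u = uniforms[i] * total
        k_new = K - 1
        for k in range(K):
            if u <= cum[k]:
                k_new = k
                break
        z[i] = k_new
        n_dk[d, k_new] += 1
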