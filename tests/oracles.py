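"""Brute-force path-enumeration oracles for the copying HMM.

Independent of the forward-backward implementation: probabilities are
summed over every explicit state path.
"""

import numpy as np


def enumerate_haploid_dosage(obs, refs, rho, theta):
    """Brute-force posterior allele probabilities of the haploid copying
    chain: sum over ALL K^M state paths of P(path) * P(obs | path), then
    the posterior expectation of the emitted allele at every site."""
    refs = np.asarray(refs, dtype=np.int64)
    K, M = refs.shape
    n_paths = K ** M
    digits = (np.arange(n_paths)[:, None] // (K ** np.arange(M - 1, -1, -1))) % K
    trans = np.where(
        digits[:, 1:] == digits[:, :-1], (1 - rho) + rho / K, rho / K
    ).prod(axis=1) / K
    alleles = refs[digits, np.arange(M)]
    emit = np.ones(n_paths)
    for j in range(M):
        if obs[j] >= 0:
            emit *= np.where(alleles[:, j] == obs[j], 1 - theta, theta)
    w = trans * emit
    z = w.sum()
    # P(emitted allele = 1) = theta + (1-2theta) * P(copied allele = 1)
    p_copy = (w[:, None] * alleles).sum(axis=0) / z
    return theta + (1 - 2 * theta) * p_copy


def enumerate_diploid(geno, refs, rho, theta):
    """Brute-force diploid posterior over all ordered pairs of copying
    paths, with unordered-genotype emissions coupling the two chains."""
    refs = np.asarray(refs, dtype=np.int64)
    K, M = refs.shape
    n_paths = K ** M
    digits = (np.arange(n_paths)[:, None] // (K ** np.arange(M - 1, -1, -1))) % K
    trans = np.where(
        digits[:, 1:] == digits[:, :-1], (1 - rho) + rho / K, rho / K
    ).prod(axis=1) / K
    q = theta + (1 - 2 * theta) * refs[digits, np.arange(M)]  # P(allele 1)
    w_pair = np.ones((n_paths, n_paths))
    for j in range(M):
        g = geno[j]
        if g < 0:
            continue
        q1 = q[:, j][:, None]
        q2 = q[:, j][None, :]
        if g == 0:
            e = (1 - q1) * (1 - q2)
        elif g == 2:
            e = q1 * q2
        else:
            e = q1 * (1 - q2) + (1 - q1) * q2
        w_pair = w_pair * e
    w_pair = w_pair * trans[:, None] * trans[None, :]
    z = w_pair.sum()
    dosage = np.empty(M)
    for j in range(M):
        q1 = q[:, j][:, None]
        q2 = q[:, j][None, :]
        dosage[j] = (w_pair * (q1 + q2)).sum() / z
    return dosage
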