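"""Haplotype-copying imputation engine.

Each sample haplotype is modelled as an imperfect mosaic of the K reference
haplotypes (a Li-Stephens hidden Markov model): the hidden state at marker j
is the reference haplotype being copied, switches between adjacent markers
occur with probability ``rho_j = 1 - exp(-4*Ne*d_j/K)`` (``d_j`` the
inter-marker distance in Morgans under a uniform genetic map), and the
emitted allele differs from the copied one with copy-error probability
``theta`` (default: the usual 1/(harmonic-number) mutation-rate estimate).

Imputation of an unphased target proceeds in two steps per individual:

1. the typed genotypes are phased against the reference panel by greedy
   forward pair decoding of two coupled copying chains (het sites are
   assigned to the orientation with higher joint forward likelihood);
2. each phased haplotype is run through the exact haploid forward-backward
   recursion over the *full* panel marker grid, with untyped markers treated
   as missing emissions; the posterior copying distribution then yields the
   allele probability ``theta + (1-2*theta) * sum_k gamma_k * a_k`` at every
   marker.

Because every reference haplotype carries exactly one classical allele per
gene, the per-gene classical dosages of an imputed individual sum to
``2 + theta*(A-2)*2 ~ 2`` by construction.

The forward-backward and phasing inner loops are numba-jitted; an exact
small-K diploid forward-backward over ordered haplotype pairs is provided
for oracle cross-checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import BinaryMarker, reduce_resolution
from .panel import ReferencePanel

logger = logging.getLogger(__name__)

try:  # pragma: no cover - numba is a hard dependency, fallback eases debugging
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco(args[0]) if args and callable(args[0]) else deco

__all__ = [
    "HmmParams",
    "TargetGenotypes",
    "DosageResult",
    "li_stephens_theta",
    "switch_probs",
    "haploid_posteriors",
    "allele_posteriors",
    "phase_genotypes",
    "diploid_posteriors_exact",
    "diploid_viterbi_phase",
    "harmonize",
    "impute",
    "best_guess",
    "call_classical",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class HmmParams:
    """Copying-model parameters.

    ``ne``: effective population size for the switch rate (default 15,000).
    ``cm_per_mb``: uniform genetic map density (default 1 cM/Mb).
    ``theta``: copy-error rate; ``None`` selects the K-dependent
    Li-Stephens default.  ``sweeps``: phasing sweeps for panel phasing.
    ``window``: markers per imputation window (0 = whole region).
    """

    ne: float = 15_000.0
    cm_per_mb: float = 1.0
    theta: float | None = None
    sweeps: int = 10
    window: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.theta is not None and not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie in (0, 1)")
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")


@dataclass
class TargetGenotypes:
    """Harmonized target sample genotypes on a subset of panel markers."""

    individuals: list[str]
    marker_ids: list[str]
    positions: np.ndarray
    geno: np.ndarray  # (n, T) float, NaN = missing

    def __post_init__(self):
        self.geno = np.asarray(self.geno, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.geno.shape != (len(self.individuals), len(self.marker_ids)):
            raise ValueError("genotype matrix shape mismatch")
        if len(self.marker_ids) == 0:
            raise ValueError("typed marker set is empty")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("typed markers must be position-sorted")


def li_stephens_theta(k: int) -> float:
    """Default copy-error rate for a K-haplotype panel:
    ``w/(2*(K + w))`` with ``w = 1 / sum_{i=1}^{K-1} 1/i``."""
    if k < 2:
        raise ValueError("need at least 2 reference haplotypes")
    w = 1.0 / np.sum(1.0 / np.arange(1, k))
    return float(w / (2.0 * (k + w)))


def switch_probs(positions: np.ndarray, k: int, params: HmmParams) -> np.ndarray:
    """Per-interval switch probability ``1 - exp(-4*Ne*d/K)`` with ``d`` the
    interval length in Morgans under a uniform ``cm_per_mb`` map."""
    d_bp = np.diff(np.asarray(positions, dtype=np.float64))
    if np.any(d_bp < 0):
        raise ValueError("positions must be sorted")
    d_morgans = d_bp * params.cm_per_mb * 1e-8
    rho = 1.0 - np.exp(-4.0 * params.ne * d_morgans / float(k))
    return np.clip(rho, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True)
def _forward(obs, refs, rho, theta, alphas):
    """Scaled forward pass; returns log-likelihood.  ``obs`` is (M,) int8
    with -1 for missing; ``refs`` is (K, M) int8; ``alphas`` is (M, K) out."""
    K, M = refs.shape
    one_m = 1.0 - theta
    ll = 0.0
    c = 0.0
    o = obs[0]
    for k in range(K):
        a = 1.0 / K
        if o >= 0:
            a *= one_m if refs[k, 0] == o else theta
        alphas[0, k] = a
        c += a
    ll += np.log(c)
    inv = 1.0 / c
    for k in range(K):
        alphas[0, k] *= inv
    for j in range(1, M):
        r = rho[j - 1]
        stay = 1.0 - r
        jump = r / K
        o = obs[j]
        c = 0.0
        if o >= 0:
            for k in range(K):
                a = stay * alphas[j - 1, k] + jump
                a *= one_m if refs[k, j] == o else theta
                alphas[j, k] = a
                c += a
        else:
            for k in range(K):
                a = stay * alphas[j - 1, k] + jump
                alphas[j, k] = a
                c += a
        ll += np.log(c)
        inv = 1.0 / c
        for k in range(K):
            alphas[j, k] *= inv
    return ll


@njit(cache=False, fastmath=True)
def _backward_gamma(obs, refs, rho, theta, alphas, gamma):
    """Backward pass combining with stored forward into state posteriors."""
    K, M = refs.shape
    one_m = 1.0 - theta
    b = np.ones(K)
    t = np.empty(K)
    for k in range(K):
        gamma[M - 1, k] = alphas[M - 1, k]
    for j in range(M - 2, -1, -1):
        o = obs[j + 1]
        tsum = 0.0
        if o >= 0:
            for k in range(K):
                tk = b[k] * (one_m if refs[k, j + 1] == o else theta)
                t[k] = tk
                tsum += tk
        else:
            for k in range(K):
                t[k] = b[k]
                tsum += b[k]
        r = rho[j]
        stay = 1.0 - r
        jump = r * tsum / K
        bs = 0.0
        gs = 0.0
        for k in range(K):
            bk = stay * t[k] + jump
            b[k] = bk
            bs += bk
            g = alphas[j, k] * bk
            gamma[j, k] = g
            gs += g
        inv_b = 1.0 / bs
        inv_g = 1.0 / gs
        for k in range(K):
            b[k] *= inv_b
            gamma[j, k] *= inv_g


@njit(cache=False, fastmath=True)
def _backward_dosage(obs, refs, rho, theta, alphas, need, out_p):
    """Backward pass fused with copy-posterior extraction.

    Where ``need[j]`` is set, writes ``sum_k gamma_jk * a_kj`` (the posterior
    probability of copying allele 1) into ``out_p[j]``; avoids materializing
    the full (M, K) posterior matrix."""
    K, M = refs.shape
    one_m = 1.0 - theta
    b = np.ones(K)
    t = np.empty(K)
    if need[M - 1]:
        num = 0.0
        for k in range(K):
            num += alphas[M - 1, k] * refs[k, M - 1]
        out_p[M - 1] = num
    for j in range(M - 2, -1, -1):
        o = obs[j + 1]
        tsum = 0.0
        if o >= 0:
            for k in range(K):
                tk = b[k] * (one_m if refs[k, j + 1] == o else theta)
                t[k] = tk
                tsum += tk
        else:
            for k in range(K):
                t[k] = b[k]
                tsum += b[k]
        r = rho[j]
        stay = 1.0 - r
        jump = r * tsum / K
        if need[j]:
            bs = 0.0
            gs = 0.0
            num = 0.0
            for k in range(K):
                bk = stay * t[k] + jump
                b[k] = bk
                bs += bk
                g = alphas[j, k] * bk
                gs += g
                num += g * refs[k, j]
            out_p[j] = num / gs
            inv_b = 1.0 / bs
            for k in range(K):
                b[k] *= inv_b
        else:
            bs = 0.0
            for k in range(K):
                bk = stay * t[k] + jump
                b[k] = bk
                bs += bk
            inv_b = 1.0 / bs
            for k in range(K):
                b[k] *= inv_b


@njit(cache=False, fastmath=True)
def _haploid_loglik(hap, refs, rho, theta):
    K, M = refs.shape
    a = np.empty(K)
    for k in range(K):
        a[k] = 1.0 / K
    ll = 0.0
    for j in range(M):
        if j > 0:
            r = rho[j - 1]
            for k in range(K):
                a[k] = (1.0 - r) * a[k] + r / K
        o = hap[j]
        if o >= 0:
            for k in range(K):
                if refs[k, j] == o:
                    a[k] *= 1.0 - theta
                else:
                    a[k] *= theta
        c = 0.0
        for k in range(K):
            c += a[k]
        ll += np.log(c)
        for k in range(K):
            a[k] /= c
    return ll


@njit(cache=False, fastmath=True)
def _greedy_phase(geno, refs, rho, theta, h1, h2):
    """Greedy forward decoding of two coupled copying chains.

    At each heterozygous site the allele orientation with the larger joint
    forward mass is chosen; homozygous sites are forced; missing genotypes
    yield -1 in both output haplotypes.
    """
    K, M = refs.shape
    one_m = 1.0 - theta
    f1 = np.empty(K)
    f2 = np.empty(K)
    for k in range(K):
        f1[k] = 1.0 / K
        f2[k] = 1.0 / K
    for j in range(M):
        stay = 1.0
        jump = 0.0
        if j > 0:
            r = rho[j - 1]
            stay = 1.0 - r
            jump = r / K
        g = geno[j]
        if g == 1:
            s11 = 0.0
            s10 = 0.0
            s21 = 0.0
            s20 = 0.0
            for k in range(K):
                t1 = stay * f1[k] + jump
                t2 = stay * f2[k] + jump
                f1[k] = t1
                f2[k] = t2
                e1 = one_m if refs[k, j] == 1 else theta
                e0 = 1.0 - e1
                s11 += t1 * e1
                s10 += t1 * e0
                s21 += t2 * e1
                s20 += t2 * e0
            first_gets_1 = s11 * s20 >= s10 * s21
            if first_gets_1:
                h1[j] = 1
                h2[j] = 0
                inv1 = 1.0 / s11
                inv2 = 1.0 / s20
            else:
                h1[j] = 0
                h2[j] = 1
                inv1 = 1.0 / s10
                inv2 = 1.0 / s21
            for k in range(K):
                e1 = one_m if refs[k, j] == 1 else theta
                e0 = 1.0 - e1
                if first_gets_1:
                    f1[k] *= e1 * inv1
                    f2[k] *= e0 * inv2
                else:
                    f1[k] *= e0 * inv1
                    f2[k] *= e1 * inv2
        elif g == 0 or g == 2:
            a = 0
            if g == 2:
                a = 1
            h1[j] = a
            h2[j] = a
            c1 = 0.0
            c2 = 0.0
            for k in range(K):
                e = one_m if refs[k, j] == a else theta
                t1 = (stay * f1[k] + jump) * e
                t2 = (stay * f2[k] + jump) * e
                f1[k] = t1
                f2[k] = t2
                c1 += t1
                c2 += t2
            inv1 = 1.0 / c1
            inv2 = 1.0 / c2
            for k in range(K):
                f1[k] *= inv1
                f2[k] *= inv2
        else:
            h1[j] = -1
            h2[j] = -1
            c1 = 0.0
            c2 = 0.0
            for k in range(K):
                t1 = stay * f1[k] + jump
                t2 = stay * f2[k] + jump
                f1[k] = t1
                f2[k] = t2
                c1 += t1
                c2 += t2
            inv1 = 1.0 / c1
            inv2 = 1.0 / c2
            for k in range(K):
                f1[k] *= inv1
                f2[k] *= inv2


# ---------------------------------------------------------------------------
# python API over the kernels
# ---------------------------------------------------------------------------

def haploid_posteriors(obs, refs, rho, theta, return_loglik: bool = False):
    """State posteriors (M, K) of the haploid copying chain given an observed
    allele vector (-1 = missing) against (K, M) reference haplotypes."""
    obs = np.ascontiguousarray(obs, dtype=np.int8)
    refs = np.ascontiguousarray(refs, dtype=np.int8)
    K, M = refs.shape
    if obs.shape[0] != M:
        raise ValueError("observation length does not match panel width")
    alphas = np.empty((M, K))
    gamma = np.empty((M, K))
    ll = _forward(obs, refs, np.asarray(rho, dtype=np.float64), float(theta), alphas)
    _backward_gamma(obs, refs, np.asarray(rho, dtype=np.float64), float(theta), alphas, gamma)
    return (gamma, ll) if return_loglik else gamma


def allele_posteriors(gamma: np.ndarray, refs: np.ndarray, theta: float) -> np.ndarray:
    """P(haplotype allele = 1) per marker from state posteriors:
    ``theta + (1-2*theta) * sum_k gamma_k a_k``."""
    copy_p = np.einsum("mk,km->m", gamma, np.asarray(refs, dtype=np.float64))
    return theta + (1.0 - 2.0 * theta) * copy_p


def phase_genotypes(geno, refs, rho, theta, both_directions: bool = False):
    """Phase one individual's genotype vector (0/1/2, -1 missing) against a
    reference panel by greedy pair decoding.  With ``both_directions`` the
    reverse-order decoding is also computed and the orientation with higher
    joint haploid likelihood is kept."""
    geno = np.ascontiguousarray(geno, dtype=np.int8)
    refs = np.ascontiguousarray(refs, dtype=np.int8)
    rho = np.asarray(rho, dtype=np.float64)
    M = geno.shape[0]
    h1 = np.empty(M, dtype=np.int8)
    h2 = np.empty(M, dtype=np.int8)
    _greedy_phase(geno, refs, rho, float(theta), h1, h2)
    if not both_directions:
        return h1, h2
    g_r = np.ascontiguousarray(geno[::-1])
    refs_r = np.ascontiguousarray(refs[:, ::-1])
    rho_r = np.ascontiguousarray(rho[::-1])
    r1 = np.empty(M, dtype=np.int8)
    r2 = np.empty(M, dtype=np.int8)
    _greedy_phase(g_r, refs_r, rho_r, float(theta), r1, r2)
    r1, r2 = np.ascontiguousarray(r1[::-1]), np.ascontiguousarray(r2[::-1])
    ll_f = _haploid_loglik(h1, refs, rho, theta) + _haploid_loglik(h2, refs, rho, theta)
    ll_r = _haploid_loglik(r1, refs, rho, theta) + _haploid_loglik(r2, refs, rho, theta)
    return (h1, h2) if ll_f >= ll_r else (r1, r2)


def diploid_viterbi_phase(geno, refs, rho, theta):
    """Phase one genotype vector by joint diploid Viterbi decoding over
    ordered reference-haplotype pairs (small K only; K^2 states).

    The MAP ordered pair of copying paths breaks the haplotype-exchange
    symmetry consistently along the chromosome (per-site posterior
    marginals are exactly 1/2 at het sites by exchangeability, so a joint
    decoding is required).  At each het site, haplotype 1 takes the allele
    better explained by its copied reference allele.  Missing genotypes
    yield -1 in both haplotypes.
    """
    geno = np.asarray(geno, dtype=np.int64)
    refs = np.asarray(refs, dtype=np.int64)
    K, M = refs.shape
    lq1 = np.log(theta + (1.0 - 2.0 * theta) * refs.astype(float))  # log P(1|k)
    lq0 = np.log(1.0 - np.exp(lq1))
    q = np.exp(lq1)

    def log_emis(j):
        g = geno[j]
        if g < 0:
            return np.zeros((K, K))
        if g == 0:
            return lq0[:, j][:, None] + lq0[:, j][None, :]
        if g == 2:
            return lq1[:, j][:, None] + lq1[:, j][None, :]
        a = q[:, j][:, None] * (1 - q[:, j])[None, :]
        return np.log(a + a.T)

    V = np.empty((M, K, K))
    V[0] = -2.0 * np.log(K) + log_emis(0)
    for j in range(1, M):
        r = rho[j - 1]
        l_stay = np.log(1.0 - r + r / K)
        l_jump = np.log(r / K)
        prev = V[j - 1]
        # max over k1' of prev + t(k1'->k1), factorized per column
        colmax = prev.max(axis=0)  # over k1'
        m1 = np.maximum(prev + l_stay, colmax[None, :] + l_jump)
        rowmax = m1.max(axis=1)  # over k2'
        V[j] = np.maximum(m1 + l_stay, rowmax[:, None] + l_jump) + log_emis(j)
        V[j] -= V[j].max()  # rescale
    # traceback
    k1 = np.empty(M, dtype=np.int64)
    k2 = np.empty(M, dtype=np.int64)
    flat = int(np.argmax(V[M - 1]))
    k1[M - 1], k2[M - 1] = divmod(flat, K)
    for j in range(M - 2, -1, -1):
        r = rho[j]
        l_stay = np.log(1.0 - r + r / K)
        l_jump = np.log(r / K)
        t1 = np.full(K, l_jump)
        t1[k1[j + 1]] = l_stay
        t2 = np.full(K, l_jump)
        t2[k2[j + 1]] = l_stay
        score = V[j] + t1[:, None] + t2[None, :]
        flat = int(np.argmax(score))
        k1[j], k2[j] = divmod(flat, K)
    return _phase_from_pair_path(geno, refs, k1, k2)


def _phase_from_pair_path(geno, refs, k1, k2):
    M = len(geno)
    h1 = np.empty(M, dtype=np.int8)
    h2 = np.empty(M, dtype=np.int8)
    for j in range(M):
        g = geno[j]
        if g == 1:
            a1 = refs[k1[j], j]
            a2 = refs[k2[j], j]
            if a1 == a2:  # one copy error; keep chain 1 on its reference
                h1[j], h2[j] = a1, 1 - a1
            else:
                h1[j], h2[j] = a1, a2
        elif g == 0 or g == 2:
            h1[j] = h2[j] = g // 2
        else:
            h1[j] = h2[j] = -1
    return h1, h2


def diploid_sample_phase(geno, refs, rho, theta, rng):
    """Phase one genotype vector by sampling an ordered pair of copying
    paths from its exact diploid posterior (forward filter, backward
    sample; small K only).

    Used for the stochastic early sweeps of iterative panel phasing, where
    deterministic decoding against unconverged reference haplotypes gets
    trapped in local optima.
    """
    geno = np.asarray(geno, dtype=np.int64)
    refs = np.asarray(refs, dtype=np.int64)
    K, M = refs.shape
    q = theta + (1.0 - 2.0 * theta) * refs.astype(float)

    def emis(j):
        q1 = q[:, j][:, None]
        q2 = q[:, j][None, :]
        g = geno[j]
        if g < 0:
            return np.ones((K, K))
        if g == 0:
            return (1 - q1) * (1 - q2)
        if g == 2:
            return q1 * q2
        return q1 * (1 - q2) + (1 - q1) * q2

    alphas = np.empty((M, K, K))
    a = np.full((K, K), 1.0 / (K * K)) * emis(0)
    a /= a.sum()
    alphas[0] = a
    for j in range(1, M):
        r = rho[j - 1]
        b = (1 - r) * a + r * a.sum(axis=0, keepdims=True) / K
        a = (1 - r) * b + r * b.sum(axis=1, keepdims=True) / K
        a = a * emis(j)
        a /= a.sum()
        alphas[j] = a
    k1 = np.empty(M, dtype=np.int64)
    k2 = np.empty(M, dtype=np.int64)
    flat = rng.choice(K * K, p=alphas[M - 1].ravel())
    k1[M - 1], k2[M - 1] = divmod(int(flat), K)
    for j in range(M - 2, -1, -1):
        r = rho[j]
        stay = 1.0 - r + r / K
        jump = r / K
        t1 = np.full(K, jump)
        t1[k1[j + 1]] = stay
        t2 = np.full(K, jump)
        t2[k2[j + 1]] = stay
        w = alphas[j] * t1[:, None] * t2[None, :]
        w = w.ravel()
        w /= w.sum()
        flat = rng.choice(K * K, p=w)
        k1[j], k2[j] = divmod(int(flat), K)
    return _phase_from_pair_path(geno, refs, k1, k2)


def diploid_posteriors_exact(geno, refs, rho, theta):
    """Exact diploid forward-backward over ordered reference-haplotype pairs.

    Intended for small K (state space K^2); used as the oracle cross-check
    for the production phase-then-haploid pipeline.  Returns per-marker
    genotype posteriors (M, 3) and allele dosages (M,) for one individual's
    genotype vector (0/1/2, -1 missing).
    """
    geno = np.asarray(geno, dtype=np.int64)
    refs = np.asarray(refs, dtype=np.int64)
    K, M = refs.shape
    # per-hap allele-1 emission probability by state and marker
    q = theta + (1.0 - 2.0 * theta) * refs.astype(float)  # (K, M)

    def emis(j):
        q1 = q[:, j][:, None]  # hap-1 state axis
        q2 = q[:, j][None, :]
        g = geno[j]
        if g < 0:
            return np.ones((K, K))
        if g == 0:
            return (1 - q1) * (1 - q2)
        if g == 2:
            return q1 * q2
        return q1 * (1 - q2) + (1 - q1) * q2

    alphas = np.empty((M, K, K))
    a = np.full((K, K), 1.0 / (K * K)) * emis(0)
    a /= a.sum()
    alphas[0] = a
    for j in range(1, M):
        r = rho[j - 1]
        b = (1 - r) * a + r * a.sum(axis=0, keepdims=True) / K
        a = (1 - r) * b + r * b.sum(axis=1, keepdims=True) / K
        a = a * emis(j)
        a /= a.sum()
        alphas[j] = a
    gp = np.empty((M, 3))
    dos = np.empty(M)
    bw = np.ones((K, K))
    for j in range(M - 1, -1, -1):
        g = alphas[j] * bw
        g /= g.sum()
        q1 = q[:, j][:, None]
        q2 = q[:, j][None, :]
        p0 = (g * (1 - q1) * (1 - q2)).sum()
        p2 = (g * q1 * q2).sum()
        gp[j] = (p0, 1.0 - p0 - p2, p2)
        dos[j] = (g * (q1 + q2)).sum()
        if j > 0:
            t = bw * emis(j)
            r = rho[j - 1]
            b = (1 - r) * t + r * t.sum(axis=0, keepdims=True) / K
            bw = (1 - r) * b + r * b.sum(axis=1, keepdims=True) / K
            bw /= bw.sum()
    return gp, dos


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(
    target_geno: pd.DataFrame,
    target_meta: pd.DataFrame,
    panel: ReferencePanel,
    maf_min: float = 0.025,
    ambiguous_freq_margin: float = 0.1,
):
    """Match raw target SNPs to the panel: restrict to the MHC window, drop
    low-MAF SNPs (target MAF < 2.5%), orient alleles to the panel strand
    (flipping complement-matching sites), and resolve or drop strand-ambiguous
    A/T and C/G sites by frequency matching.

    ``target_meta`` must carry columns ``id``, ``position``, ``a1``, ``a2``
    (genotype values count the ``a1`` allele).  Returns ``(TargetGenotypes,
    report)``; raises if no marker overlaps the panel.
    """
    meta = target_meta.set_index("id")
    panel_snps = {
        m.position: m for m in panel.markers if m.kind == "SNP"
    }
    lo, hi = panel.window
    panel_freq = dict(zip(panel.marker_ids, panel.frequencies()))
    rows = []
    kept_ids: list[str] = []
    kept_panel_ids: list[str] = []
    geno_cols: dict[str, np.ndarray] = {}
    for sid in target_geno.columns:
        if sid not in meta.index:
            rows.append({"marker": sid, "action": "dropped", "reason": "NO_POSITION"})
            continue
        pos = int(meta.loc[sid, "position"])
        if not (lo <= pos <= hi):
            rows.append({"marker": sid, "action": "dropped", "reason": "OUTSIDE_WINDOW"})
            continue
        g = target_geno[sid].to_numpy(dtype=float)
        gg = g[~np.isnan(g)]
        if gg.size == 0:
            rows.append({"marker": sid, "action": "dropped", "reason": "ALL_MISSING"})
            continue
        f = gg.sum() / (2.0 * gg.size)
        if min(f, 1 - f) < maf_min:
            rows.append({"marker": sid, "action": "dropped", "reason": "LOW_MAF"})
            continue
        pm = panel_snps.get(pos)
        if pm is None:
            rows.append({"marker": sid, "action": "dropped", "reason": "NOT_IN_PANEL"})
            continue
        a1 = str(meta.loc[sid, "a1"]).upper()
        a2 = str(meta.loc[sid, "a2"]).upper()
        pa = {pm.present_label, pm.absent_label}
        direct = {a1, a2} == pa
        comp = (
            a1 in _COMPLEMENT
            and a2 in _COMPLEMENT
            and {_COMPLEMENT[a1], _COMPLEMENT[a2]} == pa
        )
        ambiguous = a1 in _COMPLEMENT and _COMPLEMENT[a1] == a2
        if not direct and not comp:
            rows.append({"marker": sid, "action": "dropped", "reason": "ALLELE_MISMATCH"})
            continue
        if ambiguous:
            pf = panel_freq[pm.id]
            if abs(pf - 0.5) <= ambiguous_freq_margin:
                rows.append({"marker": sid, "action": "dropped", "reason": "AMBIGUOUS_STRAND"})
                continue
            # orient so the target presence frequency matches the panel
            present_is_a1 = abs(f - pf) <= abs((1 - f) - pf)
            action = "kept_freq_matched"
        else:
            eff_a1 = a1 if direct else _COMPLEMENT[a1]
            present_is_a1 = eff_a1 == pm.present_label
            action = "kept" if direct else "flipped_strand"
            if direct and not present_is_a1:
                action = "swapped_alleles"
        geno_cols[pm.id] = g if present_is_a1 else 2.0 - g
        kept_ids.append(sid)
        kept_panel_ids.append(pm.id)
        rows.append({"marker": sid, "action": action, "reason": ""})
    report = pd.DataFrame(rows, columns=["marker", "action", "reason"])
    if not kept_panel_ids:
        raise ValueError("no overlap with panel after harmonization")
    idx = panel.marker_index()
    order = np.argsort([idx[p] for p in kept_panel_ids], kind="stable")
    kept_panel_ids = [kept_panel_ids[i] for i in order]
    positions = panel.positions[[idx[p] for p in kept_panel_ids]]
    geno = np.column_stack([geno_cols[p] for p in kept_panel_ids])
    tg = TargetGenotypes(
        individuals=list(target_geno.index),
        marker_ids=kept_panel_ids,
        positions=positions,
        geno=geno,
    )
    return tg, report


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

@dataclass
class DosageResult:
    """Posterior output of one imputation run.

    ``dosage`` (individual x marker, in [0, 2]) equals ``P1 + 2*P2`` exactly;
    ``gp`` holds the genotype posterior triples; ``best_guess`` the argmax
    calls (ties to the lower genotype, flagged); ``hap_prob``/``hap_calls``
    the per-haplotype allele probabilities and hard calls (phased output).
    """

    individuals: list[str]
    markers: list[BinaryMarker]
    dosage: pd.DataFrame
    gp: np.ndarray  # (n, M, 3)
    best_guess: pd.DataFrame
    tie_flags: np.ndarray  # (n, M) bool
    hap_prob: np.ndarray  # (n, 2, M)
    hap_calls: np.ndarray  # (n, 2, M) int8
    low_confidence: list[str] = field(default_factory=list)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]


def _window_spans(m: int, window: int):
    """Overlapping marker windows with non-overlapping core spans."""
    if window <= 0 or window >= m:
        return [(0, m, 0, m)]
    overlap = max(window // 5, 1)
    spans = []
    core_lo = 0
    while core_lo < m:
        core_hi = min(core_lo + window - (overlap if core_lo else 0), m)
        lo = max(core_lo - overlap, 0)
        hi = min(core_hi + overlap, m)
        spans.append((lo, hi, core_lo, core_hi))
        core_lo = core_hi
    return spans


def impute(
    target: TargetGenotypes,
    panel: ReferencePanel,
    params: HmmParams | None = None,
    markers: Sequence[str] | None = None,
    min_typed: int = 10,
) -> DosageResult:
    """Impute all panel markers into target individuals.

    Typed sites are phased against the panel, then each haplotype is decoded
    with the haploid forward-backward over the full panel grid (untyped
    markers as missing emissions).  ``markers`` restricts the reported output
    columns (the chain always runs over the whole panel).  Deterministic.
    """
    params = params or HmmParams()
    idx = panel.marker_index()
    missing = [m for m in target.marker_ids if m not in idx]
    if missing:
        raise ValueError(f"typed marker(s) not in panel: {missing[:5]}")
    typed_idx = np.asarray([idx[m] for m in target.marker_ids], dtype=np.int64)
    K = panel.n_haplotypes
    M = panel.n_markers
    theta = params.theta if params.theta is not None else li_stephens_theta(K)
    refs = np.ascontiguousarray(panel.haplotypes, dtype=np.int8)
    positions = panel.positions
    rho_full = switch_probs(positions, K, params)
    rho_typed = switch_probs(positions[typed_idx], K, params)
    refs_typed = np.ascontiguousarray(refs[:, typed_idx])

    out_ids = list(markers) if markers is not None else list(panel.marker_ids)
    bad = [m for m in out_ids if m not in idx]
    if bad:
        raise ValueError(f"requested output marker(s) not in panel: {bad[:5]}")
    out_idx = np.asarray([idx[m] for m in out_ids], dtype=np.int64)
    out_markers = [panel.markers[i] for i in out_idx]

    n = len(target.individuals)
    S = len(out_ids)
    dosage = np.empty((n, S))
    gp = np.empty((n, S, 3))
    hap_prob = np.empty((n, 2, S))
    low_conf: list[str] = []
    spans = _window_spans(M, params.window)

    geno_int = np.where(np.isnan(target.geno), -1, target.geno).astype(np.int8)
    obs = np.empty(M, dtype=np.int8)
    p_full = np.empty((2, M))
    need = np.zeros(M, dtype=np.uint8)
    need[out_idx] = 1
    alphas_buf = np.empty((M, K))
    pbuf = np.empty(M)
    for i in range(n):
        g = geno_int[i]
        if int((g >= 0).sum()) < min_typed:
            low_conf.append(target.individuals[i])
        h1, h2 = phase_genotypes(g, refs_typed, rho_typed, theta)
        for h_i, hap in enumerate((h1, h2)):
            obs.fill(-1)
            obs[typed_idx] = hap
            for lo, hi, core_lo, core_hi in spans:
                w = hi - lo
                _forward(obs[lo:hi], refs[:, lo:hi], rho_full[lo:hi - 1],
                         theta, alphas_buf[:w])
                _backward_dosage(obs[lo:hi], refs[:, lo:hi],
                                 rho_full[lo:hi - 1], theta, alphas_buf[:w],
                                 need[lo:hi], pbuf[:w])
                p_full[h_i, core_lo:core_hi] = pbuf[core_lo - lo:core_hi - lo]
        # copy posterior -> allele probability with copy-error flip
        p1 = theta + (1.0 - 2.0 * theta) * p_full[0, out_idx]
        p2 = theta + (1.0 - 2.0 * theta) * p_full[1, out_idx]
        hap_prob[i, 0] = p1
        hap_prob[i, 1] = p2
        gp[i, :, 0] = (1 - p1) * (1 - p2)
        gp[i, :, 2] = p1 * p2
        gp[i, :, 1] = 1.0 - gp[i, :, 0] - gp[i, :, 2]
        dosage[i] = gp[i, :, 1] + 2.0 * gp[i, :, 2]

    hap_calls = (hap_prob > 0.5).astype(np.int8)
    bg, ties = best_guess_from_gp(gp)
    dosage_df = pd.DataFrame(dosage, index=target.individuals, columns=out_ids)
    bg_df = pd.DataFrame(bg, index=target.individuals, columns=out_ids)
    if low_conf:
        logger.warning("low-confidence individuals (<%d typed markers): %s",
                       min_typed, low_conf)
    return DosageResult(
        individuals=list(target.individuals),
        markers=out_markers,
        dosage=dosage_df,
        gp=gp,
        best_guess=bg_df,
        tie_flags=ties,
        hap_prob=hap_prob,
        hap_calls=hap_calls,
        low_confidence=low_conf,
    )


def best_guess_from_gp(gp: np.ndarray, tol: float = 1e-9):
    """Argmax genotype calls from posterior triples; ties broken toward the
    lower genotype count and flagged."""
    gp = np.asarray(gp, dtype=float)
    mx = gp.max(axis=-1, keepdims=True)
    is_max = gp >= mx - tol
    bg = is_max.argmax(axis=-1)  # first (= lowest) index attaining the max
    ties = is_max.sum(axis=-1) > 1
    return bg.astype(np.int8), ties


def best_guess(result: DosageResult) -> pd.DataFrame:
    """Best-guess genotype table of a :class:`DosageResult`."""
    bg, _ = best_guess_from_gp(result.gp)
    return pd.DataFrame(bg, index=result.individuals, columns=result.marker_ids)


def call_classical(
    result: DosageResult,
    gene: str,
    resolution: int = 4,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Two-allele classical calls per individual from phased posteriors.

    Picks, per haplotype, the classical allele with maximal posterior among
    the gene's HLA4 markers; degenerate flat posteriors fall back to the
    lowest marker id with an ambiguity flag.  2-digit calls are emitted by
    label reduction.
    """
    cols = [
        j for j, m in enumerate(result.markers)
        if m.kind == "HLA4" and m.gene == gene
    ]
    if not cols:
        raise ValueError(f"no HLA4 markers for gene {gene!r} in result")
    labels = [result.markers[j].info["allele"] for j in cols]
    order = np.argsort(labels, kind="stable")
    cols_arr = np.asarray(cols)[order]
    labels = [labels[i] for i in order]
    rows = []
    for i, ind in enumerate(result.individuals):
        call = []
        ambiguous = False
        for h in (0, 1):
            p = result.hap_prob[i, h, cols_arr]
            mx = p.max()
            hits = np.where(p >= mx - tol)[0]
            if len(hits) > 1:
                ambiguous = True
            a = labels[int(hits[0])]
            call.append(a if resolution == 4 else reduce_resolution(a))
        rows.append(
            {"individual": ind, "allele1": call[0], "allele2": call[1],
             "ambiguous": ambiguous}
        )
    return pd.DataFrame(rows)
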