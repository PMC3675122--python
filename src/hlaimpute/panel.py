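"""Reference-panel construction: SNP quality control, rare-marker pruning,
merging SNPs with encoded markers in genomic order, and phasing into
reference haplotypes.

QC follows the standard pre-imputation recipe for a reference panel: SNPs
with minor allele frequency < 1%, missingness > 5% or exact Hardy-Weinberg
P < 1e-6 are removed, and encoded markers (classical alleles, residues,
indels) below a 0.01% presence-frequency floor are pruned.  HWE is applied
to SNPs only; encoded markers are logically constrained one-hot blocks for
which the test has no meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markers import BinaryMarker, sort_markers

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePanel",
    "hwe_exact_pvalue",
    "qc_filter_snps",
    "prune_rare_markers",
    "merge_and_order",
    "phase_panel",
]

DEFAULT_WINDOW = (29_000_000, 34_000_000)


@dataclass
class ReferencePanel:
    """Phased binary haplotype matrix with ordered marker metadata.

    ``haplotypes`` is (K, M) with values in {0, 1}; two consecutive rows per
    source individual.  Markers are strictly sorted by genomic position with
    ties broken by marker id.
    """

    haplotypes: np.ndarray
    markers: list[BinaryMarker]
    individuals: list[str]
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        k, m = self.haplotypes.shape
        if k % 2 != 0:
            raise ValueError("haplotype count must be even (2 per individual)")
        if k != 2 * len(self.individuals):
            raise ValueError("haplotype rows must be 2 per individual")
        if m != len(self.markers):
            raise ValueError("marker list does not match matrix width")
        keys = [(mk.position, mk.id) for mk in self.markers]
        if keys != sorted(keys):
            raise ValueError("markers must be sorted by (position, id)")
        ids = [mk.id for mk in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids in panel")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype matrix must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([m.position for m in self.markers], dtype=np.int64)

    def frequencies(self) -> np.ndarray:
        """Presence frequency of each marker across the K haplotypes."""
        return self.haplotypes.mean(axis=0)

    def marker_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.markers)}

    def gene_block(self, gene: str, kind: str = "HLA4") -> np.ndarray:
        """Column indices of a gene's markers of one kind."""
        return np.asarray(
            [i for i, m in enumerate(self.markers) if m.gene == gene and m.kind == kind],
            dtype=np.int64,
        )

    def genes(self, kind: str = "HLA4") -> list[str]:
        return sorted({m.gene for m in self.markers if m.kind == kind})

    def subset_haplotypes(self, rows: np.ndarray) -> "ReferencePanel":
        """Panel restricted to an even set of haplotype rows (pairs)."""
        rows = np.asarray(rows)
        if rows.size % 2:
            raise ValueError("haplotype subset must keep pairs")
        inds = [self.individuals[i // 2] for i in rows[::2]]
        return ReferencePanel(self.haplotypes[rows], list(self.markers), inds, self.window)


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value for biallelic genotype
    counts (two-sided by probability mass, mid-p off).

    Enumerates the conditional distribution of heterozygote counts given the
    allele counts and sums the probabilities of all configurations no more
    likely than the observed one.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(len(het_values))
    # unnormalized log-probabilities via the standard recurrence
    for i in range(1, len(het_values)):
        h = het_values[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # P(h) / P(h-2) = 4 * (hom_r+1) * (hom_c+1) / (h * (h-1))
        logp[i] = logp[i - 1] + np.log(4.0 * (hom_r + 1) * (hom_c + 1)) - np.log(
            float(h) * (h - 1)
        )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    hits = np.where(het_values == n_het)[0]
    if hits.size == 0:  # inconsistent counts
        raise ValueError("heterozygote count inconsistent with allele parity")
    obs_idx = int(hits[0])
    return float(min(1.0, p[p <= p[obs_idx] * (1 + 1e-12)].sum()))


def qc_filter_snps(
    geno: pd.DataFrame,
    maf_min: float = 0.01,
    max_missing: float = 0.05,
    hwe_min_p: float = 1e-6,
):
    """Remove SNPs failing MAF, missingness or exact-HWE thresholds.

    ``geno`` is individuals x SNPs with values 0/1/2/NaN.  Returns
    ``(filtered, report)`` where ``report`` lists every removed SNP with all
    failing reason codes (``LOW_MAF``, ``HIGH_MISSING``, ``HWE_FAIL``), so
    the retained set is independent of filter order.
    """
    n = len(geno)
    if n == 0:
        raise ValueError("empty genotype table")
    rows = []
    keep = []
    for snp in geno.columns:
        g = geno[snp].to_numpy(dtype=float)
        miss = float(np.isnan(g).mean())
        gg = g[~np.isnan(g)]
        if gg.size:
            f = gg.sum() / (2.0 * gg.size)
            maf = min(f, 1.0 - f)
            n_het = int((gg == 1).sum())
            n_hom_alt = int((gg == 2).sum())
            n_hom_ref = int((gg == 0).sum())
            hwe_p = hwe_exact_pvalue(n_het, n_hom_ref, n_hom_alt)
        else:
            maf, hwe_p = 0.0, 1.0
        reasons = []
        if maf < maf_min:
            reasons.append("LOW_MAF")
        if miss > max_missing:
            reasons.append("HIGH_MISSING")
        if hwe_p < hwe_min_p:
            reasons.append("HWE_FAIL")
        if reasons:
            rows.append(
                {"marker": snp, "reasons": ";".join(reasons), "maf": maf,
                 "missing": miss, "hwe_p": hwe_p}
            )
        else:
            keep.append(snp)
    report = pd.DataFrame(rows, columns=["marker", "reasons", "maf", "missing", "hwe_p"])
    if not keep:
        raise ValueError("no informative SNPs remain after QC")
    for _, r in report.iterrows():
        logger.info("QC removed %s: %s", r["marker"], r["reasons"])
    return geno[keep], report


def prune_rare_markers(
    geno: pd.DataFrame,
    markers: Sequence[BinaryMarker],
    floor: float = 1e-4,
):
    """Drop encoded markers whose presence frequency over the 2N observed
    chromosomes is below ``floor`` (default 0.01%).

    Returns ``(pruned_genotypes, kept_markers, report)``.
    """
    by_id = {m.id: m for m in markers}
    rows, keep = [], []
    for mid in geno.columns:
        g = geno[mid].to_numpy(dtype=float)
        gg = g[~np.isnan(g)]
        freq = float(gg.sum() / (2.0 * gg.size)) if gg.size else 0.0
        if freq < floor:
            rows.append({"marker": mid, "reasons": "RARE", "frequency": freq})
        else:
            keep.append(mid)
            if mid in by_id:
                by_id[mid].frequency = freq
    kept_markers = [by_id[mid] for mid in keep if mid in by_id]
    report = pd.DataFrame(rows, columns=["marker", "reasons", "frequency"])
    return geno[keep], kept_markers, report


def merge_and_order(parts: Sequence[tuple[pd.DataFrame, Sequence[BinaryMarker]]]):
    """Merge genotype tables (SNP + encoded marker sets) into one table with
    markers strictly position-sorted; duplicate marker ids are rejected.

    All parts must cover the same individuals.
    """
    if not parts:
        raise ValueError("nothing to merge")
    seen: set[str] = set()
    all_markers: list[BinaryMarker] = []
    frames: list[pd.DataFrame] = []
    index = parts[0][0].index
    for geno, ms in parts:
        if not geno.index.equals(index):
            geno = geno.reindex(index)
        for m in ms:
            if m.id in seen:
                raise ValueError(f"duplicate marker id {m.id!r} across merged sets")
            seen.add(m.id)
        missing_cols = [m.id for m in ms if m.id not in geno.columns]
        if missing_cols:
            raise ValueError(f"marker(s) {missing_cols} absent from genotype table")
        all_markers.extend(ms)
        frames.append(geno[[m.id for m in ms]])
    merged = pd.concat(frames, axis=1)
    ordered = sort_markers(all_markers)
    return merged[[m.id for m in ordered]], ordered


def _initial_haplotypes(geno: np.ndarray, rng: np.random.Generator):
    """Random phase-consistent initialization; missing genotypes must have
    been filled beforehand."""
    n, m = geno.shape
    h = np.zeros((2 * n, m), dtype=np.int8)
    for i in range(n):
        g = geno[i]
        het = g == 1
        flip = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        h1 = (g // 2).astype(np.int8)
        h2 = h1.copy()
        h1[het] = flip
        h2[het] = 1 - flip
        h[2 * i] = h1
        h[2 * i + 1] = h2
    return h


def _repair_blocks(
    h1: np.ndarray,
    h2: np.ndarray,
    g: np.ndarray,
    col_index: Mapping[str, int],
    blocks: Mapping[str, tuple[list[str], Mapping[str, np.ndarray]]],
):
    """Project each gene block of a phased pair onto the consistent one-hot
    configuration best agreeing with the HMM phase (exactly one classical
    allele per haplotype per gene)."""
    for gene, (ids, vecs) in blocks.items():
        kept = [i for i in ids if i in col_index]
        if not kept:
            continue
        cols = np.asarray([col_index[i] for i in kept])
        keep_mask = np.asarray([i in col_index for i in ids])
        # recover the allele pair from the genotype dosages of HLA4 markers
        hla4_col = {
            f"HLA_{gene}_{a.split('*')[1]}": a for a in vecs
        }
        pair: list[str] = []
        complete = True
        for k, mid in enumerate(kept):
            a = hla4_col.get(mid)
            if a is None:
                continue
            d = g[cols[k]]
            if np.isnan(d):
                complete = False
                break
            pair.extend([a] * int(round(d)))
        if not complete or len(pair) != 2:
            continue  # partially typed or pruned allele; leave as phased
        a, b = pair
        va = vecs[a][keep_mask]
        vb = vecs[b][keep_mask]
        s_ab = (h1[cols] == va).sum() + (h2[cols] == vb).sum()
        s_ba = (h1[cols] == vb).sum() + (h2[cols] == va).sum()
        if s_ab >= s_ba:
            h1[cols], h2[cols] = va, vb
        else:
            h1[cols], h2[cols] = vb, va


def phase_panel(
    geno: pd.DataFrame,
    markers: Sequence[BinaryMarker],
    seed: int = 0,
    sweeps: int = 10,
    params=None,
    blocks: Mapping[str, tuple[list[str], Mapping[str, np.ndarray]]] | None = None,
    haplotypes: np.ndarray | None = None,
    max_missing_individual: float = 0.5,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> ReferencePanel:
    """Phase a combined unphased panel into reference haplotypes.

    Iterative conditional phasing: each sweep re-phases every individual
    against the current haplotypes of all other individuals using the
    haplotype-copying model (greedy pair decoding, forward and reverse, the
    higher-likelihood orientation wins).  Deterministic given ``seed``.

    ``blocks`` (from :func:`hlaimpute.markers.allele_block_vectors`) enables
    the one-hot repair of encoded gene blocks after phasing.  If
    ``haplotypes`` is supplied the input is treated as already phased and
    passed through unchanged (phasing a phased panel is a fixed point).
    """
    from . import hmm  # deferred: avoids import cycle

    markers = sort_markers(markers)
    ids = [m.id for m in markers]
    geno = geno[ids]
    if haplotypes is not None:
        hp = np.asarray(haplotypes, dtype=np.uint8)
        expected = hp[0::2] + hp[1::2]
        obs = geno.to_numpy(dtype=float)
        ok = np.isnan(obs) | (obs == expected)
        if not ok.all():
            raise ValueError("supplied haplotypes are inconsistent with genotypes")
        return ReferencePanel(hp, list(markers), list(geno.index), window)

    mat = geno.to_numpy(dtype=float)
    miss_frac = np.isnan(mat).mean(axis=1)
    excluded = [
        ind for ind, f in zip(geno.index, miss_frac) if f > max_missing_individual
    ]
    if excluded:
        logger.warning(
            "excluding %d individual(s) with >%.0f%% missing markers: %s",
            len(excluded), 100 * max_missing_individual, excluded,
        )
        keep = [i for i in geno.index if i not in set(excluded)]
        geno = geno.loc[keep]
        mat = geno.to_numpy(dtype=float)
    n = len(geno)
    if n == 0:
        raise ValueError("no individuals to phase")

    # hard-fill residual missing genotypes with the rounded expectation
    col_mean = np.nanmean(mat, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    fill = np.clip(np.round(col_mean), 0, 2)
    nan_r, nan_c = np.where(np.isnan(mat))
    mat[nan_r, nan_c] = fill[nan_c]
    mat = mat.astype(np.int8)

    rng = np.random.default_rng(seed)
    haps = _initial_haplotypes(mat, rng)
    positions = np.asarray([m.position for m in markers], dtype=np.int64)
    params = params or hmm.HmmParams()

    if n > 1:
        k_ref = 2 * (n - 1)
        rho = hmm.switch_probs(positions, k_ref, params)
        theta = params.theta if params.theta is not None else hmm.li_stephens_theta(k_ref)
        # exact diploid decoding is affordable for small panels; larger
        # panels fall back to greedy pair decoding.  Early sweeps sample
        # pair paths from the posterior (stochastic, escapes the local
        # optima deterministic updates get trapped in); the final sweeps
        # polish with joint Viterbi.
        exact = k_ref <= 80
        for sweep in range(sweeps):
            polish = sweep >= max(sweeps - 2, 1)
            order = rng.permutation(n)
            changed = 0
            for i in order:
                refs = np.ascontiguousarray(
                    np.delete(haps, [2 * i, 2 * i + 1], axis=0)
                )
                if exact and not polish:
                    h1, h2 = hmm.diploid_sample_phase(mat[i], refs, rho, theta, rng)
                elif exact:
                    h1, h2 = hmm.diploid_viterbi_phase(mat[i], refs, rho, theta)
                else:
                    h1, h2 = hmm.phase_genotypes(
                        mat[i], refs, rho, theta, both_directions=True
                    )
                if not (
                    np.array_equal(h1, haps[2 * i]) and np.array_equal(h2, haps[2 * i + 1])
                ):
                    changed += 1
                haps[2 * i] = h1
                haps[2 * i + 1] = h2
            if polish and changed == 0:
                break

    col_index = {m.id: j for j, m in enumerate(markers)}
    if blocks:
        for i in range(n):
            h1, h2 = haps[2 * i], haps[2 * i + 1]
            _repair_blocks(h1, h2, geno.iloc[i].to_numpy(dtype=float), col_index, blocks)
            haps[2 * i], haps[2 * i + 1] = h1, h2

    return ReferencePanel(
        haps.astype(np.uint8), list(markers), list(geno.index), window
    )
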