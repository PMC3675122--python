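"""Synthetic MHC data with known truth.

The generator emulates the statistical structure that makes HLA imputation
work: strong, long-range linkage disequilibrium between SNP haplotype
backgrounds and the classical alleles they carry.  It is a founder-mosaic
model, not a coalescent simulation:

* ``n_founders`` founder haplotypes are drawn (random SNP alleles at
  positions scattered over the 29-34 Mb window); each founder carries one
  classical allele per gene, allocated so that population allele
  frequencies match a Dirichlet-drawn spectrum (largest-remainder quota
  over equally weighted founders).
* Every sample haplotype is an independent mosaic of founders: switch
  events occur between adjacent loci with probability ``1 - exp(-r*d)``
  (``r`` per bp), and SNP alleles are copied with a small mutation/error
  rate.  The classical allele of a gene is that of the founder active at
  the gene's anchor coordinate, and every encoded marker (classical 2/4
  digit, residue, indel) follows deterministically from it through a
  generated residue table, so encoded markers are exactly one-hot per
  haplotype.
* Targets are drawn from a haplotype pool disjoint from the reference
  panel (no leakage), exposed only at a platform profile's SNP subset
  ("sparse" ~500 typed SNPs, "dense" ~5000), with classical truth withheld
  as the gold standard.
* Phenotypes are Bernoulli draws from a logistic model on the count of a
  chosen causal residue.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import (
    DEFAULT_GENE_ANCHORS,
    AlleleSequence,
    HlaTyping,
    allele_block_vectors,
    encode_amino_acids,
    encode_classical_alleles,
    encode_indels,
    residue_dosage_from_typings,
    sort_markers,
)
from .markers import BinaryMarker
from .panel import ReferencePanel
from .hmm import TargetGenotypes

__all__ = [
    "SimConfig",
    "SimulatedData",
    "PLATFORM_PROFILES",
    "simulate_panel",
    "make_target",
    "simulate_phenotypes",
    "simulate_haplotype_labels",
]

#: Typed-SNP counts emulating a low-density genome-wide array vs a dense
#: immune-targeted chip.
PLATFORM_PROFILES = {"sparse": 500, "dense": 5000}

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NUCS = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition knobs of the generator; defaults are the package's
    standard benchmark conditions."""

    n_founders: int = 40
    n_haplotypes: int = 1000  # reference panel haplotypes (K)
    n_target: int = 200  # target individuals, disjoint haplotype pool
    n_snps: int = 5500
    window: tuple[int, int] = (29_000_000, 34_000_000)
    genes: tuple[str, ...] = ("A", "B", "C", "DQA1", "DQB1", "DRB1")
    alleles_per_gene: int = 12
    dirichlet_concentration: float = 0.5
    n_protein_positions: int = 40
    n_polymorphic_positions: int = 12
    recomb_rate_per_bp: float = 4e-7  # ~2 expected switches across 5 Mb
    mutation_rate: float = 0.002  # per SNP per haplotype copy
    ambiguous_fraction: float = 0.05  # A/T and C/G SNP pairs
    marker_floor: float = 1e-4
    panel_maf_min: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founders", "n_haplotypes", "n_target", "n_snps",
                     "alleles_per_gene", "n_protein_positions",
                     "n_polymorphic_positions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even")
        for g in self.genes:
            if g not in DEFAULT_GENE_ANCHORS:
                raise ValueError(f"unknown gene {g!r}")


@dataclass
class SimulatedData:
    """Panel, truth and held-out haplotype pool of one simulation."""

    config: SimConfig
    panel: ReferencePanel
    typings: list[HlaTyping]  # panel individuals
    sequences: list[AlleleSequence]
    snp_meta: pd.DataFrame  # id, position, a1 (present), a2 (absent)
    hap_matrix: np.ndarray  # (K + 2*n_target, M) over panel markers
    hap_alleles: pd.DataFrame  # (K + 2*n_target) x genes, classical labels
    blocks: dict  # per-gene allele marker vectors
    allele_spectra: dict  # per-gene Dirichlet target frequencies by label

    @property
    def n_panel_haplotypes(self) -> int:
        return self.panel.n_haplotypes

    def panel_genotypes(self) -> pd.DataFrame:
        """Unphased genotype table of the panel individuals (for exercising
        the QC/phasing pipeline)."""
        k = self.n_panel_haplotypes
        g = self.hap_matrix[:k:2] + self.hap_matrix[1:k:2]
        return pd.DataFrame(
            g.astype(float), index=self.panel.individuals,
            columns=self.panel.marker_ids,
        )

    def target_typings(self, n: int | None = None) -> list[HlaTyping]:
        """Gold-standard typings of the held-out target individuals."""
        k = self.n_panel_haplotypes
        n = n if n is not None else self.config.n_target
        out = []
        for i in range(n):
            ind = f"T{i + 1:04d}"
            for gene in self.config.genes:
                a1 = self.hap_alleles.iloc[k + 2 * i][gene]
                a2 = self.hap_alleles.iloc[k + 2 * i + 1][gene]
                out.append(HlaTyping(ind, gene, a1, a2))
        return out


def _quota_allocation(weights: np.ndarray, target: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Assign each of len(weights) equally weighted founders an allele index
    so realized shares match ``target`` (largest-remainder method)."""
    f = len(weights)
    raw = target * f
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = f - base.sum()
    order = np.argsort(-rem, kind="stable")
    for i in order[:short]:
        base[i] += 1
    assign = np.repeat(np.arange(len(target)), base)
    rng.shuffle(assign)
    return assign


def _make_sequences(cfg: SimConfig, rng: np.random.Generator,
                    allele_labels: dict[str, list[str]]) -> list[AlleleSequence]:
    sequences: list[AlleleSequence] = []
    for gi, gene in enumerate(cfg.genes):
        labels = allele_labels[gene]
        L = cfg.n_protein_positions
        consensus = rng.choice(_AA20, size=L)
        poly = rng.choice(L, size=min(cfg.n_polymorphic_positions, L), replace=False)
        seqs = {a: consensus.copy() for a in labels}
        for j in sorted(poly):
            n_res = 2 if rng.random() < 0.7 else 3
            variants = rng.choice(
                np.setdiff1d(_AA20, [consensus[j]]), size=n_res - 1, replace=False
            )
            residues = [consensus[j], *variants]
            # distribute residues over alleles, every residue used at least once
            assign = rng.integers(0, n_res, size=len(labels))
            for r in range(n_res):
                if not np.any(assign == r):
                    assign[rng.integers(0, len(labels))] = r
            for ai, a in enumerate(labels):
                seqs[a][j] = residues[assign[ai]]
        if gi % 2 == 0 and len(labels) > 1:
            # plant one 2-residue deletion event on one allele, away from
            # the planted substitution polymorphisms
            free = np.setdiff1d(np.arange(L - 1), np.concatenate([poly, poly - 1]))
            if free.size:
                j0 = int(rng.choice(free))
                carrier = labels[int(rng.integers(0, len(labels)))]
                seqs[carrier][j0] = "-"
                seqs[carrier][j0 + 1] = "-"
        for a in labels:
            sequences.append(AlleleSequence(gene, a, "".join(seqs[a])))
    return sequences


def simulate_panel(config: SimConfig | None = None) -> SimulatedData:
    """Generate a phased reference panel plus a disjoint target haplotype
    pool, with full truth (typings, residue tables, per-haplotype alleles).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.window
    F = cfg.n_founders
    K = cfg.n_haplotypes
    H = K + 2 * cfg.n_target

    # --- SNP scaffold -----------------------------------------------------
    snp_pos = np.sort(
        rng.choice(np.arange(lo, hi, dtype=np.int64), size=cfg.n_snps, replace=False)
    )
    founder_freq = rng.beta(0.8, 0.8, size=cfg.n_snps)
    founders_snp = (rng.random((F, cfg.n_snps)) < founder_freq).astype(np.int8)
    # SNP allele labels; a small fraction strand-ambiguous (A/T, C/G)
    a1 = rng.choice(_NUCS, size=cfg.n_snps)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    amb = rng.random(cfg.n_snps) < cfg.ambiguous_fraction
    a2 = np.array([
        comp[x] if amb[i] else rng.choice(np.setdiff1d(_NUCS, [x, comp[x]]))
        for i, x in enumerate(a1)
    ])

    # --- classical alleles on founder lineages ---------------------------
    allele_labels: dict[str, list[str]] = {}
    founder_allele: dict[str, np.ndarray] = {}
    spectra: dict[str, np.ndarray] = {}
    weights = np.full(F, 1.0 / F)
    for gene in cfg.genes:
        A = cfg.alleles_per_gene
        labels = [f"{gene}*{(i // 3) + 1:02d}{(i % 3) + 1:02d}" for i in range(A)]
        q = rng.dirichlet(np.full(A, cfg.dirichlet_concentration))
        spectra[gene] = q
        founder_allele[gene] = _quota_allocation(weights, q, rng)
        allele_labels[gene] = labels

    sequences = _make_sequences(cfg, rng, allele_labels)

    # --- mosaic haplotypes ------------------------------------------------
    anchors = {g: DEFAULT_GENE_ANCHORS[g] for g in cfg.genes}
    loci_pos = np.sort(np.concatenate([snp_pos, np.array(sorted(anchors.values()))]))
    loci_pos = np.unique(loci_pos)
    nloci = len(loci_pos)
    switch_p = 1.0 - np.exp(-cfg.recomb_rate_per_bp * np.diff(loci_pos).astype(float))
    path = np.empty((H, nloci), dtype=np.int32)
    path[:, 0] = rng.integers(0, F, size=H)
    switches = rng.random((H, nloci - 1)) < switch_p
    new_f = rng.integers(0, F, size=(H, nloci - 1)).astype(np.int32)
    for j in range(1, nloci):
        path[:, j] = np.where(switches[:, j - 1], new_f[:, j - 1], path[:, j - 1])

    snp_locus_idx = np.searchsorted(loci_pos, snp_pos)
    anchor_locus_idx = {g: int(np.searchsorted(loci_pos, anchors[g])) for g in cfg.genes}
    snp_path = path[:, snp_locus_idx]
    hap_snps = founders_snp[snp_path, np.arange(cfg.n_snps)[None, :]]
    flips = rng.random(hap_snps.shape) < cfg.mutation_rate
    hap_snps = np.where(flips, 1 - hap_snps, hap_snps).astype(np.int8)

    hap_allele_rows = {}
    for gene in cfg.genes:
        fa = founder_allele[gene][path[:, anchor_locus_idx[gene]]]
        hap_allele_rows[gene] = [allele_labels[gene][i] for i in fa]
    hap_alleles = pd.DataFrame(hap_allele_rows)

    # --- panel-level QC on SNPs (MAF floor over the K panel haplotypes) ---
    panel_freq = hap_snps[:K].mean(axis=0)
    snp_keep = np.minimum(panel_freq, 1 - panel_freq) >= cfg.panel_maf_min
    snp_pos = snp_pos[snp_keep]
    hap_snps = hap_snps[:, snp_keep]
    a1, a2 = a1[snp_keep], a2[snp_keep]
    snp_ids = [f"SNP_{p}" for p in snp_pos]
    snp_markers = [
        BinaryMarker(id=sid, kind="SNP", gene="", position=int(p),
                     present_label=str(a1[i]), absent_label=str(a2[i]),
                     frequency=float(hap_snps[:K, i].mean()))
        for i, (sid, p) in enumerate(zip(snp_ids, snp_pos))
    ]
    snp_meta = pd.DataFrame(
        {"id": snp_ids, "position": snp_pos, "a1": a1, "a2": a2}
    )

    # --- encoded markers from the panel individuals -----------------------
    panel_inds = [f"R{i + 1:04d}" for i in range(K // 2)]
    typings: list[HlaTyping] = []
    for i, ind in enumerate(panel_inds):
        for gene in cfg.genes:
            typings.append(
                HlaTyping(ind, gene,
                          hap_alleles.iloc[2 * i][gene],
                          hap_alleles.iloc[2 * i + 1][gene])
            )
    m4, g4, _ = encode_classical_alleles(typings, resolution=4, anchors=anchors)
    m2, g2, _ = encode_classical_alleles(typings, resolution=2, anchors=anchors)
    ma, ga, _ = encode_amino_acids(sequences, typings, anchors=anchors)
    mi, gi_, _ = encode_indels(sequences, typings, anchors=anchors)
    encoded_markers = m4 + m2 + ma + mi

    # frequency floor over panel chromosomes
    kept_markers = []
    for m in encoded_markers:
        if m.frequency >= cfg.marker_floor:
            kept_markers.append(m)
    blocks = allele_block_vectors(kept_markers, sequences)

    # haplotype-level encoded matrix from per-haplotype alleles
    enc_sorted = sort_markers(kept_markers)
    enc_ids = [m.id for m in enc_sorted]
    enc_cols = {mid: j for j, mid in enumerate(enc_ids)}
    enc_mat = np.zeros((H, len(enc_ids)), dtype=np.int8)
    for gene, (ids, vecs) in blocks.items():
        keep = [(k, enc_cols[i]) for k, i in enumerate(ids) if i in enc_cols]
        rows_k = np.array([k for k, _ in keep])
        cols_j = np.array([j for _, j in keep])
        for a, v in vecs.items():
            hsel = hap_alleles[gene].to_numpy() == a
            if hsel.any():
                enc_mat[np.ix_(hsel, cols_j)] = v[rows_k]

    # --- merge SNPs + encoded markers in genomic order --------------------
    all_markers = sort_markers(snp_markers + enc_sorted)
    snp_col = {sid: j for j, sid in enumerate(snp_ids)}
    col_src = []
    for m in all_markers:
        if m.kind == "SNP":
            col_src.append(("snp", snp_col[m.id]))
        else:
            col_src.append(("enc", enc_cols[m.id]))
    hap_matrix = np.empty((H, len(all_markers)), dtype=np.int8)
    for j, (src, k) in enumerate(col_src):
        hap_matrix[:, j] = hap_snps[:, k] if src == "snp" else enc_mat[:, k]

    panel = ReferencePanel(
        haplotypes=hap_matrix[:K].astype(np.uint8),
        markers=list(all_markers),
        individuals=panel_inds,
        window=cfg.window,
    )
    spectra = {
        gene: pd.Series(spectra_q, index=allele_labels[gene])
        for gene, spectra_q in spectra.items()
    }
    return SimulatedData(
        config=cfg, panel=panel, typings=typings, sequences=sequences,
        snp_meta=snp_meta, hap_matrix=hap_matrix, hap_alleles=hap_alleles,
        blocks=blocks, allele_spectra=spectra,
    )


def make_target(
    sim: SimulatedData,
    profile: str = "dense",
    n: int | None = None,
    seed: int = 0,
):
    """Build target samples from the held-out haplotype pool.

    Exposes only the platform profile's SNP subset (all encoded markers
    masked) and returns ``(TargetGenotypes, gold_typings, truth_dosage)``
    where ``truth_dosage`` is the true 0/1/2 dosage table over all encoded
    markers for metric evaluation.  ``profile`` is ``"dense"``/``"sparse"``
    or an integer SNP count.
    """
    cfg = sim.config
    n = n if n is not None else cfg.n_target
    if n > cfg.n_target:
        raise ValueError("not enough held-out haplotypes for requested n")
    n_typed = PLATFORM_PROFILES.get(profile) if isinstance(profile, str) else int(profile)
    if n_typed is None:
        raise ValueError(f"unknown platform profile {profile!r}")
    rng = np.random.default_rng(seed)
    idx = sim.panel.marker_index()
    snp_cols = np.asarray(
        [idx[m.id] for m in sim.panel.markers if m.kind == "SNP"]
    )
    n_typed = min(n_typed, snp_cols.size)
    typed_cols = np.sort(rng.choice(snp_cols, size=n_typed, replace=False))
    K = sim.n_panel_haplotypes
    pool = sim.hap_matrix[K:K + 2 * n]
    geno = (pool[0::2] + pool[1::2]).astype(float)
    individuals = [f"T{i + 1:04d}" for i in range(n)]
    target = TargetGenotypes(
        individuals=individuals,
        marker_ids=[sim.panel.marker_ids[c] for c in typed_cols],
        positions=sim.panel.positions[typed_cols],
        geno=geno[:, typed_cols],
    )
    gold = sim.target_typings(n)
    enc_cols = np.asarray(
        [j for j, m in enumerate(sim.panel.markers) if m.kind != "SNP"]
    )
    truth_dosage = pd.DataFrame(
        geno[:, enc_cols], index=individuals,
        columns=[sim.panel.marker_ids[c] for c in enc_cols],
    )
    return target, gold, truth_dosage


def simulate_phenotypes(
    typings: Sequence[HlaTyping],
    sequences: Sequence[AlleleSequence],
    causal: tuple[str, int, str],
    beta: float,
    prevalence: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Case/control status from a logistic model on a causal residue.

    ``causal = (gene, position, residue)``; per individual
    ``logit P(case) = alpha + beta * dosage(residue)`` with ``alpha``
    calibrated so the expected prevalence matches ``prevalence``.  Returns
    ``(phenotypes, truth)`` with a ``status`` column (1 = case).
    """
    gene, position, residue = causal
    dose = residue_dosage_from_typings(typings, sequences, gene, position, residue)
    dose = dose.dropna()
    from scipy.special import expit, logit

    alpha = float(logit(prevalence) - beta * dose.mean())
    p = expit(alpha + beta * dose.to_numpy())
    rng = np.random.default_rng(seed)
    status = (rng.random(len(dose)) < p).astype(int)
    pheno = pd.DataFrame({"individual": dose.index, "status": status})
    truth = {"gene": gene, "position": position, "residue": residue,
             "beta": beta, "alpha": alpha}
    return pheno, truth


def simulate_haplotype_labels(
    control_freqs: dict[str, float],
    odds_ratios: dict[str, float],
    n_case: int,
    n_control: int,
    seed: int = 0,
):
    """Draw multi-locus haplotype labels for a case/control cohort with
    planted haplotype odds ratios.

    Retrospective design matching a case/control haplotype-frequency
    contrast: controls draw two haplotypes i.i.d. from ``control_freqs``;
    cases draw from the tilted distribution ``f(h) * OR(h)`` (renormalized;
    ``odds_ratios`` defaults to 1 for unlisted haplotypes), so the planted
    OR is exactly the haplotype-count odds ratio being estimated.  Returns
    ``(haplotypes (n, 2), status (n,))`` with cases first.
    """
    labels = list(control_freqs)
    p_ctrl = np.asarray([control_freqs[l] for l in labels], dtype=float)
    p_ctrl = p_ctrl / p_ctrl.sum()
    tilt = np.asarray([odds_ratios.get(l, 1.0) for l in labels], dtype=float)
    p_case = p_ctrl * tilt
    p_case = p_case / p_case.sum()
    rng = np.random.default_rng(seed)
    haps_case = rng.choice(labels, size=(n_case, 2), p=p_case)
    haps_ctrl = rng.choice(labels, size=(n_control, 2), p=p_ctrl)
    haps = np.concatenate([haps_case, haps_ctrl], axis=0)
    status = np.concatenate([np.ones(n_case), np.zeros(n_control)])
    return haps, status
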