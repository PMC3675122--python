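"""Imputation-quality metrics against gold-standard typings.

Three complementary views of accuracy are provided:

* **Dosage accuracy** ``Acc(L)`` at a locus: the imputed dosage of each
  individual's true alleles, summed over individuals and divided by the
  number of chromosomes, so uncertain but partially correct imputations get
  partial credit.  For a homozygote only the first-allele term enters, with
  its full dosage counting toward both chromosomes.
* **Correlation** between imputed and typed dosages: squared Pearson ``r``
  for biallelic markers, and a centered vector generalisation ``R^2`` for
  multi-residue positions that reduces exactly to the biallelic ``r^2`` when
  a position has two residues.
* **Genotype concordance** of best-guess classical calls, as an order-free
  multiset match per individual (0, 1/2 or 1), restricted to individuals
  typed at the evaluated resolution.

A calibration curve (binned dosage vs mean true dosage) rounds out the set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markers import HlaTyping, parse_allele, reduce_resolution

__all__ = [
    "AccuracyResult",
    "accuracy",
    "dosage_r2",
    "multiallelic_R2",
    "concordance",
    "freq_correlation",
    "calibration_curve",
]


@dataclass
class AccuracyResult:
    """Acc(L) at one locus, as a percentage, with bookkeeping."""

    locus: str
    resolution: int
    acc: float  # percent
    n: int  # individuals included
    missing_alleles: list[str]  # truth alleles absent from the marker set


def _allele_dosage_getter(dosage: pd.DataFrame, resolution: int):
    """Dosage of a classical allele label from whatever columns exist:
    the allele's own marker if present, else (at 2-digit) the sum of its
    4-digit family members, else zero (recorded as missing)."""
    cols = set(dosage.columns)

    def marker_id(label: str) -> str:
        gene, digits = parse_allele(label)
        return f"HLA_{gene}_{digits}"

    four_digit_family: dict[str, list[str]] = {}
    for c in dosage.columns:
        if c.startswith("HLA_"):
            parts = c.split("_")
            if len(parts) == 3 and len(parts[2]) == 4:
                fam = f"HLA_{parts[1]}_{parts[2][:2]}"
                four_digit_family.setdefault(fam, []).append(c)

    def get(ind: str, label: str):
        mid = marker_id(label)
        if mid in cols:
            return float(dosage.at[ind, mid]), False
        if resolution == 2 and mid in four_digit_family:
            return float(dosage.loc[ind, four_digit_family[mid]].sum()), False
        return 0.0, True

    return get


def accuracy(
    dosage: pd.DataFrame,
    truth: Sequence[HlaTyping],
    locus: str,
    resolution: int = 4,
) -> AccuracyResult:
    """Dosage accuracy Acc(L) at one HLA locus (percent).

    ``Acc = [sum_het (D(A1) + D(A2)) + sum_hom D(A1)] / (2n) * 100`` over
    the n individuals whose two truth alleles are both resolved at
    ``resolution``; homozygosity is judged from the truth typing.  Truth
    alleles with no corresponding marker contribute dosage 0 and are listed.
    """
    get = _allele_dosage_getter(dosage, resolution)
    total = 0.0
    n = 0
    missing: set[str] = set()
    for t in truth:
        if t.gene != locus or t.individual not in dosage.index:
            continue
        pair = t.resolved_pair(resolution)
        if pair is None:
            continue
        a1, a2 = pair
        d1, miss1 = get(t.individual, a1)
        if miss1:
            missing.add(a1)
        if a1 == a2:
            total += d1
        else:
            d2, miss2 = get(t.individual, a2)
            if miss2:
                missing.add(a2)
            total += d1 + d2
        n += 1
    acc = 100.0 * total / (2.0 * n) if n else float("nan")
    return AccuracyResult(locus, resolution, acc, n, sorted(missing))


def dosage_r2(x, y) -> float:
    """Squared Pearson correlation between imputed and typed dosage vectors;
    NaN when either vector is constant (undefined) or fewer than 2 pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def multiallelic_R2(X, Y, centered: bool = True) -> float:
    """Vector correlation between imputed and typed dosage vectors at one
    multi-residue position.

    ``R^2 = (sum_i <X_i - Xbar, Y_i - Ybar>)^2 /
    (sum_i ||X_i - Xbar||^2 * sum_i ||Y_i - Ybar||^2)`` over n individuals;
    for a 2-residue position this reduces exactly to the biallelic Pearson
    ``r^2`` of either residue marker.  ``centered=False`` gives the raw
    inner-product variant for sensitivity analysis.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("imputed/typed dosage arrays differ in shape")
    if X.ndim == 1:
        X = X[:, None]
        Y = Y[:, None]
    ok = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    X, Y = X[ok], Y[ok]
    if len(X) < 2:
        return float("nan")
    if centered:
        X = X - X.mean(axis=0)
        Y = Y - Y.mean(axis=0)
    sxy = float((X * Y).sum())
    sxx = float((X * X).sum())
    syy = float((Y * Y).sum())
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy * sxy / (sxx * syy)


def concordance(
    calls: pd.DataFrame,
    truth: Sequence[HlaTyping],
    resolution: int = 4,
    allele_freqs: Mapping[str, float] | None = None,
    min_freq: float = 0.0,
) -> tuple[float, int]:
    """Best-guess genotype concordance at one gene (percent).

    ``calls`` has columns ``individual``, ``allele1``, ``allele2`` (from
    :func:`hlaimpute.hmm.call_classical`).  Per individual the two called
    alleles are matched to the two truth alleles as multisets; individuals
    not fully typed at ``resolution`` are excluded from the denominator.

    With ``allele_freqs``/``min_freq`` the match is counted at the allele
    level over truth alleles whose panel frequency exceeds the floor (used
    to evaluate accuracy for common alleles only).  Returns
    ``(percent, n_alleles_compared)``.
    """
    called = {r.individual: (r.allele1, r.allele2) for r in calls.itertuples()}
    if not called:
        return float("nan"), 0
    gene = parse_allele(next(iter(called.values()))[0])[0]
    matched = 0.0
    compared = 0
    for t in truth:
        if t.gene != gene:
            continue
        pair = t.resolved_pair(resolution)
        if pair is None or t.individual not in called:
            continue
        cpair = list(called[t.individual])
        if resolution == 2:
            cpair = [reduce_resolution(a) for a in cpair]
        remaining = list(cpair)
        for a in pair:
            if allele_freqs is not None and allele_freqs.get(a, 0.0) <= min_freq:
                continue
            compared += 1
            if a in remaining:
                remaining.remove(a)
                matched += 1
    pct = 100.0 * matched / compared if compared else float("nan")
    return pct, compared


def freq_correlation(imputed_freqs, typed_freqs) -> float:
    """Squared Pearson correlation of imputed vs typed allele frequencies
    across markers."""
    return dosage_r2(imputed_freqs, typed_freqs)


def calibration_curve(
    dosage, truth_dosage, n_bins: int = 20
) -> pd.DataFrame:
    """Binned imputed-dosage calibration against true hard dosages.

    Dosages are binned on [0, 2]; per bin the count, mean imputed dosage and
    mean true dosage (0/1/2) are reported (NaN means for empty bins).  A
    well-calibrated imputation puts bin means on the diagonal.
    """
    d = np.asarray(dosage, dtype=float).ravel()
    t = np.asarray(truth_dosage, dtype=float).ravel()
    if d.shape != t.shape:
        raise ValueError("dosage and truth arrays differ in length")
    ok = ~(np.isnan(d) | np.isnan(t))
    d, t = d[ok], t[ok]
    edges = np.linspace(0.0, 2.0, n_bins + 1)
    which = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        cnt = int(sel.sum())
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "count": cnt,
                "mean_dosage": float(d[sel].mean()) if cnt else float("nan"),
                "mean_true": float(t[sel].mean()) if cnt else float("nan"),
            }
        )
    return pd.DataFrame(rows)
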