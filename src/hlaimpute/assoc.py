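"""Case/control association testing of imputed variants.

Every binary marker is tested by logistic regression of disease status on
its posterior allelic dosage (probabilistic dosages, not best-guess calls,
carry the imputation uncertainty into the test).  An amino acid position is
tested jointly with an omnibus deviance test: the alternative model fits an
individual effect for every residue at the position except one reference
residue (the most frequent, dropped to break the residues-sum-to-two
collinearity), and ``deviance(null) - deviance(alt)`` is referred to a
chi-square with (#residues - 1) degrees of freedom.  Because the dropped
column is a linear combination of the others plus the intercept, the
statistic does not depend on which residue is taken as reference.

Haplotype risk is summarized as odds ratios of multi-locus classical-allele
haplotypes against a designated reference haplotype, from a haplotype-count
logistic model (each individual contributes two haplotype observations)
with profile-likelihood confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "test_marker",
    "omnibus_position_test",
    "rank_signals",
    "haplotype_odds_ratios",
    "dosage_sanity_check",
]


@dataclass
class AssociationResult:
    """One association test: a marker, an amino acid position, or a
    haplotype contrast."""

    id: str
    kind: str  # "marker" | "position"
    beta: float
    se: float
    stat: float  # LRT deviance statistic
    df: int
    p: float  # primary p-value (LRT)
    p_wald: float = float("nan")
    flags: list[str] = field(default_factory=list)
    per_allele: pd.DataFrame | None = None


def _design(n: int, covariates=None) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if len(cov) != n:
            raise ValueError("covariate length mismatch")
        cols.extend(cov.T)
    return np.column_stack(cols)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Newton-fitted logistic model; falls back to BFGS under separation.
    Returns (result, separation_flag)."""
    import warnings

    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-8)
            sep = bool(np.any(np.abs(res.params) > 25))
            return res, sep
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, method="bfgs", maxiter=500, gtol=1e-8)
    return res, True


def _status_array(phenotypes) -> np.ndarray:
    y = np.asarray(phenotypes, dtype=float)
    vals = set(np.unique(y[~np.isnan(y)]))
    if not vals <= {0.0, 1.0}:
        raise ValueError("status must be coded 0 (control) / 1 (case)")
    if vals != {0.0, 1.0}:
        raise ValueError("both cases and controls are required")
    return y


def test_marker(
    dosage,
    phenotypes,
    covariates=None,
    marker_id: str = "marker",
) -> AssociationResult:
    """Per-marker dosage logistic regression.

    Fits ``status ~ dosage (+ covariates)``; reports the log-odds-ratio,
    its standard error, and both Wald and likelihood-ratio p-values (the
    LRT is primary; under separation only the LRT is trusted and the result
    is flagged).
    """
    x = np.asarray(dosage, dtype=float)
    y = _status_array(phenotypes)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0:
        raise ValueError(f"constant dosage vector for {marker_id!r}")
    X0 = _design(len(y), None if covariates is None else np.asarray(covariates)[ok])
    X1 = np.column_stack([X0, x])
    res0, _ = _fit_logit(y, X0)
    res1, sep = _fit_logit(y, X1)
    stat = 2.0 * (res1.llf - res0.llf)
    stat = max(stat, 0.0)
    p_lrt = float(stats.chi2.sf(stat, 1))
    beta = float(res1.params[-1])
    se = float(res1.bse[-1])
    p_wald = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    flags = ["separation"] if sep else []
    if sep:
        p_wald = float("nan")
    return AssociationResult(
        id=marker_id, kind="marker", beta=beta, se=se, stat=stat, df=1,
        p=p_lrt, p_wald=p_wald, flags=flags,
    )


def omnibus_position_test(
    residue_dosages: pd.DataFrame,
    phenotypes,
    covariates=None,
    position_id: str | None = None,
) -> AssociationResult:
    """Joint deviance test of all residues at one amino acid position.

    ``residue_dosages`` is individuals x residue markers (dosages summing to
    ~2 per row).  The most frequent residue is the reference (dropped);
    zero-variance residues are dropped with a note and the degrees of
    freedom adjusted.  Statistic: ``deviance(null) - deviance(alt)`` on a
    chi-square with (#modelled residues) df = (#residues - 1) when none are
    degenerate.
    """
    D = residue_dosages.copy()
    if D.shape[1] < 2:
        raise ValueError("omnibus test needs a position with >= 2 residues")
    y = _status_array(phenotypes)
    ok = ~(np.isnan(y) | D.isna().any(axis=1).to_numpy())
    D = D.loc[ok]
    y = y[ok]
    flags: list[str] = []
    means = D.mean(axis=0)
    reference = means.idxmax()
    cols = [c for c in D.columns if c != reference]
    kept = []
    for c in cols:
        if np.ptp(D[c].to_numpy()) == 0:
            flags.append(f"dropped_zero_variance:{c}")
        else:
            kept.append(c)
    if not kept:
        raise ValueError("no non-degenerate residues to test")
    X0 = _design(len(y), None if covariates is None else np.asarray(covariates)[ok])
    X1 = np.column_stack([X0, D[kept].to_numpy(dtype=float)])
    res0, _ = _fit_logit(y, X0)
    res1, sep = _fit_logit(y, X1)
    if sep:
        flags.append("separation")
    stat = max(2.0 * (res1.llf - res0.llf), 0.0)
    df = len(kept)
    p = float(stats.chi2.sf(stat, df))
    k0 = X0.shape[1]
    per_allele = pd.DataFrame(
        {
            "residue": kept,
            "beta": res1.params[k0:],
            "se": res1.bse[k0:],
        }
    )
    pid = position_id or "position"
    return AssociationResult(
        id=pid, kind="position", beta=float("nan"), se=float("nan"),
        stat=stat, df=df, p=p, flags=flags, per_allele=per_allele,
    )


def rank_signals(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Markers and positions ranked by p-value (stable; ties by id)."""
    rows = [
        {"id": r.id, "kind": r.kind, "stat": r.stat, "df": r.df, "p": r.p}
        for r in results
    ]
    df = pd.DataFrame(rows, columns=["id", "kind", "stat", "df", "p"])
    if len(df):
        df = df.sort_values(["p", "id"], kind="stable").reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
    else:
        df.insert(0, "rank", pd.Series(dtype=int))
    return df


# ---------------------------------------------------------------------------
# haplotype odds ratios
# ---------------------------------------------------------------------------

def _two_group_loglik(alpha: float, beta: float, a: float, b: float,
                      c: float, d: float) -> float:
    """Binomial log-likelihood of the carrier group (a cases, b controls,
    logit = alpha + beta) and the reference group (c cases, d controls,
    logit = alpha)."""
    lab = alpha + beta
    return (
        a * lab - (a + b) * np.logaddexp(0.0, lab)
        + c * alpha - (c + d) * np.logaddexp(0.0, alpha)
    )


def _profile_loglik(beta: float, a, b, c, d) -> float:
    res = optimize.minimize_scalar(
        lambda al: -_two_group_loglik(al, beta, a, b, c, d),
        bracket=(-5.0, 0.0, 5.0), method="brent",
        options={"xtol": 1e-10},
    )
    return -res.fun


def _profile_ci_log_or(a, b, c, d, level: float = 0.95):
    """Profile-likelihood CI for the log-odds-ratio of a 2x2 contrast.

    In the saturated haplotype-count logistic model, profiling one
    haplotype's coefficient reduces exactly to this two-group problem: all
    other haplotypes' parameters attain their maxima independently.
    """
    bhat = np.log(a * d / (b * c))
    llmax = _profile_loglik(bhat, a, b, c, d)
    crit = stats.chi2.ppf(level, 1) / 2.0

    def g(beta):
        return llmax - _profile_loglik(beta, a, b, c, d) - crit

    lo_bracket = bhat - 1.0
    while g(lo_bracket) < 0 and lo_bracket > bhat - 50:
        lo_bracket -= 1.0
    hi_bracket = bhat + 1.0
    while g(hi_bracket) < 0 and hi_bracket < bhat + 50:
        hi_bracket += 1.0
    lo = optimize.brentq(g, lo_bracket, bhat, xtol=1e-8)
    hi = optimize.brentq(g, bhat, hi_bracket, xtol=1e-8)
    return bhat, lo, hi


def haplotype_odds_ratios(
    haplotypes,
    phenotypes,
    reference: str,
    rare_floor: float = 0.005,
    level: float = 0.95,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-haplotype odds ratios against a reference haplotype.

    ``haplotypes`` is an (n, 2) array-like of haplotype labels (e.g.
    ``"DRB1*0301-DQA1*0501-DQB1*0201"``), two per individual;
    ``phenotypes`` the matching 0/1 status.  Haplotypes with sample
    frequency below ``rare_floor`` are pooled as ``"rare"``.  Each
    individual contributes two haplotype observations to the count model;
    the OR of haplotype h is its case/control count ratio against the
    reference with a profile-likelihood CI.  Degenerate cells (a haplotype
    absent in cases or controls) get the Haldane 0.5 continuity correction
    and a flag.  The reference-vs-itself row carries OR = 1 exactly.
    """
    H = np.asarray(haplotypes, dtype=object)
    if H.ndim != 2 or H.shape[1] != 2:
        raise ValueError("haplotypes must be (n, 2) labels")
    y = _status_array(phenotypes)
    if len(y) != len(H):
        raise ValueError("phenotype/haplotype length mismatch")
    labels = H.ravel()
    status2 = np.repeat(y, 2)
    total = len(labels)
    counts = pd.Series(labels).value_counts()
    if reference not in counts.index:
        raise ValueError(f"reference haplotype {reference!r} absent from data")
    pooled = {
        lab for lab, c in counts.items()
        if c / total < rare_floor and lab != reference
    }
    lab_eff = np.array(
        ["rare" if l in pooled else l for l in labels], dtype=object
    )
    case_counts = pd.Series(lab_eff[status2 == 1]).value_counts()
    ctrl_counts = pd.Series(lab_eff[status2 == 0]).value_counts()
    c_ref = float(case_counts.get(reference, 0))
    d_ref = float(ctrl_counts.get(reference, 0))
    if d_ref == 0:
        raise ValueError(f"reference haplotype {reference!r} absent from controls")
    rows = []
    all_labels = sorted(set(lab_eff), key=lambda l: (l == "rare", l))
    for lab in all_labels:
        a = float(case_counts.get(lab, 0))
        b = float(ctrl_counts.get(lab, 0))
        freq = (a + b) / total
        flags = []
        if lab == reference:
            rows.append(
                {"haplotype": lab, "n_case": int(a), "n_control": int(b),
                 "frequency": freq, "odds_ratio": 1.0,
                 "ci_low": float("nan"), "ci_high": float("nan"),
                 "flags": "reference"}
            )
            continue
        aa, bb, cc, dd = a, b, c_ref, d_ref
        if min(aa, bb) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c_ref + 0.5, d_ref + 0.5
            flags.append("continuity_corrected")
        bhat, lo, hi = _profile_ci_log_or(aa, bb, cc, dd, level)
        rows.append(
            {"haplotype": lab, "n_case": int(a), "n_control": int(b),
             "frequency": freq, "odds_ratio": float(np.exp(bhat)),
             "ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi)),
             "flags": ";".join(flags)}
        )
    out = pd.DataFrame(rows)
    if groups:
        out["risk_group"] = [groups.get(l, "") for l in out["haplotype"]]
    return out


def dosage_sanity_check(
    dosage: pd.DataFrame,
    markers,
    tol: float = 0.1,
) -> tuple[bool, pd.DataFrame]:
    """Check that per-individual classical-allele dosages sum to ~2 per gene.

    Returns ``(all_pass, failures)`` where failures lists every
    (individual, gene) whose HLA4 dosage sum deviates from 2 by more than
    ``tol``.
    """
    by_gene: dict[str, list[str]] = {}
    for m in markers:
        if m.kind == "HLA4" and m.id in dosage.columns:
            by_gene.setdefault(m.gene, []).append(m.id)
    rows = []
    for gene, cols in sorted(by_gene.items()):
        sums = dosage[cols].sum(axis=1)
        bad = sums[(sums - 2.0).abs() > tol]
        for ind, s in bad.items():
            rows.append({"individual": ind, "gene": gene, "dosage_sum": float(s)})
    failures = pd.DataFrame(rows, columns=["individual", "gene", "dosage_sum"])
    return len(failures) == 0, failures
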