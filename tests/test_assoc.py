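"""Association testing: per-marker regression, omnibus position tests,
ranking, haplotype odds ratios and the dosage sanity check."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from hlaimpute import assoc
from hlaimpute.markers import BinaryMarker


def _case_control(n, beta, rng, dosage=None):
    if dosage is None:
        dosage = rng.binomial(2, 0.3, n).astype(float)
    p = expit(-0.2 + beta * dosage)
    return dosage, (rng.random(n) < p).astype(float)


class TestMarkerTest:
    def test_null_marker_or_near_one(self):
        rng = np.random.default_rng(0)
        betas = []
        for _ in range(20):
            x, y = _case_control(2000, 0.0, rng)
            betas.append(assoc.test_marker(x, y).beta)
        assert abs(np.mean(betas)) < 0.05

    def test_planted_log_or_recovered(self):
        """Seed-averaged estimate of a planted log-OR 0.7 at n=2000 lands
        within +/- 0.15 of truth."""
        rng = np.random.default_rng(1)
        betas = []
        for _ in range(10):
            x, y = _case_control(2000, 0.7, rng)
            betas.append(assoc.test_marker(x, y).beta)
        assert np.mean(betas) == pytest.approx(0.7, abs=0.15)

    def test_constant_dosage_rejected(self):
        y = np.array([0.0, 1.0] * 10)
        with pytest.raises(ValueError, match="constant"):
            assoc.test_marker(np.ones(20), y)

    def test_wald_and_lrt_agree_for_strong_signals(self):
        rng = np.random.default_rng(2)
        x, y = _case_control(3000, 0.5, rng)
        r = assoc.test_marker(x, y)
        assert r.p < 1e-6 and r.p_wald < 1e-6
        assert np.log10(r.p) == pytest.approx(np.log10(r.p_wald), abs=1.0)

    def test_separation_flagged(self):
        x = np.array([0.0] * 20 + [2.0] * 20)
        y = np.array([0.0] * 20 + [1.0] * 20)
        r = assoc.test_marker(x, y)
        assert "separation" in r.flags
        assert np.isnan(r.p_wald) and r.p < 0.05

    def test_covariate_adjustment_changes_fit(self):
        rng = np.random.default_rng(3)
        cov = rng.normal(size=2000)
        x = rng.binomial(2, 0.3, 2000).astype(float)
        y = (rng.random(2000) < expit(0.8 * cov)).astype(float)
        r_adj = assoc.test_marker(x, y, covariates=cov)
        assert r_adj.df == 1 and 0 < r_adj.p <= 1


class TestOmnibus:
    def _residue_table(self, n, probs, rng):
        counts = rng.multinomial(2, probs, size=n).astype(float)
        return pd.DataFrame(
            counts, columns=[f"AA_B_9_31320027_{r}" for r in "SGR"[: len(probs)]]
        )

    def test_two_residue_position_equals_marker_lrt(self):
        """With two residues the omnibus deviance test is the df=1 LRT of
        either residue marker (the two dosage columns are collinear)."""
        rng = np.random.default_rng(4)
        D = self._residue_table(1500, [0.6, 0.4], rng)
        y = (rng.random(1500) < expit(0.3 * D.iloc[:, 1] - 0.3)).to_numpy(float)
        om = assoc.omnibus_position_test(D, y)
        single = assoc.test_marker(D.iloc[:, 1].to_numpy(), y)
        assert om.df == 1
        assert om.stat == pytest.approx(single.stat, abs=1e-6)
        assert om.p == pytest.approx(single.p, rel=1e-6)

    def test_reference_residue_choice_is_irrelevant(self):
        """The deviance statistic is invariant to which residue is dropped:
        the model span is identical because residue dosages sum to 2."""
        rng = np.random.default_rng(5)
        D = self._residue_table(800, [0.5, 0.3, 0.2], rng)
        y = (rng.random(800) < expit(0.4 * D.iloc[:, 2] - 0.4)).to_numpy(float)
        stats_by_ref = []
        for ref_col in D.columns:
            others = [c for c in D.columns if c != ref_col]
            import statsmodels.api as sm

            X1 = np.column_stack([np.ones(len(D)), D[others].to_numpy()])
            X0 = np.ones((len(D), 1))
            r1 = sm.Logit(y, X1).fit(disp=0)
            r0 = sm.Logit(y, X0).fit(disp=0)
            stats_by_ref.append(2 * (r1.llf - r0.llf))
        om = assoc.omnibus_position_test(D, y)
        for s in stats_by_ref:
            assert om.stat == pytest.approx(s, abs=1e-6)

    def test_zero_variance_residue_dropped_with_df_adjust(self):
        rng = np.random.default_rng(6)
        D = self._residue_table(500, [0.7, 0.3], rng)
        D["AA_B_9_31320027_X"] = 0.0
        y = rng.integers(0, 2, 500).astype(float)
        om = assoc.omnibus_position_test(D, y)
        assert om.df == 1
        assert any("zero_variance" in f for f in om.flags)

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError):
            assoc.omnibus_position_test(
                pd.DataFrame({"a": [1.0, 2.0]}), np.array([0.0, 1.0])
            )


class TestRankSignals:
    def test_single_marker_rank_one(self):
        r = assoc.AssociationResult("m1", "marker", 0.1, 0.1, 4.0, 1, 0.04)
        table = assoc.rank_signals([r])
        assert table.iloc[0]["rank"] == 1

    def test_empty_input_empty_table(self):
        assert len(assoc.rank_signals([])) == 0

    def test_ties_broken_by_id_stable(self):
        rs = [
            assoc.AssociationResult("b", "marker", 0, 0, 1.0, 1, 0.5),
            assoc.AssociationResult("a", "marker", 0, 0, 1.0, 1, 0.5),
            assoc.AssociationResult("c", "marker", 0, 0, 9.0, 1, 0.001),
        ]
        table = assoc.rank_signals(rs)
        assert list(table["id"]) == ["c", "a", "b"]


class TestHaplotypeOddsRatios:
    def _draw(self, n, freqs, log_or, risk, rng):
        # retrospective design: case haplotype frequencies are the control
        # frequencies tilted by the planted OR, so the haplotype-count OR
        # estimand equals exp(log_or) exactly
        labels = list(freqs)
        p = np.array([freqs[l] for l in labels], dtype=float)
        p /= p.sum()
        tilt = np.where(np.array(labels) == risk, np.exp(log_or), 1.0)
        p_case = p * tilt
        p_case /= p_case.sum()
        n_case = n // 2
        haps = np.concatenate([
            rng.choice(labels, size=(n_case, 2), p=p_case),
            rng.choice(labels, size=(n - n_case, 2), p=p),
        ])
        y = np.concatenate([np.ones(n_case), np.zeros(n - n_case)])
        return haps, y

    def test_reference_vs_itself_is_exactly_one(self):
        rng = np.random.default_rng(7)
        haps, y = self._draw(500, {"ref": 0.6, "h1": 0.4}, 0.5, "h1", rng)
        table = assoc.haplotype_odds_ratios(haps, y, "ref")
        ref_row = table[table["haplotype"] == "ref"].iloc[0]
        assert ref_row["odds_ratio"] == 1.0
        assert ref_row["flags"] == "reference"

    def test_planted_or_recovered_with_ci(self):
        # single-draw check of the estimator and CI mechanics; frequentist
        # coverage over replicates is asserted in the acceptance suite
        rng = np.random.default_rng(8)
        haps, y = self._draw(
            3000, {"ref": 0.5, "risk": 0.2, "h2": 0.3}, np.log(5.0), "risk", rng
        )
        table = assoc.haplotype_odds_ratios(haps, y, "ref").set_index("haplotype")
        row = table.loc["risk"]
        assert row["odds_ratio"] == pytest.approx(5.0, rel=0.35)
        # the profile interval brackets its own point estimate
        assert row["ci_low"] < row["odds_ratio"] < row["ci_high"]
        # null haplotype: CI straddles 1
        h2 = table.loc["h2"]
        assert h2["ci_low"] < 1.0 < h2["ci_high"]

    def test_profile_ci_matches_two_by_two_mle(self):
        # the point estimate is the 2x2 cross ratio against the reference
        rng = np.random.default_rng(9)
        haps, y = self._draw(1000, {"ref": 0.5, "h1": 0.5}, 0.8, "h1", rng)
        table = assoc.haplotype_odds_ratios(haps, y, "ref").set_index("haplotype")
        lab = np.asarray(haps).ravel()
        st = np.repeat(y, 2)
        a = ((lab == "h1") & (st == 1)).sum()
        b = ((lab == "h1") & (st == 0)).sum()
        c = ((lab == "ref") & (st == 1)).sum()
        d = ((lab == "ref") & (st == 0)).sum()
        assert table.loc["h1", "odds_ratio"] == pytest.approx(a * d / (b * c))

    def test_rare_haplotypes_pooled(self):
        rng = np.random.default_rng(10)
        freqs = {"ref": 0.5, "h1": 0.496}
        freqs.update({f"r{i}": 0.001 for i in range(4)})
        haps, y = self._draw(2000, freqs, 0.0, "h1", rng)
        table = assoc.haplotype_odds_ratios(haps, y, "ref", rare_floor=0.005)
        assert "rare" in set(table["haplotype"])
        assert not any(h.startswith("r") and h != "rare" and h != "ref"
                       for h in table["haplotype"])

    def test_degenerate_cell_continuity_corrected(self):
        haps = np.array([["ref", "ref"]] * 50 + [["h1", "ref"]] * 8)
        y = np.array([1.0] * 25 + [0.0] * 25 + [0.0] * 8)  # h1 absent in cases
        table = assoc.haplotype_odds_ratios(haps, y, "ref").set_index("haplotype")
        assert "continuity_corrected" in table.loc["h1", "flags"]
        assert np.isfinite(table.loc["h1", "odds_ratio"])

    def test_missing_reference_rejected(self):
        haps = np.array([["h1", "h2"]] * 10)
        y = np.array([0.0, 1.0] * 5)
        with pytest.raises(ValueError, match="absent"):
            assoc.haplotype_odds_ratios(haps, y, "ref")

    def test_counts_conserved_and_order_invariant(self):
        rng = np.random.default_rng(11)
        haps, y = self._draw(400, {"ref": 0.4, "h1": 0.3, "h2": 0.3}, 0.3, "h1", rng)
        t1 = assoc.haplotype_odds_ratios(haps, y, "ref")
        assert t1["n_case"].sum() + t1["n_control"].sum() == 800
        perm = rng.permutation(len(y))
        t2 = assoc.haplotype_odds_ratios(haps[perm], y[perm], "ref")
        pd.testing.assert_frame_equal(
            t1.sort_values("haplotype").reset_index(drop=True),
            t2.sort_values("haplotype").reset_index(drop=True),
        )


class TestDosageSanity:
    def _markers(self):
        return [
            BinaryMarker(id=f"HLA_A_{d}", kind="HLA4", gene="A",
                         position=29_910_000, info={"allele": f"A*{d}"})
            for d in ("0101", "0201")
        ]

    def test_clean_rows_pass(self):
        dosage = pd.DataFrame(
            {"HLA_A_0101": [1.0, 0.5], "HLA_A_0201": [1.0, 1.52]},
            index=["I1", "I2"],
        )
        ok, failures = assoc.dosage_sanity_check(dosage, self._markers())
        assert ok and failures.empty

    def test_corrupted_row_flagged(self):
        dosage = pd.DataFrame(
            {"HLA_A_0101": [1.0, 0.2], "HLA_A_0201": [1.0, 1.0]},
            index=["I1", "I2"],
        )
        ok, failures = assoc.dosage_sanity_check(dosage, self._markers())
        assert not ok
        assert list(failures["individual"]) == ["I2"]
        assert failures.iloc[0]["dosage_sum"] == pytest.approx(1.2)

    def test_zero_tolerance_flags_soft_dosages(self):
        dosage = pd.DataFrame(
            {"HLA_A_0101": [1.01], "HLA_A_0201": [1.0]}, index=["I1"]
        )
        ok, _ = assoc.dosage_sanity_check(dosage, self._markers(), tol=0.0)
        assert not ok
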