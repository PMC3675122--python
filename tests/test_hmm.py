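"""Imputation engine: forward-backward correctness against exhaustive
path-enumeration oracles, harmonization, and output invariants."""

import numpy as np
import pandas as pd
import pytest

from hlaimpute import hmm
from hlaimpute.markers import BinaryMarker
from hlaimpute.panel import ReferencePanel
from hlaimpute.simulate import make_target
from oracles import enumerate_diploid, enumerate_haploid_dosage


class TestForwardBackwardOracle:
    def test_haploid_matches_enumeration(self):
        """Posteriors from the scaled forward-backward equal exhaustive
        enumeration over all mosaic paths (small state space summed
        exactly)."""
        rng = np.random.default_rng(11)
        K, M = 4, 6
        refs = rng.integers(0, 2, (K, M)).astype(np.int8)
        obs = rng.integers(0, 2, M).astype(np.int8)
        obs[2] = -1  # untyped site
        obs[4] = -1
        rho = rng.uniform(0.01, 0.3, M - 1)
        theta = 0.05
        expected = enumerate_haploid_dosage(obs, refs, rho, theta)
        gamma = hmm.haploid_posteriors(obs, refs, rho, theta)
        got = hmm.allele_posteriors(gamma, refs, theta)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_diploid_exact_matches_pair_enumeration(self):
        rng = np.random.default_rng(5)
        K, M = 3, 5
        refs = rng.integers(0, 2, (K, M)).astype(np.int8)
        geno = rng.integers(0, 3, M).astype(np.int8)
        geno[3] = -1
        rho = rng.uniform(0.02, 0.2, M - 1)
        theta = 0.03
        expected = enumerate_diploid(geno, refs, rho, theta)
        gp, dosage = hmm.diploid_posteriors_exact(geno, refs, rho, theta)
        np.testing.assert_allclose(dosage, expected, atol=1e-10)
        np.testing.assert_allclose(gp.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(gp[:, 1] + 2 * gp[:, 2], dosage, atol=1e-10)


class TestEngineBasics:
    def _panel(self, haps, start=29_100_000, step=10_000):
        K, M = haps.shape
        markers = [
            BinaryMarker(id=f"SNP_{j:03d}", kind="SNP", gene="",
                         position=start + step * j,
                         present_label="A", absent_label="G")
            for j in range(M)
        ]
        inds = [f"R{i}" for i in range(K // 2)]
        return ReferencePanel(haps.astype(np.uint8), markers, inds)

    def test_perfect_copy_reproduces_reference_pair(self):
        """A target whose typed SNPs exactly match one reference pair, with
        theta -> 0, gets all untyped dosages equal to that pair's sums."""
        rng = np.random.default_rng(2)
        haps = rng.integers(0, 2, (6, 12)).astype(np.uint8)
        # tight spacing keeps the switch probability negligible, so the
        # copying posterior stays on the matching reference pair
        panel = self._panel(haps, step=100)
        typed = [0, 1, 2, 3, 5, 6, 8, 9, 10, 11]
        pair = haps[0] + haps[1]
        target = hmm.TargetGenotypes(
            individuals=["T1"],
            marker_ids=[panel.marker_ids[j] for j in typed],
            positions=panel.positions[typed],
            geno=pair[typed][None, :].astype(float),
        )
        params = hmm.HmmParams(theta=1e-9)
        res = hmm.impute(target, panel, params, min_typed=1)
        untyped = [4, 7]
        for j in untyped:
            assert res.dosage.at["T1", panel.marker_ids[j]] == pytest.approx(
                float(pair[j]), abs=1e-4
            )

    def test_typed_sites_reproduced_within_theta(self):
        rng = np.random.default_rng(9)
        haps = rng.integers(0, 2, (20, 30)).astype(np.uint8)
        panel = self._panel(haps)
        g = (haps[3] + haps[7]).astype(float)
        target = hmm.TargetGenotypes(
            individuals=["T1"], marker_ids=panel.marker_ids,
            positions=panel.positions, geno=g[None, :],
        )
        res = hmm.impute(target, panel, hmm.HmmParams(theta=1e-4), min_typed=1)
        np.testing.assert_allclose(
            res.dosage.loc["T1"].to_numpy(), g, atol=0.05
        )

    def test_dosage_equals_p1_plus_2p2_exactly(self, tiny_imputation):
        _, _, _, res = tiny_imputation
        implied = res.gp[:, :, 1] + 2.0 * res.gp[:, :, 2]
        np.testing.assert_array_equal(res.dosage.to_numpy(), implied)

    def test_gp_rows_sum_to_one(self, tiny_imputation):
        _, _, _, res = tiny_imputation
        np.testing.assert_allclose(res.gp.sum(axis=2), 1.0, atol=1e-9)

    def test_per_gene_hla4_dosages_sum_to_two(self, tiny_sim, tiny_imputation):
        _, _, _, res = tiny_imputation
        for gene in tiny_sim.panel.genes("HLA4"):
            cols = [m.id for m in res.markers if m.kind == "HLA4" and m.gene == gene]
            sums = res.dosage[cols].sum(axis=1)
            assert ((sums - 2.0).abs() < 0.1).all()

    def test_low_typed_count_flagged(self):
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, (6, 20)).astype(np.uint8)
        panel = self._panel(haps)
        g = np.full(20, np.nan)
        g[:5] = (haps[0] + haps[1])[:5]
        target = hmm.TargetGenotypes(
            individuals=["T1"], marker_ids=panel.marker_ids,
            positions=panel.positions, geno=g[None, :],
        )
        res = hmm.impute(target, panel)
        assert res.low_confidence == ["T1"]

    def test_windowed_equals_full_region_approximately(self, tiny_sim):
        target, _, _ = make_target(tiny_sim, profile="dense", n=5, seed=3)
        full = hmm.impute(target, tiny_sim.panel)
        windowed = hmm.impute(target, tiny_sim.panel, hmm.HmmParams(window=150))
        d1 = full.dosage.to_numpy()
        d2 = windowed.dosage.to_numpy()
        assert np.mean(np.abs(d1 - d2)) < 0.02

    def test_unknown_typed_marker_rejected(self):
        rng = np.random.default_rng(0)
        haps = rng.integers(0, 2, (4, 5)).astype(np.uint8)
        panel = self._panel(haps)
        target = hmm.TargetGenotypes(
            individuals=["T1"], marker_ids=["SNP_999"],
            positions=np.array([29_000_000]), geno=np.zeros((1, 1)),
        )
        with pytest.raises(ValueError, match="not in panel"):
            hmm.impute(target, panel)


class TestBestGuessAndCalls:
    @pytest.mark.parametrize(
        "gp,expected,tie",
        [((0.1, 0.2, 0.7), 2, False),
         ((0.5, 0.5, 0.0), 0, True),
         ((0.2, 0.6, 0.2), 1, False)],
    )
    def test_argmax_with_low_genotype_ties(self, gp, expected, tie):
        bg, ties = hmm.best_guess_from_gp(np.array([gp]))
        assert bg[0] == expected and bool(ties[0]) == tie

    def test_best_guess_matches_enumeration_argmax(self):
        rng = np.random.default_rng(8)
        K, M = 3, 5
        refs = rng.integers(0, 2, (K, M)).astype(np.int8)
        geno = rng.integers(0, 3, M).astype(np.int8)
        geno[2] = -1
        rho = rng.uniform(0.05, 0.2, M - 1)
        gp, _ = hmm.diploid_posteriors_exact(geno, refs, rho, 0.02)
        bg, _ = hmm.best_guess_from_gp(gp)
        assert list(bg) == list(gp.argmax(axis=1))

    def test_one_hot_haplotypes_give_clean_calls(self, tiny_sim, tiny_imputation):
        _, gold, _, res = tiny_imputation
        calls = hmm.call_classical(res, tiny_sim.config.genes[0], resolution=4)
        assert set(calls.columns) >= {"individual", "allele1", "allele2", "ambiguous"}
        # calls are valid allele labels of the gene
        for r in calls.itertuples():
            assert r.allele1.startswith(tiny_sim.config.genes[0] + "*")

    def test_two_digit_calls_are_reductions(self, tiny_sim, tiny_imputation):
        from hlaimpute.markers import reduce_resolution

        _, _, _, res = tiny_imputation
        gene = tiny_sim.config.genes[0]
        c4 = hmm.call_classical(res, gene, 4)
        c2 = hmm.call_classical(res, gene, 2)
        for r4, r2 in zip(c4.itertuples(), c2.itertuples()):
            assert {reduce_resolution(r4.allele1), reduce_resolution(r4.allele2)} == \
                {r2.allele1, r2.allele2}


class TestHarmonize:
    def _panel(self):
        markers = [
            BinaryMarker(id=f"SNP_{j}", kind="SNP", gene="",
                         position=29_500_000 + 1000 * j,
                         present_label=p, absent_label=a)
            for j, (p, a) in enumerate(
                [("A", "G"), ("C", "T"), ("A", "T"), ("G", "C"), ("T", "C")]
            )
        ]
        rng = np.random.default_rng(1)
        haps = rng.integers(0, 2, (40, 5)).astype(np.uint8)
        haps[:, 2] = (rng.random(40) < 0.9)  # ambiguous A/T site far from 0.5
        return ReferencePanel(haps, markers, [f"R{i}" for i in range(20)])

    def _geno(self, n=40, cols=None, seed=0):
        rng = np.random.default_rng(seed)
        cols = cols or {}
        data = {k: v for k, v in cols.items()}
        return pd.DataFrame(data, index=[f"T{i}" for i in range(n)])

    def test_strand_flip_detected(self):
        panel = self._panel()
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.4, 40).astype(float)
        geno = self._geno(cols={"s0": g})
        # target reports T/C at a panel A/G site: complement match
        meta = pd.DataFrame(
            [{"id": "s0", "position": 29_500_000, "a1": "T", "a2": "C"}]
        )
        tg, report = hmm.harmonize(geno, meta, panel)
        assert report.iloc[0]["action"] == "flipped_strand"
        # A1=T complements to A which IS the panel present allele
        np.testing.assert_array_equal(tg.geno[:, 0], g)

    def test_swapped_alleles_recoded(self):
        panel = self._panel()
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, 40).astype(float)
        geno = self._geno(cols={"s0": g})
        meta = pd.DataFrame(
            [{"id": "s0", "position": 29_500_000, "a1": "G", "a2": "A"}]
        )
        tg, report = hmm.harmonize(geno, meta, panel)
        assert report.iloc[0]["action"] == "swapped_alleles"
        np.testing.assert_array_equal(tg.geno[:, 0], 2.0 - g)

    def test_low_maf_dropped(self):
        panel = self._panel()
        g = np.zeros(40)
        g[0] = 1.0  # MAF 1.25% < 2.5%
        ok = np.clip(np.arange(40) % 3, 0, 2).astype(float)
        geno = self._geno(cols={"s0": g, "s1": ok})
        meta = pd.DataFrame([
            {"id": "s0", "position": 29_500_000, "a1": "A", "a2": "G"},
            {"id": "s1", "position": 29_501_000, "a1": "C", "a2": "T"},
        ])
        tg, report = hmm.harmonize(geno, meta, panel)
        r = report.set_index("marker")
        assert r.loc["s0", "reason"] == "LOW_MAF"
        assert tg.marker_ids == ["SNP_1"]

    def test_outside_window_dropped(self):
        panel = self._panel()
        ok = np.clip(np.arange(40) % 3, 0, 2).astype(float)
        geno = self._geno(cols={"sX": ok, "s1": ok})
        meta = pd.DataFrame([
            {"id": "sX", "position": 28_000_000, "a1": "A", "a2": "G"},
            {"id": "s1", "position": 29_501_000, "a1": "C", "a2": "T"},
        ])
        tg, report = hmm.harmonize(geno, meta, panel)
        assert report.set_index("marker").loc["sX", "reason"] == "OUTSIDE_WINDOW"

    def test_planted_flips_and_ambiguous_sites(self):
        """20 planted strand flips are all detected; A/T ambiguous sites are
        frequency-matched when the panel frequency is informative."""
        rng = np.random.default_rng(7)
        n_snps, n = 25, 200
        markers = []
        pairs = []
        for j in range(n_snps):
            if j < 20:
                p, a = ("A", "G") if j % 2 else ("C", "T")
            else:
                p, a = ("A", "T")
            markers.append(BinaryMarker(
                id=f"SNP_{j}", kind="SNP", gene="",
                position=29_500_000 + 1000 * j, present_label=p, absent_label=a))
            pairs.append((p, a))
        freqs = np.where(np.arange(n_snps) < 20, 0.4, 0.85)
        haps = (rng.random((60, n_snps)) < freqs).astype(np.uint8)
        panel = ReferencePanel(haps, markers, [f"R{i}" for i in range(30)])
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        cols, meta_rows = {}, []
        for j, (p, a) in enumerate(pairs):
            g = rng.binomial(2, panel.frequencies()[j], n).astype(float)
            if j < 20:  # plant a strand flip
                meta_rows.append({"id": f"t{j}", "position": markers[j].position,
                                  "a1": comp[p], "a2": comp[a]})
            else:
                meta_rows.append({"id": f"t{j}", "position": markers[j].position,
                                  "a1": p, "a2": a})
            cols[f"t{j}"] = g
        geno = pd.DataFrame(cols, index=[f"T{i}" for i in range(n)])
        tg, report = hmm.harmonize(geno, pd.DataFrame(meta_rows), panel)
        actions = report.set_index("marker")["action"]
        assert (actions[[f"t{j}" for j in range(20)]] == "flipped_strand").all()
        # ambiguous sites: panel frequency 0.85 is far from 0.5, so they are
        # kept by frequency matching rather than dropped
        assert (actions[[f"t{j}" for j in range(20, 25)]] == "kept_freq_matched").all()

    def test_ambiguous_near_half_dropped(self):
        rng = np.random.default_rng(8)
        markers = [BinaryMarker(id="SNP_0", kind="SNP", gene="",
                                position=29_500_000, present_label="C",
                                absent_label="G")]
        haps = rng.integers(0, 2, (40, 1)).astype(np.uint8)  # freq ~ 0.5
        panel = ReferencePanel(haps, markers, [f"R{i}" for i in range(20)])
        g = rng.binomial(2, 0.5, 50).astype(float)
        geno = pd.DataFrame({"s0": g}, index=[f"T{i}" for i in range(50)])
        meta = pd.DataFrame([{"id": "s0", "position": 29_500_000,
                              "a1": "C", "a2": "G"}])
        with pytest.raises(ValueError, match="no overlap"):
            hmm.harmonize(geno, meta, panel)

    def test_zero_overlap_rejected(self):
        panel = self._panel()
        geno = self._geno(cols={"s0": np.ones(40)})
        meta = pd.DataFrame([{"id": "s0", "position": 1, "a1": "A", "a2": "G"}])
        with pytest.raises(ValueError, match="no overlap"):
            hmm.harmonize(geno, meta, panel)
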