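"""Drift-null scan: starting frequencies, variance law, Ne, combination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sowselect as ss
from sowselect.panel import MISSING


def _tiny_panel(genotypes, chrom=None):
    g = np.asarray(genotypes, dtype=np.int8)
    n_acc, n_snp = g.shape
    return ss.GenotypePanel(
        accession_ids=[f"a{i}" for i in range(n_acc)],
        group_labels=["G1"] * n_acc,
        lat=np.full(n_acc, 60.0),
        lon=np.full(n_acc, 15.0),
        chrom=chrom or ["Chr1"] * n_snp,
        pos=np.arange(1, n_snp + 1),
        genotypes=g,
    )


class TestStartingFreqs:
    def test_fixed_and_singleton_frequencies(self):
        g = np.zeros((200, 2), dtype=np.int8)
        g[:, 0] = 1       # carried by all -> 1
        g[0, 1] = 1       # carried by 1 of 200 -> 0.005
        p0 = ss.starting_freqs(_tiny_panel(g))
        assert p0.iloc[0] == 1.0
        assert p0.iloc[1] == pytest.approx(0.005)

    def test_matches_naive_loop_oracle_with_missing(self):
        rng = np.random.default_rng(0)
        g = rng.choice(np.array([0, 1, MISSING], dtype=np.int8), size=(5, 5),
                       p=[0.4, 0.4, 0.2])
        if (g == MISSING).all(axis=0).any():  # keep every SNP observed
            g[0] = 0
        p0 = ss.starting_freqs(_tiny_panel(g)).to_numpy()
        for j in range(5):
            vals = [g[i, j] for i in range(5) if g[i, j] != MISSING]
            assert p0[j] == pytest.approx(sum(vals) / len(vals))

    def test_all_missing_snp_dropped_with_warning(self):
        g = np.zeros((3, 4), dtype=np.int8)
        g[:, 2] = MISSING
        with pytest.warns(UserWarning, match="dropped 1"):
            p0 = ss.starting_freqs(_tiny_panel(g))
        assert len(p0) == 3


class TestNullVariance:
    def test_zero_at_fixed_frequency(self):
        assert ss.null_variance(0.0, 171, 17) == 0.0
        assert ss.null_variance(1.0, 171, 17) == 0.0

    def test_symmetric_in_p0(self):
        assert ss.null_variance(0.3, 137, 16) == pytest.approx(
            ss.null_variance(0.7, 137, 16)
        )

    def test_three_term_hand_value(self):
        # (1/171 + 1/17 + 1/(171*17)) * 0.25
        assert ss.null_variance(0.5, 171, 17) == pytest.approx(0.016254, abs=5e-7)

    def test_exact_vs_approximate_form_negligible_for_ne(self):
        # inverting with/without the cross term moves Ne by < 1 across the
        # study regime — documents why using the exact form is safe
        for ne in (16, 34, 70):
            for n in (137, 208):
                s = 1 / n + 1 / ne + 1 / (n * ne)
                ne_exact = (1 + 1 / n) / (s - 1 / n)
                ne_approx = 1 / (s - 1 / n)
                assert ne_exact == pytest.approx(ne, abs=1e-9)
                assert abs(ne_approx - ne) < 1


class TestEstimateNe:
    def test_iid_simulation_with_known_truth(self):
        # dp drawn i.i.d. at the exact null variance: median over 20
        # replicates of 50k SNPs recovers Ne=50 within [40, 60]
        ne_true, n = 50, 200
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(20):
            p0 = rng.uniform(0.05, 0.95, 50_000)
            sd = np.sqrt(ss.null_variance(p0, n, ne_true))
            delta = rng.normal(0.0, sd)
            estimates.append(ss.estimate_ne(delta, p0, n).ne)
        assert 40 <= np.median(estimates) <= 60

    def test_zero_delta_flagged_invalid(self):
        p0 = np.linspace(0.1, 0.9, 1000)
        est = ss.estimate_ne(np.zeros(1000), p0, 200)
        assert not est.valid
        assert np.isnan(est.ne)

    def test_too_few_snps_rejected(self):
        p0 = np.full(50, 0.5)
        with pytest.raises(ValueError, match="MAF floor"):
            ss.estimate_ne(np.zeros(50), p0, 100)

    def test_maf_floor_excludes_rare_snps(self):
        p0 = np.concatenate([np.full(500, 0.5), np.full(500, 0.01)])
        delta = np.zeros(1000)
        delta[:500] = 0.1
        est = ss.estimate_ne(delta, p0, 100)
        assert est.n_snps_used == 500


class TestScan:
    def test_zero_delta_uncentered(self):
        z, p, n_exc = ss.scan(np.zeros(10), np.full(10, 0.01), center=False)
        assert (z == 0).all() and (p == 1).all() and n_exc == 0

    def test_p_monotone_decreasing_in_abs_z(self):
        delta = np.array([-0.3, -0.1, 0.0, 0.05, 0.2])
        z, p, _ = ss.scan(delta, np.full(5, 0.01), center=False)
        order = np.argsort(np.abs(z))
        assert (np.diff(p[order]) <= 0).all()

    def test_zero_variance_snps_excluded_and_counted(self):
        var0 = np.array([0.01, 0.0, 0.02])
        z, p, n_exc = ss.scan(np.array([0.1, 0.1, 0.1]), var0, center=False)
        assert n_exc == 1
        assert np.isnan(z[1]) and np.isnan(p[1])
        assert np.isfinite(z[[0, 2]]).all()

    def test_centering_absorbs_constant_shift(self):
        rng = np.random.default_rng(3)
        delta = rng.normal(0.02, 0.05, 5000)  # biased mean, e.g. reference bias
        z, _, _ = ss.scan(delta, np.full(5000, 0.05**2), center=True)
        assert abs(np.nanmean(z)) < 1e-12


class TestCombine:
    def _series(self, vals, start=1):
        idx = pd.MultiIndex.from_arrays(
            [["Chr1"] * len(vals), np.arange(start, start + len(vals))],
            names=["chrom", "pos"],
        )
        return pd.Series(vals, index=idx)

    def test_product_of_two(self):
        out = ss.combine_experiments(
            {"A": self._series([0.1, 0.5]), "B": self._series([0.1, 0.2])}
        )
        assert out["combined_score"].iloc[0] == pytest.approx(0.01)
        assert out["combined_score"].iloc[1] == pytest.approx(0.1)
        assert (out["n_sites"] == 2).all()

    def test_single_table_unchanged(self):
        vals = [0.3, 0.001, 0.9]
        out = ss.combine_experiments({"A": self._series(vals)})
        assert np.allclose(out["combined_score"], vals)

    def test_missing_sites_skipped_and_counted(self):
        a = self._series([0.1, 0.2], start=1)
        b = self._series([0.5], start=1)  # missing SNP at pos 2
        out = ss.combine_experiments({"A": a, "B": b})
        assert out.loc[("Chr1", 1), "n_sites"] == 2
        assert out.loc[("Chr1", 2), "n_sites"] == 1
        assert out.loc[("Chr1", 2), "combined_score"] == pytest.approx(0.2)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="no p-value tables"):
            ss.combine_experiments({})

    def test_neg_ln_product_of_uniforms_is_gamma(self):
        # Fisher identity: -ln of the product of 4 independent U(0,1)
        # p-values ~ Gamma(4, 1)
        rng = np.random.default_rng(11)
        tables = {f"s{i}": self._series(rng.uniform(size=10_000)) for i in range(4)}
        out = ss.combine_experiments(tables)
        neg_ln = -np.log(out["combined_score"].to_numpy())
        ks = stats.kstest(neg_ln, "gamma", args=(4,)).statistic
        assert ks < 0.05

    def test_fisher_transform_is_calibrated(self):
        rng = np.random.default_rng(12)
        tables = {f"s{i}": self._series(rng.uniform(size=5000)) for i in range(4)}
        out = ss.combine_experiments(tables, fisher=True)
        # calibrated p-values are uniform
        assert stats.kstest(out["fisher_p"], "uniform").statistic < 0.05


class TestWriteScan:
    def test_roundtrip_byte_identical(self, tmp_path):
        rng = np.random.default_rng(5)
        idx = pd.MultiIndex.from_arrays(
            [["Chr2"] * 5 + ["Chr1"] * 5, list(range(10, 0, -1))],
            names=["chrom", "pos"],
        )
        table = pd.DataFrame(
            {"p0": rng.uniform(size=10), "combined_score": rng.uniform(size=10)},
            index=idx,
        )
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        ss.write_scan(table, f1)
        df = ss.read_scan(f1)
        assert len(df) == 10
        # sorted by (chrom, pos)
        assert df["chrom"].is_monotonic_increasing or (
            df.groupby("chrom")["pos"].apply(lambda s: s.is_monotonic_increasing).all()
        )
        ss.write_scan(df, f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestDriftScanModel:
    def _fit(self, panel, fitness=None, ne=34, n=208, seed=0, sites=("NA", "SR")):
        p0 = ss.starting_freqs(panel)
        p_hat, n_sample = {}, {}
        for i, site in enumerate(sites):
            calls, _ = ss.simulate_selection_experiment(
                panel, fitness, ne, n, seed=seed + i, site_id=site
            )
            p_hat[site] = pd.Series(calls.calls.mean(axis=0), index=p0.index)
            n_sample[site] = n
        return ss.DriftScan(p0, p_hat, n_sample).fit()

    def test_neutral_full_simulation_recovers_ne(self, study_panel):
        res = self._fit(study_panel, ne=34, n=208, seed=40)
        for est in res.ne_estimates.values():
            assert est.valid
            assert abs(est.ne - 34) / 34 < 0.4  # single replicate; medians tested elsewhere

    def test_selected_private_snps_rank_top(self, study_panel):
        # implant 10 SNPs private to one accession, give it 10x fitness at
        # both sites: those SNPs must land in the top 1% of combined scores
        g = study_panel.genotypes.copy()
        private = np.arange(100, 2100, 200)
        g[:, private] = 0
        g[0, private] = 1
        panel = ss.GenotypePanel(
            accession_ids=list(study_panel.accession_ids),
            group_labels=list(study_panel.group_labels),
            lat=study_panel.lat.copy(),
            lon=study_panel.lon.copy(),
            chrom=list(study_panel.chrom),
            pos=study_panel.pos.copy(),
            genotypes=g,
        )
        fitness = np.ones(panel.n_accessions)
        fitness[0] = 10.0
        res = self._fit(panel, fitness=fitness, ne=70, n=199, seed=60,
                        sites=("NA", "NB", "SR", "ST"))
        ranks = res.table["combined_score"].rank(pct=True).to_numpy()
        assert (ranks[private] <= 0.01).mean() >= 0.9

    def test_summary_mentions_sites_and_ne(self, study_panel):
        res = self._fit(study_panel, seed=80)
        text = res.summary()
        assert "NA" in text and "SR" in text and "Ne" in text

    def test_ne_override(self, study_panel):
        p0 = ss.starting_freqs(study_panel)
        calls, _ = ss.simulate_selection_experiment(
            study_panel, None, 34, 208, seed=90, site_id="SR"
        )
        p_hat = {"SR": pd.Series(calls.calls.mean(axis=0), index=p0.index)}
        res = ss.DriftScan(p0, p_hat, {"SR": 208}).fit(ne={"SR": 34.0})
        assert res.ne_estimates["SR"].ne == 34.0
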