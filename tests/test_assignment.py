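"""Panel assignment: mismatch rates, classification workflow, composition."""

import numpy as np
import pandas as pd
import pytest

import sowselect as ss
from sowselect.panel import HET, MISSING, SampleCalls
from sowselect.simulate import simulate_site_samples

from conftest import naive_mismatch


def _calls_from_vector(panel, vec, sample_id="s1", site="NA"):
    return SampleCalls(
        sample_ids=[sample_id],
        site_ids=[site],
        chrom=list(panel.chrom),
        pos=panel.pos.copy(),
        calls=np.asarray(vec, dtype=np.int8)[None, :],
    )


class TestMismatchRate:
    def test_identical_zero(self):
        v = np.tile([0, 1], 5000).astype(np.int8)
        assert ss.mismatch_rate(v, v) == 0.0

    def test_complementary_one(self):
        v = np.tile([0, 1], 5000).astype(np.int8)
        assert ss.mismatch_rate(v, 1 - v) == 1.0

    def test_five_in_thousand(self):
        acc = np.zeros(1000, dtype=np.int8)
        smp = acc.copy()
        smp[:5] = 1
        assert ss.mismatch_rate(smp, acc) == pytest.approx(0.005)

    def test_het_and_missing_excluded(self):
        acc = np.array([0, 1, 0, 1, 0, 1], dtype=np.int8)
        smp = np.array([0, 1, HET, MISSING, 1, MISSING], dtype=np.int8)
        # informative: positions 0,1,4 -> one discordant
        assert ss.mismatch_rate(smp, acc) == pytest.approx(1 / 3)
        assert ss.mismatch_rate(smp, acc) == pytest.approx(naive_mismatch(smp, acc))

    def test_zero_informative_is_nan(self):
        acc = np.array([0, 1], dtype=np.int8)
        smp = np.array([HET, MISSING], dtype=np.int8)
        assert np.isnan(ss.mismatch_rate(smp, acc))

    def test_matches_naive_oracle_random(self, small_panel):
        rng = np.random.default_rng(0)
        smp = rng.choice(
            np.array([0, 1, HET, MISSING], dtype=np.int8), size=small_panel.n_snps
        )
        for row in (0, 7, 23):
            assert ss.mismatch_rate(smp, small_panel.genotypes[row]) == pytest.approx(
                naive_mismatch(smp, small_panel.genotypes[row])
            )


class TestAssignSample:
    def test_noiseless_sample_is_experimental(self, small_panel):
        sc = _calls_from_vector(small_panel, small_panel.genotypes[6])
        r = ss.assign_sample(sc, small_panel, min_informative=1000)
        assert r.sample_class == "experimental"
        assert r.best_accession == small_panel.accession_ids[6]
        assert r.mismatch == 0.0

    def test_constructed_native_with_brute_force_verification(self, small_panel):
        # flip 5% of one accession's calls at sites where flipping also
        # moves it away from every other accession
        g = small_panel.genotypes
        base = g[0].copy()
        target = int(0.06 * small_panel.n_snps)
        flipped = 0
        # prefer sites where the whole panel agrees (flip moves away from all)
        for j in range(small_panel.n_snps):
            if flipped >= target:
                break
            if (g[:, j] == base[j]).all():
                base[j] = 1 - base[j]
                flipped += 1
        rng = np.random.default_rng(1)
        while flipped < target:
            j = int(rng.integers(small_panel.n_snps))
            base[j] = 1 - g[0, j]
            flipped = int((base != g[0]).sum())
        # brute-force oracle: mismatch to every accession
        mins = min(naive_mismatch(base, g[i]) for i in range(g.shape[0]))
        assert mins >= 0.05
        r = ss.assign_sample(
            _calls_from_vector(small_panel, base), small_panel, min_informative=1000
        )
        assert r.sample_class == "native_volunteer"

    def test_low_data_below_min_informative(self, small_panel):
        vec = small_panel.genotypes[3].copy()
        vec[900:] = MISSING  # 900 informative sites
        r = ss.assign_sample(
            _calls_from_vector(small_panel, vec), small_panel, min_informative=1000
        )
        assert r.sample_class == "low_data"
        assert r.n_informative == 900

    def test_het_precedence_over_match(self, small_panel):
        vec = small_panel.genotypes[3].copy()
        vec[: small_panel.n_snps // 2] = HET  # matches acc3 at homozygous sites
        r = ss.assign_sample(
            _calls_from_vector(small_panel, vec), small_panel, min_informative=100
        )
        assert r.sample_class == "heterozygous"

    def test_tie_gives_low_data_with_candidates(self, small_panel):
        g = np.vstack([small_panel.genotypes, small_panel.genotypes[0]])
        dup = ss.GenotypePanel(
            accession_ids=small_panel.accession_ids + ["dup"],
            group_labels=small_panel.group_labels + ["G1"],
            lat=np.append(small_panel.lat, 60.0),
            lon=np.append(small_panel.lon, 15.0),
            chrom=list(small_panel.chrom),
            pos=small_panel.pos.copy(),
            genotypes=g,
        )
        r = ss.assign_sample(
            _calls_from_vector(dup, g[0]), dup, min_informative=1000
        )
        assert r.sample_class == "low_data"
        assert set(r.candidates) == {small_panel.accession_ids[0], "dup"}

    def test_unaligned_calls_rejected(self, small_panel):
        sc = _calls_from_vector(small_panel, small_panel.genotypes[0])
        sc = SampleCalls(
            sample_ids=sc.sample_ids,
            site_ids=sc.site_ids,
            chrom=sc.chrom[::-1],
            pos=sc.pos[::-1].copy(),
            calls=sc.calls,
        )
        with pytest.raises(ValueError, match="aligned"):
            ss.assign_samples(sc, small_panel)

    def test_monotone_in_min_informative(self, small_panel):
        # raising min_informative can only move samples into low_data
        calls, _ = simulate_site_samples(
            small_panel,
            ss.SimConfig(
                n_accessions=50, n_snps=2000, rng_seed=5,
                ne_per_site={"NA": 20}, n_sample_per_site={"NA": 80},
                site_coords={"NA": (62.9, 18.3)},
            ),
            "NA",
        )
        lo = ss.assign_samples(calls, small_panel, min_informative=500)
        hi = ss.assign_samples(calls, small_panel, min_informative=950)
        for a, b in zip(lo, hi):
            if a.sample_class == "low_data":
                assert b.sample_class == "low_data"
            elif b.sample_class != "low_data":
                assert a.sample_class == b.sample_class

    def test_noiseless_accuracy_is_perfect(self, small_panel):
        calls, truth = ss.simulate_selection_experiment(small_panel, None, 25, 120, seed=6)
        res = ss.assign_samples(calls, small_panel, min_informative=1000)
        assert all(
            r.sample_class == "experimental" and r.best_accession == t
            for r, t in zip(res, truth.source)
        )


class TestMinSnps:
    def test_duplicate_accessions_flagged_every_k(self, small_panel):
        g = np.vstack([small_panel.genotypes[:10], small_panel.genotypes[0]])
        panel = ss.GenotypePanel(
            accession_ids=[f"a{i}" for i in range(10)] + ["a0dup"],
            group_labels=["G1"] * 11,
            lat=np.full(11, 60.0),
            lon=np.full(11, 15.0),
            chrom=list(small_panel.chrom),
            pos=small_panel.pos.copy(),
            genotypes=g,
        )
        res = ss.min_snps_by_simulation(panel, [100, 500], n_reps=3, seed=1)
        assert ("a0", "a0dup") in res.indistinguishable_pairs

    def test_divergent_panel_needs_few_snps(self):
        # 20 accessions differing pairwise at >= 10% of sites: some k <= 2000
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, size=(20, 4000)).astype(np.int8)  # ~50% divergence
        panel = ss.GenotypePanel(
            accession_ids=[f"a{i}" for i in range(20)],
            group_labels=["G1"] * 20,
            lat=np.full(20, 60.0),
            lon=np.full(20, 15.0),
            chrom=["Chr1"] * 4000,
            pos=np.arange(1, 4001),
            genotypes=g,
        )
        # brute-force check of the premise
        for i in range(20):
            for j in range(i + 1, 20):
                assert (g[i] != g[j]).mean() >= 0.10
        res = ss.min_snps_by_simulation(panel, [200, 1000, 2000], n_reps=5, seed=2)
        assert res.min_k is not None and res.min_k <= 2000
        assert res.indistinguishable_pairs == []

    def test_determinism(self, small_panel):
        a = ss.min_snps_by_simulation(small_panel, [200, 800], n_reps=3, seed=9)
        b = ss.min_snps_by_simulation(small_panel, [200, 800], n_reps=3, seed=9)
        assert a.min_k == b.min_k
        pd.testing.assert_frame_equal(a.per_k, b.per_k)

    def test_nonincreasing_with_divergence(self):
        # a 3-point divergence ladder: more divergent panels never need more SNPs
        rng = np.random.default_rng(8)
        min_ks = []
        for flip in (0.02, 0.10, 0.40):
            base = rng.integers(0, 2, size=3000).astype(np.int8)
            g = np.vstack(
                [np.where(rng.random(3000) < flip, 1 - base, base) for _ in range(12)]
            ).astype(np.int8)
            panel = ss.GenotypePanel(
                accession_ids=[f"a{i}" for i in range(12)],
                group_labels=["G1"] * 12,
                lat=np.full(12, 60.0),
                lon=np.full(12, 15.0),
                chrom=["Chr1"] * 3000,
                pos=np.arange(1, 3001),
                genotypes=g,
            )
            res = ss.min_snps_by_simulation(
                panel, [50, 100, 200, 400, 800, 1600, 3000], n_reps=5, seed=4
            )
            assert res.min_k is not None
            min_ks.append(res.min_k)
        assert min_ks == sorted(min_ks, reverse=True)

    def test_ascending_grid_required(self, small_panel):
        with pytest.raises(ValueError, match="ascending"):
            ss.min_snps_by_simulation(small_panel, [500, 100])


class TestComposition:
    def _single_class_results(self, n, cls="experimental", acc="accA", site="NA"):
        return [
            ss.AssignmentResult(
                sample_id=f"s{i}", site_id=site, sample_class=cls,
                best_accession=acc if cls == "experimental" else None,
                mismatch=0.0, n_informative=10_000, het_fraction=0.0,
            )
            for i in range(n)
        ]

    def test_all_one_accession(self):
        comp = ss.summarize_composition(self._single_class_results(10))
        assert comp.accession_counts.loc["NA", "accA"] == 10
        fracs = comp.class_fractions().loc["NA"]
        assert fracs["experimental"] == 1.0
        assert fracs.drop("experimental").sum() == 0.0

    def test_truth_fractions_recovered_without_noise(self, small_panel):
        cfg = ss.SimConfig(
            n_accessions=50, n_snps=2000, rng_seed=13,
            ne_per_site={"NA": 25}, n_sample_per_site={"NA": 1000},
            site_coords={"NA": (62.9, 18.3)},
            native_fraction=0.158, het_fraction=0.088,
            genotype_error_rate=0.0, missing_rate=0.0,
        )
        calls, truth = simulate_site_samples(small_panel, cfg, "NA")
        res = ss.assign_samples(calls, small_panel, min_informative=1000)
        comp = ss.summarize_composition(res)
        fr = comp.class_fractions().loc["NA"]
        n_nat = truth.source.count("native")
        n_het = truth.source.count("heterozygous")
        assert fr["native_volunteer"] == pytest.approx(n_nat / 1000)
        assert fr["heterozygous"] == pytest.approx(n_het / 1000)
        assert fr["experimental"] == pytest.approx(1 - (n_nat + n_het) / 1000)
        assert fr["low_data"] == 0.0
        # mirrors the expected 75.4 / 15.8 / 8.8 split
        assert fr["native_volunteer"] == pytest.approx(0.158)
        assert fr["heterozygous"] == pytest.approx(0.088)

    def test_empty_site_all_zero(self):
        comp = ss.summarize_composition(
            self._single_class_results(5), sites=["NA", "EMPTY"]
        )
        assert comp.class_counts.loc["EMPTY"].sum() == 0
        assert comp.accession_counts.loc["EMPTY"].sum() == 0

    def test_undeclared_site_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            ss.summarize_composition(self._single_class_results(3), sites=["XX"])
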