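import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptmvar.disease import (
    active_driver,
    active_driver_table,
    bh_adjust,
    cancer_gene_enrichment,
    central_residue_enrichment,
    region_enrichment_fisher,
    region_enrichment_poisson,
)
from ptmvar.regions import PTMRegion, PTMSite


def _masks(ann_idx, region_span, length=1000, disorder=False):
    ann = np.zeros(length, dtype=bool)
    ann[ann_idx] = True
    reg = np.zeros(length, dtype=bool)
    reg[region_span[0] : region_span[1]] = True
    dis = np.full(length, disorder)
    return {"P1": ann}, {"P1": reg}, {"P1": dis}


class TestFisher:
    def test_spec_table(self):
        # [[10,90],[10,890]] in the structured stratum
        ann, reg, dis = _masks(list(range(10)) + list(range(100, 110)), (0, 100))
        out = region_enrichment_fisher(ann, reg, dis)
        structured = next(r for r in out if r.stratum == "structured")
        odds, p = stats.fisher_exact([[10, 90], [10, 890]], alternative="greater")
        assert structured.observed == 10
        assert structured.odds_ratio == pytest.approx(9.888888888888889)
        assert structured.p == pytest.approx(p)

    def test_no_annotations_p_one(self):
        ann, reg, dis = _masks([], (0, 100))
        out = region_enrichment_fisher(ann, reg, dis)
        assert all(r.p == 1.0 for r in out)

    def test_all_residues_in_regions_flagged(self):
        ann, reg, dis = _masks([5], (0, 1000))
        out = region_enrichment_fisher(ann, reg, dis)
        structured = next(r for r in out if r.stratum == "structured")
        assert np.isnan(structured.odds_ratio)
        assert "undefined" in structured.note


class TestPoisson:
    def test_expected_four_observed_four(self):
        # 40 annotations, region covers 1/10 of residues -> expected 4
        counts = np.zeros(1000)
        counts[:4] = 1  # 4 records inside the region
        counts[500:536] = 1  # 36 outside
        reg = np.zeros(1000, dtype=bool)
        reg[:100] = True
        res = region_enrichment_poisson({"P1": counts}, {"P1": reg})
        assert res.expected == pytest.approx(4.0)
        assert res.observed == 4
        assert res.p == pytest.approx(stats.poisson.sf(3, 4.0))
        assert res.p == pytest.approx(0.56653, abs=1e-4)
        assert res.expected_sd == pytest.approx(2.0)

    def test_observed_zero_upper_tail_near_one(self):
        counts = np.zeros(1000)
        counts[500:540] = 1
        reg = np.zeros(1000, dtype=bool)
        reg[:100] = True
        res = region_enrichment_poisson({"P1": counts}, {"P1": reg})
        assert res.observed == 0
        assert res.p == 1.0

    def test_no_annotations_error(self):
        with pytest.raises(ValueError, match="no disease annotations"):
            region_enrichment_poisson({"P1": np.zeros(10)}, {"P1": np.zeros(10, dtype=bool)})

    def test_multiplicity_counts(self):
        counts = np.zeros(100)
        counts[5] = 7
        reg = np.zeros(100, dtype=bool)
        reg[:10] = True
        res = region_enrichment_poisson({"P1": counts}, {"P1": reg})
        assert res.observed == 7


class TestCentralResidue:
    def _inputs(self, n_ann_sites):
        seq = "S" * 100 + "A" * 100
        sites = pd.DataFrame(
            {
                "protein": "P1",
                "position": np.arange(1, 11),
                "residue": "S",
                "ptm_type": "phospho",
            }
        )
        ann = np.zeros(200, dtype=bool)
        ann[:n_ann_sites] = True  # annotate the first sites
        ann[50:52] = True  # 2 background S annotations among 90
        return {"P1": ann}, sites, {"P1": seq}

    def test_binomial_upper_tail(self):
        annotated, sites, seqs = self._inputs(5)
        res = central_residue_enrichment(annotated, sites, seqs, "phospho")
        rate = 2 / 90
        expect = stats.binomtest(5, 10, rate, alternative="greater").pvalue
        assert res.p == pytest.approx(expect)
        assert res.observed == 5
        assert res.expected == pytest.approx(10 * rate)

    def test_no_sites_of_type(self):
        annotated, sites, seqs = self._inputs(0)
        res = central_residue_enrichment(annotated, sites, seqs, "ubiq")
        assert "no sites" in res.note


class TestBH:
    def test_brute_force_definition(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=15)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        expect = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            k = m - rank_from_top
            running = min(running, p[idx] * m / k)
            expect[idx] = running
        np.testing.assert_allclose(q, expect, atol=1e-12)

    def test_monotone_in_p_rank(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.8])
        q = bh_adjust(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()


class TestActiveDriver:
    def _region(self, start, end):
        return PTMRegion("P1", start, end, [PTMSite("P1", (start + end) // 2, "S", "phospho")])

    def test_zero_mutations_gene_p_one(self):
        res = active_driver("P1", 100, np.zeros(100), [self._region(40, 60)], np.zeros(100, dtype=bool))
        assert res.gene_p == 1.0
        assert all(p == 1.0 for p in res.region_p.values())

    def test_uniform_mutations_not_significant(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.5, size=400)
        res = active_driver("P1", 400, counts, [self._region(100, 130)], np.zeros(400, dtype=bool))
        assert res.gene_p > 0.01

    def test_hotspot_detected(self):
        counts = np.zeros(400)
        counts[:] = 0.0
        rng = np.random.default_rng(1)
        counts += rng.poisson(0.1, size=400)
        counts[100:115] += 3  # dense cluster inside the region
        res = active_driver("P1", 400, counts, [self._region(100, 114)], np.zeros(400, dtype=bool))
        assert res.gene_p < 1e-6

    def test_expectation_conservation(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(0.3, size=300).astype(float)
        disorder = np.zeros(300, dtype=bool)
        disorder[100:200] = True
        regions = [self._region(10, 24), self._region(150, 164)]
        # the fitted model's expected counts must sum to the observed total
        import statsmodels.api as sm

        X = sm.add_constant(disorder.astype(float), has_constant="add")
        fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
        assert fit.predict(X).sum() == pytest.approx(counts.sum())

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="length"):
            active_driver("P1", 100, np.zeros(50), [], np.zeros(100, dtype=bool))

    def test_table_bh_and_fisher_combine(self):
        results = []
        rng = np.random.default_rng(3)
        for i in range(5):
            counts = rng.poisson(0.2, size=200).astype(float)
            res = active_driver(f"P{i}", 200, counts, [self._region(50, 64)], np.zeros(200, dtype=bool))
            results.append(res)
        table = active_driver_table(results)
        assert len(table) == 5
        np.testing.assert_allclose(
            table["gene_q"].to_numpy(), bh_adjust(table["gene_p"].to_numpy()), atol=1e-12
        )
        # gene_p for one region equals Fisher combination of that single p
        one = results[0]
        p0 = list(one.region_p.values())[0]
        chi = -2 * math.log(max(p0, 1e-300))
        assert one.gene_p == pytest.approx(float(stats.chi2.sf(chi, 2)))


class TestCancerGenes:
    def test_disjoint_or_at_most_one(self):
        res = cancer_gene_enrichment({"A", "B"}, {"C", "D"}, {"A", "B", "C", "D", "E"})
        assert res.observed == 0
        assert res.p >= 0.05

    def test_planted_overlap_small_p(self):
        universe = {f"G{i}" for i in range(100)}
        sig = {f"G{i}" for i in range(10)}
        cancer = {f"G{i}" for i in range(8)} | {"G50"}
        res = cancer_gene_enrichment(sig, cancer, universe)
        assert res.p < 1e-4

    def test_all_cancer_genes_degenerate(self):
        universe = {"A", "B"}
        res = cancer_gene_enrichment({"A"}, {"A", "B"}, universe)
        assert "degenerate" in res.note

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            cancer_gene_enrichment(set(), set(), set())
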