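import numpy as np
import pytest

from ptmvar.regions import (
    PTMRegion,
    PTMSite,
    build_regions,
    classify_zones,
    cluster_bins,
    filter_by_support,
    frame_to_sites,
    match_peptides,
    region_masks,
    sites_to_frame,
    validate_site,
)


def site(pos, protein="P1", residue="S", ptm_type="phospho", n_pubs=1):
    return PTMSite(protein, pos, residue, ptm_type, n_pubs)


class TestBuildRegions:
    def test_single_interior_site(self):
        regions = build_regions([site(50)], {"P1": 100})
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (43, 57)
        assert r.length == 15

    def test_two_overlapping_sites_merge(self):
        regions = build_regions([site(50), site(60)], {"P1": 100})
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (43, 67)

    def test_terminus_clipping(self):
        regions = build_regions([site(3)], {"P1": 100})
        assert (regions[0].start, regions[0].end) == (1, 10)

    def test_adjacent_but_disjoint_windows_not_merged(self):
        # windows [43,57] and [58,72] touch end-to-start without sharing a residue
        regions = build_regions([site(50), site(65)], {"P1": 100})
        assert len(regions) == 2

    def test_windows_sharing_one_residue_merge(self):
        # [43,57] and [57,71] share residue 57
        regions = build_regions([site(50), site(64)], {"P1": 100})
        assert len(regions) == 1

    def test_every_site_in_exactly_one_region(self):
        sites = [site(p) for p in (5, 20, 21, 40, 90)]
        regions = build_regions(sites, {"P1": 100})
        placed = [s for r in regions for s in r.sites]
        assert sorted(s.position for s in placed) == [5, 20, 21, 40, 90]
        for r in regions:
            for s in r.sites:
                assert r.start <= s.position <= r.end

    def test_idempotent_on_own_sites(self):
        sites = [site(p) for p in (5, 20, 21, 40, 90)]
        first = build_regions(sites, {"P1": 100})
        again = build_regions([s for r in first for s in r.sites], {"P1": 100})
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in first]

    def test_coverage_equals_window_union(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            length = int(rng.integers(20, 120))
            positions = sorted(set(rng.integers(1, length + 1, size=6).tolist()))
            sites = [site(int(p)) for p in positions]
            regions = build_regions(sites, {"P1": length})
            union = set()
            for p in positions:
                union |= set(range(max(1, p - 7), min(length, p + 7) + 1))
            covered = {q for r in regions for q in range(r.start, r.end + 1)}
            assert covered == union


class TestZones:
    def test_single_site_zones(self):
        r = build_regions([site(50)], {"P1": 100})[0]
        zones = classify_zones(r)
        assert zones[50] == "DI"
        assert zones[51] == "N1"
        assert zones[54] == "N2"

    def test_nearest_site_wins(self):
        r = build_regions([site(50), site(53)], {"P1": 100})[0]
        assert classify_zones(r)[51] == "N1"

    def test_equidistant(self):
        r = build_regions([site(50), site(52)], {"P1": 100})[0]
        assert classify_zones(r)[51] == "N1"

    def test_zone_partition_tiles_region(self):
        r = build_regions([site(30), site(38), site(45)], {"P1": 100})[0]
        zones = classify_zones(r)
        assert sorted(zones) == list(range(r.start, r.end + 1))
        assert set(zones.values()) <= {"DI", "N1", "N2"}
        assert {p for p, z in zones.items() if z == "DI"} == set(r.site_positions)

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            positions = sorted(set(rng.integers(10, 90, size=4).tolist()))
            r = build_regions([site(int(p)) for p in positions], {"P1": 100})
            for region in r:
                zones = classify_zones(region)
                for q in range(region.start, region.end + 1):
                    d = min(abs(q - p) for p in region.site_positions)
                    expect = "DI" if d == 0 else ("N1" if d <= 2 else "N2")
                    assert zones[q] == expect


class TestClusterBins:
    def test_single_site_bin1(self):
        r = build_regions([site(50)], {"P1": 100})[0]
        assert set(cluster_bins(r).values()) == {1}

    def test_three_adjacent_sites(self):
        r = build_regions([site(50), site(51, residue="T"), site(52, residue="Y")], {"P1": 100})[0]
        assert cluster_bins(r)[50] == 3

    def test_cap_at_five(self):
        sites = [site(50 + i) for i in range(6)]
        r = build_regions(sites, {"P1": 100})[0]
        assert cluster_bins(r)[52] == 5

    def test_multi_type_position_counts_once(self):
        two_types = [site(50, residue="K", ptm_type="ubiq"), site(50, residue="K", ptm_type="acet")]
        r = build_regions(two_types, {"P1": 100})[0]
        assert cluster_bins(r)[50] == 1


class TestMatchPeptides:
    def test_single_occurrence(self):
        pep = "AAAAAAASAAAAAAA"
        proteome = {"P1": "MMM" + pep + "MMM"}
        sites, rejected = match_peptides([(pep, "phospho")], proteome)
        assert not rejected
        assert len(sites) == 1
        assert sites[0].position == 3 + 8  # center S
        assert proteome["P1"][sites[0].position - 1] == "S"

    def test_two_occurrences_two_sites(self):
        pep = "AAAAAAASAAAAAAA"
        proteome = {"P1": pep + "WW" + pep}
        sites, _ = match_peptides([(pep, "phospho")], proteome)
        assert len(sites) == 2

    def test_incompatible_center_rejected(self):
        pep = "AAAAAAAKAAAAAAA"
        sites, rejected = match_peptides([(pep, "phospho")], {"P1": pep})
        assert not sites
        assert "incompatible" in rejected[0]["reason"]

    def test_no_match_reported(self):
        sites, rejected = match_peptides([("AAAAAAASAAAAAAA", "phospho")], {"P1": "WWWW"})
        assert not sites
        assert rejected[0]["reason"] == "no match in proteome"


class TestSupportFilter:
    def test_min_pubs_one_is_identity(self):
        sites = [site(10, n_pubs=1), site(30, n_pubs=2), site(50, n_pubs=3)]
        assert filter_by_support(sites, 1) == sites

    def test_min_pubs_two(self):
        sites = [site(10, n_pubs=1), site(30, n_pubs=2), site(50, n_pubs=3)]
        assert len(filter_by_support(sites, 2)) == 2

    def test_all_removed_warns(self):
        with pytest.warns(UserWarning):
            out = filter_by_support([site(10, n_pubs=1)], 5)
        assert out == []


class TestValidation:
    def test_residue_type_mismatch(self):
        with pytest.raises(ValueError, match="allowed set"):
            validate_site(site(10, residue="K", ptm_type="phospho"))

    def test_sequence_mismatch(self):
        with pytest.raises(ValueError, match="claims"):
            validate_site(site(1, residue="S"), sequence="A")

    def test_unknown_type(self):
        with pytest.raises(ValueError, match="unknown PTM type"):
            PTMSite("P1", 1, "S", "glyco")


def test_frame_round_trip():
    sites = [site(5), site(20, residue="K", ptm_type="ubiq", n_pubs=3)]
    back = frame_to_sites(sites_to_frame(sites))
    assert [(s.protein, s.position, s.residue, s.ptm_type, s.n_pubs) for s in back] == [
        (s.protein, s.position, s.residue, s.ptm_type, s.n_pubs) for s in sites
    ]


def test_region_masks(annotated, cohort):
    _, regions, masks, _ = annotated
    for r in regions:
        assert masks[r.protein][r.start - 1 : r.end].all()
    total = sum(m.sum() for m in masks.values())
    assert total == sum(r.length for r in regions)
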