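import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from ptmvar.variants import (
    AA_CODONS,
    BASES,
    CODON_SITE_COUNTS,
    CODON_TO_AA,
    GeneModel,
    annotate_variant,
    annotate_variants,
    classify_rare,
    codon_degeneracy,
    conservation_score,
    filter_codon_conflicts,
    gc_window,
    nearest_recomb,
)


class TestAnnotateVariant:
    def test_met_to_ile(self):
        model = GeneModel("P1", "ATG")
        rec, reason = annotate_variant(3, "G", "A", model)
        assert reason is None
        assert (rec["ref_aa"], rec["alt_aa"], rec["is_nonsyn"]) == ("M", "I", True)

    def test_synonymous_gly(self):
        model = GeneModel("P1", "GGG")
        rec, reason = annotate_variant(3, "G", "A", model)
        assert reason is None
        assert (rec["ref_aa"], rec["alt_aa"], rec["is_nonsyn"]) == ("G", "G", False)

    def test_stop_gain_rejected(self):
        model = GeneModel("P1", "TAC")
        rec, reason = annotate_variant(3, "C", "G", model)
        assert rec is None and reason == "stop-gain"

    def test_ref_mismatch(self):
        model = GeneModel("P1", "ATG")
        rec, reason = annotate_variant(1, "C", "T", model)
        assert rec is None and reason == "ref-mismatch"

    def test_outside_cds(self):
        model = GeneModel("P1", "ATG")
        assert annotate_variant(4, "A", "T", model)[1] == "outside-cds"

    def test_indel_like_rejected(self):
        model = GeneModel("P1", "ATG")
        assert annotate_variant(1, "AT", "A", model)[1] == "not-snv"

    def test_all_codon_edits_match_biopython_oracle(self):
        for codon, aa in CODON_TO_AA.items():
            if aa == "*":
                continue
            model = GeneModel("P1", codon)
            for i in range(3):
                for b in BASES:
                    if b == codon[i]:
                        continue
                    mut = codon[:i] + b + codon[i + 1 :]
                    oracle = str(Seq(mut).translate())
                    rec, reason = annotate_variant(i + 1, codon[i], b, model)
                    if oracle == "*":
                        assert reason == "stop-gain"
                    else:
                        assert rec["alt_aa"] == oracle
                        assert rec["is_nonsyn"] == (oracle != aa)


class TestCodonTables:
    def test_degeneracy_examples(self):
        assert codon_degeneracy("L") == 6
        assert codon_degeneracy("M") == 1
        assert codon_degeneracy("W") == 1

    def test_degeneracy_unknown(self):
        with pytest.raises(ValueError):
            codon_degeneracy("B")

    def test_degeneracy_matches_codon_lists(self):
        for aa, codons in AA_CODONS.items():
            assert codon_degeneracy(aa) == len(codons)
        assert sum(len(v) for v in AA_CODONS.values()) == 61

    def test_site_count_conservation(self):
        # per codon: syn + nonsyn + stop-excluded fraction = 3
        for codon, (syn, nonsyn) in CODON_SITE_COUNTS.items():
            n_stop = sum(
                CODON_TO_AA[codon[:i] + b + codon[i + 1 :]] == "*"
                for i in range(3)
                for b in BASES
                if b != codon[i]
            )
            assert syn + nonsyn + n_stop / 3 == pytest.approx(3.0, abs=1e-12)

    def test_ggg_site_counts(self):
        # GGG: 3 of 9 changes synonymous -> 1 syn site
        syn, nonsyn = CODON_SITE_COUNTS["GGG"]
        assert syn == pytest.approx(1.0)
        assert nonsyn == pytest.approx(2.0)


class TestRareClassification:
    def test_boundaries(self):
        subs = pd.DataFrame({"daf": [0.004, 0.005, 0.006]})
        out = classify_rare(subs)
        assert out["is_rare"].tolist() == [True, True, False]

    def test_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            classify_rare(pd.DataFrame({"daf": [0.1]}), threshold=0.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        subs = pd.DataFrame({"daf": rng.uniform(1e-5, 0.5, size=200)})
        prev = np.zeros(len(subs), dtype=bool)
        for t in (0.001, 0.005, 0.01, 0.02, 0.5):
            cur = classify_rare(subs, t)["is_rare"].to_numpy()
            assert (prev <= cur).all()
            prev = cur


class TestCodonConflicts:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["protein", "residue_index", "is_nonsyn"])

    def test_two_nonsyn_same_codon_both_dropped(self):
        subs = self._frame([("P1", 5, True), ("P1", 5, True), ("P1", 6, True)])
        out = filter_codon_conflicts(subs)
        assert out["residue_index"].tolist() == [6]

    def test_syn_partner_kept(self):
        subs = self._frame([("P1", 5, True), ("P1", 5, True), ("P1", 5, False)])
        out = filter_codon_conflicts(subs)
        assert len(out) == 1 and not out["is_nonsyn"].iloc[0]

    def test_singleton_kept_and_idempotent(self):
        subs = self._frame([("P1", 5, True), ("P2", 5, True)])
        out = filter_codon_conflicts(subs)
        assert len(out) == 2
        again = filter_codon_conflicts(out)
        assert again.equals(out)

    def test_never_increases(self):
        rng = np.random.default_rng(3)
        subs = self._frame(
            [("P1", int(rng.integers(1, 6)), bool(rng.integers(2))) for _ in range(50)]
        )
        assert len(filter_codon_conflicts(subs)) <= len(subs)


class TestFeatures:
    def test_gc_window_all_g(self):
        assert gc_window("G" * 50, 25) == 100.0

    def test_gc_window_all_at(self):
        assert gc_window("ATATAT" * 10, 30) == 0.0

    def test_gc_window_fourteen_of_thirtyfive(self):
        cds = "G" * 14 + "A" * 21
        # full 35-mer window: offset 17 covers the whole string
        assert gc_window(cds, 17) == pytest.approx(40.0)

    def test_gc_window_clipped_at_bounds(self):
        assert gc_window("GGAA", 0) == pytest.approx(50.0)

    def test_nearest_recomb_exact_hit(self):
        assert nearest_recomb([100], [50, 100, 200], [1.0, 2.0, 3.0])[0] == 2.0

    def test_nearest_recomb_closer_locus(self):
        # position 103: d=3 to 100, d=5 to 108
        assert nearest_recomb([103], [100, 108], [1.0, 9.0])[0] == 1.0

    def test_nearest_recomb_tie_lower_coordinate(self):
        assert nearest_recomb([104], [100, 108], [1.0, 9.0])[0] == 1.0

    def test_nearest_recomb_empty_track(self):
        with pytest.raises(ValueError):
            nearest_recomb([1], [], [])

    def test_conservation_identity_column(self):
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        assert conservation_score("W", ["W", "W"]) == pytest.approx(float(m["W", "W"]))

    def test_conservation_gap_score(self):
        assert conservation_score("A", ["-"]) == -10.0


def test_annotate_variants_drops_daf_zero():
    model = GeneModel("P1", "ATGGGG")
    variants = pd.DataFrame(
        {
            "chrom": ["P1", "P1", "P1"],
            "pos": [3, 6, 6],
            "ref": ["G", "G", "G"],
            "alt": ["A", "A", "A"],
            "daf": [0.0, 0.01, 0.001],
        }
    )
    subs, rejects = annotate_variants(variants, {"P1": model})
    assert len(subs) == 2
    assert rejects["reason"].tolist() == ["daf-zero"]


def test_gene_model_validation():
    with pytest.raises(ValueError, match="not divisible"):
        GeneModel("P1", "ATGG")
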