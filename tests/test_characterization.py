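"""Unit tests for constitutive/alternative classification, proportion
tests, sequence features and the PWM splice-site scorer."""

import math
import types

import numpy as np
import pandas as pd
import pytest

from oncoscreen import (
    SplicingEvent, affected_proportion_test, classify_constitutive,
    compare_regulation_groups, extract_splice_site_windows, score_splice_site,
    sequence_features, train_splice_site_model,
)
from oncoscreen.characterization import (ACCEPTOR_WINDOW, DONOR_WINDOW,
                                         SpliceSiteModel, reverse_complement)


def seg_event(chrom, start, end, etype="SE", strand="+"):
    return SplicingEvent(event_id="e", event_type=etype, chrom=chrom,
                         strand=strand, start=start, end=end)


class TestClassification:
    def test_exon_at_psi_one_constitutive(self):
        assert classify_constitutive([1.0, 1.0, 1.0], "SE") == "constitutive"

    def test_intron_at_psi_zero_constitutive(self):
        assert classify_constitutive([0.0, 0.0], "RI") == "constitutive"

    def test_exon_below_threshold_alternative(self):
        assert classify_constitutive([0.93], "SE") == "alternative"

    def test_unquantifiable_unclassified(self):
        assert classify_constitutive([np.nan], "SE") == "unclassified"

    def test_per_replicate_mode(self):
        # mean is 0.9975 (inside epsilon=0.004) but one replicate is not
        psis = [1.0, 1.0, 1.0, 0.99]
        assert classify_constitutive(psis, "SE", epsilon=0.004) == "constitutive"
        assert classify_constitutive(psis, "SE", epsilon=0.004,
                                     mode="all") == "alternative"

    @pytest.mark.parametrize("etype", ["SE", "RI"])
    def test_monotone_in_epsilon(self, etype, rng):
        psis = rng.uniform(0, 1, size=5)
        labels = [classify_constitutive(psis, etype, epsilon=e)
                  for e in (0.0, 0.01, 0.05, 0.2, 0.5)]
        seen_constitutive = False
        for lab in labels:
            if lab == "constitutive":
                seen_constitutive = True
            elif seen_constitutive:
                pytest.fail("larger epsilon flipped constitutive back")


class TestProportionTest:
    def test_identical_proportions_p_one(self):
        classes = ["constitutive"] * 100 + ["alternative"] * 100
        affected = ([True] * 10 + [False] * 90) * 2
        res = affected_proportion_test(classes, affected)
        assert res["p"] == pytest.approx(1.0)

    def test_extreme_separation(self):
        classes = ["constitutive"] * 50 + ["alternative"] * 50
        affected = [False] * 50 + [True] * 50
        res = affected_proportion_test(classes, affected)
        assert res["p"] < 1e-10

    def test_matches_hand_two_by_two_chi_square(self):
        # 56/1000 vs 201/1000 with Yates continuity correction
        classes = ["constitutive"] * 1000 + ["alternative"] * 1000
        affected = [True] * 56 + [False] * 944 + [True] * 201 + [False] * 799
        res = affected_proportion_test(classes, affected)
        obs = np.array([[56, 944], [201, 799]], dtype=float)
        row, col, tot = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True), obs.sum()
        exp = row * col / tot
        chi2 = ((np.abs(obs - exp) - 0.5) ** 2 / exp).sum()
        assert res["chi2"] == pytest.approx(chi2)
        assert res["proportion_constitutive"] == pytest.approx(0.056)
        assert res["proportion_alternative"] == pytest.approx(0.201)

    def test_empty_class_named_in_error(self):
        with pytest.raises(ValueError, match="alternative"):
            affected_proportion_test(["constitutive"] * 3, [True, False, False])


class TestSequenceFeatures:
    def test_gc_extremes(self):
        genome = {"c": "GCGCATAT"}
        length, gc = sequence_features(seg_event("c", 0, 4), genome)
        assert (length, gc) == (4, 100.0)
        length, gc = sequence_features(seg_event("c", 4, 8), genome)
        assert (length, gc) == (4, 0.0)

    def test_ambiguous_bases_excluded_with_warning(self):
        genome = {"c": "GCATN"}
        with pytest.warns(UserWarning, match="ambiguous"):
            length, gc = sequence_features(seg_event("c", 0, 5), genome)
        assert length == 5
        assert gc == pytest.approx(50.0)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            sequence_features(seg_event("c", 0, 10), {"c": "ACGT"})

    def test_gc_plus_at_is_hundred(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        genome = {"c": seq}
        _, gc = sequence_features(seg_event("c", 0, 200), genome)
        at = 100.0 * (seq.count("A") + seq.count("T")) / 200
        assert gc + at == pytest.approx(100.0)


class TestWindowExtraction:
    def test_plus_strand_exon_windows(self):
        left = "T" * 20
        exon = "AAA" + "G" * 10 + "CCC"
        right = "GTAAGT" + "A" * 14
        genome = {"c": "X" * 0 + left + exon + right}
        ev = seg_event("c", 20, 36)
        donor, acceptor = extract_splice_site_windows(ev, genome)
        assert donor == "CCC" + "GTAAGT"
        assert acceptor == "T" * 20 + "AAA"

    def test_minus_strand_exon_windows_mirror_plus(self):
        # build a plus-strand locus, then reverse-complement the whole
        # chromosome: the same biological windows must come back
        left = "CTTTCTTTCTTTCTTTCTTT"
        exon = "ATG" + "GCA" * 8 + "GAG"
        right = "GTAAGA" + "TTTTTTTTTTTTTT"
        seq = left + exon + right
        ev_plus = seg_event("c", 20, 20 + len(exon))
        d_plus, a_plus = extract_splice_site_windows(ev_plus, {"c": seq})
        rc = reverse_complement(seq)
        n = len(seq)
        ev_minus = seg_event("c", n - (20 + len(exon)), n - 20, strand="-")
        d_minus, a_minus = extract_splice_site_windows(ev_minus, {"c": rc})
        assert d_minus == d_plus
        assert a_minus == a_plus

    def test_minus_strand_intron_windows_mirror_plus(self):
        left = "CCCGGGCCCGGGCCCGGGCA"
        intron = "GTAAGT" + "T" * 30 + "TTTTTTTTTTTTTTTTTCAG"
        right = "GTTAAACCCGGGTTTAAACC"
        seq = left + intron + right
        ev_plus = seg_event("c", 20, 20 + len(intron), etype="RI")
        d_plus, a_plus = extract_splice_site_windows(ev_plus, {"c": seq})
        assert d_plus.endswith("GTAAGT")
        assert a_plus[:20].endswith("CAG")
        rc = reverse_complement(seq)
        n = len(seq)
        ev_minus = seg_event("c", n - (20 + len(intron)), n - 20,
                             etype="RI", strand="-")
        d_minus, a_minus = extract_splice_site_windows(ev_minus, {"c": rc})
        assert d_minus == d_plus
        assert a_minus == a_plus


class TestSpliceSiteModel:
    def test_repeated_kmer_is_argmax(self):
        model = train_splice_site_model(["CAGGTAAGT"] * 100, "donor")
        best = "".join("ACGT"[i] for i in np.argmax(model.foreground, axis=1))
        assert best == "CAGGTAAGT"

    def test_consensus_score_closed_form(self):
        fg = np.full((9, 4), 0.01)
        fg[:, 2] = 0.97  # G at every position
        model = SpliceSiteModel("donor", fg, np.full(4, 0.25))
        score = score_splice_site(model, "G" * 9)
        assert score == pytest.approx(9 * math.log2(0.97 / 0.25))

    def test_additive_over_positions(self, rng):
        fg = rng.dirichlet(np.ones(4), size=9)
        model = SpliceSiteModel("donor", fg, np.full(4, 0.25))
        w = "ACGTACGTA"
        lod = np.log2(model.foreground / model.background)
        expected = sum(lod[i, "ACGT".index(b)] for i, b in enumerate(w))
        assert score_splice_site(model, w) == pytest.approx(expected)

    def test_uniform_foreground_scores_near_zero(self, rng):
        sites = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(2000)]
        model = train_splice_site_model(sites, "donor")
        scores = [score_splice_site(model, "".join(rng.choice(list("ACGT"), 9)))
                  for _ in range(200)]
        assert abs(np.mean(scores)) < 0.5

    def test_foreground_draws_score_positive_background_negative(self, rng):
        cons = "CAGGTAAGT"
        strong = []
        for _ in range(500):
            w = [c if rng.random() < 0.8 else rng.choice(list("ACGT"))
                 for c in cons]
            strong.append("".join(w))
        model = train_splice_site_model(strong, "donor")
        fg_scores = [score_splice_site(model, s) for s in strong[:100]]
        bg_scores = [score_splice_site(model, "".join(rng.choice(list("ACGT"), 9)))
                     for _ in range(100)]
        assert np.mean(fg_scores) > 0
        assert np.mean(bg_scores) <= 0

    def test_zero_pseudocount_unobserved_base_guarded(self):
        with pytest.raises(ValueError):
            train_splice_site_model(["AAAAAAAAA"] * 5, "donor", pseudocount=0.0)

    def test_wrong_length_named_in_error(self):
        with pytest.raises(ValueError, match="length"):
            train_splice_site_model(["ACGT"], "donor")

    def test_ambiguous_base_skipped_with_warning(self):
        model = train_splice_site_model(["CAGGTAAGT"] * 10, "donor")
        with pytest.warns(UserWarning, match="skipped"):
            s_n = score_splice_site(model, "CAGGTAAGN")
        s_full = score_splice_site(model, "CAGGTAAGT")
        lod = math.log2(model.foreground[8, 3] / model.background[8, 3])
        assert s_n == pytest.approx(s_full - lod)

    def test_serialization_roundtrip(self):
        model = train_splice_site_model(["CAGGTAAGT"] * 10, "donor")
        clone = SpliceSiteModel.from_dict(model.to_dict())
        assert score_splice_site(clone, "CAGGTAAGT") == pytest.approx(
            score_splice_site(model, "CAGGTAAGT"))


class TestGroupComparison:
    def _features(self, rows):
        return pd.DataFrame(rows, columns=["regulation", "feature_length",
                                           "gc_percent"])

    def test_identical_groups_all_p_one(self):
        rows = [("higher-in-knockdown", 100, 40.0), ("higher-in-control", 100, 40.0),
                ("higher-in-knockdown", 200, 50.0), ("higher-in-control", 200, 50.0)]
        res = compare_regulation_groups(self._features(rows),
                                        feature_columns=("feature_length",
                                                         "gc_percent"))
        assert np.allclose(res["p"].to_numpy(), 1.0)

    def test_single_element_groups_exact_path(self):
        rows = [("higher-in-knockdown", 100, 40.0), ("higher-in-control", 200, 50.0)]
        res = compare_regulation_groups(self._features(rows),
                                        feature_columns=("feature_length",))
        # only C(2,1) = 2 assignments: exact two-sided p = 1
        assert res.loc["feature_length", "p"] == pytest.approx(1.0)

    def test_empty_group_skipped_with_warning(self):
        rows = [("higher-in-knockdown", 100, 40.0), ("unaffected", 200, 50.0)]
        with pytest.warns(UserWarning, match="empty regulation group"):
            res = compare_regulation_groups(self._features(rows),
                                            feature_columns=("feature_length",))
        assert len(res) == 0
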