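"""Kinase inference: windows, pattern matching, motif-x-style enrichment,
family percentages and activity scores."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import phosflow as pf
from phosflow.io import EFFECT_INDUCED, EFFECT_INHIBITED
from phosflow.kinase import (
    activity_scores,
    binomial_tail,
    build_pattern,
    extract_window,
    family_percentages,
    match_pattern,
    motif_enrichment,
    parse_pattern,
    peptide_key,
)


class TestWindows:
    def test_exact_fit_no_padding(self):
        seq = "ABCDEFGSIJKLMNO"
        assert extract_window(seq, "S", 8) == "ABCDEFGsIJKLMNO"

    def test_n_terminal_padding(self):
        seq = "SABCDEFGHIJ"
        assert extract_window(seq, "S", 1) == "_______sABCDEFG"

    def test_c_terminal_padding(self):
        seq = "ABCDEFGHIT"
        assert extract_window(seq, "T", 10).endswith("t" + "_" * 7)

    def test_window_equals_string_slice(self, default_dataset):
        ds = default_dataset
        prot, res, pos, _ = ds.truth.regulated_sites[0]
        seq = ds.proteome[prot]
        window = extract_window(seq, res, pos)
        lo = max(0, pos - 8)
        expected = seq[lo : pos + 7]
        expected = (
            "_" * (15 - 7 - (pos - lo)) + expected + "_" * (7 - (len(seq) - pos))
        )
        assert window.upper() == expected.upper().rjust(0)
        assert window[7] == res.lower()

    def test_residue_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="match"):
            extract_window("AAAA" + "S" + "AAAA", "T", 5)


class TestMatchPattern:
    @pytest.mark.parametrize(
        "window,pattern,expected",
        [
            ("AAAAAAAsPKAAAAA", "sP", True),
            ("AAAAAAAsAKAAAAA", "sP", False),
            ("AAAARAAsAAAAAAA", "R..s", True),  # R at -3
            ("AAAAARAsAAAAAAA", "R..s", False),
            ("AAAAAAAsPAAAKAA", "sP...K", True),  # P at +1, K at +5
            ("AAAAAAAsPAAKAAA", "sP...K", False),
            ("AAAAAAAtPKAAAAA", "sP", False),  # center anchored
            ("AAAAAAAtPKAAAAA", "xP", True),  # 'x' matches any center
            ("AAAAAAAsAEAAAAA", "s.E", True),
        ],
    )
    def test_pattern_semantics(self, window, pattern, expected):
        assert match_pattern(window, pattern) is expected

    def test_pattern_without_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor|center"):
            match_pattern("AAAAAAAsPKAAAAA", "RKK")

    def test_build_and_parse_roundtrip(self):
        for fixed, center in [(((1, "P"),), "s"), (((-3, "R"),), "s"), (((1, "P"), (5, "K")), "t")]:
            pattern = build_pattern(center, fixed)
            got_center, got_fixed = parse_pattern(pattern)
            assert got_center == center
            assert sorted(got_fixed) == sorted(fixed)


class TestBinomialOracle:
    def exact_tail(self, k, n, q):
        return sum(math.comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(k, n + 1))

    def test_matches_exact_sum_small_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(1, 21))
            k = int(rng.integers(0, n + 1))
            q = float(rng.uniform(0.01, 0.99))
            expected = self.exact_tail(k, n, q) if k > 0 else 1.0
            assert binomial_tail(k, n, q) == pytest.approx(expected, rel=1e-12)

    def test_spec_example_ten_windows(self):
        # 10 foreground windows, 5 carrying P at +1, background frequency 0.05
        expected = self.exact_tail(5, 10, 0.05)
        assert binomial_tail(5, 10, 0.05) == pytest.approx(expected, rel=1e-12)
        fg = ["AAAAAAAsPAAAAAA"] * 5 + ["AAAAAAAsAAAAAAA"] * 5
        bg = ["AAAAAAAsPAAAAAA"] * 5 + ["AAAAAAAsAAAAAAA"] * 95
        found = motif_enrichment(fg, bg, p_threshold=expected * 1.001, min_occurrences=5, center="s")
        assert found and found[0].pattern == "sP"
        assert found[0].steps[0]["p"] == pytest.approx(expected, rel=1e-12)
        none_found = motif_enrichment(
            fg, bg, p_threshold=expected * 0.999, min_occurrences=5, center="s"
        )
        assert none_found == []


class TestMotifEnrichment:
    def test_foreground_equal_background_yields_nothing(self):
        rng = np.random.default_rng(2)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        windows = [
            "".join(rng.choice(alphabet, 7)) + "s" + "".join(rng.choice(alphabet, 7))
            for _ in range(200)
        ]
        assert motif_enrichment(windows, windows, min_occurrences=5, center="s") == []

    def test_empty_foreground_is_empty_result(self):
        bg = ["AAAAAAAsAAAAAAA"] * 10
        assert motif_enrichment([], bg, center="s") == []

    def test_planted_motif_is_top_hit_with_enrichment(self, default_dataset, default_results):
        motifs = default_results["motifs"]
        assert motifs, "no motifs recovered"
        top = motifs[0]
        assert (1, "P") in top.fixed  # planted proline at +1
        assert top.fold_enrichment > 2.0

    def test_emitted_foreground_matches_emitted_pattern(self, default_results):
        for motif in default_results["motifs"]:
            assert motif.fg_matches >= 1
            # every step's restriction is consistent with the final pattern
            for step in motif.steps:
                assert (step["offset"], step["residue"]) in set(motif.fixed) | (
                    {(0, motif.center)} if motif.center else set()
                )


class TestFamilyPercentages:
    def test_hand_percentages_and_unmatched(self):
        links = pd.DataFrame(
            {
                "peptide_key": [f"k{i}" for i in range(10)] + ["k0", "k1"],
                "family": ["MAPK"] * 10 + ["CK", "CK"],
            }
        )
        detected = [f"k{i}" for i in range(10)] + ["u1", "u2"]
        upregulated = ["k0", "k1", "k2", "k3", "k4", "u1"]
        table = family_percentages(upregulated, detected, links).set_index("family")
        assert table.loc["MAPK", "percentage"] == pytest.approx(50.0)
        assert table.loc["CK", "percentage"] == pytest.approx(100.0)
        assert table.loc["(unmatched)", "n_upregulated"] == 1
        assert table.loc["(unmatched)", "percentage"] == pytest.approx(100.0 / 6.0)

    def test_no_upregulated_links_is_zero(self):
        links = pd.DataFrame({"peptide_key": ["a", "b"], "family": ["MAPK", "MAPK"]})
        table = family_percentages(["c"], ["a", "b", "c"], links).set_index("family")
        assert table.loc["MAPK", "percentage"] == 0.0

    def test_empty_link_table_gives_only_unmatched(self):
        table = family_percentages(["a"], ["a"], pd.DataFrame(columns=["peptide_key", "family"]))
        assert table["family"].tolist() == ["(unmatched)"]
        assert table["percentage"].iloc[0] == 100.0


def site_quant_frame(rows):
    defaults = {
        "sample_label": "case", "significant": True, "regulated": True,
        "combined_z": 2.0, "residue": "S",
    }
    out = []
    for row in rows:
        rec = dict(defaults)
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


def annotation_frame(rows):
    return pd.DataFrame(rows, columns=["kinase_accession", "site", "effect"])


class TestActivityScores:
    def test_single_induced_site_hand_score(self):
        sq = site_quant_frame(
            [{"protein": "K1", "position": 10, "combined_log2fc": 1.0, "total_psms": 3}]
        )
        ann = annotation_frame([("K1", "S10", EFFECT_INDUCED)])
        scores, coverage = activity_scores(sq, ann, sample_label="case")
        assert scores["score"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert scores["call"].iloc[0] == "increased"  # 1.0 >= 0.53
        assert coverage["n_kinases_scored"] == 1

    def test_mixed_effects_hand_score(self):
        # (L=1, n=2, induced) + (L=0.5, n=2, inhibited) -> (2 - 1)/4 = 0.25
        sq = site_quant_frame(
            [
                {"protein": "K1", "position": 10, "combined_log2fc": 1.0, "total_psms": 2},
                {"protein": "K1", "position": 30, "combined_log2fc": 0.5, "total_psms": 2},
            ]
        )
        ann = annotation_frame(
            [("K1", "S10", EFFECT_INDUCED), ("K1", "S30", EFFECT_INHIBITED)]
        )
        scores, _ = activity_scores(sq, ann, sample_label="case")
        assert scores["score"].iloc[0] == pytest.approx(0.25, abs=1e-12)
        assert scores["call"].iloc[0] == "unchanged"

    def test_nonsignificant_sites_do_not_enter(self):
        sq = site_quant_frame(
            [
                {"protein": "K1", "position": 10, "combined_log2fc": 5.0,
                 "total_psms": 9, "significant": False},
            ]
        )
        ann = annotation_frame([("K1", "S10", EFFECT_INDUCED)])
        scores, coverage = activity_scores(sq, ann, sample_label="case")
        assert scores.empty
        assert coverage["n_kinases_with_detected_site"] == 1

    def test_effect_flip_negates_score_exactly(self):
        sq = site_quant_frame(
            [
                {"protein": "K1", "position": 10, "combined_log2fc": 0.8, "total_psms": 4},
                {"protein": "K1", "position": 30, "combined_log2fc": -0.3, "total_psms": 7},
            ]
        )
        ann = annotation_frame(
            [("K1", "S10", EFFECT_INDUCED), ("K1", "S30", EFFECT_INHIBITED)]
        )
        flipped = ann.copy()
        flipped["effect"] = [EFFECT_INHIBITED, EFFECT_INDUCED]
        s1, _ = activity_scores(sq, ann, sample_label="case")
        s2, _ = activity_scores(sq, flipped, sample_label="case")
        assert s2["score"].iloc[0] == -s1["score"].iloc[0]

    @given(st.integers(2, 100))
    def test_invariant_to_uniform_psm_rescaling(self, k):
        sq = site_quant_frame(
            [
                {"protein": "K1", "position": 10, "combined_log2fc": 0.8, "total_psms": 4},
                {"protein": "K1", "position": 30, "combined_log2fc": -0.3, "total_psms": 7},
            ]
        )
        ann = annotation_frame(
            [("K1", "S10", EFFECT_INDUCED), ("K1", "S30", EFFECT_INHIBITED)]
        )
        base, _ = activity_scores(sq, ann, sample_label="case")
        sq2 = sq.assign(total_psms=sq["total_psms"] * k)
        scaled, _ = activity_scores(sq2, ann, sample_label="case")
        assert scaled["score"].iloc[0] == pytest.approx(base["score"].iloc[0], rel=1e-12)

    def test_score_bounded_by_max_site_fold_change(self, default_results):
        activity = default_results["activity"]
        sites = default_results["levels"]["phosphosite"]
        max_l = sites["combined_log2fc"].abs().max()
        assert (activity["score"].abs() <= max_l + 1e-9).all()

    def test_planted_kinase_directions_recovered(self, default_dataset, default_results):
        from phosflow.evaluate import kinase_recovery

        rec = kinase_recovery(
            default_results["activity"], default_dataset.truth, default_dataset.annotations
        )
        assert rec["sensitivity"] >= 0.9
        assert rec["specificity"] >= 0.9


class TestLinkTable:
    def test_links_are_consistent_with_windows(self, default_dataset):
        ds = default_dataset
        assert set(ds.links.columns) == {"peptide_key", "family"}
        phospho = ds.psms[ds.psms["population"] != "nonphospho"]
        keys = {
            peptide_key(p, s)
            for p, s in zip(phospho["peptide"], phospho["site_positions"])
        }
        assert set(ds.links["peptide_key"]) <= keys
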