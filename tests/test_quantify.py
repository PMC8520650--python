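"""Quantification chain: normalization, ratios, z-scores, aggregation, calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import phosflow as pf
from phosflow.quantify import (
    _bin_edges,
    aggregate,
    assign_zscores,
    call_significance,
    compute_ratios,
    normalize_channels,
    signed_fold_change,
)
from phosflow.synthetic import make_design


def make_psms(rows, channels=("114", "115")):
    defaults = {
        "peptide": "PEPTIDE", "protein": "P1", "site_positions": "S5", "population": "mono",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("psm_id", f"p{i}")
        rec.setdefault("experiment_id", "E1")
        out.append(rec)
    cols = list(pf.synthetic.PSM_FIXED_COLUMNS) + list(channels)
    return pd.DataFrame(out)[[c for c in cols if c in out[0]]]


def two_channel_design():
    return pd.DataFrame(
        {
            "experiment_id": ["E1", "E1"],
            "channel": ["114", "115"],
            "sample_label": ["ref", "case"],
            "is_denominator": [1, 0],
        }
    )


class TestNormalizeChannels:
    def test_equal_sums_are_identity(self):
        psms = make_psms([{"114": 100.0, "115": 100.0}])
        scaled, factors = normalize_channels(psms, two_channel_design())
        assert (factors["factor"] == 1.0).all()
        pd.testing.assert_frame_equal(scaled, psms)

    def test_hand_evaluated_factors(self):
        # sums {100, 300} -> grand mean 200 -> factors {2, 2/3}; both sums 200
        psms = make_psms(
            [{"114": 60.0, "115": 100.0}, {"114": 40.0, "115": 200.0}]
        )
        scaled, factors = normalize_channels(psms, two_channel_design())
        f = dict(zip(factors["channel"], factors["factor"]))
        assert f["114"] == pytest.approx(2.0)
        assert f["115"] == pytest.approx(2.0 / 3.0)
        assert scaled["114"].sum() == pytest.approx(200.0)
        assert scaled["115"].sum() == pytest.approx(200.0)

    def test_post_normalization_sums_equal_on_fixture(self, default_dataset):
        ds = default_dataset
        scaled, _ = normalize_channels(ds.psms, ds.design)
        for exp in ("EXP1", "EXP2"):
            sums = scaled.loc[
                scaled["experiment_id"] == exp, list(ds.config.channels)
            ].sum(axis=0)
            assert np.allclose(sums, sums.mean(), rtol=1e-9)

    def test_recovers_planted_bias_up_to_grand_mean(self):
        # zero noise, no regulation: factor_c * bias_c constant across channels
        proteome = {"P1": "A" * 20 + "S" + "A" * 20}
        design = make_design(pf.SimulationConfig())
        loadings = {
            (e, ch): b
            for e in ("EXP1", "EXP2")
            for ch, b in zip(("114", "115", "116", "117"), (1.0, 2.0, 0.5, 1.3))
        }
        truth = pf.GroundTruth(channel_loadings=loadings)
        noise = pf.NoiseParams(ratio_sd_high=0.0, ratio_sd_low=0.0)
        psms, _ = pf.generate_psm_table(
            proteome, design, truth, noise, seed=1,
            extra_sites=[("P1", "S", 21)], nonphospho_proteins=["P1"],
        )
        _, factors = normalize_channels(psms, design)
        for exp, grp in factors.groupby("experiment_id"):
            prods = [
                row.factor * loadings[(exp, row.channel)]
                for row in grp.itertuples(index=False)
            ]
            assert np.allclose(prods, prods[0], rtol=1e-6)

    def test_zero_intensity_channel_is_hard_error(self):
        psms = make_psms([{"114": 100.0, "115": 0.0}])
        with pytest.raises(ValueError, match="115"):
            normalize_channels(psms, two_channel_design())

    def test_preserves_within_channel_rank_order(self, default_dataset):
        ds = default_dataset
        scaled, _ = normalize_channels(ds.psms, ds.design)
        for exp in ("EXP1",):
            raw = ds.psms[ds.psms["experiment_id"] == exp]["116"].to_numpy()
            new = scaled[scaled["experiment_id"] == exp]["116"].to_numpy()
            assert (np.argsort(raw, kind="stable") == np.argsort(new, kind="stable")).all()


class TestComputeRatios:
    def test_hand_ratios_and_denominator_drop(self):
        psms = make_psms(
            [
                {"psm_id": "a", "114": 50.0, "115": 100.0},
                {"psm_id": "b", "114": 50.0, "115": 50.0},
                {"psm_id": "c", "114": 0.0, "115": 80.0},
            ]
        )
        ratios, log = compute_ratios(psms, two_channel_design())
        by_id = ratios.set_index("psm_id")
        assert by_id.loc["a", "log2_ratio"] == pytest.approx(1.0)
        assert by_id.loc["b", "log2_ratio"] == 0.0
        assert "c" not in by_id.index
        assert log["dropped_zero_denominator"] == 1
        assert by_id.loc["a", "total_intensity"] == pytest.approx(150.0)


class TestAssignZscores:
    def test_zero_spread_bin_yields_zero(self):
        ratios = pd.DataFrame(
            {
                "psm_id": [f"p{i}" for i in range(5)],
                "experiment_id": "E1",
                "channel": "115",
                "log2_ratio": 0.4,
                "total_intensity": np.arange(5, dtype=float),
            }
        )
        out, log = assign_zscores(ratios, bin_size=300)
        assert (out["z"] == 0.0).all()
        assert log["zero_spread_bins"] == 1

    def test_hand_standardization_nonrobust(self):
        ratios = pd.DataFrame(
            {
                "psm_id": ["a", "b", "c"],
                "experiment_id": "E1",
                "channel": "115",
                "log2_ratio": [-1.0, 0.0, 1.0],
                "total_intensity": [3.0, 2.0, 1.0],
            }
        )
        out, _ = assign_zscores(ratios, bin_size=300, robust=False)
        assert out["z"].tolist() == [-1.0, 0.0, 1.0]

    def test_robust_uses_median_and_mad(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0, 100.0])
        ratios = pd.DataFrame(
            {
                "psm_id": [f"p{i}" for i in range(5)],
                "experiment_id": "E1",
                "channel": "115",
                "log2_ratio": vals,
                "total_intensity": np.arange(5, dtype=float),
            }
        )
        out, _ = assign_zscores(ratios, bin_size=300, robust=True)
        med = np.median(vals)
        mad = 1.4826 * np.median(np.abs(vals - med))
        np.testing.assert_allclose(out["z"].to_numpy(), (vals - med) / mad)

    def test_single_global_bin_matches_population_standardization(self):
        # oracle equivalence: one experiment, records < 2*bin_size,
        # non-robust == whole-population (x - mean) / sd
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.4, 150)
        ratios = pd.DataFrame(
            {
                "psm_id": [f"p{i}" for i in range(150)],
                "experiment_id": "E1",
                "channel": "115",
                "log2_ratio": vals,
                "total_intensity": rng.lognormal(10, 1, 150),
            }
        )
        out, log = assign_zscores(ratios, bin_size=300, robust=False)
        expected = (vals - vals.mean()) / vals.std(ddof=1)
        np.testing.assert_allclose(out["z"].to_numpy(), expected, rtol=1e-12)
        assert log["fallback_single_bin_groups"] == 1

    def test_z_monotone_in_ratio_within_bin(self, null_results):
        ratios = null_results["quant"]["ratios"]
        grp = ratios[(ratios["experiment_id"] == "EXP1") & (ratios["channel"] == "115")]
        top = grp.sort_values("total_intensity", ascending=False).head(300)
        order = top.sort_values("log2_ratio")
        assert order["z"].is_monotonic_increasing

    def test_remainder_bin_absorption(self):
        assert _bin_edges(750, 300) == [(0, 300), (300, 600), (600, 750)]
        assert _bin_edges(740, 300) == [(0, 300), (300, 740)]
        assert _bin_edges(100, 300) == [(0, 100)]

    def test_calibration_flat_across_intensity_deciles(self, null_results):
        # the intensity-ranked standardization removes the planted
        # intensity-variance dependence: |z| >= 1 fraction ~ 0.317 per decile
        from phosflow.evaluate import zscore_decile_calibration

        phospho = null_results["quant"]["ratios"]
        cal = zscore_decile_calibration(phospho[phospho["population"] != "nonphospho"])
        assert (cal["fraction"] - 0.3173).abs().max() < 0.03


class TestAggregate:
    def _ratio_frame(self, rows):
        defaults = {
            "experiment_id": "E1", "channel": "115", "sample_label": "case",
            "population": "mono", "peptide": "PEP", "protein": "P1",
            "site_positions": "S5", "log2_ratio": 0.0, "total_intensity": 1.0, "z": 0.0,
        }
        out = []
        for i, row in enumerate(rows):
            rec = dict(defaults)
            rec.update(row)
            rec.setdefault("psm_id", f"p{i}")
            out.append(rec)
        return pd.DataFrame(out)

    def test_single_psm_identity(self):
        quant = aggregate(self._ratio_frame([{"z": 2.0, "log2_ratio": 1.0}]), "phosphosite")
        assert quant["combined_z"].iloc[0] == 2.0
        assert quant["total_psms"].iloc[0] == 1

    def test_weighted_average_across_experiments(self):
        # exp A: median z 1.0 over 3 PSMs; exp B: 2.0 over 1 PSM -> 1.25
        rows = [
            {"experiment_id": "A", "z": 1.0, "psm_id": f"a{i}"} for i in range(3)
        ] + [{"experiment_id": "B", "z": 2.0, "psm_id": "b0"}]
        quant = aggregate(self._ratio_frame(rows), "phosphosite")
        assert quant["combined_z"].iloc[0] == pytest.approx(1.25)
        assert quant["total_psms"].iloc[0] == 4
        assert not quant["single_experiment"].iloc[0]

    def test_single_experiment_key_is_flagged(self):
        rows = [
            {"experiment_id": "A", "protein": "P1", "psm_id": "a"},
            {"experiment_id": "B", "protein": "P1", "psm_id": "b"},
            {"experiment_id": "A", "protein": "P2", "site_positions": "S9", "psm_id": "c"},
        ]
        quant = aggregate(self._ratio_frame(rows), "phosphosite").set_index("protein")
        assert not quant.loc["P1", "single_experiment"]
        assert quant.loc["P2", "single_experiment"]

    def test_multi_phospho_psm_feeds_every_site(self):
        rows = [{"site_positions": "S5;T9", "population": "multi", "log2_ratio": 0.7}]
        quant = aggregate(self._ratio_frame(rows), "phosphosite")
        assert sorted(quant["position"]) == [5, 9]
        assert (quant["combined_log2fc"] == 0.7).all()

    def test_protein_level_uses_only_nonphospho(self):
        rows = [
            {"population": "nonphospho", "site_positions": "", "log2_ratio": 0.5},
            {"population": "mono", "log2_ratio": 3.0},
        ]
        quant = aggregate(self._ratio_frame(rows), "protein")
        assert len(quant) == 1
        assert quant["combined_log2fc"].iloc[0] == 0.5

    def test_signed_fold_change_convention(self):
        assert signed_fold_change(-1.0) == -2.0
        assert signed_fold_change(1.0) == 2.0
        assert signed_fold_change(0.0) == 1.0


class TestCallSignificance:
    def _quant(self, z, fc, psms=10):
        return pd.DataFrame(
            {"combined_z": [z], "signed_fc": [fc], "total_psms": [psms]}
        )

    def test_phospho_boundary_inclusive(self):
        out = call_significance(self._quant(1.0, 1.5), "phosphosite")
        assert bool(out["significant"].iloc[0]) and bool(out["regulated"].iloc[0])

    def test_protein_psm_floor_blocks_regulation(self):
        out = call_significance(self._quant(2.5, 2.0, psms=4), "protein")
        assert not bool(out["significant"].iloc[0])
        assert not bool(out["regulated"].iloc[0])

    def test_protein_at_thresholds_passes(self):
        out = call_significance(self._quant(1.96, -1.5, psms=5), "protein")
        assert bool(out["regulated"].iloc[0])

    def test_subthreshold_z_blocks_large_fold_change(self):
        out = call_significance(self._quant(0.9, 3.0), "phosphosite")
        assert not bool(out["significant"].iloc[0])

    def test_raising_fc_threshold_never_increases_regulated(self, default_results):
        sites = default_results["levels"]["phosphosite"]
        counts = [
            int(call_significance(sites, "phosphosite", fc_threshold=fc)["regulated"].sum())
            for fc in (1.0, 1.5, 2.0, 3.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestNullCalibration:
    def test_no_effect_fixture_significant_fraction(self, null_results):
        from phosflow.evaluate import significant_fraction

        frac, n = significant_fraction(null_results["levels"]["phosphosite"])
        assert n > 10000
        assert abs(frac - 0.3173) < 0.03

    def test_regulated_far_rarer_than_significant(self, null_results):
        sites = null_results["levels"]["phosphosite"]
        reg = sites["regulated"].mean()
        sig = sites["significant"].mean()
        assert reg < sig / 3


class TestParameterRecovery:
    def test_planted_fold_changes_recovered(self, default_dataset, default_results):
        from phosflow.evaluate import site_recovery

        rec = site_recovery(
            default_results["levels"]["phosphosite"], default_dataset.truth, "IFN"
        )
        assert rec["n_planted_recovered"] == len(default_dataset.truth.regulated_sites)
        assert abs(rec["bias"]) < 0.05
        assert rec["sensitivity"] >= 0.9
        assert rec["specificity"] >= 0.95


@given(st.floats(min_value=-6, max_value=6, allow_nan=False))
def test_signed_fc_inverts_cleanly(l2fc):
    fc = signed_fold_change(l2fc)
    assert abs(fc) >= 1.0
    back = np.log2(fc) if fc > 0 else -np.log2(-fc)
    assert back == pytest.approx(l2fc, abs=1e-12)
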