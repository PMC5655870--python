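"""Feature-extraction arithmetic, replicate QC, and pipeline properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibroenergetics import features as feat
from fibroenergetics import synthesize as syn
from fibroenergetics.core import FEATURES, Cohort
from conftest import NOISE_FREE, single_line_cohort


class TestReplicateQc:
    def test_single_outlier_discarded(self):
        # mean 12.5, sample SD sqrt(50) ~ 7.07; |30 - 12.5| = 17.5 > 14.14
        values = np.array([10, 10, 10, 10, 10, 10, 10, 30], dtype=float)
        keep = feat.replicate_qc(values)
        assert keep.tolist() == [True] * 7 + [False]

    def test_all_equal_all_kept(self):
        assert feat.replicate_qc(np.full(6, 4.2)).all()

    def test_two_point_case_keeps_both(self):
        # each point deviates 0.5 = SD/sqrt(2) < 2 SD
        assert feat.replicate_qc(np.array([0.0, 1.0])).all()

    def test_below_two_values_raises(self):
        with pytest.raises(ValueError):
            feat.replicate_qc(np.array([1.0]))

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=40))
    def test_discard_bound_and_mask_shape(self, values):
        """At most floor((n-1)/4) replicates can sit beyond 2 sample SDs,
        so the mask is never all-False."""
        values = np.asarray(values)
        keep = feat.replicate_qc(values)
        assert keep.shape == values.shape
        assert keep.any()
        assert (~keep).sum() <= (len(values) - 1) // 4

    def test_normal_draws_never_lose_half(self):
        """Empirical check at the protocol's n=8 over 10^4 draws."""
        rng = np.random.default_rng(123)
        worst = 0
        for _ in range(10_000):
            keep = feat.replicate_qc(rng.normal(size=8))
            worst = max(worst, int((~keep).sum()))
        assert worst <= 4  # floor(8/2)


class TestNonmitoCorrection:
    def test_subtracts_aarot_floor(self):
        corrected = feat.nonmito_correct(
            {"baseline": 100.0, "oligomycin": 40.0, "FCCP": 150.0, "AA_Rot": 20.0})
        assert corrected["baseline"] == 80.0
        assert corrected["AA_Rot"] == 0.0

    def test_degenerate_no_mitochondrial_respiration(self):
        corrected = feat.nonmito_correct({"baseline": 20.0, "AA_Rot": 20.0})
        assert corrected["baseline"] == 0.0

    def test_missing_aarot_raises(self):
        with pytest.raises(ValueError, match="AA_Rot"):
            feat.nonmito_correct({"baseline": 100.0})


class TestFluxFeatures:
    CORR = {"baseline": 80.0, "oligomycin": 10.0, "FCCP": 130.0, "AA_Rot": 0.0}
    ECAR = {"baseline": 60.0, "AA_Rot": 75.0}

    def test_worked_example(self):
        out = feat.flux_features(self.CORR, self.ECAR, protein=1.0)
        assert out["ocr_base"] == 80
        assert out["ocr_oligo_sens"] == 70
        assert out["ocr_max"] == 130
        assert out["ocr_spare"] == 50
        assert out["ecar_base"] == 60
        assert out["ecar_aarot"] == 75
        assert out["ocr_ecar_ratio"] == pytest.approx(80 / 60)

    def test_protein_normalization_homogeneity(self):
        one = feat.flux_features(self.CORR, self.ECAR, protein=1.0)
        two = feat.flux_features(self.CORR, self.ECAR, protein=2.0)
        for key in ("ocr_base", "ocr_oligo_sens", "ocr_max", "ocr_spare",
                    "ecar_base", "ecar_aarot"):
            assert two[key] == pytest.approx(one[key] / 2)
        assert two["ocr_ecar_ratio"] == pytest.approx(one["ocr_ecar_ratio"])

    def test_oligomycin_equal_to_baseline_gives_zero_sensitive_rate(self):
        corr = dict(self.CORR, oligomycin=80.0)
        assert feat.flux_features(corr, self.ECAR, 1.0)["ocr_oligo_sens"] == 0.0

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError, match="protein"):
            feat.flux_features(self.CORR, self.ECAR, protein=0.0)

    def test_zero_ecar_flags_ratio_missing(self):
        out = feat.flux_features(self.CORR, {"baseline": 0.0, "AA_Rot": 5.0}, 1.0)
        assert np.isnan(out["ocr_ecar_ratio"])


def _fluor_frame(tmrm_signal, tmrm_bg, mtg_signal=(500.0,) * 4, mtg_bg=(50.0,) * 4):
    rows = []
    for dye, signal, bg in (("TMRM", tmrm_signal, tmrm_bg),
                            ("MTG", mtg_signal, mtg_bg)):
        rows += [{"line_id": "L", "well_id": f"{dye}S{i}", "dye": dye,
                  "fccp_treated": False, "rfu": v, "protein": 1.0}
                 for i, v in enumerate(signal)]
        rows += [{"line_id": "L", "well_id": f"{dye}B{i}", "dye": dye,
                  "fccp_treated": True, "rfu": v, "protein": 1.0}
                 for i, v in enumerate(bg)]
    return pd.DataFrame(rows)


class TestFluorescenceFeatures:
    def test_background_subtraction(self):
        out, clamped = feat.tmrm_mtg_features(
            _fluor_frame((800.0,) * 4, (100.0,) * 4), protein=1.0)
        assert out["tmrm"] == 700.0
        assert out["mtg"] == 450.0
        assert clamped == 0

    def test_fully_depolarized_gives_zero(self):
        out, _ = feat.tmrm_mtg_features(
            _fluor_frame((100.0,) * 4, (100.0,) * 4), protein=1.0)
        assert out["tmrm"] == 0.0

    def test_noise_driven_negative_clamped_and_counted(self):
        out, clamped = feat.tmrm_mtg_features(
            _fluor_frame((90.0, 95.0, 92.0, 91.0), (100.0,) * 4), protein=1.0)
        assert out["tmrm"] == 0.0
        assert clamped == 1

    def test_outlier_excluded_before_averaging(self):
        # one 5-SD-scale outlier among the untreated wells is dropped by QC
        signal = (800.0, 800.0, 800.0, 800.0, 800.0, 800.0, 800.0, 4000.0)
        out, _ = feat.tmrm_mtg_features(_fluor_frame(signal, (100.0,) * 8),
                                        protein=1.0)
        assert out["tmrm"] == 700.0

    def test_missing_background_raises(self):
        df = _fluor_frame((800.0,) * 4, (100.0,) * 4)
        df = df[~((df["dye"] == "TMRM") & df["fccp_treated"])]
        with pytest.raises(ValueError, match="TMRM"):
            feat.tmrm_mtg_features(df, protein=1.0)


def _atp_frame(per_condition: dict[str, float]) -> pd.DataFrame:
    rows = []
    for cond, lum in per_condition.items():
        rows += [{"line_id": "L", "well_id": f"{cond}{i}", "condition": cond,
                  "luminescence": lum, "protein": 1.0} for i in range(3)]
    return pd.DataFrame(rows)


class TestAtpFeatures:
    STANDARD = pd.DataFrame({"atp_amount": [0.0, 100.0],
                             "luminescence": [0.0, 1000.0]})

    def test_interpolation_midpoint(self):
        out = feat.atp_features(_atp_frame({"baseline": 500.0, "dg2": 500.0,
                                            "oligo": 500.0}),
                                self.STANDARD, protein=1.0)
        assert out["atp_base"] == 50.0
        assert out["atp_2dg_delta"] == 0.0

    def test_delta_sign_convention(self):
        # baseline 300, 2DG 100, oligo 320 (per mg) -> deltas (200, -20):
        # a post-oligomycin ATP rise yields a negative oligo delta
        out = feat.atp_features(_atp_frame({"baseline": 3000.0, "dg2": 1000.0,
                                            "oligo": 3200.0}),
                                self.STANDARD, protein=1.0)
        assert out["atp_base"] == pytest.approx(300.0)
        assert out["atp_2dg_delta"] == pytest.approx(200.0)
        assert out["atp_oligo_delta"] == pytest.approx(-20.0)

    def test_nonmonotone_standard_rejected(self):
        bad = pd.DataFrame({"atp_amount": [0.0, 50.0, 100.0],
                            "luminescence": [0.0, 900.0, 800.0]})
        with pytest.raises(ValueError, match="increasing"):
            feat.atp_features(_atp_frame({"baseline": 500.0, "dg2": 400.0,
                                          "oligo": 450.0}), bad, protein=1.0)

    def test_end_segment_extrapolation(self):
        x = feat.interp_extrap(np.array([-50.0, 1500.0]),
                               np.array([0.0, 1000.0]), np.array([0.0, 100.0]))
        np.testing.assert_allclose(x, [-5.0, 150.0])


class TestBuildProfiles:
    def test_line_missing_aarot_is_flagged_not_fatal(self, default_cfg):
        rng = np.random.default_rng(30)
        profiles = syn.sample_line_profiles(default_cfg.groups["control"], rng, n=2)
        c0 = single_line_cohort(profiles.iloc[0], rng=np.random.default_rng(1),
                                line_id="OK")
        c1 = single_line_cohort(profiles.iloc[1], rng=np.random.default_rng(2),
                                line_id="BAD")
        flux = pd.concat([c0.flux, c1.flux[c1.flux["phase"] != "AA_Rot"]])
        cohort = Cohort(
            lines=pd.concat([c0.lines, c1.lines], ignore_index=True),
            flux=flux.reset_index(drop=True),
            fluorescence=pd.concat([c0.fluorescence, c1.fluorescence],
                                   ignore_index=True),
            atp=pd.concat([c0.atp, c1.atp], ignore_index=True),
            atp_standard=c0.atp_standard).validate()
        out, qc = feat.build_profiles(cohort)
        assert np.isnan(out.set_index("line_id").loc["BAD", "ocr_base"])
        assert not np.isnan(out.set_index("line_id").loc["OK", "ocr_base"])
        assert (qc["line_id"] == "BAD").any()

    def test_well_order_invariance(self, default_cfg):
        rng = np.random.default_rng(31)
        profile = syn.sample_line_profiles(default_cfg.groups["sALS"], rng,
                                           n=1).iloc[0]
        noise = syn.NoiseSpec(technical_cv=0.1, outlier_rate=0.0, protein_cv=0.0)
        cohort = single_line_cohort(profile, noise=noise,
                                    rng=np.random.default_rng(3))
        shuffled = Cohort(
            lines=cohort.lines,
            flux=cohort.flux.sample(frac=1.0, random_state=8).reset_index(drop=True),
            fluorescence=cohort.fluorescence.sample(frac=1.0, random_state=8
                                                    ).reset_index(drop=True),
            atp=cohort.atp.sample(frac=1.0, random_state=8).reset_index(drop=True),
            atp_standard=cohort.atp_standard).validate()
        a, _ = feat.build_profiles(cohort)
        b, _ = feat.build_profiles(shuffled)
        for f in FEATURES:
            assert a.iloc[0][f] == pytest.approx(b.iloc[0][f], rel=1e-12)

    def test_raw_signal_homogeneity(self, default_cfg):
        """Scaling all raw signals of a line by c scales the features by c
        (the OCR/ECAR ratio excepted)."""
        rng = np.random.default_rng(32)
        profile = syn.sample_line_profiles(default_cfg.groups["control"], rng,
                                           n=1).iloc[0]
        cohort = single_line_cohort(profile, rng=np.random.default_rng(4))
        c = 3.0
        # the ATP channel is linear in (luminescence - intercept), so scale
        # the standard curve consistently with the wells
        scaled = Cohort(
            lines=cohort.lines,
            flux=cohort.flux.assign(ocr_raw=cohort.flux["ocr_raw"] * c,
                                    ecar_raw=cohort.flux["ecar_raw"] * c),
            fluorescence=cohort.fluorescence.assign(
                rfu=cohort.fluorescence["rfu"] * c),
            atp=cohort.atp.assign(luminescence=cohort.atp["luminescence"]),
            atp_standard=cohort.atp_standard.assign(
                atp_amount=cohort.atp_standard["atp_amount"] * c)).validate()
        a, _ = feat.build_profiles(cohort)
        b, _ = feat.build_profiles(scaled)
        for f in ("tmrm", "mtg", "ocr_base", "ocr_oligo_sens", "ocr_max",
                  "ocr_spare", "ecar_base", "ecar_aarot", "atp_base",
                  "atp_2dg_delta", "atp_oligo_delta"):
            assert b.iloc[0][f] == pytest.approx(c * a.iloc[0][f], rel=1e-9)
        assert b.iloc[0]["ocr_ecar_ratio"] == pytest.approx(
            a.iloc[0]["ocr_ecar_ratio"], rel=1e-9)
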