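"""The synthetic-data generator: image pairs and survival cohorts."""

import numpy as np
import pytest

from stromascore import (
    AffineTransform2D,
    CohortSimConfig,
    ImageSimConfig,
    example_clinical_table,
    simulate_cohort,
    simulate_image_pair,
)
from stromascore.stains import DEFAULT_ISH_STAINS, rgb_to_od, unmix


class TestImagePair:
    def test_identical_seed_gives_bit_identical_output(self):
        a = simulate_image_pair(ImageSimConfig(seed=3))
        b = simulate_image_pair(ImageSimConfig(seed=3))
        assert np.array_equal(a.ihc_image, b.ihc_image)
        assert np.array_equal(a.ish_image, b.ish_image)
        assert np.array_equal(a.tumor_mask_true.data, b.tumor_mask_true.data)
        assert a.tbs_true == b.tbs_true

    def test_zero_blue_fraction_gives_zero_tbs(self):
        pair = simulate_image_pair(
            ImageSimConfig(seed=1, blue_positive_fraction_stroma=0.0)
        )
        assert pair.tbs_true == 0.0
        assert not pair.blue_pos_stroma_true.data.any()

    def test_zero_tumor_fraction_gives_empty_tumor_and_zero_tbt(self):
        pair = simulate_image_pair(ImageSimConfig(seed=1, tumor_fraction=0.0))
        assert not pair.tumor_mask_true.data.any()
        assert pair.tbt_true == 0.0

    def test_tbs_matches_brute_force_pixel_sum(self, default_pair):
        """Ground-truth TBS must equal an explicit per-pixel loop over the
        drawn blue ODs restricted to the positive stromal pixel set."""
        total = 0.0
        count = 0
        od = default_pair.blue_od_true
        pos = default_pair.blue_pos_stroma_true.data
        for i in range(od.shape[0]):
            for j in range(od.shape[1]):
                if pos[i, j]:
                    total += od[i, j]
                    count += 1
        assert default_pair.tbs_true == pytest.approx(total, rel=1e-12)
        assert default_pair.score_panel_true.blue_area_stroma == count
        assert default_pair.score_panel_true.mean_blue_od_stroma == pytest.approx(
            total / count
        )

    def test_mask_set_algebra(self, default_pair):
        r = default_pair.roi_mask.data
        t = default_pair.tumor_mask_true.data
        s = default_pair.stroma_mask_true.data
        assert not np.any(t & ~r)
        assert np.array_equal(s, r & ~t)

    def test_noise_free_render_unmixes_back_to_drawn_ods(self, clean_pair):
        """Rendering then unmixing with the shared stain matrix recovers the
        drawn per-pixel ODs up to 8-bit quantization (within 2 gray levels
        when re-rendered)."""
        from stromascore.stains import od_to_rgb

        maps = unmix(rgb_to_od(clean_pair.ish_image), DEFAULT_ISH_STAINS)
        recovered_od = (
            maps["nuclear_fast_red"][..., None]
            * DEFAULT_ISH_STAINS.vector("nuclear_fast_red")
            + maps["nbt_bcip"][..., None] * DEFAULT_ISH_STAINS.vector("nbt_bcip")
        )
        rerendered = od_to_rgb(recovered_od, quantize=False)
        assert np.abs(rerendered - clean_pair.ish_image.astype(float)).max() <= 2.0
        # and the chromogen map itself is close to the drawn field
        assert np.abs(maps["nbt_bcip"] - clean_pair.blue_od_true).max() < 0.08

    def test_invalid_config_names_offending_field(self):
        with pytest.raises(ValueError, match="tumor_fraction"):
            ImageSimConfig(tumor_fraction=1.5)
        with pytest.raises(ValueError, match="blue_od_scale"):
            ImageSimConfig(blue_od_scale=0.0)
        with pytest.raises(ValueError, match="64"):
            ImageSimConfig(tile_height=32)

    def test_sidecar_written_with_truth(self, tmp_path, default_pair):
        import json

        from stromascore.synthetic import write_image_pair

        paths = write_image_pair(default_pair, tmp_path, "S1")
        sidecar = json.loads((tmp_path / "S1_truth.json").read_text())
        assert sidecar["scores_true"]["tbs"] == pytest.approx(default_pair.tbs_true)
        for p in paths.values():
            assert (tmp_path / p).exists() or p


class TestCohort:
    def test_identical_seed_gives_identical_cohort(self):
        a = simulate_cohort(CohortSimConfig(n_patients=50, seed=9))
        b = simulate_cohort(CohortSimConfig(n_patients=50, seed=9))
        assert a.equals(b)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            CohortSimConfig(n_patients=5)

    def test_event_fraction_near_target(self):
        cfg = CohortSimConfig(n_patients=600, seed=4, target_event_fraction=0.33)
        df = simulate_cohort(cfg)
        assert df["event"].mean() == pytest.approx(0.33, abs=0.05)

    def test_null_effects_give_near_zero_coefficients(self):
        from stromascore.survival import assign_tertiles, cox_univariate

        cfg = CohortSimConfig(
            n_patients=2000, seed=2, log_hr_tertile_step=0.0, preset="univariate_tertile"
        )
        df = simulate_cohort(cfg)
        tert = assign_tertiles(df["tbs"].to_numpy(), ids=df["patient_id"].to_numpy())
        df["tbs_tertile"] = tert.index
        fit = cox_univariate(df, "tbs_tertile")
        assert np.abs(fit.coef).max() < 0.1

    def test_near_zero_score_mass_matches_weight(self):
        df = simulate_cohort(CohortSimConfig(n_patients=2000, seed=6))
        # default w0 = 10/86; near-zero draws are uniform on (0, 1)
        assert (df["tbs"] < 1.0).mean() == pytest.approx(10 / 86, abs=0.03)

    def test_monotone_likelihood_two_group_fit_is_flagged(self):
        """One event per group with no censoring has a monotone partial
        likelihood (no finite MLE); the fit must be flagged, not silently
        returned as converged."""
        import pandas as pd

        from stromascore.survival import cox_univariate

        df = pd.DataFrame(
            {"time_to_recurrence": [1.0, 2.0], "event": [1, 1], "g": [1.0, 0.0]}
        )
        fit = cox_univariate(df, "g")
        assert not fit.converged


class TestExampleClinicalTable:
    def test_margins_match_study_cohort(self):
        df = example_clinical_table()
        assert len(df) == 86
        assert (df["treatment"] == 0).sum() == 68  # surgery only
        assert df["n_status"].sum() == 21
        assert df["gender"].sum() == 23
        assert df["site"].sum() == 65
        assert df["perineural"].sum() == 15
        assert df["margin"].sum() == 39
        assert df["t_status"].sum() == 6
        assert df["grade"].sum() == 11
        assert df["stage"].value_counts().to_dict() == {1: 55, 3: 28, 2: 3}
        assert (df["tbs"] < 1.0).sum() == 10

    def test_table_is_deterministic(self):
        assert example_clinical_table().equals(example_clinical_table())
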