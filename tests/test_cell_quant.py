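import numpy as np
import pandas as pd
import pytest

from plaquekit import cell_quant as cq
from plaquekit.imgio import MultichannelSection
from plaquekit.segmentation import LabelMask

from conftest import brute_force_otsu


def painted_scene():
    """Three painted nuclei with known per-region expression values."""
    labels = np.zeros((40, 40), dtype=np.int32)
    labels[2:6, 2:6] = 1
    labels[10:14, 20:24] = 2
    labels[30:34, 8:12] = 3
    img = np.zeros((40, 40))
    for lab, val in ((1, 10.0), (2, 40.0), (3, 90.0)):
        img[labels == lab] = val
    sec = MultichannelSection({"Iba1": img}, pixel_size_um=1.0)
    return LabelMask(labels, 1.0), sec


class TestMeasureExpression:
    def test_painted_values_recovered_exactly(self):
        nuclei, sec = painted_scene()
        cells = cq.measure_expression(nuclei, sec)
        assert cells["mean_Iba1"].tolist() == [10.0, 40.0, 90.0]

    def test_constant_channel(self):
        nuclei, sec = painted_scene()
        sec2 = MultichannelSection({"Iba1": np.full((40, 40), 7.0)}, pixel_size_um=1.0)
        cells = cq.measure_expression(nuclei, sec2)
        assert cells["mean_Iba1"].tolist() == [7.0, 7.0, 7.0]

    def test_empty_mask_empty_table(self):
        sec = MultichannelSection({"Iba1": np.zeros((8, 8))}, pixel_size_um=1.0)
        cells = cq.measure_expression(LabelMask(np.zeros((8, 8), np.int32), 1.0), sec)
        assert len(cells) == 0

    def test_dimension_mismatch_rejected(self):
        nuclei, _ = painted_scene()
        sec = MultichannelSection({"Iba1": np.zeros((8, 8))}, pixel_size_um=1.0)
        with pytest.raises(ValueError, match="does not match"):
            cq.measure_expression(nuclei, sec)


class TestClassifyPositive:
    def test_clear_bimodal_split(self):
        calls = cq.classify_positive([10.0, 11.0, 12.0, 200.0, 210.0])
        assert calls.tolist() == [False, False, False, True, True]

    def test_all_equal_all_negative(self):
        assert not cq.classify_positive([5.0, 5.0, 5.0]).any()

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            v = rng.lognormal(3.0, 1.0, size=100)
            uniq, counts = np.unique(v, return_counts=True)
            thr = brute_force_otsu(counts, uniq)
            np.testing.assert_array_equal(cq.classify_positive(v), v > thr)


class TestNearestPlaque:
    def plaque_disc(self, r_um=15.0, centre=(40.0, 40.0), n=120, px=1.0):
        yy, xx = np.mgrid[:n, :n] * px
        labels = (np.hypot(xx - centre[0], yy - centre[1]) <= r_um).astype(np.int32)
        return LabelMask(labels, px)

    def cells_at(self, points):
        return pd.DataFrame(
            {
                "cell_id": range(1, len(points) + 1),
                "centroid_x_um": [p[0] for p in points],
                "centroid_y_um": [p[1] for p in points],
            }
        )

    def test_inside_plaque_distance_zero(self):
        plaques = self.plaque_disc()
        out = cq.nearest_plaque_metrics(self.cells_at([(40.0, 40.0)]), plaques)
        assert out["dist_to_plaque_border_um"].iloc[0] == 0.0
        assert bool(out["plaque_associated"].iloc[0])

    def test_analytic_distance_outside_disc(self):
        plaques = self.plaque_disc(r_um=15.0)
        d = 25.0
        out = cq.nearest_plaque_metrics(self.cells_at([(40.0 + d, 40.0)]), plaques)
        got = out["dist_to_plaque_border_um"].iloc[0]
        assert abs(got - (d - 15.0)) <= np.sqrt(2.0)  # one pixel diagonal

    def test_association_radius_inclusive(self):
        plaques = self.plaque_disc(r_um=15.0)
        near = cq.nearest_plaque_metrics(self.cells_at([(40.0 + 15.0 + 29.0, 40.0)]), plaques)
        far = cq.nearest_plaque_metrics(self.cells_at([(40.0 + 15.0 + 33.0, 40.0)]), plaques)
        assert bool(near["plaque_associated"].iloc[0])
        assert not bool(far["plaque_associated"].iloc[0])

    def test_no_plaque_sentinel(self):
        empty = LabelMask(np.zeros((50, 50), np.int32), 1.0)
        out = cq.nearest_plaque_metrics(self.cells_at([(10.0, 10.0)]), empty)
        assert np.isinf(out["dist_to_plaque_border_um"].iloc[0])
        assert np.isnan(out["nearest_plaque_area_um2"].iloc[0])
        assert not bool(out["plaque_associated"].iloc[0])

    def test_nearest_area_reported(self):
        plaques = self.plaque_disc(r_um=15.0)
        out = cq.nearest_plaque_metrics(self.cells_at([(70.0, 40.0)]), plaques)
        true_area = float((plaques.labels > 0).sum())
        assert out["nearest_plaque_area_um2"].iloc[0] == true_area


class TestAssociatedSummary:
    def make(self, areas, associated, positive):
        cells = pd.DataFrame(
            {
                "nearest_plaque_area_um2": areas,
                "plaque_associated": associated,
                "iba1_positive": positive,
            }
        )
        labels = np.zeros((10, 10), np.int32)
        labels[0, 0] = 1
        return cells, LabelMask(labels, 1.0)

    def test_closed_form_normalised_count(self):
        cells, plaques = self.make([1000.0] * 3, [True] * 3, [True] * 3)
        s = cq.plaque_associated_summary(cells, plaques)
        assert s["n_associated"] == 3
        assert s["normalised_count_per_um2"] == pytest.approx(0.003)

    def test_zero_associated_is_zero(self):
        cells, plaques = self.make([1000.0], [False], [True])
        s = cq.plaque_associated_summary(cells, plaques)
        assert s["n_associated"] == 0
        assert s["normalised_count_per_um2"] == 0.0

    def test_doubling_areas_halves_normalised_count(self):
        cells, plaques = self.make([500.0, 800.0], [True, True], [True, True])
        s1 = cq.plaque_associated_summary(cells, plaques)
        cells2 = cells.assign(nearest_plaque_area_um2=cells["nearest_plaque_area_um2"] * 2)
        s2 = cq.plaque_associated_summary(cells2, plaques)
        assert s2["normalised_count_per_um2"] == pytest.approx(
            s1["normalised_count_per_um2"] / 2.0
        )

    def test_no_plaque_undefined(self):
        cells, _ = self.make([np.nan], [False], [True])
        s = cq.plaque_associated_summary(cells, LabelMask(np.zeros((5, 5), np.int32), 1.0))
        assert s["n_associated"] is None


class TestRadialProfile:
    def test_uniform_image_flat_profile(self):
        sec = MultichannelSection({"Iba1": np.full((100, 100), 3.0)}, pixel_size_um=1.0)
        prof = cq.radial_profile(sec, "Iba1", (50.0, 50.0), r_max_um=20.0, dr_um=2.0)
        assert np.allclose(prof.values, 3.0)

    def test_gaussian_blob_matches_analytic_curve(self):
        px, s, amp = 0.25, 4.0, 100.0
        n = 400
        yy, xx = np.mgrid[:n, :n] * px
        c = (n - 1) * px / 2.0
        img = amp * np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * s * s))
        sec = MultichannelSection({"ch": img}, pixel_size_um=px)
        prof = cq.radial_profile(sec, "ch", (c, c), r_max_um=20.0, dr_um=0.5)
        analytic = amp * np.exp(-(prof.bin_centres_um ** 2) / (2 * s * s))
        rmse = np.sqrt(np.nanmean((prof.values - analytic) ** 2))
        assert rmse < 0.02 * amp

    def test_normalisation_contract(self, rng):
        img = rng.uniform(1, 10, (80, 80))
        sec = MultichannelSection({"ch": img}, pixel_size_um=1.0)
        prof = cq.radial_profile(sec, "ch", (40.0, 40.0), 20.0, 0.5, normalised=True)
        assert abs(np.nansum(prof.values) * 0.5 - 1.0) < 1e-9

    def test_centre_outside_image_rejected(self):
        sec = MultichannelSection({"ch": np.zeros((10, 10))}, pixel_size_um=1.0)
        with pytest.raises(ValueError, match="outside image"):
            cq.radial_profile(sec, "ch", (50.0, 5.0), 5.0, 0.5)

    def test_bins_off_image_are_nan(self):
        sec = MultichannelSection({"ch": np.ones((20, 20))}, pixel_size_um=1.0)
        prof = cq.radial_profile(sec, "ch", (0.0, 0.0), r_max_um=40.0, dr_um=1.0)
        assert np.isnan(prof.values[-5:]).all()


class TestHistogram:
    def test_normalised_histogram_integrates_to_one(self, rng):
        edges = np.linspace(0, 300, 21)
        h = cq.intensity_histogram(rng.uniform(0, 300, 500), edges, normalised=True)
        assert abs(np.sum(h.values * np.diff(edges)) - 1.0) < 1e-9


class TestPooling:
    def make_images(self):
        return pd.DataFrame(
            {
                "animal_id": ["a1", "a1", "a1", "a2", "a2", "b1", "b1"],
                "group": ["g1", "g1", "g1", "g1", "g1", "g2", "g2"],
                "m": [1.0, 2.0, 100.0, 4.0, 6.0, 10.0, 20.0],
            }
        )

    def test_animal_median_and_group_mean_sem(self):
        animals, groups = cq.pool_scalar(self.make_images(), ["m"])
        a = animals.set_index("animal_id")["m"]
        assert a["a1"] == 2.0  # median of {1, 2, 100}
        assert a["a2"] == 5.0
        g1 = groups.set_index("group")
        assert g1.loc["g1", "m_mean"] == pytest.approx((2.0 + 5.0) / 2)
        sd = np.std([2.0, 5.0], ddof=1)
        assert g1.loc["g1", "m_sem"] == pytest.approx(sd / np.sqrt(2))

    def test_matches_independent_loop_on_random_cohort(self, rng):
        rows = []
        for g in ("g1", "g2"):
            for a in range(4):
                for i in range(6):
                    rows.append(
                        {"animal_id": f"{g}a{a}", "group": g, "m": rng.normal(10, 3)}
                    )
        df = pd.DataFrame(rows)
        animals, groups = cq.pool_scalar(df, ["m"])
        # independent recomputation with plain loops
        for g in ("g1", "g2"):
            med = []
            for a in range(4):
                vals = sorted(
                    r["m"] for r in rows if r["animal_id"] == f"{g}a{a}"
                )
                med.append((vals[2] + vals[3]) / 2.0)
            mean = sum(med) / len(med)
            sd = np.sqrt(sum((x - mean) ** 2 for x in med) / (len(med) - 1))
            row = groups.set_index("group").loc[g]
            assert row["m_mean"] == pytest.approx(mean, abs=1e-12)
            assert row["m_sem"] == pytest.approx(sd / 2.0, abs=1e-12)

    def test_order_invariance_bit_exact(self, rng):
        df = self.make_images()
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a1, g1 = cq.pool_scalar(df, ["m"])
        a2, g2 = cq.pool_scalar(shuffled, ["m"])
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_curve_pooling_elementwise(self):
        rows = []
        for img, vals in (("i1", [1.0, 10.0]), ("i2", [3.0, 30.0]), ("i3", [5.0, 50.0])):
            for b, v in zip((0.5, 1.5), vals):
                rows.append(
                    {"animal_id": "a1", "group": "g", "bin": b, "value": v, "image": img}
                )
        pooled = cq.pool_curves(pd.DataFrame(rows))
        assert pooled.set_index("bin")["mean"].tolist() == [3.0, 30.0]
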