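import numpy as np
import pandas as pd
import pytest

from mrtkit.foci import (
    FociDetectorConfig,
    Micrograph,
    detect_foci,
    segment_nuclei,
    summarize_foci,
)
from mrtkit.simulate import gen_micrographs


def _disk_image(centers, radius=20, size=256):
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = 1.0
    return img


class TestSegmentNuclei:
    def test_blank_image_warns_and_empty(self):
        img = Micrograph(np.zeros((64, 64)), np.zeros((64, 64)))
        with pytest.warns(UserWarning, match="blank"):
            labels = segment_nuclei(img)
        assert labels.max() == 0

    def test_fifty_disks(self):
        rng = np.random.default_rng(3)
        centers = [(40 + 55 * i + rng.integers(-3, 4), 40 + 55 * j + rng.integers(-3, 4))
                   for i in range(7) for j in range(7)][:50]
        nuc = _disk_image(centers, radius=18, size=420)
        nuc += rng.normal(0, 0.03, nuc.shape)
        img = Micrograph(np.clip(nuc, 0, None), np.zeros_like(nuc))
        labels = segment_nuclei(img)
        assert labels.max() == len(centers)

    def test_two_touching_disks_split(self):
        nuc = _disk_image([(60, 50), (60, 86)], radius=20, size=128)
        img = Micrograph(nuc, np.zeros_like(nuc))
        labels = segment_nuclei(img)
        assert labels.max() == 2

    def test_small_objects_removed(self):
        nuc = _disk_image([(40, 40)], radius=20, size=128)
        nuc[100:103, 100:103] = 1.0  # 9 px speck
        img = Micrograph(nuc, np.zeros_like(nuc))
        assert segment_nuclei(img).max() == 1


class TestDetectFoci:
    def test_blank_focus_channel(self):
        nuc = _disk_image([(40, 40), (40, 100)], radius=20, size=160)
        img = Micrograph(nuc, np.zeros_like(nuc))
        tab = detect_foci(img, segment_nuclei(img))
        assert (tab.focus_count == 0).all()
        assert not tab.pan_nuclear_flag.any()

    def test_shape_mismatch_rejected(self):
        img = Micrograph(np.zeros((32, 32)), np.zeros((32, 32)))
        with pytest.raises(ValueError, match="shape"):
            detect_foci(img, np.zeros((16, 16), dtype=int))

    def test_pan_nuclear_flagged_and_excluded(self):
        imgs, truth, _ = gen_micrographs(9, n_nuclei=20, mean_foci=15,
                                         sd_foci=9.7, pan_nuclear_fraction=0.5)
        flagged = 0
        for img in imgs:
            tab = detect_foci(img, segment_nuclei(img))
            flagged += int(tab.pan_nuclear_flag.sum())
            assert tab.loc[tab.pan_nuclear_flag, "focus_count"].isna().all()
        assert flagged == int(truth.pan_nuclear.sum())

    def test_intensity_scaling_invariance(self):
        imgs, _, _ = gen_micrographs(5, n_nuclei=20, mean_foci=20, sd_foci=8)
        img = imgs[0]
        labels = segment_nuclei(img)
        t1 = detect_foci(img, labels)
        scaled = Micrograph(img.nucleus_channel, img.focus_channel * 7.3)
        t2 = detect_foci(scaled, labels)
        np.testing.assert_array_equal(t1.focus_count.to_numpy(),
                                      t2.focus_count.to_numpy())

    def test_recall_precision_on_known_positions(self):
        imgs, _, pos = gen_micrographs(7, n_nuclei=60, mean_foci=4,
                                       sd_foci=2.3, snr=8)
        recalls, precisions = [], []
        for i, img in enumerate(imgs):
            labels = segment_nuclei(img)
            _, peaks = detect_foci(img, labels, return_positions=True)
            tp = pos[pos.image == i][["row", "col"]].to_numpy()
            pk = peaks[["row", "col"]].to_numpy()
            if len(tp) == 0 or len(pk) == 0:
                continue
            d = np.sqrt(((pk[:, None, :] - tp[None, :, :]) ** 2).sum(-1))
            flat = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            used_d, used_t = set(), set()
            for di, ti in flat:
                if d[di, ti] > 3:
                    break
                if di in used_d or ti in used_t:
                    continue
                used_d.add(di)
                used_t.add(ti)
            recalls.append(len(used_t) / len(tp))
            precisions.append(len(used_d) / len(pk))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.9

    def test_mean_count_within_10pct_across_seeds(self):
        # generator-truth accuracy invariant at SNR >= 5
        ratios = []
        for seed in range(20):
            imgs, truth, _ = gen_micrographs(seed, n_nuclei=20, mean_foci=30,
                                             sd_foci=10, snr=8)
            det = []
            for img in imgs:
                det += list(detect_foci(img, segment_nuclei(img))
                            .focus_count.dropna())
            ratios.append(np.mean(det) / truth.true_count.mean())
        assert abs(np.mean(ratios) - 1.0) < 0.10

    def test_dense_condition_within_10pct(self):
        # crowded 67-per-nucleus condition at the minimum supported SNR,
        # averaged over a few seeds
        ratios = []
        for seed in (2, 6, 11):
            imgs, truth, _ = gen_micrographs(seed, n_nuclei=40, mean_foci=67,
                                             sd_foci=18, snr=5)
            det = []
            for img in imgs:
                det += list(detect_foci(img, segment_nuclei(img))
                            .focus_count.dropna())
            ratios.append(np.mean(det) / truth.true_count.mean())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.10)


def _counts_table(counts, condition):
    return pd.DataFrame({
        "nucleus_id": range(len(counts)), "area_px2": 2800,
        "focus_count": counts, "pan_nuclear_flag": False,
        "condition": condition, "time_h": 72.0})


class TestSummarizeFoci:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(20, 50).astype(float)
        rep = summarize_foci([_counts_table(x, "a"), _counts_table(x, "b")])
        assert rep["p_value"] > 0.99
        assert rep["difference"] == 0.0

    def test_treated_vs_control_printed_values(self):
        # 72 h means/SDs: 42 +- 14 treated vs 15 +- 9.7 control, n=50
        rng = np.random.default_rng(1)
        treated = np.clip(rng.normal(42, 14, 50), 0, None)
        control = np.clip(rng.normal(15, 9.7, 50), 0, None)
        rep = summarize_foci([_counts_table(treated, "treated"),
                              _counts_table(control, "control")])
        assert rep["test"] == "welch_t"
        assert rep["p_value"] < 1e-4

    def test_dunnett_flags_only_shifted_group(self):
        hits = np.zeros(2)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ctrl = rng.normal(15, 5, 40)
            same = rng.normal(15, 5, 40)
            shifted = rng.normal(30, 5, 40)
            rep = summarize_foci(
                [_counts_table(ctrl, "control"), _counts_table(same, "g1"),
                 _counts_table(shifted, "g2")], control="control")
            dun = rep["dunnett"].set_index("condition")["p_value"]
            hits += [dun["g1"] < 0.05, dun["g2"] < 0.05]
        assert hits[1] >= 18  # shifted flagged with high power
        assert hits[0] <= 3   # null group rarely flagged

    def test_small_group_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        a = _counts_table(rng.poisson(10, 30).astype(float), "a")
        b = _counts_table(rng.poisson(12, 30).astype(float), "b")
        tiny = _counts_table([5.0, 6.0], "tiny")
        with pytest.warns(UserWarning, match="tiny"):
            rep = summarize_foci([a, b, tiny])
        assert set(rep["group_stats"].condition) == {"a", "b"}

    def test_single_group_rejected(self):
        a = _counts_table(np.arange(10.0), "a")
        with pytest.raises(ValueError, match="2 groups"):
            summarize_foci([a])


class TestMicrographIO:
    def test_tiff_roundtrip(self, tmp_path):
        imgs, _, _ = gen_micrographs(1, n_nuclei=4, nuclei_per_image=4,
                                     mean_foci=10, sd_foci=5)
        path = tmp_path / "img.tiff"
        imgs[0].to_tiff(path)
        back = Micrograph.from_tiff(path)
        np.testing.assert_allclose(back.focus_channel,
                                   imgs[0].focus_channel, rtol=1e-6)

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical shape"):
            Micrograph(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Micrograph(-np.ones((4, 4)), np.zeros((4, 4)))
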