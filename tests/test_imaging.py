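import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hric import (
    UNASSIGNED,
    CellTypeProfile,
    GateBox,
    ImageScene,
    PseudoColorSpec,
    Sensor,
    SensorSet,
    classify_nuclei,
    per_event_ratios,
    per_nucleus_ratios,
    pseudo_color,
    ratio_image,
    segment_nuclei,
    simulate_flow,
    simulate_images,
)
from conftest import default_config


def three_sensors(**targets):
    return SensorSet(
        [
            Sensor("C1", target=targets.get("C1", "CONTROL")),
            Sensor("C2", target=targets.get("C2", "CONTROL")),
            Sensor("C3", target=targets.get("C3", "CONTROL")),
        ],
        "C1",
    )


def uniform_scene(values=(1.0, 2.0, 1.0), shape=(20, 20), mask_value=1):
    pixels = np.stack([np.full(shape, v) for v in values])
    mask = np.full(shape, mask_value, dtype=np.int32)
    return ImageScene(["C1", "C2", "C3"], pixels), mask


class TestSegmentNuclei:
    def test_blank_scene_has_no_nuclei(self):
        scene = ImageScene(["C1", "C2", "C3"], np.full((3, 32, 32), 4.0))
        assert segment_nuclei(scene).max() == 0

    def test_recovers_simulated_disks(self):
        """Five well-separated disks: five components, Jaccard >= 0.9."""
        profile = CellTypeProfile("A", {})
        scene = simulate_images(
            [profile],
            three_sensors(),
            (160, 160),
            5,
            radius_range=(7, 9),
            config=default_config(background=5.0),
        )
        mask = segment_nuclei(scene)
        assert mask.max() == 5
        truth = scene.truth_mask > 0
        found = mask > 0
        jaccard = (truth & found).sum() / (truth | found).sum()
        assert jaccard >= 0.9

    def test_labels_are_positive_consecutive_integers(self):
        profile = CellTypeProfile("A", {})
        scene = simulate_images(
            [profile], three_sensors(), (120, 120), 4, config=default_config()
        )
        mask = segment_nuclei(scene)
        assert set(np.unique(mask)) == {0, 1, 2, 3, 4}

    def test_min_size_filters_specks(self):
        pixels = np.full((3, 40, 40), 1.0)
        pixels[:, 5:7, 5:7] = 1000.0  # 4-pixel speck
        pixels[:, 20:30, 20:30] = 1000.0  # 100-pixel nucleus
        scene = ImageScene(["C1", "C2", "C3"], pixels)
        assert segment_nuclei(scene, min_size=20).max() == 1


class TestPerNucleusRatios:
    def test_uniform_nucleus_gives_exact_ratio(self):
        scene, mask = uniform_scene(values=(1.0, 2.0, 1.0))
        measurements, excluded = per_nucleus_ratios(scene, mask, [("C2", "C1")])
        assert measurements[0].ratios["C2/C1"] == pytest.approx(2.0)
        assert excluded == 0

    def test_geometric_mean_of_two_pixels(self):
        pixels = np.zeros((3, 1, 2))
        pixels[0] = 1.0
        pixels[1, 0, 0], pixels[1, 0, 1] = 1.0, 4.0
        scene = ImageScene(["C1", "C2", "C3"], pixels)
        mask = np.ones((1, 2), dtype=np.int32)
        measurements, _ = per_nucleus_ratios(scene, mask, [("C2", "C1")])
        assert measurements[0].ratios["C2/C1"] == pytest.approx(2.0)  # sqrt(1*4)

    def test_noise_free_simulated_nucleus_matches_closed_form(self):
        profile = CellTypeProfile("A", {"m1": 0.5})
        sensors = three_sensors(C2="m1")
        cfg = default_config(ratio_noise_log10_sd=0.0, background=0.0)
        scene = simulate_images(
            [profile], sensors, (80, 80), 2, config=cfg, pixel_noise_log10_sd=0.0
        )
        measurements, _ = per_nucleus_ratios(
            scene, scene.truth_mask, [("C2", "C1"), ("C3", "C1")]
        )
        for m in measurements:
            assert m.ratios["C2/C1"] == pytest.approx(0.5, rel=1e-10)
            assert m.ratios["C3/C1"] == pytest.approx(1.0, rel=1e-10)

    def test_geometric_mean_identity(self):
        """gm of per-pixel ratios == ratio of per-pixel gms (positive pixels)."""
        rng = np.random.default_rng(2)
        num, den = rng.lognormal(size=50), rng.lognormal(size=50)
        gm = lambda x: np.exp(np.mean(np.log(x)))
        assert gm(num / den) == pytest.approx(gm(num) / gm(den))

    def test_nucleus_with_no_valid_pixels_is_dropped(self):
        scene, mask = uniform_scene(values=(0.0, 2.0, 1.0))
        measurements, excluded = per_nucleus_ratios(scene, mask, [("C2", "C1")])
        assert measurements == []
        assert excluded == mask.size


class TestPseudoColor:
    spec = PseudoColorSpec(-0.25, 0.75)  # hmKO2/hmAG1 display convention

    def test_range_endpoints_map_to_zero_and_one(self):
        img = np.array([[10.0**-0.25, 10.0**0.75]])
        np.testing.assert_allclose(pseudo_color(img, self.spec), [[0.0, 1.0]])

    def test_out_of_range_values_clip(self):
        img = np.array([[10.0**1.5, 10.0**-2.0, 0.0]])
        np.testing.assert_allclose(pseudo_color(img, self.spec), [[1.0, 0.0, 0.0]])

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            PseudoColorSpec(0.5, 0.5)

    @given(st.lists(st.floats(min_value=1e-4, max_value=1e4), min_size=2, max_size=10))
    def test_monotone_in_ratio(self, values):
        out = pseudo_color(np.array(sorted(values)), self.spec)
        assert (np.diff(out) >= 0).all()

    def test_idempotent_under_reclipping(self):
        rng = np.random.default_rng(3)
        img = rng.lognormal(0, 1.0, size=(8, 8))
        once = pseudo_color(img, self.spec)
        assert once.min() >= 0.0 and once.max() <= 1.0
        np.testing.assert_array_equal(np.clip(once, 0, 1), once)


class TestClassifyNuclei:
    gates = [
        GateBox("A", [(0.1, 1.0), (-1.0, 1.0)]),
        GateBox("B", [(-1.0, -0.1), (-1.0, 1.0)]),
    ]
    axes = ["C2/C1", "C3/C1"]

    def test_nucleus_inside_gate_gets_label_and_colour(self):
        from hric.imaging import NucleusMeasurement

        m = NucleusMeasurement(1, 50, {"C2/C1": 10.0**0.5, "C3/C1": 1.0}, (5.0, 5.0))
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[4:7, 4:7] = 1
        labels, overlay = classify_nuclei([m], self.gates, self.axes, mask=mask)
        assert labels[1] == "A"
        np.testing.assert_array_equal(overlay[5, 5], [1.0, 0.0, 0.0])

    def test_nucleus_in_no_gate_is_unassigned_and_uncoloured(self):
        from hric.imaging import NucleusMeasurement

        m = NucleusMeasurement(1, 50, {"C2/C1": 1.0, "C3/C1": 1.0}, (5.0, 5.0))
        mask = np.ones((4, 4), dtype=np.int32)
        labels, overlay = classify_nuclei([m], self.gates, self.axes, mask=mask)
        assert labels[1] == UNASSIGNED
        assert overlay.sum() == 0

    def test_three_type_scene_classified_accurately(self):
        """Profiles >= 4-fold apart per axis: >= 90% of nuclei gated right."""
        profiles = [
            CellTypeProfile("A", {"y": 1.0, "z": 1.0}),
            CellTypeProfile("B", {"y": 0.2, "z": 1.0}),
            CellTypeProfile("C", {"y": 1.0, "z": 0.2}),
        ]
        sensors = three_sensors(C2="y", C3="z")
        scene = simulate_images(
            [(p, 1.0) for p in profiles],
            sensors,
            (300, 300),
            30,
            config=default_config(background=2.0),
        )
        mask = segment_nuclei(scene)
        measurements, _ = per_nucleus_ratios(
            scene, mask, [("C2", "C1"), ("C3", "C1")]
        )
        gates = [
            GateBox("A", [(-0.3, 0.3), (-0.3, 0.3)]),
            GateBox("B", [(-1.3, -0.3), (-0.3, 0.3)]),
            GateBox("C", [(-0.3, 0.3), (-1.3, -0.3)]),
        ]
        labels, _ = classify_nuclei(measurements, gates, self.axes)
        # match segmented nuclei to ground-truth nuclei by overlap
        correct = total = 0
        for m in measurements:
            truth_ids, counts = np.unique(
                scene.truth_mask[mask == m.nucleus_id], return_counts=True
            )
            true_id = truth_ids[np.argmax(counts)]
            if true_id == 0:
                continue
            total += 1
            correct += labels[m.nucleus_id] == scene.truth_labels[true_id - 1]
        assert total >= 25
        assert correct / total >= 0.9


class TestImagingFlowConcordance:
    def test_nucleus_and_event_ratio_centers_agree(self):
        """Per-nucleus geometric-mean ratios and flow per-event ratios built
        from the same profile agree within 3 combined SE."""
        profile = CellTypeProfile("A", {"m1": 0.6})
        sensors = three_sensors(C2="m1")
        cfg = default_config()
        scene = simulate_images(
            [profile], sensors, (360, 360), 60, config=cfg
        )
        measurements, _ = per_nucleus_ratios(
            scene, scene.truth_mask, [("C2", "C1")]
        )
        nuc = np.log10([m.ratios["C2/C1"] for m in measurements])

        flow_sensors = SensorSet(
            [Sensor("C1"), Sensor("C2", target="m1")], "C1"
        )
        sample = simulate_flow([(profile, 1.0)], flow_sensors, cfg)
        ev = np.log10(per_event_ratios(sample, "C2", "C1").values())

        se = np.sqrt(nuc.var(ddof=1) / len(nuc) + ev.var(ddof=1) / len(ev))
        assert abs(nuc.mean() - ev.mean()) < 3 * se


class TestRatioImage:
    def test_zero_denominator_pixels_map_to_zero(self):
        pixels = np.zeros((3, 2, 2))
        pixels[0, 0, 0] = 2.0
        pixels[1] = 6.0
        scene = ImageScene(["C1", "C2", "C3"], pixels)
        img = ratio_image(scene, "C2", "C1")
        assert img[0, 0] == pytest.approx(3.0)
        assert img[1, 1] == 0.0
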