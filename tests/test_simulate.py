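"""Synthetic study generator: determinism, bounds, error-event rates,
noise-model calibration against analytic oracles."""

import math

import numpy as np
import pytest

from sonoagree import curation, metrics
from sonoagree.model import Region, Status, StructureClass
from sonoagree.simulate import (
    AnnotatorProfile,
    StudyConfig,
    analytic_dice_disks,
    disk_polygon,
    expected_dice_under_jitter,
    generate_scene,
    replica_study_annotations,
    simulate_annotator,
    simulate_study,
)

NOISELESS = dict(translation_sigma=0, boundary_noise_sigma=0, scale_sigma=0,
                 p_omit=0, p_wrong_kind=0, p_skip_image=0)
UNIT_DIFFICULTY = {c: 1.0 for c in StructureClass}


class TestSceneGeneration:
    def test_same_seed_gives_identical_scene(self, manifest):
        a = generate_scene(Region.ISB, manifest, 512, 384, 42)
        b = generate_scene(Region.ISB, manifest, 512, 384, 42)
        assert a.keys() == b.keys()
        for k in a:
            assert all(np.array_equal(x, y) for x, y in zip(a[k], b[k]))

    def test_acb_template_has_three_structures(self, manifest):
        scene = generate_scene(Region.ACB, manifest, 512, 384, 0)
        assert set(scene) == {"femoral_artery", "saphenous_nerve", "sartorius"}

    def test_many_scenes_stay_within_bounds(self, manifest):
        for seed in range(300):
            scene = generate_scene(Region.ISB, manifest, 512, 384, seed)
            for comps in scene.values():
                for comp in comps:
                    assert comp[:, 0].min() >= 0 and comp[:, 0].max() <= 512
                    assert comp[:, 1].min() >= 0 and comp[:, 1].max() <= 384


class TestAnnotatorModel:
    def test_noiseless_profile_reproduces_ground_truth(self, manifest):
        scene = generate_scene(Region.ACB, manifest, 512, 384, 1)
        profile = AnnotatorProfile("E01", **NOISELESS)
        anns = simulate_annotator(scene, profile, manifest, "acb_01", 9)
        for ann in anns:
            assert ann.status is Status.PRESENT
            truth = np.round(scene[ann.structure_id][0], 2)
            assert np.array_equal(ann.components[0], truth)

    def test_omit_probability_one_marks_everything_absent(self, manifest):
        scene = generate_scene(Region.ACB, manifest, 512, 384, 1)
        profile = AnnotatorProfile("E01", **{**NOISELESS, "p_omit": 1.0})
        anns = simulate_annotator(scene, profile, manifest, "acb_01", 9)
        assert all(a.status is Status.ABSENT for a in anns)

    def test_error_event_frequencies_converge(self, manifest):
        p_omit, n = 0.1, 1000
        scene = generate_scene(Region.SNB, manifest, 512, 384, 2)  # one nerve
        profile = AnnotatorProfile("E01", **{**NOISELESS, "p_omit": p_omit})
        hits = 0
        for seed in range(n):
            (ann,) = simulate_annotator(scene, profile, manifest, "snb_01", seed,
                                        UNIT_DIFFICULTY)
            hits += ann.status is Status.ABSENT
        se = math.sqrt(p_omit * (1 - p_omit) / n)
        assert abs(hits / n - p_omit) <= 3 * se

    def test_translation_jitter_dice_matches_semianalytic_expectation(self, manifest):
        """Monte-Carlo mean Dice of a jittered disk against its ground
        truth must agree with the closed-form lens Dice integrated over
        the Rayleigh distribution of the centre offset."""
        radius, sigma, reps = 20.0, 5.0, 500
        truth_poly = disk_polygon(100, 100, radius, 256)
        truth_mask = metrics.rasterize([truth_poly], 200, 200)
        scene = {"femoral_artery": (truth_poly,)}
        profile = AnnotatorProfile("E01", **{**NOISELESS, "translation_sigma": sigma})
        values = []
        for seed in range(reps):
            (ann,) = simulate_annotator(scene, profile, manifest, "acb_01", seed,
                                        UNIT_DIFFICULTY)
            mask = metrics.rasterize(ann.components, 200, 200)
            values.append(metrics.dice(truth_mask, mask))
        mc_mean = float(np.mean(values))
        mc_se = float(np.std(values, ddof=1)) / math.sqrt(reps)
        expected = expected_dice_under_jitter(radius, sigma)
        assert abs(mc_mean - expected) <= 3 * mc_se

    def test_mean_dice_decreases_with_boundary_noise(self, manifest):
        """More boundary noise must strictly lower the mean pairwise Dice
        (three noise levels, >=100 simulated pairs each)."""
        scene = generate_scene(Region.ACB, manifest, 512, 384, 3)
        truth = scene["femoral_artery"]
        means = []
        for level, sigma in enumerate([0.5, 2.0, 5.0]):
            profile = AnnotatorProfile("E01", **{**NOISELESS, "boundary_noise_sigma": sigma})
            vals = []
            for seed in range(110):
                a = simulate_annotator({"femoral_artery": truth}, profile, manifest,
                                       "acb_01", 2 * seed, UNIT_DIFFICULTY)[0]
                b = simulate_annotator({"femoral_artery": truth}, profile, manifest,
                                       "acb_01", 2 * seed + 1, UNIT_DIFFICULTY)[0]
                ma = metrics.rasterize(a.components, 512, 384)
                mb = metrics.rasterize(b.components, 512, 384)
                vals.append(metrics.dice(ma, mb))
            means.append(float(np.mean(vals)))
        assert means[0] > means[1] > means[2]


class TestStudySimulation:
    def test_same_master_seed_gives_identical_studies(self, tmp_path):
        from sonoagree.model import write_annotations, write_manifest

        config = StudyConfig(n_humans=3, scans_per_region=1, seed=42)
        for run in ("a", "b"):
            man, anns = simulate_study(config)
            d = tmp_path / run
            d.mkdir()
            write_manifest(man, d / "manifest.yaml")
            write_annotations(anns, d / "annotations", man)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes()

    def test_default_config_matches_study_design(self):
        config = StudyConfig()
        assert config.n_humans == 19
        assert config.scans_per_region == 5
        assert len(config.regions) == 6

    def test_default_grouped_potential_is_1710(self, replica_study):
        manifest, anns = replica_study
        _, report = curation.curate(anns, manifest)
        assert report.grouped_potential == 1710

    def test_replica_reproduces_full_accounting_chain(self, replica_study):
        manifest, anns = replica_study
        _, report = curation.curate(anns, manifest)
        chain = (report.potential_annotations, report.grouped_potential,
                 report.total_removed, report.analysed)
        assert chain == (1900, 1710, 31, 1679)

    def test_class_difficulty_ordering_emerges_in_pipeline(self):
        """With difficulty ordered artery < muscle < nerve, the pooled
        class mean Dice must come out artery > muscle > nerve, for both
        human-human and AI-human comparisons."""
        from sonoagree import agreement

        for seed in (1, 2, 3):
            config = StudyConfig(n_humans=5, scans_per_region=2, seed=seed)
            man, anns = simulate_study(config)
            curated, _ = curation.curate(anns, man)
            rows = agreement.summarize(
                agreement.pairwise_scores(curated, man), man, by="class"
            )
            for mode in ("HH", "HAI"):
                sub = rows[(rows["mode"] == mode) & (rows["metric"] == "dice")]
                mean = dict(zip(sub["scope"], sub["mean"]))
                assert mean["artery"] > mean["muscle"] > mean["nerve"]


class TestAnalyticDice:
    def test_coincident_disks(self):
        assert analytic_dice_disks(20, 20, 0) == 1.0

    def test_disjoint_disks(self):
        assert analytic_dice_disks(10, 15, 25) == 0.0
        assert analytic_dice_disks(10, 15, 40) == 0.0

    def test_contained_disk(self):
        # small disk entirely inside the large one: lens = small disk area
        expected = 2 * math.pi * 100 / (math.pi * (100 + 400))
        assert analytic_dice_disks(10, 20, 5) == pytest.approx(expected)

    def test_matches_high_resolution_rasterization(self):
        a = metrics.rasterize([disk_polygon(495, 500, 20 * 5, 1024)], 1000, 1000)
        b = metrics.rasterize([disk_polygon(545, 500, 20 * 5, 1024)], 1000, 1000)
        # 5x supersampled geometry: d=10, r=20 at scale 5
        assert metrics.dice(a, b) == pytest.approx(analytic_dice_disks(20, 20, 10), abs=0.005)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            analytic_dice_disks(-1, 5, 2)
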