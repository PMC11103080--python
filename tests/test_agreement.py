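"""Pairwise scoring and pooled summaries: pair counting, empty-pair
policies, summary statistics, and the HH/HAI comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sonoagree import agreement, curation
from sonoagree.agreement import MetricConfig, pairwise_scores, scores_to_frame, summarize
from sonoagree.model import Annotation, Status, ValidationError, manifest_from_dict, manifest_to_dict
from sonoagree.simulate import AnnotatorProfile, StudyConfig, disk_polygon, simulate_study

TRI = ((100.0, 100.0), (140.0, 100.0), (120.0, 135.0))


def _study_one_scan(manifest, statuses, scan_id="acb_01", group="sartorius"):
    """Curated annotations with the given per-annotator statuses on one
    structure of one scan (all other scans fully present elsewhere is not
    needed: entries are built post-curation)."""
    anns = []
    for annotator, status in statuses.items():
        comps = (disk_polygon(150, 150, 30),) if status is Status.PRESENT else ()
        anns.append(Annotation(annotator, scan_id, group, comps, status))
    return anns


class TestPairCounting:
    def test_19_humans_yield_171_hh_and_19_hai_pairs(self, manifest):
        statuses = {h: Status.PRESENT for h in manifest.humans}
        statuses["AI"] = Status.PRESENT
        scores = pairwise_scores(_study_one_scan(manifest, statuses), manifest)
        hh = [s for s in scores if s.mode == "HH"]
        hai = [s for s in scores if s.mode == "HAI"]
        assert len(hh) == math.comb(19, 2) == 171
        assert len(hai) == 19

    def test_skipped_annotator_contributes_no_pairs(self, manifest):
        statuses = {"E01": Status.PRESENT, "E02": Status.PRESENT, "E03": Status.IMAGE_SKIPPED}
        scores = pairwise_scores(_study_one_scan(manifest, statuses), manifest, modes=("HH",))
        assert len(scores) == 1

    def test_pair_count_formula_with_both_empty_flagged(self, manifest):
        statuses = {"E01": Status.PRESENT, "E02": Status.ABSENT,
                    "E03": Status.ABSENT, "E04": Status.PRESENT}
        scores = pairwise_scores(_study_one_scan(manifest, statuses), manifest, modes=("HH",))
        assert len(scores) == math.comb(4, 2)
        assert sum(1 for s in scores if s.both_empty) == 1  # E02-E03

    def test_missing_ai_annotator_is_configuration_error(self, manifest):
        doc = manifest_to_dict(manifest)
        doc["annotators"] = [a for a in doc["annotators"] if a["role"] != "ai"]
        no_ai = manifest_from_dict(doc)
        with pytest.raises(ValidationError, match="AI"):
            pairwise_scores(_study_one_scan(no_ai, {"E01": Status.PRESENT}), no_ai)


class TestEmptyPolicies:
    def test_one_empty_scores_worst_value(self, manifest):
        region_scores = pairwise_scores(
            _study_one_scan(manifest, {"E01": Status.PRESENT, "E02": Status.ABSENT}),
            manifest, modes=("HH",),
        )
        assert region_scores[0].value == 0.0
        line = [Annotation("E01", "rsb_01", "peritoneum", (((50.0, 200.0), (400.0, 210.0)),)),
                Annotation("E02", "rsb_01", "peritoneum", (), Status.ABSENT)]
        line_scores = pairwise_scores(line, manifest, modes=("HH",))
        assert line_scores[0].value == 1.0

    def test_both_empty_excluded_by_default_scored_perfect_on_request(self, manifest):
        anns = _study_one_scan(manifest, {"E01": Status.ABSENT, "E02": Status.ABSENT})
        (excluded,) = pairwise_scores(anns, manifest, modes=("HH",))
        assert excluded.both_empty and math.isnan(excluded.value)
        (perfect,) = pairwise_scores(
            anns, manifest, MetricConfig(both_empty="perfect"), modes=("HH",)
        )
        assert perfect.value == 1.0

    def test_zero_noise_panel_agrees_perfectly(self):
        config = StudyConfig(
            n_humans=4, scans_per_region=1, seed=7,
            human_profile=AnnotatorProfile(
                "template", translation_sigma=0, boundary_noise_sigma=0,
                scale_sigma=0, p_omit=0, p_wrong_kind=0, p_skip_image=0,
            ),
            ai_profile=AnnotatorProfile(
                "AI", role="ai", translation_sigma=0, boundary_noise_sigma=0,
                scale_sigma=0, p_omit=0, p_wrong_kind=0, p_skip_image=0,
            ),
        )
        man, anns = simulate_study(config)
        curated, _ = curation.curate(anns, man)
        scores = pairwise_scores(curated, man)
        dice_values = [s.value for s in scores if s.metric == "dice"]
        assert dice_values and all(v == 1.0 for v in dice_values)
        h_values = [s.value for s in scores if s.metric == "hausdorff"]
        assert h_values and all(v == pytest.approx(0.0, abs=1e-9) for v in h_values)


class TestSummarize:
    def _scores(self, values, manifest, group="sartorius"):
        return [
            agreement.PairScore("acb_01", group, f"E{i:02d}", f"E{i + 1:02d}",
                                "HH", "dice", v)
            for i, v in enumerate(values, start=1)
        ]

    def test_three_point_pool(self, manifest):
        rows = summarize(self._scores([0.5, 0.7, 0.9], manifest), manifest)
        row = rows.iloc[0]
        assert (row["min"], row["median"], row["max"]) == (0.5, 0.7, 0.9)
        assert row["mean"] == pytest.approx(0.7)
        assert row["sd"] == pytest.approx(0.2)
        assert row["n_pairs"] == 3

    def test_single_score_flags_sd_undefined(self, manifest):
        row = summarize(self._scores([0.8], manifest), manifest).iloc[0]
        assert row["min"] == row["mean"] == row["median"] == row["max"] == 0.8
        assert math.isnan(row["sd"])

    def test_even_pool_median_is_central_midpoint(self, manifest):
        row = summarize(self._scores([0.2, 0.4, 0.6, 1.0], manifest), manifest).iloc[0]
        assert row["median"] == pytest.approx(0.5)

    def test_all_both_empty_scope_emitted_not_dropped(self, manifest):
        scores = [agreement.PairScore("acb_01", "sartorius", "E01", "E02",
                                      "HH", "dice", math.nan, both_empty=True)]
        row = summarize(scores, manifest).iloc[0]
        assert row["n_pairs"] == 0 and row["n_both_empty"] == 1
        assert math.isnan(row["mean"])

    def test_permuting_annotator_labels_leaves_summary_unchanged(self, small_curated):
        man, curated, _ = small_curated
        scores = pairwise_scores(curated, man, modes=("HH",))
        base = summarize(scores, man, by="class")
        humans = man.humans
        mapping = dict(zip(humans, humans[1:] + humans[:1]))
        relabelled = [
            agreement.PairScore(s.scan_id, s.group_id, mapping[s.annotator_a],
                                mapping[s.annotator_b], s.mode, s.metric,
                                s.value, s.both_empty)
            for s in scores
        ]
        permuted = summarize(relabelled, man, by="class")
        pd.testing.assert_frame_equal(base, permuted)

    def test_class_pooling_covers_all_four_classes(self, small_curated):
        man, curated, _ = small_curated
        rows = summarize(pairwise_scores(curated, man), man, by="class")
        assert set(rows["scope"]) == {"artery", "muscle", "nerve", "fascia_serosa"}
        assert (rows.loc[rows["scope"] == "fascia_serosa", "metric"] == "hausdorff").all()


class TestCompareModes:
    def _row(self, scope, mode, metric, mean, sd):
        return {"scope": scope, "scope_kind": "structure", "mode": mode,
                "metric": metric, "n_pairs": 10, "n_both_empty": 0,
                "min": 0.0, "mean": mean, "median": mean, "max": 1.0, "sd": sd}

    def test_higher_dice_mean_is_superior(self):
        hh = pd.DataFrame([self._row("muscle", "HH", "dice", 0.80, 0.23)])
        hai = pd.DataFrame([self._row("muscle", "HAI", "dice", 0.77, 0.23)])
        out = agreement.compare_modes(hh, hai)
        assert out.loc[0, "superior_mean"] == "HH"
        assert out.loc[0, "smaller_sd"] == "equal"

    def test_lower_hausdorff_mean_is_superior(self):
        hh = pd.DataFrame([self._row("fascia", "HH", "hausdorff", 0.08, 0.13)])
        hai = pd.DataFrame([self._row("fascia", "HAI", "hausdorff", 0.16, 0.21)])
        out = agreement.compare_modes(hh, hai)
        assert out.loc[0, "superior_mean"] == "HH"
        assert out.loc[0, "smaller_sd"] == "HH"

    def test_identical_rows_tie(self):
        hh = pd.DataFrame([self._row("x", "HH", "dice", 0.5, 0.1)])
        hai = pd.DataFrame([self._row("x", "HAI", "dice", 0.5, 0.1)])
        out = agreement.compare_modes(hh, hai)
        assert out.loc[0, "superior_mean"] == "equal"

    def test_scope_mismatch_rejected(self):
        hh = pd.DataFrame([self._row("x", "HH", "dice", 0.5, 0.1)])
        hai = pd.DataFrame([self._row("y", "HAI", "dice", 0.5, 0.1)])
        with pytest.raises(ValidationError):
            agreement.compare_modes(hh, hai)
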