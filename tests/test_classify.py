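"""Nucleus detection, the counting rule, backends and dataset splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilscore.classify import (
    PatchLabel,
    Prediction,
    RuleBasedBackend,
    classify_patch,
    detect_nuclei,
    rule_label,
    split_dataset,
    train_small_classifier,
)
from tilscore.synthgen import PatchSampler, PatchSpec, generate_patch


class TestRuleLabel:
    @pytest.mark.parametrize(
        "n_lymph,n_tumor,expected",
        [
            (3, 1, PatchLabel.TIL_POSITIVE),
            (2, 7, PatchLabel.TIL_NEGATIVE),
            (50, 0, PatchLabel.OTHER_NECROTIC),
            (0, 1, PatchLabel.TIL_NEGATIVE),
            (0, 0, PatchLabel.OTHER_NECROTIC),
        ],
    )
    def test_rule_examples(self, n_lymph, n_tumor, expected):
        assert rule_label(n_lymph, n_tumor) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rule_label(-1, 0)

    def test_rule_is_a_total_partition(self):
        # every count pair maps to exactly one class, consistent with the
        # threshold definition, over an exhaustive grid
        for n_l in range(11):
            for n_t in range(11):
                label = rule_label(n_l, n_t)
                if n_t == 0:
                    assert label == PatchLabel.OTHER_NECROTIC
                elif n_l >= 3:
                    assert label == PatchLabel.TIL_POSITIVE
                else:
                    assert label == PatchLabel.TIL_NEGATIVE


class TestDetectNuclei:
    def test_exact_counts_on_noiseless_patch(self, tissue_patch):
        patch, _, _ = tissue_patch
        cells = detect_nuclei(patch)
        assert sum(c.cell_class == "lymphocyte" for c in cells) == 3
        assert sum(c.cell_class == "tumor" for c in cells) == 1

    def test_tumor_only_patch(self):
        patch, _, _ = generate_patch(
            PatchSpec(n_lymphocytes=0, n_tumor_cells=5, seed=21)
        )
        cells = detect_nuclei(patch)
        assert sum(c.cell_class == "lymphocyte" for c in cells) == 0
        assert sum(c.cell_class == "tumor" for c in cells) == 5

    def test_blank_patch_yields_no_cells(self):
        white = np.full((150, 150, 3), 255, dtype=np.uint8)
        assert detect_nuclei(white) == []

    def test_detected_centroids_match_ground_truth(self, tissue_patch):
        patch, true_cells, _ = tissue_patch
        detected = detect_nuclei(patch)
        for truth in true_cells:
            distances = [
                np.hypot(
                    d.centroid[0] - truth.centroid[0],
                    d.centroid[1] - truth.centroid[1],
                )
                for d in detected
            ]
            nearest = detected[int(np.argmin(distances))]
            assert min(distances) < 3.0
            assert nearest.cell_class == truth.cell_class


class TestClassifyPatch:
    def test_reference_backend_one_hot(self):
        patch, _, _ = generate_patch(
            PatchSpec(n_lymphocytes=4, n_tumor_cells=2, seed=31)
        )
        pred = classify_patch(patch, RuleBasedBackend())
        assert pred.label == PatchLabel.TIL_POSITIVE
        np.testing.assert_array_equal(pred.probabilities, [1.0, 0.0, 0.0])

    def test_argmax_label(self):
        pred = Prediction.from_probabilities([0.2, 0.2, 0.6])
        assert pred.label == PatchLabel.OTHER_NECROTIC

    def test_tie_breaks_to_lowest_code(self):
        pred = Prediction.from_probabilities([0.4, 0.4, 0.2])
        assert pred.label == PatchLabel.TIL_POSITIVE

    def test_probabilities_must_be_simplex(self):
        with pytest.raises(ValueError):
            Prediction(label=PatchLabel.TIL_POSITIVE, probabilities=np.array([0.9, 0.9, 0.9]))

    def test_uninitialized_backend_rejected(self, tissue_patch):
        with pytest.raises(ValueError):
            classify_patch(tissue_patch[0], None)


class TestEndToEndLabelRecovery:
    def _recovery_rate(self, n: int, noise_sd: float, seed0: int) -> float:
        sampler = PatchSampler()
        backend = RuleBasedBackend()
        rng = np.random.default_rng(99)
        hits = 0
        for i in range(n):
            label = sampler.sample_label(rng)
            n_l, n_t = sampler.sample_counts(label, rng)
            patch, _, truth = generate_patch(
                PatchSpec(
                    n_lymphocytes=n_l, n_tumor_cells=n_t, noise_sd=noise_sd, seed=seed0 + i
                )
            )
            hits += backend.predict(patch).label == truth
        return hits / n

    def test_perfect_recovery_noiseless(self):
        assert self._recovery_rate(60, 0.0, 10_000) == 1.0

    def test_recovery_at_noise_sd_8(self):
        assert self._recovery_rate(60, 8.0, 20_000) >= 0.9


class TestSplitDataset:
    def test_80_20_per_label(self):
        labels = np.repeat([0, 1, 2], 100)
        train_idx, val_idx = split_dataset(labels, train_frac=0.8, seed=0)
        assert len(train_idx) == 240 and len(val_idx) == 60
        for cls in range(3):
            assert (labels[train_idx] == cls).sum() == 80
            assert (labels[val_idx] == cls).sum() == 20
        assert set(train_idx) & set(val_idx) == set()

    def test_ten_disjoint_folds(self):
        labels = np.repeat([0, 1, 2], 40)
        folds = split_dataset(labels, n_folds=10, seed=1)
        assert sorted(np.unique(folds)) == list(range(10))
        for fold in range(10):
            assert (folds == fold).sum() == 12
            for cls in range(3):
                assert ((folds == fold) & (labels == cls)).sum() == 4

    def test_same_seed_same_assignment(self):
        labels = np.repeat([0, 1, 2], 30)
        a = split_dataset(labels, seed=5)
        b = split_dataset(labels, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_stratification_by_extra_key(self):
        labels = np.tile([0, 1, 2], 20)
        strata = np.repeat(["siteA", "siteB"], 30)
        train_idx, _ = split_dataset(labels, train_frac=0.8, seed=2, strata=strata)
        for site in ("siteA", "siteB"):
            for cls in range(3):
                members = (strata == site) & (labels == cls)
                n_train = np.isin(np.flatnonzero(members), train_idx).sum()
                assert n_train == 8  # 80% of 10

    def test_impossible_folds_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([0, 0, 1, 1, 2, 2], n_folds=10)


class TestTrainableBackend:
    def test_small_classifier_learns_easy_synthetic_data(self):
        from tilscore.synthgen import generate_labeled_dataset

        patches, labels, _ = generate_labeled_dataset(60, seed=3)
        labels = [int(l) for l in labels]
        train_idx, val_idx = split_dataset(labels, seed=0)
        backend = train_small_classifier(
            [patches[i] for i in train_idx],
            [labels[i] for i in train_idx],
            seed=0,
            max_iter=150,
        )
        pred = backend.predict(patches[0])
        assert abs(pred.probabilities.sum() - 1.0) < 1e-6
        accuracy = np.mean(
            [backend.predict(patches[i]).label == labels[i] for i in train_idx]
        )
        assert accuracy > 1 / 3  # clearly better than chance

    def test_missing_class_rejected(self, tissue_patch):
        with pytest.raises(ValueError):
            train_small_classifier([tissue_patch[0]] * 4, [0, 0, 1, 1])


@given(
    st.integers(min_value=0, max_value=20), st.integers(min_value=0, max_value=20)
)
@settings(max_examples=60, deadline=None)
def test_rule_label_total_over_random_counts(n_l, n_t):
    label = rule_label(n_l, n_t)
    assert label in (PatchLabel.TIL_POSITIVE, PatchLabel.TIL_NEGATIVE, PatchLabel.OTHER_NECROTIC)
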