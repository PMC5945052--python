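import numpy as np
import pytest

from steatoscope.metrics import (ConfusionMatrix, UndefinedMetricError,
                                 accuracy, auroc, col_recall, confusion,
                                 precision_conventional, recall_conventional,
                                 round_half_up, row_precision)

from .oracles import auroc_pairs_oracle

# The published 5-class macrosteatosis count table (rows = actual).
MACRO_CLASSES = ["central_vein", "macro_fat", "bile_duct", "portal_vein",
                 "portal_artery"]
MACRO_COUNTS = np.array([
    [230, 8, 0, 25, 0],
    [6, 343, 0, 12, 0],
    [0, 1, 17, 27, 5],
    [15, 8, 14, 298, 2],
    [2, 4, 4, 7, 13],
])
# The published binary microsteatosis count table.
MICRO_CLASSES = ["micro_fat", "others"]
MICRO_COUNTS = np.array([[7109, 1862], [2116, 7660]])


class TestConfusion:
    def test_diagonal_on_perfect_agreement(self):
        y = ["a", "b", "a", "c"] * 2 + ["b", "c"]
        cm = confusion(y, y, ["a", "b", "c"])
        assert cm.total == 10
        assert np.trace(cm.counts) == 10

    def test_matches_pair_counting_oracle(self, rng):
        classes = ["x", "y", "z"]
        y_true = rng.choice(classes, 50).tolist()
        y_pred = rng.choice(classes, 50).tolist()
        cm = confusion(y_true, y_pred, classes)
        for i, a in enumerate(classes):
            for j, b in enumerate(classes):
                n = sum(1 for t, p in zip(y_true, y_pred) if t == a and p == b)
                assert cm.counts[i, j] == n

    def test_empty_input_zero_matrix(self):
        cm = confusion([], [], ["a", "b"])
        assert cm.total == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["a"], ["q"], ["a", "b"])


@pytest.fixture(scope="module")
def macro_cm():
    return ConfusionMatrix(MACRO_COUNTS, MACRO_CLASSES)


@pytest.fixture(scope="module")
def micro_cm():
    return ConfusionMatrix(MICRO_COUNTS, MICRO_CLASSES)


class TestTableConventions:
    """Row 'PRECISION' / column 'RECALL' reproduce the published tables."""

    @pytest.mark.parametrize("cls,expected", [
        ("macro_fat", 95.01), ("central_vein", 87.45)])
    def test_macro_row_precision_published_values(self, macro_cm, cls, expected):
        assert row_precision(macro_cm, cls) == expected

    @pytest.mark.parametrize("cls,expected", [
        ("macro_fat", 94.23), ("central_vein", 90.91)])
    def test_macro_col_recall_published_values(self, macro_cm, cls, expected):
        assert col_recall(macro_cm, cls) == expected

    @pytest.mark.parametrize("cls,row,col", [
        # cells whose published metrics are inconsistent with the published
        # counts; the count-derived arithmetic is asserted instead
        ("bile_duct", 34.0, 48.57),       # 17/50, 17/35
        ("portal_vein", 88.43, 80.76),    # 298/337, 298/369
        ("portal_artery", 43.33, 65.0)])  # 13/30, 13/20
    def test_macro_metrics_from_counts(self, macro_cm, cls, row, col):
        assert row_precision(macro_cm, cls) == row
        assert col_recall(macro_cm, cls) == col

    def test_micro_table_metrics(self, micro_cm):
        assert row_precision(micro_cm, "micro_fat") == 79.24
        assert row_precision(micro_cm, "others") == 78.36  # 7660/9776
        assert col_recall(micro_cm, "micro_fat") == 77.06
        assert col_recall(micro_cm, "others", decimals=3) == 80.445

    def test_micro_accuracy_trace_over_total(self, micro_cm):
        assert accuracy(micro_cm) == 78.78  # 100 * 14769 / 18747

    def test_identity_matrix_everything_100(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int) * 5, ["a", "b", "c"])
        for c in cm.class_names:
            assert row_precision(cm, c) == 100.0
            assert col_recall(cm, c) == 100.0
        assert accuracy(cm) == 100.0

    def test_conventional_aliases_swap(self, macro_cm):
        assert (precision_conventional(macro_cm, "macro_fat")
                == col_recall(macro_cm, "macro_fat"))
        assert (recall_conventional(macro_cm, "macro_fat")
                == row_precision(macro_cm, "macro_fat"))

    def test_zero_diagonal_accuracy(self):
        cm = ConfusionMatrix(np.array([[0, 3], [3, 0]]), ["a", "b"])
        assert accuracy(cm) == 0.0

    def test_undefined_metrics(self):
        cm = ConfusionMatrix(np.array([[2, 0], [0, 0]]), ["a", "b"])
        with pytest.raises(UndefinedMetricError):
            row_precision(cm, "b")
        with pytest.raises(UndefinedMetricError):
            col_recall(cm, "b")
        with pytest.raises(UndefinedMetricError):
            accuracy(ConfusionMatrix(np.zeros((2, 2), int), ["a", "b"]))

    def test_rounding_half_up(self):
        assert round_half_up(87.445, 2) == 87.45
        assert round_half_up(87.444, 2) == 87.44
        assert round_half_up(80.4445, 3) == 80.445


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_all_pairs_oracle(self, rng):
        scores = rng.integers(0, 50, size=200) / 7.0  # force some ties
        labels = rng.uniform(size=200) > 0.5
        assert abs(auroc(scores, labels)
                   - auroc_pairs_oracle(scores, labels)) < 1e-12

    def test_inversion_symmetry(self, rng):
        scores = rng.normal(size=100)
        labels = rng.uniform(size=100) > 0.6
        assert auroc(-scores, labels) == pytest.approx(
            1.0 - auroc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 2, 3], [1, 1, 1])
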