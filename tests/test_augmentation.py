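"""Class-conditional narrative augmentation: multiplicity, purity, labels."""

import numpy as np
import pandas as pd
import pytest

from mineinjury.augmentation import (
    AugmentationPlan,
    augment_narrative,
    augment_training_set,
    class_counts,
    fit_class_models,
)
from mineinjury.narrative_vectors import EmbeddingModel, EmbeddingParams, train_embedding
from mineinjury.records import CLASS_FIELD, NARRATIVE_FIELD
from tests.conftest import FAST_EMBEDDING


@pytest.fixture(scope="module")
def class_model() -> EmbeddingModel:
    """An embedding over a 30-token vocabulary, every token in vocabulary."""
    rng = np.random.default_rng(0)
    vocab = [f"tok{i:02d}" for i in range(30)]
    docs = [list(rng.choice(vocab, size=8)) for _ in range(120)]
    return train_embedding(docs, FAST_EMBEDDING)


def test_ten_token_narrative_yields_18_variants(class_model):
    tokens = [f"tok{i:02d}" for i in range(10)]
    variants = augment_narrative(tokens, class_model, n_words=6, top_k=3, seed=1)
    assert len(variants) == 18


def test_short_narrative_untouched(class_model):
    tokens = [f"tok{i:02d}" for i in range(5)]
    assert augment_narrative(tokens, class_model, n_words=6, top_k=3, seed=1) == []


def test_variants_have_hamming_distance_one(class_model):
    rng = np.random.default_rng(7)
    vocab = class_model.tokens
    for case in range(100):
        length = int(rng.integers(6, 15))
        tokens = list(rng.choice(vocab, size=length))
        for variant in augment_narrative(tokens, class_model, seed=case):
            assert len(variant) == len(tokens)
            diffs = [i for i, (a, b) in enumerate(zip(tokens, variant)) if a != b]
            assert len(diffs) == 1


def test_oov_positions_skipped_and_redrawn(class_model):
    # 4 in-vocabulary tokens among 10: all 4 eligible positions used -> 12 variants
    tokens = ["tok00", "oovA", "tok01", "oovB", "tok02", "oovC",
              "oovD", "tok03", "oovE", "oovF"]
    variants = augment_narrative(tokens, class_model, n_words=6, top_k=3, seed=2)
    assert len(variants) == 4 * 3
    for v in variants:
        changed = [i for i, (a, b) in enumerate(zip(tokens, v)) if a != b]
        assert tokens[changed[0]].startswith("tok")


def test_substituted_positions_are_distinct(class_model):
    tokens = [f"tok{i:02d}" for i in range(12)]
    variants = augment_narrative(tokens, class_model, n_words=6, top_k=3, seed=3)
    changed = {next(i for i, (a, b) in enumerate(zip(tokens, v)) if a != b) for v in variants}
    assert len(changed) == 6


class TestFitClassModels:
    def _frame(self, labels_docs):
        return pd.DataFrame(
            [(lbl, " ".join(doc)) for lbl, docs in labels_docs.items() for doc in docs],
            columns=[CLASS_FIELD, NARRATIVE_FIELD],
        )

    def test_one_model_per_class(self):
        df = self._frame({f"c{i}": [["w", "u", "v"]] * 3 for i in range(9)})
        models = fit_class_models(df, FAST_EMBEDDING)
        assert sorted(models) == [f"c{i}" for i in range(9)]

    def test_two_class_toy(self):
        df = self._frame({"a": [["p", "q"]] * 2, "b": [["r", "s"]] * 2})
        assert len(fit_class_models(df, FAST_EMBEDDING)) == 2

    def test_class_corpora_are_isolated(self):
        df = self._frame(
            {"a": [["unique_a_token", "w"]] * 3, "b": [["w", "other"]] * 3}
        )
        models = fit_class_models(df, FAST_EMBEDDING)
        assert "unique_a_token" in models["a"]
        assert "unique_a_token" not in models["b"]

    def test_class_without_narratives_is_an_error(self):
        df = pd.DataFrame({CLASS_FIELD: ["a", "b"], NARRATIVE_FIELD: ["w u", ""]})
        with pytest.raises(ValueError, match="'b'"):
            fit_class_models(df, FAST_EMBEDDING)


class TestAugmentTrainingSet:
    @pytest.fixture
    def training_frame(self, class_model):
        vocab = class_model.tokens
        rows = []
        for i in range(4):
            rows.append(("minor", " ".join(vocab[i : i + 10])))
        for i in range(10):
            rows.append(("major", " ".join(vocab[i : i + 8])))
        return pd.DataFrame(rows, columns=[CLASS_FIELD, NARRATIVE_FIELD])

    def _plan(self, class_model, **kwargs):
        defaults = dict(
            per_class_models={"minor": class_model, "major": class_model},
            classes_to_augment={"minor"},
            seed=0,
        )
        defaults.update(kwargs)
        return AugmentationPlan(**defaults)

    def test_only_target_classes_grow(self, training_frame, class_model):
        out = augment_training_set(training_frame, self._plan(class_model))
        counts = class_counts(out)
        assert counts["major"] == 10  # untouched
        assert counts["minor"] == 4 + 4 * 18  # every narrative eligible

    def test_synthetic_rows_keep_source_label_and_provenance(self, training_frame, class_model):
        out = augment_training_set(training_frame, self._plan(class_model))
        synth = out[out["provenance"] != "original"]
        assert (synth[CLASS_FIELD] == "minor").all()
        assert synth["provenance"].str.match(r"synthetic:\d+").all()

    def test_originals_all_retained(self, training_frame, class_model):
        out = augment_training_set(training_frame, self._plan(class_model))
        originals = out[out["provenance"] == "original"]
        assert len(originals) == len(training_frame)

    def test_empty_augment_set_is_identity(self, training_frame, class_model):
        out = augment_training_set(training_frame, self._plan(class_model, classes_to_augment=set()))
        assert len(out) == len(training_frame)
        assert (out[NARRATIVE_FIELD] == training_frame[NARRATIVE_FIELD]).all()

    def test_test_rows_rejected(self, training_frame, class_model):
        tagged = training_frame.assign(split=["test"] + ["train"] * (len(training_frame) - 1))
        with pytest.raises(ValueError, match="test data"):
            augment_training_set(tagged, self._plan(class_model))

    def test_per_class_cap(self, training_frame, class_model):
        out = augment_training_set(
            training_frame, self._plan(class_model, max_new_per_class=5)
        )
        assert class_counts(out)["minor"] == 4 + 5

    def test_invalid_plan_rejected(self, class_model):
        with pytest.raises(ValueError, match="n_words"):
            AugmentationPlan(per_class_models={}, classes_to_augment=set(), n_words=0)
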