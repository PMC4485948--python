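"""Move features, one-vs-all classifiers, voting, capture, persistence."""

import numpy as np
import pytest

from nephtrack.ml import (
    CLASSES,
    IDX_CORR,
    IDX_DISTANCE,
    IDX_DX,
    IDX_DY,
    IDX_IMG_DIFF,
    IDX_REL_Z,
    N_FEATURES,
    MoveClassifier,
    MoveContext,
    capture_training_examples,
    class_counts,
    classify_move,
    examples_to_dataframe,
    extract_move_features,
    load_classifier,
    save_classifier,
    split_examples,
    train_classifiers,
)
from nephtrack.tracker import TrackConfig
from tests.conftest import disk_mask, make_cross_section, make_node

from nephtrack.features import allocate_nodes, compute_shape_profile


def profiled_node(x, y, z, radius=8, stretch=1.0):
    """Node on a rasterised ellipse with its true profile attached."""
    shape = (80, 80)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = ((yy - y) / radius) ** 2 + ((xx - x) / (radius * stretch)) ** 2 <= 1
    cs = make_cross_section(mask, slice_index=z)
    node = allocate_nodes(cs, max_mean_spacing=100)[0]
    node.profile = compute_shape_profile(cs, node)
    return node


class TestFeatureExtraction:
    def test_self_move_has_zero_differences_and_unit_correlation(self):
        a = profiled_node(40, 40, 0, stretch=1.4)
        b = profiled_node(40, 40, 1, stretch=1.4)
        f = extract_move_features(a, b, MoveContext(relative_z=0.2))
        np.testing.assert_allclose(f[6:12], 0.0, atol=1e-9)
        assert f[IDX_DISTANCE] == 0.0
        assert f[IDX_CORR] == pytest.approx(1.0)
        assert f[IDX_IMG_DIFF] == 1

    def test_vector_length_is_66(self):
        a = profiled_node(40, 40, 0)
        f = extract_move_features(a, profiled_node(45, 42, 1), MoveContext(0.5, 2, (1, -2)))
        assert f.shape == (N_FEATURES,) == (66,)
        assert (f[IDX_DX], f[IDX_DY]) == (1, -2)

    def test_scaled_profile_keeps_unit_correlation_but_changes_area(self):
        a = profiled_node(40, 40, 0, radius=6, stretch=1.5)
        b = profiled_node(40, 40, 1, radius=12, stretch=1.5)
        f = extract_move_features(a, b, MoveContext(0.1))
        assert f[IDX_CORR] == pytest.approx(1.0, abs=0.05)
        assert abs(f[10]) > 0  # area difference feature

    def test_swap_flips_differences_preserves_means_distance_correlation(self):
        a = profiled_node(30, 30, 0, radius=6, stretch=1.8)
        b = profiled_node(44, 38, 1, radius=9)
        ctx = MoveContext(relative_z=0.3)
        fab = extract_move_features(a, b, ctx)
        fba = extract_move_features(b, a, ctx)
        np.testing.assert_allclose(fab[6:12], -fba[6:12], atol=1e-12)
        np.testing.assert_allclose(fab[0:6], fba[0:6], atol=1e-12)
        assert fab[IDX_DISTANCE] == fba[IDX_DISTANCE]
        assert fab[IDX_CORR] == pytest.approx(fba[IDX_CORR], abs=1e-12)

    def test_offset_corrects_distance(self):
        a = profiled_node(40, 40, 0)
        b = profiled_node(43, 38, 1)
        f = extract_move_features(a, b, MoveContext(0.1, 1, (3, -2)))
        assert f[IDX_DISTANCE] == 0.0

    def test_missing_profile_raises(self):
        a = profiled_node(40, 40, 0)
        b = profiled_node(44, 40, 1)
        b.profile = None
        with pytest.raises(ValueError, match="profile"):
            extract_move_features(a, b, MoveContext(0.1))

    def test_bad_image_difference_rejected(self):
        a = profiled_node(40, 40, 0)
        with pytest.raises(ValueError):
            extract_move_features(a, profiled_node(42, 40, 4), MoveContext(0.1, 4))


def gaussian_move_examples(n_per_class=200, seed=0):
    """Synthetic 66-feature examples with class-conditional structure.

    Valid classes carry small factor differences and high profile
    correlation; invalid classes the opposite; class 4 huge areas;
    class 5 deep relative z — mirroring what real moves look like.
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls in CLASSES:
        for _ in range(n_per_class):
            f = rng.normal(0, 0.3, N_FEATURES)
            f[IDX_IMG_DIFF] = 1
            f[IDX_REL_Z] = rng.uniform(0, 0.55)
            f[IDX_CORR] = rng.uniform(0.8, 1.0)
            if cls == 1:
                f[0] += 1.0  # high mean circularity
            elif cls == 2:
                f[3] += 3.0  # high mean aspect ratio
            elif cls == 3:
                f[6:12] += rng.normal(0, 2.5, 6)  # wild factor differences
                f[IDX_CORR] = rng.uniform(-0.5, 0.4)
            elif cls == 4:
                f[4] += 8.0  # glomerulus-sized area
            else:
                f[IDX_REL_Z] = rng.uniform(0.7, 1.0)
                f[4] -= 2.0
            X.append(f)
            y.append(cls)
    return list(zip(np.array(X), y))


class TestTraining:
    def test_split_ratios_give_exact_sizes(self):
        X = np.zeros((1000, 3))
        y = np.zeros(1000, int)
        (tr, _), (va, _), (te, _) = split_examples(X, y, (0.7, 0.15, 0.15), 0)
        assert (len(tr), len(va), len(te)) == (700, 150, 150)

    def test_split_is_a_permutation(self):
        X = np.arange(40).reshape(-1, 1).astype(float)
        y = np.arange(40)
        (Xtr, ytr), (Xva, yva), (Xte, yte) = split_examples(X, y, (0.7, 0.15, 0.15), 3)
        assert sorted(np.concatenate([ytr, yva, yte]).tolist()) == list(range(40))

    def test_separable_blobs_reach_high_accuracy(self):
        examples = gaussian_move_examples(200, seed=1)
        ann, svm, report = train_classifiers(examples, random_state=1)
        assert report["ann"]["test"]["accuracy_5class"] >= 95.0
        assert report["svm"]["test"]["accuracy_5class"] >= 95.0

    def test_duplicating_examples_keeps_decision_function(self):
        examples = gaussian_move_examples(60, seed=2)
        X = np.array([e[0] for e in examples])
        y = np.array([e[1] for e in examples])
        a = MoveClassifier("svm", random_state=0).fit(X, y)
        b = MoveClassifier("svm", random_state=0).fit(
            np.vstack([X, X]), np.concatenate([y, y])
        )
        probe = X[::7]
        np.testing.assert_allclose(a.scores(probe), b.scores(probe), atol=1e-6)

    def test_missing_class_is_named_in_error(self):
        examples = [(f, c) for f, c in gaussian_move_examples(30) if c != 4]
        X = np.array([e[0] for e in examples])
        y = np.array([e[1] for e in examples])
        with pytest.raises(ValueError, match="4"):
            MoveClassifier("ann").fit(X, y)

    def test_report_contains_confusions_and_metrics(self):
        _, _, report = train_classifiers(gaussian_move_examples(40, 3), random_state=3)
        for model in ("ann", "svm"):
            for split in ("train", "validation", "test"):
                entry = report[model][split]
                assert np.array(entry["confusion_5class"]).shape == (5, 5)
                for key in ("accuracy", "precision", "sensitivity"):
                    assert 0 <= entry[key] <= 100


@pytest.fixture(scope="module")
def fitted():
    examples = gaussian_move_examples(150, seed=4)
    ann, svm, _ = train_classifiers(examples, random_state=4)
    return ann, svm, examples


class TestVoting:

    def test_default_thresholds_and_width(self):
        assert MoveClassifier("ann").threshold == 0.3
        assert MoveClassifier("svm").rbf_width == 5.0

    def test_winning_class_drives_final_decision(self, fitted):
        ann, _, examples = fitted
        by_class = {c: next(f for f, y in examples if y == c) for c in CLASSES}
        assert classify_move(by_class[4], ann).final == "terminate"
        assert classify_move(by_class[5], ann).final == "region_signal"
        assert classify_move(by_class[3], ann).final == "invalid"
        assert classify_move(by_class[1], ann).final in ("valid", "invalid")

    def test_raising_threshold_never_accepts_more(self, fitted):
        ann, _, examples = fitted
        moves = [f for f, _ in examples[:300]]
        accepted = []
        for thr in np.linspace(0.1, 0.9, 9):
            n = sum(classify_move(f, ann, threshold=thr).final == "valid" for f in moves)
            accepted.append(n)
        assert accepted == sorted(accepted, reverse=True)

    def test_wrong_feature_length_rejected(self, fitted):
        ann, _, _ = fitted
        with pytest.raises(ValueError, match="66"):
            ann.scores(np.zeros(10))


class TestPersistence:
    def test_round_trip_is_bit_identical(self, tmp_path):
        examples = gaussian_move_examples(60, seed=5)
        ann, svm, _ = train_classifiers(examples, random_state=5)
        probe = np.array([f for f, _ in examples[::11]])
        for clf in (ann, svm):
            p = tmp_path / f"{clf.model}.joblib"
            save_classifier(clf, p)
            loaded = load_classifier(p)
            np.testing.assert_array_equal(loaded.scores(probe), clf.scores(probe))
            assert loaded.threshold == clf.threshold

    def test_layout_hash_guard(self, tmp_path):
        import joblib

        examples = gaussian_move_examples(60, seed=6)
        ann, _, _ = train_classifiers(examples, random_state=6)
        p = tmp_path / "m.joblib"
        save_classifier(ann, p)
        blob = joblib.load(p)
        blob["layout_hash"] = "different"
        joblib.dump(blob, p)
        with pytest.raises(ValueError, match="layout"):
            load_classifier(p)


class TestCapture:
    def test_pure_tube_run_yields_only_valid_classes(self, single_tube_pipeline):
        from nephtrack.phantom import make_truth_labeller

        stack, truth, binary, feats = single_tube_pipeline
        labeller = make_truth_labeller(truth)
        p0 = truth.paths[0].points[0]
        seed = feats.find_node_near(p0.x, p0.y, 0)
        examples = capture_training_examples(
            stack, feats, [seed], labeller, config=TrackConfig(tracking_radius=25.0)
        )
        assert examples
        assert {c for _, c in examples} <= {1, 2}

    def test_clutter_run_captures_abnormal_moves(self, two_tube_clutter_pipeline):
        from nephtrack.phantom import make_truth_labeller

        stack, truth, binary, feats = two_tube_clutter_pipeline
        labeller = make_truth_labeller(truth)
        seeds = [
            feats.find_node_near(t.points[0].x, t.points[0].y, 0) for t in truth.paths
        ]
        examples = capture_training_examples(
            stack, feats, [s for s in seeds if s], labeller,
            config=TrackConfig(tracking_radius=28.0), capture_all=True,
        )
        counts = class_counts(examples)
        assert counts[3] >= 1
        assert counts[1] + counts[2] >= 1

    def test_no_seeds_gives_empty_set(self, single_tube_pipeline):
        stack, truth, binary, feats = single_tube_pipeline
        assert capture_training_examples(stack, feats, [], lambda *a: 1) == []

    def test_example_dataframe_has_label_column(self):
        examples = gaussian_move_examples(5, seed=7)
        df = examples_to_dataframe(examples)
        assert df.shape == (25, 67)
        assert "label" in df.columns


@pytest.fixture(scope="module")
def phantom_trained_ann():
    from nephtrack.phantom import generate_move_dataset
    from nephtrack.ml import train_classifiers

    examples = generate_move_dataset(40, seed=9)
    ann, _, _ = train_classifiers(examples, random_state=9)
    return ann


class TestClassifierInTheLoop:
    """The trained validator steering the tracker itself."""

    def test_glomerulus_class_terminates_tracking(self, phantom_trained_ann):
        ann = phantom_trained_ann
        from nephtrack.phantom import (
            LABEL_GLOMERULUS,
            PhantomSpec,
            TubeSpec,
            generate_stack,
        )
        from nephtrack.preprocess import preprocess_stack
        from nephtrack.features import extract_features
        from nephtrack.tracker import track

        spec = PhantomSpec(
            image_size=(128, 128), n_slices=16,
            tubes=(TubeSpec(start=(64.0, 64.0), cortex_radius=8, tortuosity=0.5,
                            glomerulus=True, glomerulus_depth=6),),
            seed=15,
        )
        stack, truth = generate_stack(spec)
        feats = extract_features(preprocess_stack(stack))
        p0 = truth.paths[0].points[0]  # tube starts below the glomerulus
        seed = feats.find_node_near(p0.x, p0.y, p0.z)
        graph = track(stack, feats, seed, TrackConfig(tracking_radius=28.0),
                      classifier=ann)
        # no linked node may sit on the glomerulus blob
        for nid, node in graph.nodes.items():
            pix = node.cross_section.pixels
            vals = truth.labels[node.z][pix[:, 0], pix[:, 1]]
            assert not (vals == LABEL_GLOMERULUS).any()
        # yet the tube itself was followed downward
        assert max(n.z for n in graph.nodes.values()) == stack.n_slices - 1

    def test_region_signal_flips_unidirectional_mode(self, phantom_trained_ann):
        ann = phantom_trained_ann
        from nephtrack.phantom import PhantomSpec, TubeSpec, generate_stack
        from nephtrack.preprocess import preprocess_stack
        from nephtrack.features import extract_features
        from nephtrack.tracker import track

        spec = PhantomSpec(
            image_size=(128, 128), n_slices=30,
            tubes=(TubeSpec(start=(50.0, 55.0), cortex_radius=10, medulla_radius=4,
                            transition_slice=8, transition_steepness=0.6,
                            tortuosity=0.5),),
            seed=15,
        )
        stack, truth = generate_stack(spec)
        feats = extract_features(preprocess_stack(stack))
        p0 = truth.paths[0].points[0]
        graph = track(stack, feats, (p0.x, p0.y, 0),
                      TrackConfig(tracking_radius=28.0), classifier=ann)
        assert graph.region_signal_fired

    def test_pipeline_loads_persisted_model(self, phantom_trained_ann, tmp_path, single_tube_pipeline):
        ann = phantom_trained_ann
        from nephtrack.pipeline import RunConfig, run_pipeline

        stack, truth, binary, feats = single_tube_pipeline
        save_classifier(ann, tmp_path / "model.joblib")
        p0 = truth.paths[0].points[0]
        cfg = RunConfig(
            seeds=[(p0.x, p0.y, 0)], ml_enabled=True,
            model_path=str(tmp_path / "model.joblib"),
            tracking=TrackConfig(tracking_radius=25.0),
        )
        report = run_pipeline(cfg, stack=stack, truth_paths=truth.paths)
        entry = report["seeds"][0]
        assert entry["alpha"] >= 95.0
        assert entry["path_length"] >= 0.9 * stack.n_slices
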