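"""Unit typing, functional modules, lesions, decoding and geometry."""

import numpy as np
import pytest

from metanav import agent as ag
from metanav import synthetic, units
from metanav.logs import ActivationDataset
from metanav.synthetic import PlantedUnitSpec


def planted_dataset(seed=0, amp=1.0, noise=0.1, n_steps=600):
    specs = (
        [PlantedUnitSpec("spatial", amp, noise, quadrant=q) for q in range(4)]
        + [PlantedUnitSpec("landmark", amp, noise)] * 4
        + [PlantedUnitSpec("conjunctive", amp, noise, quadrant=q) for q in range(4)]
        + [PlantedUnitSpec("noise", 0.0, noise)] * 4
    )
    return specs, synthetic.generate_planted_activations(specs, n_steps, seed)


class TestSpatialMaps:
    def test_constant_unit_gives_flat_maps(self):
        specs = [PlantedUnitSpec("noise", 0.0, 0.0)]
        ds = synthetic.generate_planted_activations(specs, 200, seed=0)
        maps = units.unit_spatial_maps(ds, 0)
        assert np.allclose(maps, maps.flat[0])

    def test_impulse_peaks_at_source_and_decays(self):
        ds = synthetic.generate_planted_activations(
            [PlantedUnitSpec("noise", 0.0, 0.0)], 2000, seed=1
        )
        act = np.zeros(len(ds))
        act[(ds.cell[:, 0] == 3) & (ds.cell[:, 1] == 4) & (ds.env_id == 0)] = 1.0
        ds = ActivationDataset(
            activations=act[:, None], logits=ds.logits, cell=ds.cell,
            goal_cell=ds.goal_cell, env_id=ds.env_id, trial=ds.trial,
            landmark_adj=ds.landmark_adj, goal_adj=ds.goal_adj,
            post_landmark=ds.post_landmark,
        )
        m = units.unit_spatial_maps(ds, 0)[0]
        assert np.unravel_index(m.argmax(), m.shape) == (3, 4)
        assert m[3, 4] > m[3, 5] > m[3, 6]

    def test_smoothing_conserves_mean(self):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter

        field = rng.normal(0, 1, (8, 8))
        sm = gaussian_filter(field, sigma=0.7, mode="reflect")
        assert sm.mean() == pytest.approx(field.mean(), abs=1e-6)


class TestClassification:
    def test_planted_types_recovered(self):
        specs, ds = planted_dataset(seed=3, amp=1.0, noise=0.1)
        labels = units.classify_units(ds)
        for spec, lab in zip(specs, labels):
            if spec.kind == "spatial":
                assert lab.label == "spatial"
            elif spec.kind == "landmark":
                assert lab.label == "landmark"
            elif spec.kind == "conjunctive":
                assert lab.label == "conjunctive"

    def test_recovery_rate_over_seeds(self):
        """>= 95% correct labels on planted units (amplitude 2x noise s.d.)."""
        correct = total = 0
        for seed in range(10):
            specs, ds = planted_dataset(seed=seed, amp=0.2, noise=0.1, n_steps=800)
            labels = units.classify_units(ds)
            for spec, lab in zip(specs, labels):
                if spec.kind == "noise":
                    continue
                total += 1
                correct += lab.label == spec.kind
        assert correct / total >= 0.95

    def test_degenerate_unit_labelled_none(self):
        ds = synthetic.generate_planted_activations(
            [PlantedUnitSpec("noise", 0.0, 0.0)], 300, seed=0
        )
        assert units.classify_units(ds)[0].label == "none"


class TestModules:
    def test_wired_units_top_the_right_ranking(self):
        specs = (
            [PlantedUnitSpec("noise", 0.0, 0.3, wired_to="direction")] * 5
            + [PlantedUnitSpec("noise", 0.0, 0.3, wired_to="state")] * 5
            + [PlantedUnitSpec("noise", 0.0, 0.3)] * 10
        )
        ds = synthetic.generate_planted_activations(specs, 400, seed=4)
        modules = units.identify_functional_modules(ds, k=5)
        assert set(modules.vector) == set(range(5))
        assert set(modules.transition) == set(range(5, 10))
        assert set(modules.unspecialized) <= set(range(10, 20))

    def test_r2_in_unit_interval_and_k_zero(self):
        _, ds = planted_dataset(seed=5, n_steps=300)
        modules = units.identify_functional_modules(ds, k=0)
        assert len(modules.vector) == len(modules.transition) == 0
        assert ((modules.r2_direction >= 0) & (modules.r2_direction <= 1)).all()
        assert ((modules.r2_state >= 0) & (modules.r2_state <= 1)).all()

    def test_sets_disjoint_with_overlap_resolution(self):
        # one unit drives BOTH logit groups: must land in exactly one set
        specs = (
            [PlantedUnitSpec("noise", 0.0, 0.3, wired_to="direction")] * 3
            + [PlantedUnitSpec("noise", 0.0, 0.3, wired_to="state")] * 3
            + [PlantedUnitSpec("noise", 0.0, 0.3)] * 6
        )
        ds = synthetic.generate_planted_activations(specs, 400, seed=6)
        both = ds.logits.copy()
        both[:, :] += ds.activations[:, [6]]  # unit 6 drives everything
        ds = ActivationDataset(
            activations=ds.activations, logits=both, cell=ds.cell,
            goal_cell=ds.goal_cell, env_id=ds.env_id, trial=ds.trial,
            landmark_adj=ds.landmark_adj, goal_adj=ds.goal_adj,
            post_landmark=ds.post_landmark,
        )
        modules = units.identify_functional_modules(ds, k=4)
        assert len(set(modules.vector) & set(modules.transition)) == 0
        assert len(modules.vector) == len(modules.transition) == 4

    def test_k_too_large_rejected(self):
        _, ds = planted_dataset(n_steps=200)
        with pytest.raises(ValueError):
            units.identify_functional_modules(ds, k=999)


class TestLesions:
    def test_empty_lesion_bit_identical(self, tiny_trained, open_field_task):
        params, _ = tiny_trained
        a, _ = ag.evaluate(params, open_field_task, 5, 11)
        b, _ = ag.evaluate(params, open_field_task, 5, 11, lesion=np.array([], int))
        assert (a.steps["action"] == b.steps["action"]).all()
        assert (a.trials["steps_to_goal"] == b.trials["steps_to_goal"]).all()

    def test_full_lesion_makes_logits_observation_independent(self, tiny_trained, rng):
        params, _ = tiny_trained
        state = ag.init_recurrent_state(params, 1)
        full = np.arange(100)
        l1, _, s1 = ag.forward(params, rng.normal(0, 1, 48), state, lesion=full)
        l2, _, s2 = ag.forward(params, rng.normal(0, 1, 48), state, lesion=full)
        np.testing.assert_array_equal(l1, l2)
        assert not s1[0].any() and not s1[1].any()

    def test_lesion_idempotent(self, tiny_trained, rng):
        params, _ = tiny_trained
        lesioned = units.apply_lesion(params, [3, 7, 12])
        obs = rng.normal(0, 1, 48)
        state = ag.init_recurrent_state(params, 1)
        _, _, (h, c) = lesioned(obs, state)
        assert not h[:, [3, 7, 12]].any() and not c[:, [3, 7, 12]].any()
        # feeding the lesioned state back in changes nothing about the zeros
        _, _, (h2, c2) = lesioned(obs, (h, c))
        assert not h2[:, [3, 7, 12]].any() and not c2[:, [3, 7, 12]].any()

    def test_lesioned_evaluation_paired_deltas(self, tiny_trained):
        params, _ = tiny_trained
        task = ag.TaskConfig(conditions=("directions_only", "states_only"), kinds=("open",))
        out = units.evaluate_lesioned(
            params, {"none": np.array([], int)}, task, n_trials=8, seed=0
        )
        assert (out["excess_steps"] == 0).all()


def readout_dataset(seed=0, noise=0.0, n=2000):
    """Activations that contain the current location verbatim in two units."""
    rng = np.random.default_rng(seed)
    cell = rng.integers(0, 8, (n, 2))
    acts = rng.normal(0, 1, (n, 8))
    acts[:, 0] = cell[:, 1] + rng.normal(0, noise, n)  # x
    acts[:, 1] = cell[:, 0] + rng.normal(0, noise, n)  # y
    return ActivationDataset(
        activations=acts, logits=np.zeros((n, 8)), cell=cell,
        goal_cell=np.tile([3, 3], (n, 1)), env_id=np.zeros(n, int),
        trial=np.arange(n), landmark_adj=rng.random(n) < 0.3,
        goal_adj=rng.random(n) < 0.3, post_landmark=np.ones(n, bool),
    )


class TestDecoding:
    def test_linear_readout_near_zero_error(self):
        ds = readout_dataset()
        err = units.decode_continuous(ds, [0, 1], target="current")
        assert err < 0.05

    def test_noise_units_at_permutation_chance(self):
        ds = readout_dataset(seed=1)
        err = units.decode_continuous(ds, [2, 3, 4], target="current")
        rng = np.random.default_rng(2)
        null = []
        for _ in range(100):
            perm = rng.permutation(len(ds))
            shuffled = ActivationDataset(
                activations=ds.activations, logits=ds.logits,
                cell=ds.cell[perm], goal_cell=ds.goal_cell, env_id=ds.env_id,
                trial=ds.trial, landmark_adj=ds.landmark_adj,
                goal_adj=ds.goal_adj, post_landmark=ds.post_landmark,
            )
            null.append(units.decode_continuous(shuffled, [2, 3, 4], target="current"))
        lo, hi = np.percentile(null, [0.5, 99.5])
        assert lo <= err <= hi

    def test_intercept_absorbs_constant_shift(self):
        ds = readout_dataset(seed=3)
        shifted = ActivationDataset(
            activations=ds.activations + 100.0, logits=ds.logits, cell=ds.cell,
            goal_cell=ds.goal_cell, env_id=ds.env_id, trial=ds.trial,
            landmark_adj=ds.landmark_adj, goal_adj=ds.goal_adj,
            post_landmark=ds.post_landmark,
        )
        a = units.decode_continuous(ds, [0, 1])
        b = units.decode_continuous(shifted, [0, 1])
        assert a == pytest.approx(b, abs=1e-6)

    def test_binary_perfectly_separable(self):
        ds = readout_dataset(seed=4)
        acts = ds.activations.copy()
        acts[:, 5] = np.where(ds.landmark_adj, 5.0, -5.0)
        ds2 = ActivationDataset(
            activations=acts, logits=ds.logits, cell=ds.cell,
            goal_cell=ds.goal_cell, env_id=ds.env_id, trial=ds.trial,
            landmark_adj=ds.landmark_adj, goal_adj=ds.goal_adj,
            post_landmark=ds.post_landmark,
        )
        assert units.decode_binary(ds2, [5], target="landmark") == 0.0

    def test_binary_shuffled_labels_near_half(self):
        rng = np.random.default_rng(5)
        ds = readout_dataset(seed=5, n=4000)
        shuffled = ActivationDataset(
            activations=ds.activations, logits=ds.logits, cell=ds.cell,
            goal_cell=ds.goal_cell, env_id=ds.env_id, trial=ds.trial,
            landmark_adj=rng.permutation(ds.landmark_adj),
            goal_adj=ds.goal_adj, post_landmark=ds.post_landmark,
        )
        err = units.decode_binary(shuffled, [2, 3, 4], target="landmark")
        assert err == pytest.approx(0.5, abs=0.08)

    def test_decoding_error_monotone_in_snr(self):
        errs = [
            units.decode_continuous(readout_dataset(seed=6, noise=s), [0, 1])
            for s in (0.0, 0.5, 2.0)
        ]
        assert errs[0] < errs[1] < errs[2]

    def test_single_class_rejected(self):
        ds = readout_dataset(seed=7)
        ds.goal_adj[:] = True
        with pytest.raises(ValueError):
            units.decode_binary(ds, [0, 1], target="goal")


class TestGeometry:
    def test_planted_plane_concentrates_variance(self):
        rng = np.random.default_rng(8)
        n = 1500
        basis = rng.normal(0, 1, (2, 10))
        coords = rng.normal(0, 1, (n, 2))
        acts = coords @ basis + rng.normal(0, 1e-4, (n, 10))
        ds = readout_dataset(seed=8, n=n)
        ds2 = ActivationDataset(
            activations=acts, logits=np.zeros((n, 8)), cell=ds.cell,
            goal_cell=ds.goal_cell, env_id=ds.env_id, trial=ds.trial,
            landmark_adj=ds.landmark_adj, goal_adj=ds.goal_adj,
            post_landmark=ds.post_landmark,
        )
        out = units.representational_pca(ds2, list(range(10)))
        evr = out.attrs["explained_variance_ratio"]
        assert evr[:2].sum() > 0.999

    def test_centroid_table_shape_and_orthogonality(self, tiny_trained):
        params, _ = tiny_trained
        ds = units.record_activations(params, n_trials_per_env=6, seed=0,
                                      env_suite=units.ENV_SUITE[:1])
        out = units.representational_pca(ds, list(range(10)))
        assert {"r", "c", "condition", "pc1", "pc2", "pc3"} <= set(out.columns)
        from sklearn.decomposition import PCA

        X = ds.activations[:, :10]
        p = PCA(n_components=3).fit(X)
        gram = p.components_ @ p.components_.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)


class TestRecording:
    def test_four_environment_suite(self, tiny_trained):
        params, _ = tiny_trained
        ds = units.record_activations(params, n_trials_per_env=3, seed=1)
        assert set(ds.env_id) == {0, 1, 2, 3}
        assert ds.activations.shape[1] == 100

    def test_landmark_adjacency_flag_definition(self, tiny_trained):
        params, _ = tiny_trained
        ds = units.record_activations(params, n_trials_per_env=4, seed=2,
                                      env_suite=units.ENV_SUITE[:1])
        layout = units.ENV_SUITE[0]
        adj = units.landmark_adjacent_map(layout)
        expect = adj[ds.cell[:, 0], ds.cell[:, 1]]
        np.testing.assert_array_equal(ds.landmark_adj, expect)
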