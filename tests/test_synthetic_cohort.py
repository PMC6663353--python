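import numpy as np
import pytest
from scipy import stats

from ndikit.connectome_io import load_connectome, load_manifest
from ndikit.synthetic_cohort import SyntheticSpec, base_network, generate_cohort, generate_subject


class TestSpecValidation:
    def test_tier_sizes_must_sum(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_nodes=100, tier_sizes=(10, 10, 10, 10))

    def test_probability_bounds(self):
        dens = ((1.5, 0, 0, 0), (0, 0, 0, 0), (0, 0, 0, 0), (0, 0, 0, 0))
        with pytest.raises(ValueError):
            SyntheticSpec(density=dens)

    def test_tier_of_node_layout(self):
        spec = SyntheticSpec()
        t = spec.tier_of_node
        assert len(t) == 170
        assert (t == 1).sum() == 20 and (t == 4).sum() == 56


class TestGenerateSubject:
    def test_determinism(self):
        spec = SyntheticSpec(seed=3, noise_scale=0.0)
        a = generate_subject(spec, age=30, seed=9)
        b = generate_subject(spec, age=30, seed=9)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_valid_normalized_connectome(self):
        c = generate_subject(SyntheticSpec(seed=1), age=50, seed=2)
        w = c.weights
        assert w.max() == pytest.approx(1.0)
        assert np.all(w >= 0)
        np.testing.assert_array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)

    def test_realized_block_densities(self):
        dens = ((0.9, 0.2, 0.1, 0.05), (0.2, 0.3, 0.1, 0.05),
                (0.1, 0.1, 0.2, 0.05), (0.05, 0.05, 0.05, 0.1))
        spec = SyntheticSpec(seed=5, density=dens)
        w = base_network(spec)
        t = spec.tier_of_node
        core = np.flatnonzero(t == 1)
        sub = w[np.ix_(core, core)]
        realized = (sub > 0).sum() / (len(core) * (len(core) - 1))
        assert realized == pytest.approx(0.9, abs=0.05)
        outer = np.flatnonzero(t == 4)
        sub4 = w[np.ix_(outer, outer)]
        realized4 = (sub4 > 0).sum() / (len(outer) * (len(outer) - 1))
        assert realized4 == pytest.approx(0.1, abs=0.05)

    def test_core_block_is_strongest_and_densest(self):
        spec = SyntheticSpec(seed=7)
        w = base_network(spec)
        t = spec.tier_of_node
        core = np.flatnonzero(t == 1)
        outer = np.flatnonzero(t == 4)
        core_w = w[np.ix_(core, core)]
        outer_w = w[np.ix_(outer, outer)]
        assert core_w[core_w > 0].min() > (outer_w[outer_w > 0].max() if (outer_w > 0).any() else 0)
        core_density = (core_w > 0).mean()
        outer_density = (outer_w > 0).mean()
        assert core_density > outer_density

    def test_zero_age_slope_no_systematic_age_effect(self):
        # with the age trend off, per-subject mean weights are exchangeable
        # between young and old groups (subject-level two-sample test)
        spec = SyntheticSpec(seed=11, age_slope=0.0, n_nodes=85,
                             tier_sizes=(10, 25, 22, 28))
        base = base_network(spec)
        rng = np.random.default_rng(0)
        significant = 0
        runs = 40
        for r in range(runs):
            def group_means(age, n=10):
                out = []
                for _ in range(n):
                    c = generate_subject(spec, age=age, seed=int(rng.integers(2**31)), base=base)
                    out.append(c.weights[c.weights > 0].mean())
                return out
            p = stats.ttest_ind(group_means(10.0), group_means(80.0)).pvalue
            significant += int(p < 0.05)
        assert significant <= max(runs * 0.05 * 3, 6)  # near-nominal false-positive rate

    def test_positive_age_slope_strengthens_core(self):
        spec = SyntheticSpec(seed=13, age_slope=0.004, noise_scale=0.0)
        young = generate_subject(spec, age=10, seed=1)
        old = generate_subject(spec, age=80, seed=1)
        t = spec.tier_of_node
        core = np.flatnonzero(t == 1)
        rest = np.flatnonzero(t > 1)
        # after max-normalization the core/periphery weight ratio grows with age
        def ratio(c):
            cw = c.weights[np.ix_(core, core)]
            rw = c.weights[np.ix_(rest, rest)]
            return cw[cw > 0].mean() / rw[rw > 0].mean()
        assert ratio(old) > ratio(young)


class TestPlantedImportanceOrdering:
    def test_core_dominates_and_leaves_trail_in_median_ndi(self):
        # the planted core must carry the highest median dependency and the
        # outermost tier the lowest; the middle tiers' order is not fixed
        # (a sparsely-backed relay can outrank a redundant inner node)
        from ndikit.connectome_io import Connectome, default_labels
        from ndikit.ndi_core import ndi_scores

        for seed in (1, 2, 3):
            spec = SyntheticSpec(seed=seed)
            w = base_network(spec)
            w /= w.max()
            c = Connectome(w, np.array([f"n{i}" for i in range(len(w))], dtype=object),
                           default_labels(len(w)))
            s = ndi_scores(c).ndi
            medians = [np.median(s[spec.tier_of_node == t]) for t in range(1, 5)]
            assert medians[0] > max(medians[1:])
            assert medians[3] <= min(medians[1], medians[2])


class TestGenerateCohort:
    def test_manifest_spans_all_age_groups(self):
        spec = SyntheticSpec(seed=1, n_subjects=24)
        manifest, connectomes = generate_cohort(spec)
        assert len(manifest) == 24 and len(connectomes) == 24
        assert set(manifest.table["age_group"]) == {"U20", "U40", "U60", "O60"}

    def test_reproducible_from_master_seed(self):
        spec = SyntheticSpec(seed=2, n_subjects=3)
        _, a = generate_cohort(spec)
        _, b = generate_cohort(spec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.weights, y.weights)

    def test_single_subject(self):
        manifest, connectomes = generate_cohort(SyntheticSpec(seed=3, n_subjects=1))
        assert len(manifest) == 1 and len(connectomes) == 1

    def test_files_round_trip(self, tmp_path):
        spec = SyntheticSpec(seed=4, n_subjects=2)
        manifest, connectomes = generate_cohort(spec, out_dir=tmp_path)
        reloaded = load_manifest(tmp_path / "manifest.csv")
        assert len(reloaded) == 2
        for row, c in zip(reloaded.table.itertuples(), connectomes):
            on_disk = load_connectome(row.path, tmp_path / "labels.tsv")
            np.testing.assert_allclose(on_disk.weights, c.weights, atol=1e-15)
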