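"""Synthetic cohort generator: HRF, planted effects, null images, fixtures."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from voxnet import (
    HRFParams,
    PhantomSpec,
    generate_cohort,
    generate_null_metric_images,
    hrf_response,
    toy_graph,
    write_cohort,
)


class TestHRF:
    def test_no_stimuli_gives_zero_signal(self):
        np.testing.assert_array_equal(hrf_response([], 8, 2.68), np.zeros(8))

    def test_two_stimuli_sum_linearly_and_exactly(self):
        # second stimulus 5.36 s (two acquisitions) after the first
        both = hrf_response([0.0, 5.36], 8, 2.68)
        summed = hrf_response([0.0], 8, 2.68) + hrf_response([5.36], 8, 2.68)
        np.testing.assert_array_equal(both, summed)

    def test_negative_onset_rejected(self):
        with pytest.raises(ValueError):
            hrf_response([-1.0], 8, 2.68)

    def test_onset_beyond_window_rejected(self):
        with pytest.raises(ValueError):
            hrf_response([30.0], 8, 2.68)

    def test_unique_maximum_at_peak_delay_sample(self):
        # Independent evaluation of the double-gamma shape: the analytic
        # kernel peaks near peak_delay, so the sampled response to a single
        # stimulus at t=0 must peak at the acquisition closest to it.
        params = HRFParams()
        fine_t = np.linspace(0.01, 30, 20000)
        shape1 = params.peak_delay / params.dispersion + 1.0
        shape2 = params.undershoot_delay / params.dispersion + 1.0
        fine = sp_stats.gamma.pdf(fine_t, shape1, scale=params.dispersion) - (
            params.undershoot_ratio
            * sp_stats.gamma.pdf(fine_t, shape2, scale=params.dispersion)
        )
        analytic_peak_time = fine_t[np.argmax(fine)]
        tr = 2.68
        expected_sample = int(np.argmin(np.abs(np.arange(8) * tr - analytic_peak_time)))
        signal = hrf_response([0.0], 8, tr, params)
        assert int(np.argmax(signal)) == expected_sample
        assert (signal == signal.max()).sum() == 1


class TestCohortGeneration:
    def test_seeded_determinism(self, tiny_spec):
        a = generate_cohort(tiny_spec)
        b = generate_cohort(tiny_spec)
        assert len(a) == len(b) == 4
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            for va, vb in zip(sa.sessions, sb.sessions):
                np.testing.assert_array_equal(va.data, vb.data)

    def test_subject_structure(self, tiny_spec):
        cohort = generate_cohort(tiny_spec)
        subj = cohort[0]
        assert len(subj.sessions) == tiny_spec.n_sessions
        assert subj.sessions[0].grid_shape == tiny_spec.grid_shape
        assert subj.sessions[0].n_timepoints == tiny_spec.images_per_session
        assert subj.tissue_mask.grid_shape == tiny_spec.grid_shape

    @staticmethod
    def within_block_correlations(subj, block):
        data = subj.sessions[0].data[block]  # (k, t)
        corr = np.corrcoef(data)
        iu = np.triu_indices(corr.shape[0], k=1)
        return corr[iu]

    def test_zero_multiplier_matches_pure_noise(self):
        spec = PhantomSpec(
            grid_shape=(10, 10, 4),
            n_sessions=1,
            images_per_session=128,
            trials_per_session=15,
            trial_len=8,
            group_sizes={"g1": 1, "g2": 1},
            effect_table={"g1": {"posterior": 0.0, "anterior": 0.0},
                          "g2": {"posterior": 0.0, "anterior": 0.0}},
            background_amp=0.0,
            seed=3,
        )
        subj = generate_cohort(spec)[0]
        rs = self.within_block_correlations(subj, spec.region_masks()["posterior"])
        # null sampling distribution of r at t=128: SD ~ 1/sqrt(127)
        assert abs(rs.mean()) < 0.03
        assert np.quantile(np.abs(rs), 0.95) < 3.0 / np.sqrt(127)

    def test_planted_effect_monotone_in_multiplier(self):
        means = []
        for m in (0.2, 0.6, 1.0):
            vals = []
            for seed in range(20):
                spec = PhantomSpec(
                    grid_shape=(10, 10, 4),
                    n_sessions=1,
                    images_per_session=128,
                    trials_per_session=15,
                    trial_len=8,
                    group_sizes={"g1": 1, "g2": 1},
                    effect_table={"g1": {"posterior": m, "anterior": 0.0},
                                  "g2": {"posterior": m, "anterior": 0.0}},
                    seed=100 + seed,
                )
                subj = generate_cohort(spec)[0]
                rs = self.within_block_correlations(
                    subj, spec.region_masks()["posterior"]
                )
                vals.append(rs.mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_aged_posterior_correlation_below_young(self, tiny_spec):
        # 20 subjects per group, aged posterior multiplier < young
        spec = PhantomSpec(
            grid_shape=(10, 10, 4),
            n_sessions=1,
            images_per_session=128,
            trials_per_session=15,
            trial_len=8,
            group_sizes={"young": 20, "aged": 20},
            effect_table=tiny_spec.effect_table,
            seed=7,
        )
        cohort = generate_cohort(spec)
        block = spec.region_masks()["posterior"]
        by_group = {"young": [], "aged": []}
        for subj in cohort:
            rs = self.within_block_correlations(subj, block)
            by_group[subj.group_label].append(rs.mean())
        assert np.mean(by_group["aged"]) < np.mean(by_group["young"])

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(grid_shape=(1, 8, 4))

    def test_trials_must_fit_in_session(self):
        with pytest.raises(ValueError):
            PhantomSpec(images_per_session=64, trials_per_session=15, trial_len=8)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(group_sizes={"young": 5})


class TestNullMetricImages:
    def test_same_seed_identical(self):
        a1, a2 = generate_null_metric_images((3, 3), (6, 6, 3), seed=9)
        b1, b2 = generate_null_metric_images((3, 3), (6, 6, 3), seed=9)
        for x, y in zip(a1 + a2, b1 + b2):
            np.testing.assert_array_equal(x.values, y.values)

    def test_groups_share_one_generating_law(self):
        # group means agree within Monte-Carlo error over many images
        g1, g2 = generate_null_metric_images((40, 40), (8, 8, 4), seed=2)
        m1 = np.mean([img.values.mean() for img in g1])
        m2 = np.mean([img.values.mean() for img in g2])
        se = 1.0 / np.sqrt(40 * 8 * 8 * 4)
        assert abs(m1 - m2) < 4 * se

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            generate_null_metric_images((1, 3), (4, 4, 2), seed=0)


class TestToyGraphs:
    @pytest.mark.parametrize(
        "name,n,m",
        [("K5", 5, 10), ("path3", 3, 2), ("ring6", 6, 6), ("star6", 7, 6),
         ("two_components_80_20", 100, 100)],
    )
    def test_named_fixture_shapes(self, name, n, m):
        g = toy_graph(name)
        assert g.n == n and g.n_edges == m

    def test_two_component_structure(self):
        import networkx as nx

        g = toy_graph("two_components_80_20")
        sizes = sorted(len(c) for c in nx.connected_components(g.graph))
        assert sizes == [20, 80]

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            toy_graph("mystery9")


class TestSpecSerialization:
    def test_yaml_round_trip(self, tiny_spec):
        text = tiny_spec.to_yaml()
        back = PhantomSpec.from_yaml(text)
        assert back.grid_shape == tiny_spec.grid_shape
        assert back.group_sizes == tiny_spec.group_sizes
        assert back.effect_table == tiny_spec.effect_table
        np.testing.assert_allclose(back.affine, tiny_spec.affine)
        assert back.hrf == tiny_spec.hrf
        # and the round-tripped spec generates the identical cohort
        a = generate_cohort(tiny_spec)[0]
        b = generate_cohort(back)[0]
        np.testing.assert_array_equal(a.sessions[0].data, b.sessions[0].data)


class TestCohortOnDisk:
    def test_write_cohort_files_and_table(self, tmp_path, tiny_spec):
        import pandas as pd

        table_path = write_cohort(tiny_spec, tmp_path / "cohort")
        table = pd.read_csv(table_path)
        assert len(table) == sum(tiny_spec.group_sizes.values())
        assert set(table.columns) >= {"subject_id", "group", "mask", "sessions"}
        first = table.iloc[0]
        from voxnet.prep import load_bold, load_mask

        sessions = first["sessions"].split(";")
        assert len(sessions) == tiny_spec.n_sessions
        v = load_bold(sessions[0])
        assert v.grid_shape == tiny_spec.grid_shape
        assert v.tr == pytest.approx(tiny_spec.tr, abs=1e-5)
        m = load_mask(first["mask"])
        assert m.grid_shape == tiny_spec.grid_shape
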