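"""Time assignment, uniformization, normalization and the staging workflows."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from cyclestage.metrics import (
    circular_rank_correlation,
    mean_abs_circular_difference,
)
from cyclestage.simulate import SimConfig, label_with_pathology, simulate_cycle
from cyclestage.splines import CurveSet, SplineSpec
from cyclestage.staging import (
    MolecularStager,
    StagingModel,
    apply_model,
    crossvalidate_staging,
    estimate_sample_time,
    fit_whole_cycle,
    normalize_for_cycle,
    phase_of,
    reassign_proliferative,
    refit_percentage,
    stage_secretory,
    uniformize_times,
)


def _linear_model(slopes, domain=(1.0, 14.0), grid_step=0.01):
    """StagingModel whose gene curves are exact lines f_i(d) = slope_i * d,
    built from an interpolating spline through the line."""
    k = 4
    t = np.linspace(domain[0], domain[1], 9)
    spec = SplineSpec(k=k, cyclic=False, domain=domain)
    from cyclestage.splines import fit_curve_matrix

    Y = np.column_stack([s * t for s in slopes])
    cs = fit_curve_matrix(t, Y, spec, [f"g{i}" for i in range(len(slopes))], lambdas=[1e-9])
    means = pd.Series(Y.mean(axis=0), index=cs.gene_ids)
    return StagingModel(curves=cs, time_axis_kind="pod_14day", grid_step=grid_step, gene_means=means)


class TestEstimateSampleTime:
    def test_two_linear_curves_analytic_minimum(self):
        """f1(d)=d, f2(d)=2d and y=(5,10): the loss (5-d)^2 + (10-2d)^2 is
        minimized at d = 5 exactly."""
        model = _linear_model([1.0, 2.0])
        y = pd.Series([5.0, 10.0], index=["g0", "g1"], name="s1")
        res = estimate_sample_time(y, model)
        assert res["model_time"] == pytest.approx(5.0, abs=1e-6)

    def test_equals_brute_force_grid_scan(self, rng):
        """The fast vectorized argmin must agree exactly with an independent
        dense scan that evaluates the loss time point by time point."""
        for _ in range(10):
            n_genes = 20
            t_knots = np.linspace(0, 100, 12, endpoint=False)
            spec = SplineSpec(k=6, cyclic=True, domain=(0.0, 100.0))
            from cyclestage.splines import fit_curve_matrix

            Y = rng.normal(size=(12, n_genes))
            cs = fit_curve_matrix(t_knots, Y, spec, [f"g{i}" for i in range(n_genes)])
            model = StagingModel(
                curves=cs, time_axis_kind="percentage_cyclic", grid_step=0.5,
                gene_means=pd.Series(Y.mean(axis=0), index=cs.gene_ids),
            )
            y = pd.Series(rng.normal(size=n_genes), index=cs.gene_ids, name="s")
            res = estimate_sample_time(y, model)
            # independent oracle: explicit loop over the same grid
            grid = np.arange(0.0, 100.0, 0.5)
            losses = []
            for d in grid:
                pred = cs.predict([d])[0]
                losses.append(np.mean((y.to_numpy() - pred) ** 2))
            assert res["model_time"] == grid[int(np.argmin(losses))]
            assert res["min_mse"] == pytest.approx(min(losses))

    def test_flat_curves_tie_break_to_smallest_time(self):
        model = _linear_model([0.0, 0.0])
        y = pd.Series([1.0, 2.0], index=["g0", "g1"])
        with pytest.warns(UserWarning, match="tie"):
            times = model._stager().predict(y.to_frame().T)
        assert times[0] == pytest.approx(1.0)

    def test_insufficient_gene_overlap_is_error(self):
        model = _linear_model([1.0, 2.0, 3.0, 4.0, 5.0])
        y = pd.DataFrame({"g0": [5.0], "g1": [10.0]})
        with pytest.raises(ValueError, match="overlap"):
            model._stager().predict(y)

    def test_missing_genes_dropped_with_warning(self, caplog):
        model = _linear_model([1.0, 2.0, 0.5])
        y = pd.Series([5.0, 10.0], index=["g0", "g1"])
        import logging

        with caplog.at_level(logging.WARNING, logger="cyclestage.staging"):
            res = estimate_sample_time(y, model)
        assert res["model_time"] == pytest.approx(5.0, abs=1e-6)
        assert any("missing" in r.message for r in caplog.records)


class TestUniformize:
    def test_midpoint_rank_formula(self):
        assignments = pd.DataFrame(
            {"model_time": [3.0, 50.0, 10.0]},
            index=pd.Index(["A", "B", "C"], name="sample_id"),
        )
        out = uniformize_times(assignments)
        assert out.loc["A", "percentage"] == pytest.approx(100 * 0.5 / 3)
        assert out.loc["C", "percentage"] == pytest.approx(50.0)
        assert out.loc["B", "percentage"] == pytest.approx(100 * 2.5 / 3)

    def test_equally_spaced_and_order_preserving(self, rng):
        times = rng.uniform(0, 7, 40)
        assignments = pd.DataFrame(
            {"model_time": times}, index=[f"s{i:02d}" for i in range(40)]
        )
        out = uniformize_times(assignments, period=7.0)
        pct = np.sort(out["percentage"].to_numpy())
        assert np.allclose(np.diff(pct), 100.0 / 40)
        order_in = np.argsort(times)
        order_out = np.argsort(out["percentage"].to_numpy())
        assert np.array_equal(order_in, order_out)

    def test_tie_break_lexicographic(self):
        assignments = pd.DataFrame(
            {"model_time": [2.0, 2.0]}, index=pd.Index(["zz", "aa"], name="sample_id")
        )
        out = uniformize_times(assignments)
        assert out.loc["aa", "percentage"] < out.loc["zz", "percentage"]

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError, match="2 samples"):
            uniformize_times(pd.DataFrame({"model_time": [1.0]}, index=["a"]))

    def test_anchor_starts_scale_at_menstrual_cluster(self):
        # menstrual samples straddle the seam: 6.9 and 0.1 on a period-7 axis
        assignments = pd.DataFrame(
            {"model_time": [6.9, 0.1, 2.0, 4.0]},
            index=pd.Index(["m1", "m2", "p", "s"], name="sample_id"),
        )
        out = uniformize_times(assignments, period=7.0, anchor_times=[6.9, 0.1])
        assert out.loc["m1", "percentage"] < out.loc["m2", "percentage"]
        assert out.loc["m1", "percentage"] == pytest.approx(100 * 0.5 / 4)


class TestPhases:
    @pytest.mark.parametrize(
        "pct,phase",
        [
            (5.0, "menstrual"),
            (0.0, "menstrual"),
            (8.0, "proliferative"),
            (57.99, "proliferative"),
            (58.0, "secretory"),
            (99.9, "secretory"),
        ],
    )
    def test_boundaries_half_open(self, pct, phase):
        assert phase_of(pct) == phase

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            phase_of(100.0)
        with pytest.raises(ValueError):
            phase_of(-0.1)


class TestNormalize:
    def test_gene_means_preserved_and_perfect_fit_constant(self, rng):
        t = np.linspace(0, 100, 60, endpoint=False)
        spec = SplineSpec(k=8, cyclic=True, domain=(0.0, 100.0))
        from cyclestage.splines import fit_curve_matrix

        Y = np.column_stack(
            [np.sin(2 * np.pi * t / 100), rng.normal(size=60)]
        )
        cs = fit_curve_matrix(t, Y, spec, ["sine", "noise"])
        em = pd.DataFrame(cs.predict(t).T, index=["sine", "noise"], columns=[f"s{i}" for i in range(60)])
        em.loc["noise"] += rng.normal(0, 0.1, 60)
        norm = normalize_for_cycle(em, cs, pd.Series(t, index=em.columns))
        assert np.max(np.abs(norm.mean(axis=1) - em.mean(axis=1))) < 1e-10
        # the perfectly fitted row collapses to its mean
        assert np.max(np.abs(norm.loc["sine"] - em.loc["sine"].mean())) < 1e-9

    def test_idempotent_under_refit(self, rng):
        """Once the cycle component is removed, refitting curves to the
        normalized matrix and normalizing again changes (almost) nothing:
        the refit curves of cycle-free data are near-constant."""
        t = np.linspace(0, 100, 50, endpoint=False)
        em = pd.DataFrame(
            rng.normal(size=(5, 50)) + np.sin(2 * np.pi * t / 100),
            index=[f"g{i}" for i in range(5)], columns=[f"s{i}" for i in range(50)],
        )
        cs = refit_percentage(em, t, k=10)
        once = normalize_for_cycle(em, cs, t)
        twice = normalize_for_cycle(once, refit_percentage(once, t, k=10), t)
        assert np.max(np.abs(twice.to_numpy() - once.to_numpy())) < 0.05

    def test_normalized_row_is_cyclically_flat(self, benchmark):
        em, truth, _ = benchmark
        pct = truth.true_percentage
        cyc_ids = [g for g, c in zip(truth.gene_ids, truth.cyclic) if c][:30]
        sub = em.loc[cyc_ids]
        cs = refit_percentage(sub, pct, k=30)
        norm = normalize_for_cycle(sub, cs, pct)
        cs2 = refit_percentage(norm, pct, k=30)
        grid = np.linspace(0, 100, 200, endpoint=False)
        before = cs.predict(grid)
        after = cs2.predict(grid)
        amp_before = before.max(axis=0) - before.min(axis=0)
        amp_after = after.max(axis=0) - after.min(axis=0)
        assert np.median(amp_after / amp_before) < 0.1

    def test_gene_mismatch_is_error(self, rng):
        em = pd.DataFrame(rng.normal(size=(2, 30)), index=["a", "zz"],
                          columns=[f"s{i}" for i in range(30)])
        t = np.linspace(0, 100, 30, endpoint=False)
        cs = refit_percentage(em.rename(index={"zz": "b"}), t, k=5)
        with pytest.raises(ValueError, match="zz"):
            normalize_for_cycle(em, cs, t)


class TestReassignProliferative:
    @pytest.mark.parametrize("n_prolif,expected", [(9, [3, 3, 3]), (10, [4, 3, 3]), (11, [4, 4, 3])])
    def test_equal_split_with_remainder_to_earlier_groups(self, rng, n_prolif, expected):
        n_men, n_sec = 6, 6
        t = np.r_[
            np.zeros(n_men), rng.uniform(0.2, 1.8, n_prolif), np.full(n_sec, 2.0)
        ]
        stage = np.r_[np.ones(n_men), np.full(n_prolif, 3), np.full(n_sec, 5)].astype(int)
        ids = [f"s{i:02d}" for i in range(len(t))]
        genes = rng.normal(size=(60, 1)) * t[None, :] + rng.normal(0, 0.05, size=(60, len(t)))
        em = pd.DataFrame(genes, index=[f"g{i}" for i in range(60)], columns=ids)
        ann = pd.DataFrame({"stage": stage}, index=pd.Index(ids, name="sample_id"))
        out = reassign_proliferative(em, ann)
        counts = out["stage"].value_counts()
        assert [counts.get(2, 0), counts.get(3, 0), counts.get(4, 0)] == expected

    def test_groups_follow_true_time_order_noiseless(self, rng):
        t_true = np.r_[np.zeros(5), np.linspace(0.3, 1.7, 9), np.full(5, 2.0)]
        stage = np.r_[np.ones(5), np.full(9, 3), np.full(5, 5)].astype(int)
        ids = [f"s{i:02d}" for i in range(19)]
        em = pd.DataFrame(
            rng.normal(size=(40, 1)) * t_true[None, :],
            index=[f"g{i}" for i in range(40)], columns=ids,
        )
        ann = pd.DataFrame({"stage": stage}, index=pd.Index(ids, name="sample_id"))
        out = reassign_proliferative(em, ann)
        prolif = out.loc[[f"s{i:02d}" for i in range(5, 14)]]
        # stages 2/3/4 in the order of the true axis
        assert list(prolif["stage"]) == [2, 2, 2, 3, 3, 3, 4, 4, 4]

    def test_all_tied_times_is_error(self, rng):
        t = np.r_[np.zeros(4), np.ones(6), np.full(4, 2.0)]
        stage = np.r_[np.ones(4), np.full(6, 3), np.full(4, 5)].astype(int)
        ids = [f"s{i}" for i in range(14)]
        em = pd.DataFrame(np.ones((20, 14)), index=[f"g{i}" for i in range(20)], columns=ids)
        ann = pd.DataFrame({"stage": stage}, index=pd.Index(ids, name="sample_id"))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="same time"):
                reassign_proliferative(em, ann)


class TestWholeCycle:
    def test_sample_matching_curves_recovers_encoded_time(self, benchmark):
        em, truth, ann = benchmark
        from cyclestage.staging import reassign_proliferative

        model, assignments = fit_whole_cycle(em, reassign_proliferative(em, ann))
        probe = pd.DataFrame(
            model.curves.predict([3.0]).T, index=model.curves.gene_ids, columns=["probe"]
        )
        t = model.assign(probe).loc["probe", "model_time"]
        assert abs(t - 3.0) <= model.grid_step + 1e-9

    def test_recovery_of_true_times(self, benchmark):
        em, truth, ann = benchmark
        model, assignments = fit_whole_cycle(em, reassign_proliferative(em, ann))
        r = circular_rank_correlation(
            assignments["model_time"].to_numpy(), truth.true_percentage.to_numpy()
        )
        assert r >= 0.9

    def test_too_few_stages_is_error(self, rng):
        em = pd.DataFrame(rng.normal(size=(10, 8)), index=[f"g{i}" for i in range(10)],
                          columns=[f"s{i}" for i in range(8)])
        ann = pd.DataFrame({"stage": [1, 1, 1, 1, 5, 5, 5, 5]},
                           index=pd.Index(em.columns, name="sample_id"))
        with pytest.raises(ValueError, match="distinct stages"):
            fit_whole_cycle(em, ann)


class TestSecretoryModels:
    def test_pod_eligibility_and_training_time(self):
        ann = pd.DataFrame(
            {
                "stage": [5, 6, 7],
                "pod_1": [6.0, 4.0, 3.0],
                "pod_2": [7.0, 8.0, np.nan],
            },
            index=pd.Index(["a", "b", "c"], name="sample_id"),
        )
        from cyclestage.staging import _pod_training

        t = _pod_training(ann)
        # (6,7) agree within 2 -> mean 6.5; (4,8) spread 4 -> out; single call -> out
        assert list(t.index) == ["a"]
        assert t["a"] == pytest.approx(6.5)

    def test_excluded_sample_still_assigned(self, secretory_cohort):
        em, truth, ann = secretory_cohort
        model, assignments = stage_secretory(em, ann, mode="pod_14day")
        eligible = model.training_assignments["training_time"].notna()
        assert set(assignments.index) == set(em.columns)
        assert (~eligible).sum() > 0  # some samples trained nothing yet got times

    def test_pod_and_3stage_models_agree(self, secretory_cohort):
        em, truth, ann = secretory_cohort
        _, a_pod = stage_secretory(em, ann, mode="pod_14day")
        _, a_3st = stage_secretory(em, ann, mode="stage_3sec")
        r = pearsonr(a_pod["model_time"], a_3st["model_time"]).statistic
        assert r >= 0.95

    def test_too_few_training_samples_is_error(self, rng):
        em = pd.DataFrame(rng.normal(size=(20, 5)), index=[f"g{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(5)])
        ann = pd.DataFrame(
            {"stage": [5] * 5, "pod_1": [3.0] * 5, "pod_2": [4.0] * 5},
            index=pd.Index(em.columns, name="sample_id"),
        )
        with pytest.raises(ValueError, match="training"):
            stage_secretory(em, ann, mode="pod_14day")


class TestCrossValidation:
    def test_folds_partition_and_determinism(self, secretory_cohort):
        em, truth, ann = secretory_cohort
        rep1 = crossvalidate_staging(em.iloc[:150], ann, K=3, seed=5)
        rep2 = crossvalidate_staging(em.iloc[:150], ann, K=3, seed=5)
        all_samples = [s for f in rep1["folds"] for s in f]
        assert len(all_samples) == len(set(all_samples)) == rep1["n_training"]
        assert rep1["folds"] == rep2["folds"]
        assert rep1["pooled_heldout_r"] == rep2["pooled_heldout_r"]

    def test_heldout_tracks_in_sample(self, secretory_cohort):
        em, truth, ann = secretory_cohort
        rep = crossvalidate_staging(em, ann, K=5, seed=1)
        assert rep["pooled_heldout_r"] >= 0.9
        assert abs(rep["in_sample_r"] - rep["pooled_heldout_r"]) < 0.1


class TestApplyModel:
    def test_self_application_reproduces_percentages(self, benchmark_pipeline):
        result = benchmark_pipeline
        model = result.percentage_model
        pct = result.assignments["percentage"]
        # noiseless matrix generated from the model's own curves
        em0 = pd.DataFrame(
            model.curves.predict(pct.to_numpy()).T,
            index=model.curves.gene_ids, columns=pct.index,
        )
        out = apply_model(model, em0)
        assert mean_abs_circular_difference(out["percentage"], pct) < model.grid_step

    def test_constant_per_gene_shift_invariance(self, benchmark_pipeline, benchmark, rng):
        em, truth, _ = benchmark
        model = benchmark_pipeline.percentage_model
        shift = pd.Series(rng.normal(0, 3, em.shape[0]), index=em.index)
        base = apply_model(model, em)
        shifted = apply_model(model, em.add(shift, axis=0))
        assert np.array_equal(base["model_time"].to_numpy(), shifted["model_time"].to_numpy())

    def test_cross_platform_offsets_recovered(self, benchmark, benchmark_pipeline):
        em, truth, _ = benchmark
        model = benchmark_pipeline.percentage_model
        rng = np.random.default_rng(77)
        # platform B: same biology, per-gene offsets, fresh noise
        offsets = rng.normal(0, 2.0, em.shape[0])
        mean = truth.mean_expression(truth.true_percentage.to_numpy())
        emB = pd.DataFrame(
            mean + offsets[:, None] + rng.normal(0, 0.5, em.shape),
            index=em.index, columns=[f"B{i}" for i in range(em.shape[1])],
        )
        out = apply_model(model, emB)
        r = circular_rank_correlation(out["percentage"].to_numpy(), truth.true_percentage.to_numpy())
        assert r >= 0.95

    def test_low_coverage_is_error(self, benchmark_pipeline, rng):
        model = benchmark_pipeline.percentage_model
        few = model.curves.gene_ids[:100]
        em = pd.DataFrame(rng.normal(size=(100, 4)), index=few, columns=list("wxyz"))
        with pytest.raises(ValueError, match="coverage"):
            apply_model(model, em)
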