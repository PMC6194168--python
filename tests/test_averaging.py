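"""Averaging-model prediction, fitting, selection, GOF and importance."""

import itertools

import numpy as np
import pytest

import funcmeas as fm
from funcmeas.averaging import (
    AveragingModel,
    AveragingParams,
    predict_eam,
    relative_importance,
    select_model,
)
from funcmeas.design import ABSENT, DesignError


def eam_params(w0=1.0, s0=0.0, wa=1.0, wt=1.0, sa=None, st=None):
    return AveragingParams(
        w0=w0, s0=s0, w_audio=wa, w_tactile=wt,
        s_audio=list(sa if sa is not None else [60.0] * 5),
        s_tactile=list(st if st is not None else [-60.0] * 3),
    )


class TestPredictEam:
    def test_symmetry_cancels(self, design):
        p = eam_params(sa=[60.0] * 5, st=[-60.0] * 3)
        assert predict_eam(p, ("AS0", "TS_ME"), design) == pytest.approx(0.0)

    def test_set_size_attenuation(self, design):
        p = eam_params(sa=[60.0] * 5, st=[-60.0] * 3)
        # audio-only: (1*0 + 1*60) / (1 + 1)
        assert predict_eam(p, ("AS0", ABSENT), design) == pytest.approx(30.0)

    def test_weight_zero_reduces_to_unimodal(self, design):
        p0 = eam_params(wt=0.0)
        bi = predict_eam(p0, ("AS+50", "TS_HI"), design)
        uni = predict_eam(p0, ("AS+50", ABSENT), design)
        assert bi == pytest.approx(uni)

    def test_invalid_cell_rejected(self, design):
        with pytest.raises(DesignError):
            predict_eam(eam_params(), ("AS0", "T9"), design)


def grid_search_sse(cell_means, design, wa_grid, wt_grid):
    """Independent oracle: direct prediction formula + plain lstsq per weight pair.

    Builds the linear system for (s0, s-values) straight from the averaging
    equation, never touching the fitter's internals.  Returns (best sse,
    best (wa, wt)).
    """
    cells = design.cells()
    y = np.array([cell_means[c] for c in cells])
    na, nt = len(design.audio_codes), len(design.tactile_codes)
    best, best_w = np.inf, None
    for wa, wt in itertools.product(wa_grid, wt_grid):
        X = np.zeros((len(cells), 1 + na + nt))
        for r, (a, t) in enumerate(cells):
            den = 1.0
            den += wa if a != ABSENT else 0.0
            den += wt if t != ABSENT else 0.0
            X[r, 0] = 1.0 / den
            if a != ABSENT:
                X[r, 1 + design.audio_codes.index(a)] = wa / den
            if t != ABSENT:
                X[r, 1 + na + design.tactile_codes.index(t)] = wt / den
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        beta = np.clip(beta, -AveragingModel.SCALE_BOUND, AveragingModel.SCALE_BOUND)
        sse = float(((y - X @ beta) ** 2).sum())
        if sse < best:
            best, best_w = sse, (wa, wt)
    return best, best_w


class TestFitEam:
    def test_noiseless_recovery(self, design, noiseless_cohort, noiseless_table):
        for subject in noiseless_table.subjects[:3]:
            truth = noiseless_cohort.truth[subject]
            res = AveragingModel(
                noiseless_table.subject_cell_means(subject), design).fit(seed=0)
            assert res.sse < 1e-8
            assert res.params.w_audio == pytest.approx(truth.weight_audio, abs=1e-4)
            assert res.params.w_tactile == pytest.approx(truth.weight_tactile, abs=1e-4)
            np.testing.assert_allclose(res.params.s_audio, truth.scale_audio, atol=1e-4)
            np.testing.assert_allclose(res.params.s_tactile, truth.scale_tactile, atol=1e-4)

    def test_weight_ratio_three_recovered(self, design):
        p = eam_params(wa=1.5, wt=0.5, sa=[-80, -40, 0, 40, 80], st=[60, 0, -70])
        cm = {c: predict_eam(p, c, design) for c in design.cells()}
        res = AveragingModel(cm, design).fit(seed=3)
        assert res.weight_ratio == pytest.approx(3.0, abs=1e-3)

    def test_matches_grid_search_oracle(self, small_design, rng):
        p = AveragingParams(w0=1.0, s0=5.0, w_audio=1.2, w_tactile=0.7,
                            s_audio=[-50.0, 40.0], s_tactile=[30.0, -20.0])
        cm = {c: predict_eam(p, c, small_design) + rng.normal(0, 3)
              for c in small_design.cells()}
        res = AveragingModel(cm, small_design).fit(seed=0, n_restarts=20)
        # coarse lattice, then a refined lattice around the coarse optimum
        coarse = np.linspace(0.05, 5.0, 60)
        sse_c, (wa_c, wt_c) = grid_search_sse(cm, small_design, coarse, coarse)
        step = coarse[1] - coarse[0]
        fine_a = np.linspace(max(0.01, wa_c - step), wa_c + step, 41)
        fine_t = np.linspace(max(0.01, wt_c - step), wt_c + step, 41)
        sse_f, _ = grid_search_sse(cm, small_design, fine_a, fine_t)
        oracle = min(sse_c, sse_f)
        assert res.sse <= oracle + 1e-6

    def test_all_constant_data_degenerate(self, design):
        cm = {c: 12.0 for c in design.cells()}
        res = AveragingModel(cm, design).fit(seed=0)
        assert res.degenerate
        assert not res.converged

    def test_incomplete_cells_rejected(self, design, noiseless_table):
        cm = noiseless_table.subject_cell_means("S01")
        cm.pop(("AS0", "TS_ME"))
        with pytest.raises(DesignError, match="incomplete"):
            AveragingModel(cm, design)

    def test_margins_required(self):
        d = fm.build_design(["A1", "A2"], ["T1", "T2"], reps=1, unimodal_audio=False)
        with pytest.raises(DesignError, match="unimodal margins"):
            AveragingModel({c: 0.0 for c in d.cells()}, d)

    def test_identification_invariance(self, design, noiseless_table):
        """Weight ratios and importances do not depend on the w0 constant."""
        cm = noiseless_table.subject_cell_means("S02")
        r1 = AveragingModel(cm, design, w0=1.0).fit(seed=0)
        r2 = AveragingModel(cm, design, w0=2.5).fit(seed=0)
        assert r1.weight_ratio == pytest.approx(r2.weight_ratio, rel=1e-3)
        i1, i2 = r1.importance(), r2.importance()
        for k in i1.entries:
            assert i1.entries[k] == pytest.approx(i2.entries[k], abs=1e-3)


class TestFitDam:
    def test_dam_on_eam_data_has_equal_level_weights(self, design, noiseless_table):
        cm = noiseless_table.subject_cell_means("S01")
        res = AveragingModel(cm, design, variant="differential").fit(seed=0)
        assert np.ptp(res.params.w_audio) < 1e-3
        assert np.ptp(res.params.w_tactile) < 1e-3

    def test_nesting_inequality(self, design, noisy_table):
        cm = noisy_table.subject_cell_means("S03")
        sse_eam = AveragingModel(cm, design, "equal").fit(seed=1, n_restarts=10).sse
        sse_dam = AveragingModel(cm, design, "differential").fit(seed=1, n_restarts=10).sse
        assert sse_dam <= sse_eam + 1e-6

    def test_single_level_factor_rejected(self):
        d = fm.build_design(["A1", "A2"], ["T1"], reps=1)
        with pytest.raises(DesignError):
            AveragingModel({c: 0.0 for c in d.cells()}, d, variant="differential")


class TestSelectModel:
    def test_single_candidate_identity(self, design, noisy_table):
        res = AveragingModel(noisy_table.subject_cell_means("S01"), design).fit(seed=0)
        assert select_model([res]) is res

    def test_tie_broken_toward_fewer_params(self, design, noiseless_table):
        # noiseless: both sse under the BIC floor -> tie -> EAM wins
        cm = noiseless_table.subject_cell_means("S01")
        r_e = AveragingModel(cm, design, "equal").fit(seed=0)
        r_d = AveragingModel(cm, design, "differential").fit(seed=0)
        assert select_model([r_e, r_d]).model.variant == "equal"

    def test_mismatched_data_rejected(self, design, noisy_table):
        r1 = AveragingModel(noisy_table.subject_cell_means("S01"), design).fit(seed=0)
        r2 = AveragingModel(noisy_table.subject_cell_means("S02"), design).fit(seed=0)
        with pytest.raises(ValueError):
            select_model([r1, r2])

    def test_eam_selected_majority_under_eam_truth(self, design):
        """Cell-mean BIC prefers the true equal-weight model in most subjects."""
        co = fm.simulate_cohort(fm.make_paper_like_config(seed=11, n_subjects=30, noise_sd=2.0))
        table = fm.cell_means(co.records, design)
        wins = 0
        for s in table.subjects:
            cm = table.subject_cell_means(s)
            r_e = AveragingModel(cm, design, "equal").fit(seed=0, n_restarts=10)
            r_d = AveragingModel(cm, design, "differential").fit(seed=0, n_restarts=10)
            wins += select_model([r_e, r_d]).model.variant == "equal"
        assert wins >= 18  # clear majority; measured rate ~0.67-0.82 across seeds

    def test_bic_selection_toward_noiseless_limit(self):
        """The information-rich (many-reps, vanishing-noise) endpoint selects the
        true equal-weight model for every subject, and dominates the noisy end.

        The cell-mean BIC compares a fixed 23-cell table, so the selection rate
        is statistically flat in the number of repetitions at fixed nonzero
        noise (the sse ratio of nested fits is scale-free); consistency shows
        up only as the noiseless limit is approached.
        """
        rates = []
        for reps, noise in ((6, 3.0), (60, 1.0), (600, 0.0)):
            d = fm.build_design(reps=reps)
            comp = fm.PopulationComponent(
                proportion=1.0, rule="averaging_equal_weight", w0=1.0,
                s0_mean=0.0, s0_sd=0.0, weight_audio_mean=1.5, weight_audio_sd=0.1,
                weight_tactile_mean=0.5, weight_tactile_sd=0.05,
                scale_audio_mean=[-90.0, -45.0, 0.0, 45.0, 90.0],
                scale_tactile_mean=[70.0, 0.0, -80.0], scale_sd=5.0, noise_sd=noise)
            cfg = fm.SimulationConfig(n_subjects=8, design=d, population=[comp], seed=21)
            table = fm.cell_means(fm.simulate_cohort(cfg).records, d)
            wins = 0
            for s in table.subjects:
                cm = table.subject_cell_means(s)
                r_e = AveragingModel(cm, d, "equal").fit(seed=0, n_restarts=8)
                r_d = AveragingModel(cm, d, "differential").fit(seed=0, n_restarts=8)
                wins += select_model([r_e, r_d]).model.variant == "equal"
            rates.append(wins / 8)
        assert rates[-1] == 1.0
        assert rates[-1] >= max(rates)


class TestResidualGof:
    def test_perfect_fit_zero_residuals(self, design, noiseless_table):
        from funcmeas.design import CellMeansTable
        sub = CellMeansTable(
            design=design,
            means=noiseless_table.means[
                noiseless_table.means["subject"].isin(noiseless_table.subjects[:4])
            ],
        )
        fits = fm.fit_cohort(sub, seed=0)
        gof = fm.residual_gof(fits, sub)
        for results in gof.values():
            for r in results:
                assert r.degenerate or r.F == pytest.approx(0.0, abs=1e-6)

    def test_adding_misfit_detected(self, design):
        """EAM force-fitted to an adding cohort leaves significant residual structure."""
        co = fm.simulate_cohort(
            fm.make_paper_like_config(seed=801, n_subjects=17, noise_sd=2.0, rule="adding"))
        table = fm.cell_means(co.records, design)
        fits = fm.fit_cohort(table, seed=0, n_restarts=10)
        gof = fm.residual_gof(fits, table)
        assert any(r.significant(0.05) for rs in gof.values() for r in rs)


class TestImportance:
    def test_hand_profile(self):
        prof = relative_importance(eam_params(wa=2.0, wt=1.0))
        assert prof.entries == pytest.approx({"w0": 0.25, "audio": 0.5, "tactile": 0.25})

    def test_scale_invariance(self):
        p1 = eam_params(wa=2.0, wt=1.0)
        p10 = eam_params(w0=10.0, wa=20.0, wt=10.0)
        assert relative_importance(p1).entries == pytest.approx(
            relative_importance(p10).entries)

    def test_zero_weight_zero_importance(self):
        prof = relative_importance(eam_params(wt=0.0))
        assert prof.entries["tactile"] == 0.0
        assert sum(prof.entries.values()) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_importance(eam_params(w0=0.0, wa=0.0, wt=0.0))


def test_scale_indeterminacy_of_predictions(design):
    """Scaling all weights (incl. w0) by c > 0 leaves every prediction unchanged."""
    p = eam_params(wa=1.3, wt=0.6, sa=[-80, -40, 0, 40, 80], st=[50, 0, -60])
    p_scaled = AveragingParams(
        w0=3.0 * p.w0, s0=p.s0, w_audio=3.0 * p.w_audio, w_tactile=3.0 * p.w_tactile,
        s_audio=p.s_audio, s_tactile=p.s_tactile)
    for cell in design.cells():
        assert predict_eam(p, cell, design) == pytest.approx(
            predict_eam(p_scaled, cell, design))
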