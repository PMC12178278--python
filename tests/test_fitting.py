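"""Block concatenation and the coarse-to-fine pSFT estimation pipeline."""

import numpy as np
import pytest
from sklearn.base import clone

from psft.design import (
    BLANK_SF,
    build_probe_sf_sequence,
    build_run_design,
    build_session_schedule,
)
from psft.fitting import (
    PSFTRegressor,
    _best_cell,
    coarse_grid_search,
    concatenate_condition_blocks,
    fine_grid_search,
    fit_psft,
    percent_signal_change,
    r_squared,
)
from psft.model import MU_BOUNDS, SIGMA_BOUNDS, PSFTParams, predict_bold


class TestConcatenation:
    def test_nine_runs_give_18_spliced_blocks(self):
        runs = build_session_schedule(9, seed=0)
        seqs = [build_probe_sf_sequence(r, seed=i) for i, r in enumerate(runs)]
        sp = concatenate_condition_blocks(
            [(None, r, s) for r, s in zip(runs, seqs)], "AttendLSF"
        )
        assert sp.n_blocks == 18
        assert len(sp.boundaries) == 18

    def test_single_block_length(self):
        d = build_run_design(n_blocks=1, block_s=40.5, blank_s=10, initial_blank_s=0,
                             conditions=("A",))
        s = build_probe_sf_sequence(d, seed=0)
        sp = concatenate_condition_blocks([(None, d, s)], "A")
        assert sp.sf_per_tr.size == 51  # ceil(40.5 + 10)

    def test_round_trip(self, session_runs, rng):
        runs, seqs = session_runs
        series = [rng.normal(size=r.n_trs) for r in runs]
        sp = concatenate_condition_blocks(list(zip(series, runs, seqs)), "AttendHSF")
        blocks = sp.split_blocks()
        assert len(blocks) == sp.n_blocks
        i = 0
        for run, y in zip(runs, series):
            for b in run.condition_blocks("AttendHSF"):
                assert np.array_equal(blocks[i], y[run.block_tr_slice(b)])
                i += 1

    def test_absent_condition_rejected(self, session_runs):
        runs, seqs = session_runs
        with pytest.raises(ValueError, match="absent"):
            concatenate_condition_blocks([(None, runs[0], seqs[0])], "NoSuch")


class TestGrids:
    def test_grid_shapes_and_endpoints(self, spliced_baseline, kernel, rng):
        y = rng.normal(size=spliced_baseline.sf_per_tr.size)
        c = coarse_grid_search(y, spliced_baseline.sf_per_tr, kernel)
        assert c.sse_surface.shape == (10, 10)
        assert c.mu_grid[0] == pytest.approx(0.009)
        assert c.mu_grid[-1] == pytest.approx(6.0)
        assert c.sigma_grid[0] == pytest.approx(0.1)
        assert c.sigma_grid[-1] == pytest.approx(4.0)
        f = fine_grid_search(y, spliced_baseline.sf_per_tr, c, kernel)
        assert f.sse_surface.shape == (100, 100)

    def test_coarse_recovers_its_own_node(self, spliced_baseline, kernel):
        mus = np.logspace(np.log10(MU_BOUNDS[0]), np.log10(MU_BOUNDS[1]), 10)
        sigmas = np.linspace(*SIGMA_BOUNDS, 10)
        truth = PSFTParams(mus[4], sigmas[3], 1.0, 0.0)  # beta/beta0 as fixed in grid
        y = predict_bold(spliced_baseline.sf_per_tr, truth, kernel=kernel)
        c = coarse_grid_search(y, spliced_baseline.sf_per_tr, kernel)
        assert c.mu == pytest.approx(mus[4])
        assert c.sigma == pytest.approx(sigmas[3])
        assert c.sse == pytest.approx(0.0, abs=1e-18)

    def test_tied_minima_are_averaged(self):
        mus = np.array([0.5, 1.0, 2.0])
        sigmas = np.array([1.0, 3.0])
        sse = np.array([[9.0, 9.0], [5.0, 9.0], [5.0 + 1e-15, 9.0]])
        mu, sigma, _ = _best_cell(mus, sigmas, sse)
        assert mu == pytest.approx(1.5)  # exact-tie average after rounding
        assert sigma == pytest.approx(1.0)

    def test_fine_not_worse_than_coarse_inside_span(self, spliced_baseline, kernel, rng):
        y = rng.normal(size=spliced_baseline.sf_per_tr.size)
        c = coarse_grid_search(y, spliced_baseline.sf_per_tr, kernel)
        f = fine_grid_search(y, spliced_baseline.sf_per_tr, c, kernel)
        assert f.sse <= c.sse * (1 + 1e-9)


class TestFit:
    def test_noiseless_recovery(self, spliced_baseline, kernel):
        truth = PSFTParams(0.8, 1.4, 1.1, -0.2)
        sf = spliced_baseline.sf_per_tr
        y = predict_bold(sf, truth, kernel=kernel)
        est = PSFTRegressor().fit(sf, y)
        assert est.mu_ == pytest.approx(truth.mu, rel=1e-2)
        assert est.sigma_ == pytest.approx(truth.sigma, rel=2e-2)
        assert est.r2_ == pytest.approx(100.0, abs=1e-6)

    def test_fit_never_worse_than_init(self, spliced_baseline, kernel, rng):
        sf = spliced_baseline.sf_per_tr
        y = predict_bold(sf, PSFTParams(2.0, 0.5, 1.0, 0.0), kernel=kernel)
        y = y + rng.normal(0, 0.5, y.size)
        init = PSFTParams(0.05, 3.5)  # deliberately poor start
        fit = fit_psft(y, sf, init, kernel)
        init_sse = np.sum((y - predict_bold(sf, init, kernel=kernel)) ** 2)
        assert fit.sse <= init_sse + 1e-9
        assert fit.params.in_bounds()

    def test_constant_series(self, spliced_baseline, kernel):
        sf = spliced_baseline.sf_per_tr
        y = np.full(sf.size, 3.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_psft(y, sf, PSFTParams(1.0, 1.0), kernel)
        assert fit.sse < 1e-10  # beta ~ 0, beta0 ~ 3 reproduces the flat series
        assert fit.r2 == 0.0

    def test_out_of_bounds_init_rejected(self, spliced_baseline, kernel):
        with pytest.raises(ValueError, match="bounds"):
            fit_psft(np.zeros(spliced_baseline.sf_per_tr.size),
                     spliced_baseline.sf_per_tr, PSFTParams(10.0, 1.0), kernel)

    def test_deterministic(self, spliced_baseline, kernel, rng):
        sf = spliced_baseline.sf_per_tr
        y = predict_bold(sf, PSFTParams(1.5, 1.0, 1.0, 0.0), kernel=kernel)
        y = y + rng.normal(0, 0.4, y.size)
        a = PSFTRegressor().fit(sf, y)
        b = PSFTRegressor().fit(sf, y)
        assert (a.mu_, a.sigma_, a.beta_, a.beta0_) == (b.mu_, b.sigma_, b.beta_, b.beta0_)


class TestRegressorAPI:
    def test_sklearn_protocol(self, spliced_baseline, kernel):
        est = PSFTRegressor(tol=1e-8)
        assert clone(est).get_params()["tol"] == 1e-8
        sf = spliced_baseline.sf_per_tr
        y = predict_bold(sf, PSFTParams(1.0, 1.0, 1.0, 0.1), kernel=kernel)
        est.fit(sf.reshape(-1, 1), y)  # column-vector input accepted
        pred = est.predict(sf)
        assert r_squared(pred, y) == pytest.approx(100.0, abs=1e-6)
        res = est.fit_result(voxel_id=7, condition="AttendLSF")
        assert res.voxel_id == 7 and res.condition == "AttendLSF"

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            PSFTRegressor().fit(np.ones((5, 2)), np.ones(5))
        with pytest.raises(ValueError):
            PSFTRegressor().fit(np.ones(5), np.ones(6))
        with pytest.raises(Exception):
            PSFTRegressor().predict(np.ones(5))  # not fitted


class TestHelpers:
    def test_r_squared_conventions(self, rng):
        y = rng.normal(size=50)
        assert r_squared(y, y) == pytest.approx(100.0)
        assert r_squared(np.full(50, y.mean()), y) == pytest.approx(0.0)
        assert r_squared(np.full(50, y.mean() + 10), y) < 0

    def test_percent_signal_change(self):
        x = np.array([100.0, 100.0, 110.0, 90.0])
        blank = np.array([True, True, False, False])
        psc = percent_signal_change(x, blank)
        assert np.allclose(psc, [0, 0, 10, -10])
        assert np.allclose(percent_signal_change(x), 100 * (x - 100) / 100)
        with pytest.raises(ValueError):
            percent_signal_change(np.array([1.0, -1.0]))
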