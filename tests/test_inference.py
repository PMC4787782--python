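"""Hysteresis histograms, model binning, rmse and the global fit."""

import numpy as np
import pandas as pd
import pytest

from hairpinfs import (build_hysteresis_histogram, global_fit,
                       model_histogram, rmse)
from hairpinfs.constants import thermal_energy
from hairpinfs.errors import DomainError, EmptyDataError
from hairpinfs.inference import HysteresisHistogram, _batched_bin_weights
from hairpinfs.simulate import generate_event_tables, loading_rate_pn_s
from hairpinfs import datasets as ds


def _events(rows):
    return pd.DataFrame(rows, columns=["molecule_id", "speed_nm_s", "cycle",
                                       "F_unfold_pN", "F_fold_pN"])


class TestBuildHistogram:
    def test_single_molecule_single_pair(self):
        ev = _events([(0, 50.0, 0, 7.0, 5.0)])
        hist = build_hysteresis_histogram(ev, 50.0)
        assert hist.weights.sum() == pytest.approx(1.0)
        centers = 0.5 * (hist.bin_edges_pn[:-1] + hist.bin_edges_pn[1:])
        assert centers[np.argmax(hist.weights)] == pytest.approx(2.0, abs=0.5)

    def test_cycle_weighting_hand_computed(self):
        # molecule 0: 10 cycles, one (u, f) pair; molecule 1: 1 cycle, one pair
        rows = [(0, 50.0, c, 8.0 if c == 0 else np.nan,
                 6.0 if c == 0 else np.nan) for c in range(10)]
        rows += [(1, 50.0, 0, 7.0, 7.0)]
        hist = build_hysteresis_histogram(_events(rows), 50.0)
        # molecule 0's single pair carries weight 10/11, molecule 1's 1/11;
        # delta = 2.0 falls in the last bin (rightmost edge inclusive),
        # delta = 0.0 in the first
        assert hist.weights[-1] == pytest.approx(10.0 / 11.0)
        assert hist.weights[0] == pytest.approx(1.0 / 11.0)

    def test_alternative_weightings(self):
        rows = [(0, 50.0, 0, 8.0, 6.0), (0, 50.0, 1, 8.5, 6.5),
                (1, 50.0, 0, 7.0, 7.0)]
        ev = _events(rows)
        for strategy in ("cycles", "pair", "molecule"):
            hist = build_hysteresis_histogram(ev, 50.0, weighting=strategy)
            assert hist.weights.sum() == pytest.approx(1.0)
        by_pair = build_hysteresis_histogram(ev, 50.0, weighting="pair")
        # molecule 0 contributes 4 of 5 equally-weighted pairs
        assert by_pair.weights.max() <= 0.8 + 1e-9

    def test_no_valid_pairs_raises(self):
        ev = _events([(0, 50.0, 0, 7.0, np.nan)])
        with pytest.raises(EmptyDataError):
            build_hysteresis_histogram(ev, 50.0)


class TestRmse:
    def test_identical_vectors_give_zero(self):
        assert rmse(np.array([0.2, 0.8]), np.array([0.2, 0.8])) == 0.0

    def test_hand_computed_value(self):
        assert rmse(np.array([0.5, 0.5]), np.array([0.3, 0.7])) == \
            pytest.approx(0.2)

    def test_scale_equivariance(self):
        x, y = np.array([0.1, 0.4, 0.5]), np.array([0.2, 0.3, 0.5])
        assert rmse(3 * x, 3 * y) == pytest.approx(3 * rmse(x, y))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError, match="mismatch"):
            rmse(np.array([1.0]), np.array([1.0, 2.0]))


class TestModelHistogram:
    def test_bin_refinement_recovers_density_pointwise(self, rna10_params):
        from hairpinfs import RampSpec, hysteresis_density, ramp_density

        keff, v = 0.06, 150.0
        coarse = model_histogram(rna10_params, v, keff,
                                 np.arange(-5.0, 15.0, 0.5), f_max_pn=25.0)
        fine_edges = np.arange(3.0, 9.0, 0.05)
        fine = model_histogram(rna10_params, v, keff, fine_edges, f_max_pn=25.0)
        s = ramp_density(rna10_params, RampSpec(keff * v, 0, 25.0, "stretch"))
        r = ramp_density(rna10_params, RampSpec(keff * v, 0, 25.0, "release"))
        h = hysteresis_density(s, r)
        centers = 0.5 * (fine_edges[:-1] + fine_edges[1:])
        density_est = fine / 0.05 * np.trapezoid(
            np.interp(centers, h.grid_pn, h.density_per_pn) * 0.05)
        expected = np.interp(centers, h.grid_pn, h.density_per_pn)
        assert np.max(np.abs(density_est - expected)) < 0.02 * expected.max() + 1e-4
        assert coarse.sum() == pytest.approx(1.0)

    def test_mean_increases_with_speed_and_decreases_with_k0(self, rna10_params):
        edges = np.arange(-5.0, 20.0, 0.5)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def mean_delta(params, speed):
            w = model_histogram(params, speed, 0.06, edges, f_max_pn=25.0)
            return float((w * centers).sum())

        means_v = [mean_delta(rna10_params, v) for v in (50, 150, 300, 450)]
        assert all(a < b for a, b in zip(means_v, means_v[1:]))

        from hairpinfs import TwoStateParams
        means_k = []
        for k0 in (4e-6, 4e-5, 4e-4):
            p = TwoStateParams(17.7, 3.0, 121.0, k0)
            means_k.append(mean_delta(p, 150.0))
        assert all(a > b for a, b in zip(means_k, means_k[1:]))

    def test_batched_weights_match_single_path(self, rna10_params):
        edges = np.arange(-5.0, 20.0, 0.5)
        single = model_histogram(rna10_params, 150.0, 0.06, edges,
                                 f_max_pn=25.0)
        batched = _batched_bin_weights(
            rna10_params.x_fwd_nm, np.array([rna10_params.k0_per_s]),
            rna10_params.L_nm, rna10_params.dG_pn_nm(), 0.06 * 150.0,
            edges, 0.0, 25.0, 0.01, thermal_energy())[0]
        assert np.max(np.abs(single - batched)) < 1e-9


class TestGlobalFit:
    def test_exact_recovery_on_model_generated_histograms(self, rna10_params):
        rec = ds.PUBLISHED["RNA10"]
        keff = {v: 0.06 for v in (50.0, 150.0, 300.0, 450.0)}
        edges = 0.5 * np.arange(-10, 51)
        hists = []
        for v in keff:
            w = model_histogram(rna10_params, v, keff[v], edges, f_max_pn=25.0)
            hists.append(HysteresisHistogram(v, edges, w / w.sum(), 10, 100))
        fit = global_fit(hists, rec.transition_length_nm,
                         rec.dG_total_kj_mol, keff, f_max_pn=25.0)
        assert fit.x_fwd_hat_nm == pytest.approx(rna10_params.x_fwd_nm,
                                                 abs=0.02)
        assert fit.k0_hat_per_s == pytest.approx(rna10_params.k0_per_s,
                                                 rel=0.05)
        assert not fit.boundary_warning
        assert fit.x_fwd_interval_nm[0] <= fit.x_fwd_hat_nm \
            <= fit.x_fwd_interval_nm[1]
        assert fit.rmse_total < 1e-4

    def test_recovery_from_simulated_events_single_seed(self):
        # one study-scale replicate: estimate lands near the generating value
        name = "RNA10"
        rec = ds.PUBLISHED[name]
        cfg = ds.study_simulation_config(name, seed=1)
        ev = generate_event_tables(cfg)
        hists = [build_hysteresis_histogram(ev, v) for v in cfg.speeds_nm_s]
        keff = {v: loading_rate_pn_s(cfg.params, cfg.construct, v) / v
                for v in cfg.speeds_nm_s}
        fit = global_fit(hists, rec.transition_length_nm, rec.dG_total_kj_mol,
                         keff, f_max_pn=rec.ramp_F_max_pn)
        assert fit.x_fwd_hat_nm == pytest.approx(rec.x_fwd_nm, abs=0.5)
        assert 3e-6 < fit.k0_hat_per_s < 5e-4

    def test_fit_invariant_to_molecule_relabelling(self):
        cfg = ds.study_simulation_config("DNA18", seed=8)
        ev = generate_event_tables(cfg)
        rec = ds.PUBLISHED["DNA18"]
        keff = {v: loading_rate_pn_s(cfg.params, cfg.construct, v) / v
                for v in cfg.speeds_nm_s}

        def run(events):
            hists = [build_hysteresis_histogram(events, v)
                     for v in cfg.speeds_nm_s]
            return global_fit(hists, rec.transition_length_nm,
                              rec.dG_total_kj_mol, keff, f_max_pn=20.0)

        base = run(ev)
        relabel = ev.copy()
        relabel["molecule_id"] = (relabel["molecule_id"] + 5) % cfg.n_molecules
        shuffled = run(relabel.sample(frac=1.0, random_state=0))
        assert shuffled.x_fwd_hat_nm == pytest.approx(base.x_fwd_hat_nm,
                                                      abs=1e-9)
        assert shuffled.k0_hat_per_s == pytest.approx(base.k0_hat_per_s,
                                                      rel=1e-9)

    def test_missing_keff_rejected(self):
        edges = 0.5 * np.arange(0, 10)
        hist = HysteresisHistogram(150.0, edges,
                                   np.full(9, 1.0 / 9.0), 1, 1)
        with pytest.raises(DomainError, match="k_eff"):
            global_fit([hist], 17.7, 121.0, {50.0: 0.06})
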