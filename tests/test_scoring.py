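"""Site scoring and lineal-energy statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microtrack import (BeamConfig, LinealSampleSet, ToyTrackSpec,
                        dose_distribution, lineal_values, mean_chord_length,
                        score_sites, simulate_batch, toy_track, y_dose_mean,
                        y_frequency_mean, ydbar_pipeline)
from microtrack.scoring import SamplingGrid, _track_site_eps
from microtrack.synth import random_toy_track

from conftest import brute_force_sites


class TestMeanChordLength:
    def test_sphere_values(self):
        assert mean_chord_length(750.0) == pytest.approx(1.0)
        assert mean_chord_length(1000.0) == pytest.approx(4.0 / 3.0)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            mean_chord_length(0.0)


class TestScoreSites:
    def test_single_event_occupies_seven_sites(self):
        """One deposit at an origin-anchored node reaches the node and its
        six face neighbours (diagonals are sqrt(2) g > r_d away)."""
        tr = toy_track(ToyTrackSpec(2000.0, [((0, 0, 0), 2000.0, "ionization")]))
        grid = SamplingGrid(site_radius=1000.0, origin=np.zeros(3))
        sites = score_sites([tr], grid)
        assert len(sites) == 7
        assert all(s.epsilon == pytest.approx(2000.0) for s in sites)

    def test_two_distant_events_disjoint(self):
        tr = toy_track(ToyTrackSpec(4000.0, [
            ((0, 0, 0), 2000.0, "ionization"),
            ((10000.0, 0, 0), 2000.0, "ionization")]))
        grid = SamplingGrid(site_radius=1000.0, origin=np.zeros(3))
        assert len(score_sites([tr], grid)) == 14

    def test_empty_after_filtering(self):
        tr = toy_track(ToyTrackSpec(100.0, [((0, 0, 0), 100.0, "vibrational")]))
        grid = SamplingGrid(site_radius=500.0)
        assert score_sites([tr], grid, processes=["ionization"]) == []

    def test_brute_force_oracle_on_random_tracks(self, rng):
        """Spatial-hash scorer agrees exactly with the all-nodes oracle."""
        for k in range(50):
            tr = random_toy_track(rng)
            grid = SamplingGrid(site_radius=float(rng.uniform(300, 1500)))
            fast = sorted(_track_site_eps(tr, grid))
            brute = sorted(eps for _, eps in brute_force_sites([tr], grid))
            assert len(fast) == len(brute)
            np.testing.assert_allclose(fast, brute, rtol=1e-12)

    def test_lattice_translation_invariance(self, rng):
        """Shifting the anchor by whole grid spacings leaves the eps
        multiset unchanged."""
        tr = random_toy_track(rng, n_events=25)
        base = SamplingGrid(site_radius=800.0, origin=np.zeros(3))
        shifted = SamplingGrid(site_radius=800.0,
                               origin=np.array([800.0, -1600.0, 800.0]))
        a = np.sort(_track_site_eps(tr, base))
        b = np.sort(_track_site_eps(tr, shifted))
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestLinealStatistics:
    def test_lineal_values_examples(self):
        y = lineal_values([4.0 / 3.0 * 1000.0], 1000.0).y_values
        assert y[0] == pytest.approx(1.0)
        y = lineal_values([2000.0], 750.0).y_values
        assert y[0] == pytest.approx(2.0)
        assert len(lineal_values([], 500.0).y_values) == 0

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            lineal_values([100.0, 0.0], 500.0)

    @pytest.mark.parametrize("ys,yf,yd", [
        ([2.0], 2.0, 2.0),
        ([1.0, 1.0, 1.0, 1.0], 1.0, 1.0),
        ([1.0, 3.0], 2.0, 2.5),
    ])
    def test_moment_estimators(self, ys, yf, yd):
        s = LinealSampleSet(np.array(ys), r_d=500.0, n_tracks=1)
        assert y_frequency_mean(s) == pytest.approx(yf)
        assert y_dose_mean(s) == pytest.approx(yd)

    def test_empty_errors(self):
        s = LinealSampleSet(np.array([]), r_d=500.0, n_tracks=0)
        with pytest.raises(ValueError):
            y_frequency_mean(s)
        with pytest.raises(ValueError):
            y_dose_mean(s)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1,
                    max_size=60))
    def test_dose_mean_dominates_frequency_mean(self, ys):
        """y_D >= y_F for any sample (Cauchy-Schwarz), equality iff all
        samples coincide."""
        s = LinealSampleSet(np.array(ys), r_d=500.0, n_tracks=1)
        yd, yf = y_dose_mean(s), y_frequency_mean(s)
        assert yd >= yf * (1.0 - 1e-12)
        if np.ptp(ys) == 0:
            assert yd == pytest.approx(yf)


class TestDoseDistribution:
    def test_all_equal_single_bin(self):
        s = LinealSampleSet(np.full(10, 2.5), r_d=500.0, n_tracks=1)
        f, d, edges = dose_distribution(s, np.array([1.0, 2.0, 3.0, 4.0]))
        widths = np.diff(edges)
        assert (f * widths).sum() == pytest.approx(1.0)
        assert (d * widths).sum() == pytest.approx(1.0)
        assert np.count_nonzero(d) == 1

    def test_unit_integrals_and_moment_consistency(self, rng):
        y = rng.lognormal(0.0, 1.0, size=400)
        s = LinealSampleSet(y, r_d=500.0, n_tracks=1)
        edges = np.logspace(-3, 3, 400)
        f, d, edges = dose_distribution(s, edges)
        widths = np.diff(edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        assert (f * widths).sum() == pytest.approx(1.0, abs=1e-9)
        assert (d * widths).sum() == pytest.approx(1.0, abs=1e-9)
        assert (mids * d * widths).sum() == pytest.approx(y_dose_mean(s),
                                                          rel=0.01)


class TestPipeline:
    def test_pooled_estimator_track_invariance(self, water_set):
        """y_D is invariant under permuting tracks and under splitting one
        batch into replicates (pooled sites are identical)."""
        tracks = simulate_batch(5e3, 20, water_set, seed=31)
        grid = SamplingGrid(site_radius=500.0)
        eps_all = np.concatenate([_track_site_eps(t, grid) for t in tracks])
        perm = np.random.default_rng(0).permutation(len(tracks))
        eps_perm = np.concatenate(
            [_track_site_eps(tracks[i], grid) for i in perm])
        yd_all = y_dose_mean(lineal_values(eps_all, 500.0))
        yd_perm = y_dose_mean(lineal_values(eps_perm, 500.0))
        assert yd_all == pytest.approx(yd_perm, rel=1e-12)
        halves = [np.concatenate([_track_site_eps(t, grid)
                                  for t in tracks[i::2]]) for i in range(2)]
        yd_pooled = y_dose_mean(lineal_values(np.concatenate(halves), 500.0))
        assert yd_pooled == pytest.approx(yd_all, rel=1e-12)

    def test_end_to_end_reproducible(self):
        kw = dict(n_tracks=8, replicates=2, seed=99, n_photon_samples=2000)
        beam = BeamConfig.kvp(100, [("Al", 1.0)])
        a = ydbar_pipeline(beam, **kw)
        b = ydbar_pipeline(beam, **kw)
        assert a.y_D == b.y_D
        assert a.y_F == b.y_F
        np.testing.assert_array_equal(a.y_D_replicates, b.y_D_replicates)

    def test_result_invariants(self, water_set):
        res = ydbar_pipeline(BeamConfig.mono_electron(20.0), n_tracks=10,
                             replicates=2, seed=5, xs_set=water_set)
        assert res.y_D >= res.y_F > 0
        widths = np.diff(res.bin_edges)
        assert (res.f_y * widths).sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.d_y * widths).sum() == pytest.approx(1.0, abs=1e-9)
        assert res.xs_label == water_set.label
        assert res.r_d == 500.0
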