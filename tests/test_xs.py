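"""Cross-section provider: channel probabilities, free paths, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microtrack import (CrossSectionSet, DomainError, InteractionChannel,
                        channel_probabilities, default_water_set,
                        mean_free_path, read_xs, sample_interaction,
                        write_xs)
from microtrack import xs as xsmod


def _const_channel(name, kind, sigma, threshold=0.0, **kw):
    return InteractionChannel(
        name=name, kind=kind,
        sigma=lambda e, s=sigma: np.full_like(np.asarray(e, float), s),
        threshold=threshold, **kw)


def _toy_set(sigmas, density=3.343e22):
    kinds = [xsmod.EXC, xsmod.ION, xsmod.ELASTIC, xsmod.VIB, xsmod.ATT]
    chans = []
    for i, s in enumerate(sigmas):
        kind = kinds[i % len(kinds)]
        kw = {}
        if kind == xsmod.ION:
            kw["binding_energy"] = 13.0
        elif kind in (xsmod.EXC, xsmod.VIB):
            kw["loss_eV"] = 10.0
        chans.append(_const_channel(f"c{i}", kind, s, **kw))
    return CrossSectionSet(channels=chans, medium_density=density,
                           label="toy")


class TestChannelProbabilities:
    def test_single_channel_is_certain(self):
        s = _toy_set([5e-17])
        assert channel_probabilities(100.0, s) == {"excitation_electronic": 1.0}

    @pytest.mark.parametrize("sigmas,expected", [
        ((1e-16, 1e-16), (0.5, 0.5)),
        ((1e-17, 2e-17, 7e-17), (0.1, 0.2, 0.7)),
    ])
    def test_proportional_to_sigma(self, sigmas, expected):
        s = _toy_set(list(sigmas))
        probs = channel_probabilities(500.0, s)
        assert np.allclose(sorted(probs.values()), sorted(expected))
        assert abs(sum(probs.values()) - 1.0) < 1e-12

    def test_domain_error(self, water_set):
        with pytest.raises(DomainError):
            channel_probabilities(0.5, water_set)
        with pytest.raises(DomainError):
            channel_probabilities(2e7, water_set)

    def test_sums_to_one_across_default_domain(self, water_set):
        for e in np.logspace(0.1, 6.9, 25):
            p = channel_probabilities(e, water_set)
            assert abs(sum(p.values()) - 1.0) < 1e-12


class TestMeanFreePath:
    def test_hand_value(self):
        s = _toy_set([1e-16], density=3.343e22)
        assert mean_free_path(100.0, s) == pytest.approx(2.991, rel=1e-3)

    def test_inverse_proportionality(self):
        a = mean_free_path(100.0, _toy_set([1e-16]))
        b = mean_free_path(100.0, _toy_set([2e-16]))
        assert a / b == pytest.approx(2.0, rel=1e-12)

    def test_zero_sigma_errors(self):
        s = _toy_set([1e-16])
        s.channels[0].threshold = 50.0
        with pytest.raises(ValueError):
            mean_free_path(20.0, s)


class TestSampleInteraction:
    def test_forced_excitation_fixed_loss(self, rng):
        s = _toy_set([1e-16])
        out = sample_interaction(100.0, s, rng)
        assert out.channel.process == "excitation_electronic"
        assert out.energy_loss == 10.0
        assert out.secondary_KE is None

    def test_ionization_additivity_and_bounds(self, water_set, rng):
        for _ in range(200):
            e = float(rng.uniform(20.0, 5e4))
            out = sample_interaction(e, water_set, rng)
            assert out.energy_loss <= e + 1e-9
            if out.channel.kind == xsmod.ION:
                b = out.channel.binding_energy
                assert out.energy_loss == pytest.approx(b + out.secondary_KE)
                assert 0.0 <= out.secondary_KE <= 0.5 * (e - b) + 1e-9

    def test_elastic_loses_nothing(self, water_set, rng):
        # energy transfer by elastic scattering is treated as negligible
        hits = 0
        for _ in range(300):
            out = sample_interaction(2e3, water_set, rng)
            if out.channel.kind == xsmod.ELASTIC:
                hits += 1
                assert out.energy_loss == 0.0
                assert -1.0 <= out.deflection_cos <= 1.0
        assert hits > 0


class TestDefaultWaterSet:
    def test_no_ionization_below_first_threshold(self, water_set):
        p = channel_probabilities(10.0, water_set)
        assert p.get("ionization", 0.0) == 0.0

    def test_ionization_dominates_excitation_at_1kev(self, water_set):
        p = channel_probabilities(1000.0, water_set)
        assert p["ionization"] > p["excitation_electronic"]

    def test_total_sigma_positive_across_domain(self, water_set):
        lo, hi = water_set.energy_domain
        assert lo == 1.0 and hi == 1e7
        for e in (1.0, 10.0, 1e3, 1e7):
            tot = float(water_set.total_sigma(e)[0])
            assert np.isfinite(tot) and tot > 0.0

    def test_stopping_power_tracks_reference(self, water_set):
        """The calibrated sharing keeps stopping on the reference curve."""
        n_nm = water_set.medium_density * 1e-7
        for e in (1e3, 1e4, 1e5, 1e6):
            f = water_set.hard_fraction_at(e)
            a = water_set.soft_scale_at(e)
            tot = 0.0
            for i, ch in enumerate(water_set.channels):
                s = float(ch.sigma_at(np.array([e]))[0])
                if s <= 0:
                    continue
                if ch.kind == xsmod.ION:
                    b = ch.binding_energy
                    fk = f if 0.5 * (e - b) > 50.0 else 0.0
                    tot += s * (b + fk * xsmod._mean_w_hard(e, b)
                                + (1 - fk) * xsmod._mean_w_soft(e, b, a))
                elif ch.kind in (xsmod.EXC, xsmod.VIB):
                    tot += s * ch.loss_eV
            s_model = tot * n_nm
            s_ref = float(xsmod.reference_stopping_eV_nm(e))
            assert s_model == pytest.approx(s_ref, rel=0.02)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, water_set):
        p1 = tmp_path / "xs1.txt"
        p2 = tmp_path / "xs2.txt"
        write_xs(water_set, str(p1), n=64)
        again = read_xs(str(p1))
        write_xs(again, str(p2), n=64)
        assert p1.read_text() == p2.read_text()
        assert again.label == water_set.label

    def test_read_back_matches_on_grid(self, tmp_path, water_set):
        p = tmp_path / "xs.txt"
        write_xs(water_set, str(p), n=128)
        again = read_xs(str(p))
        e = np.array([30.0, 1e3, 1e5])
        np.testing.assert_allclose(again.total_sigma(e),
                                   water_set.total_sigma(e), rtol=0.05)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(e=st.floats(min_value=20.0, max_value=9.9e6),
       seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_interaction_never_overdraws_energy(water_set, e, seed):
    """No sampled collision can lose more energy than the electron has."""
    out = sample_interaction(e, water_set, np.random.default_rng(seed))
    assert 0.0 <= out.energy_loss <= e + 1e-9
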