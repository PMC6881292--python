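"""Photon fields, filtration and secondary-electron sampling."""

import numpy as np
import pytest

from microtrack import (PhotonSpectrum, apply_filtration, kvp_spectrum,
                        linac6mv_spectrum, read_spectrum,
                        sample_source_energy, secondary_electron_spectrum,
                        write_spectrum)
from microtrack.spectra import (ElectronSourceSpectrum, compton_edge_keV,
                                sample_compton_electron,
                                water_interaction_coefficients)
from microtrack import constants as C


def _mono_photons(e_keV):
    return PhotonSpectrum(np.array([e_keV * 0.999, e_keV * 1.001]),
                          np.array([1.0]), label=f"mono {e_keV} keV")


class TestKvpSpectrum:
    def test_endpoint(self):
        s = kvp_spectrum(60.0)
        assert s.bin_edges[-1] <= 60.0 + 1e-9
        assert s.fluence[s.midpoints > 60.0].sum() == 0.0

    def test_no_k_lines_below_edge(self):
        s = kvp_spectrum(60.0)
        # pure continuum: fluence decreases monotonically above the peak
        i = int(np.argmax(s.fluence))
        assert np.all(np.diff(s.fluence[i:]) <= 1e-12)

    def test_k_lines_present_at_200kvp(self):
        s = kvp_spectrum(200.0)
        mid = s.midpoints
        for line in (59.318, 67.244):
            i = int(np.searchsorted(s.bin_edges, line) - 1)
            neighbours = 0.5 * (s.fluence[i - 2] + s.fluence[i + 2])
            assert s.fluence[i] > 1.5 * neighbours, f"no line near {line} keV"

    def test_out_of_range_potential(self):
        with pytest.raises(ValueError):
            kvp_spectrum(400.0)


class TestFiltration:
    def test_zero_thickness_identity(self):
        s = kvp_spectrum(100.0)
        f = apply_filtration(s, [("Al", 0.0), ("Cu", 0.0)])
        np.testing.assert_allclose(f.fluence, s.fluence)

    def test_hardening_monotonic(self):
        s = kvp_spectrum(100.0)
        assert apply_filtration(s, [("Al", 2.0)]).mean_energy() >= s.mean_energy()

    def test_order_independence(self):
        s = kvp_spectrum(200.0)
        a = apply_filtration(apply_filtration(s, [("Cu", 0.5)]), [("Al", 0.5)])
        b = apply_filtration(apply_filtration(s, [("Al", 0.5)]), [("Cu", 0.5)])
        np.testing.assert_allclose(a.fluence, b.fluence, rtol=1e-12)

    def test_heavy_filtration_removes_soft_photons(self):
        f = apply_filtration(kvp_spectrum(200.0), [("Cu", 0.5), ("Al", 0.5)])
        soft = f.fluence[f.midpoints < 20.0].sum()
        assert soft / f.fluence.sum() < 0.01

    def test_unknown_material(self):
        with pytest.raises(ValueError):
            apply_filtration(kvp_spectrum(100.0), [("Pb", 1.0)])


class TestLinac6MV:
    def test_depth_hardening(self):
        assert (linac6mv_spectrum(10.0).mean_energy()
                > linac6mv_spectrum(0.0).mean_energy())

    def test_endpoint_6mev(self):
        s = linac6mv_spectrum(5.0)
        assert s.bin_edges[-1] <= 6000.0 + 1e-9

    def test_out_of_field_unsupported(self):
        with pytest.raises(ValueError):
            linac6mv_spectrum(10.0, field="out_of_field")


class TestSecondaryElectrons:
    def test_compton_edge_bound(self):
        """Mono 100 keV photons: no Compton electron above the edge
        2E^2/(mc^2+2E) = 28.1 keV."""
        edge = compton_edge_keV(100.0)
        assert edge == pytest.approx(28.1, abs=0.1)
        rng = np.random.default_rng(3)
        t = [sample_compton_electron(100.0, rng) for _ in range(5000)]
        assert max(t) <= edge + 1e-9

    def test_photoelectric_dominates_at_10kev(self):
        pe, inc = water_interaction_coefficients(10.0)
        assert (pe / (pe + inc)).item() > 0.9
        es = secondary_electron_spectrum(_mono_photons(10.0), 4000, seed=1)
        # photoelectrons carry E_gamma - K binding
        assert es.mean_energy() > 0.9 * (10.0 - C.WATER_K_BINDING_KEV)

    def test_deterministic(self):
        s = apply_filtration(kvp_spectrum(200.0), [("Cu", 0.5)])
        a = secondary_electron_spectrum(s, 3000, seed=9)
        b = secondary_electron_spectrum(s, 3000, seed=9)
        np.testing.assert_array_equal(a.weight, b.weight)
        np.testing.assert_array_equal(a.bin_edges, b.bin_edges)

    def test_harder_photons_give_harder_electrons(self):
        kvp = secondary_electron_spectrum(
            apply_filtration(kvp_spectrum(200.0), [("Cu", 0.5), ("Al", 0.5)]),
            5000, seed=2)
        mv = secondary_electron_spectrum(linac6mv_spectrum(10.0), 5000, seed=2)
        assert mv.mean_energy() > kvp.mean_energy()

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            PhotonSpectrum(np.array([1.0, 2.0]), np.array([0.0]))


class TestSourceSampling:
    def test_single_bin(self, rng):
        es = ElectronSourceSpectrum(np.array([4.0, 6.0]), np.array([1.0]))
        for _ in range(20):
            assert 4.0 <= sample_source_energy(es, rng) <= 6.0

    def test_two_equal_bins_binomial(self, rng):
        es = ElectronSourceSpectrum(np.array([0.0, 1.0, 2.0]),
                                    np.array([1.0, 1.0]))
        draws = es.sample_energies_keV(10000, rng)
        n_low = int((draws < 1.0).sum())
        assert abs(n_low - 5000) <= 3 * np.sqrt(10000 * 0.25)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            ElectronSourceSpectrum(np.array([0.0, 1.0]), np.array([0.0]))


class TestSpectrumIO:
    def test_round_trip(self, tmp_path):
        s = apply_filtration(kvp_spectrum(100.0), [("Al", 1.0)])
        p = tmp_path / "spec.txt"
        write_spectrum(s, str(p))
        again = read_spectrum(str(p))
        assert isinstance(again, PhotonSpectrum)
        np.testing.assert_allclose(again.fluence, s.fluence)
        np.testing.assert_allclose(again.midpoints, s.midpoints, rtol=1e-12)
        assert again.label == s.label

    def test_comma_delimited_tolerated(self, tmp_path):
        p = tmp_path / "spec.csv"
        p.write_text("# label: user beam\n# kind: electron\n"
                     "10,1.0\n20, 2.0\n30 1.0\n")
        es = read_spectrum(str(p))
        assert isinstance(es, ElectronSourceSpectrum)
        assert len(es.weight) == 3
        assert es.parent_label == "user beam"
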