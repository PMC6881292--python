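"""Photon fields and secondary-electron source spectra.

Models the photon side of the simulation chain: kVp tube spectra
(Kramers-form bremsstrahlung with tungsten K lines and inherent filtration),
added filtration through Al/Cu/water layers, an analytic 6 MV therapy
spectrum hardened to water depth, and the conversion of a photon spectrum to
the first-collision secondary-electron source spectrum via photoelectric and
Compton (Klein-Nishina) sampling in water.

The electron source spectra produced here feed
:func:`microtrack.transport.simulate_batch`; full electron transport then
captures the slowing-down physics.  Absolute dosimetry is out of scope: all
fluence values are relative weights.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from . import constants as C

_MU_TABLES = {"Al": C.MU_AL, "Cu": C.MU_CU, "water": C.MU_WATER}

#: inherent tube filtration (mm Al equivalent) applied to generated kVp
#: spectra; typical of diagnostic/orthovoltage tubes
INHERENT_FILTRATION_MM_AL = 1.0
#: fraction of total fluence carried by tungsten K lines at endpoint kVp,
#: scaled by (1 - K_edge/kVp); crude Birch-Marshall-style magnitude
K_LINE_FRACTION = 0.15
#: water-equivalent flattening-filter hardening (cm) of the 6 MV model,
#: set so the surface spectrum's fluence-mean energy (~1.7 MeV) matches
#: published Monte Carlo 6 MV linac spectra
LINAC6MV_FILTER_CM = 22.0


@dataclass
class PhotonSpectrum:
    """Binned relative photon fluence. ``bin_edges`` keV, ascending."""

    bin_edges: np.ndarray
    fluence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if len(self.bin_edges) != len(self.fluence) + 1:
            raise ValueError("need len(bin_edges) == len(fluence) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        if np.any(self.fluence < 0) or not np.any(self.fluence > 0):
            raise ValueError("fluence must be >= 0 with at least one positive bin")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_energy(self) -> float:
        return float((self.midpoints * self.fluence).sum() / self.fluence.sum())


@dataclass
class FilterLayer:
    material: str
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.material not in _MU_TABLES:
            raise ValueError(f"unknown filter material {self.material!r}")
        if self.thickness_mm < 0:
            raise ValueError("thickness must be >= 0")


@dataclass
class ElectronSourceSpectrum:
    """Binned secondary-electron source spectrum (keV edges)."""

    bin_edges: np.ndarray
    weight: np.ndarray
    parent_label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if len(self.bin_edges) != len(self.weight) + 1:
            raise ValueError("need len(bin_edges) == len(weight) + 1")
        if np.any(self.weight < 0) or not np.any(self.weight > 0):
            raise ValueError("weights must be >= 0 with at least one positive bin")

    def mean_energy(self) -> float:
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float((mid * self.weight).sum() / self.weight.sum())

    def sample_energies_keV(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.weight / self.weight.sum()
        idx = rng.choice(len(p), size=n, p=p)
        lo = self.bin_edges[idx]
        hi = self.bin_edges[idx + 1]
        return lo + rng.random(n) * (hi - lo)

    def sample_energies_eV(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.maximum(self.sample_energies_keV(n, rng) * 1e3, 1.0)


def mass_attenuation(material: str, e_keV) -> np.ndarray:
    """Total mass attenuation coefficient (cm^2/g) from the baked-in tables."""
    if material not in _MU_TABLES:
        raise ValueError(f"unknown material {material!r}")
    return C.loglog_interp(np.asarray(e_keV, dtype=float) / 1e3, _MU_TABLES[material])


def klein_nishina_total(e_keV) -> np.ndarray:
    """Total Klein-Nishina cross section per electron (cm^2)."""
    k = np.asarray(e_keV, dtype=float) / (C.ELECTRON_REST_EV / 1e3)
    re2 = C.CLASSICAL_E_RADIUS_CM ** 2
    t1 = (1.0 + k) / k ** 2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log1p(2.0 * k) / k)
    t2 = np.log1p(2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    out = 2.0 * np.pi * re2 * (t1 + t2 - t3)
    return out if out.size > 1 else float(out.reshape(-1)[0])


def water_interaction_coefficients(e_keV) -> tuple[np.ndarray, np.ndarray]:
    """(photoelectric, incoherent) mass coefficients of water, cm^2/g.

    Photoelectric from the baked-in XCOM table; incoherent as free-electron
    Klein-Nishina times the electron density of water (binding corrections
    are negligible where Compton matters).
    """
    e = np.atleast_1d(np.asarray(e_keV, dtype=float))
    pe = np.atleast_1d(C.loglog_interp(e / 1e3, C.MU_PE_WATER))
    inc = np.atleast_1d(klein_nishina_total(e)) * C.WATER_ELECTRONS_PER_GRAM
    return pe, inc


def compton_edge_keV(e_keV: float) -> float:
    """Maximum Compton-electron energy 2E^2/(m_e c^2 + 2E)."""
    mc2 = C.ELECTRON_REST_EV / 1e3
    return 2.0 * e_keV ** 2 / (mc2 + 2.0 * e_keV)


def sample_compton_electron(e_keV: float, rng: np.random.Generator) -> float:
    """Compton-electron energy via Kahn's Klein-Nishina sampling."""
    a = e_keV / (C.ELECTRON_REST_EV / 1e3)
    while True:
        u1, u2, u3 = rng.random(3)
        if u1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a):
            r = 1.0 + 2.0 * a * u2          # r = E / E'
            if u3 <= 4.0 * (1.0 / r - 1.0 / r ** 2):
                break
        else:
            r = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * u2)
            cost = 1.0 - (r - 1.0) / a
            if u3 <= 0.5 * (cost ** 2 + 1.0 / r):
                break
    return e_keV * (1.0 - 1.0 / r)


# --------------------------------------------------------------------------
# spectrum generation
# --------------------------------------------------------------------------

def kvp_spectrum(tube_potential: float, bin_width: float = 1.0) -> PhotonSpectrum:
    """Kramers-form tungsten-anode tube spectrum at ``tube_potential`` kV.

    The bremsstrahlung continuum ∝ (kVp/E - 1) is attenuated by the inherent
    tube filtration (``INHERENT_FILTRATION_MM_AL``); tungsten K lines are
    added when the potential exceeds the K edge (69.5 keV).  Fluence is zero
    above the tube potential.
    """
    if not (10.0 <= tube_potential <= 300.0):
        raise ValueError("tube potential must be in [10, 300] kV")
    edges = np.arange(1.0, tube_potential + bin_width * 0.5, bin_width)
    if edges[-1] < tube_potential:
        edges = np.append(edges, tube_potential)
    mid = 0.5 * (edges[:-1] + edges[1:])
    fl = np.maximum(tube_potential / mid - 1.0, 0.0)
    mu = mass_attenuation("Al", mid) * C.DENSITY_G_CM3["Al"]
    fl = fl * np.exp(-mu * INHERENT_FILTRATION_MM_AL * 0.1)
    if tube_potential > C.TUNGSTEN_K_EDGE_KEV:
        frac = K_LINE_FRACTION * (1.0 - C.TUNGSTEN_K_EDGE_KEV / tube_potential)
        line_total = frac * fl.sum()
        w = C.TUNGSTEN_K_LINE_WEIGHT / C.TUNGSTEN_K_LINE_WEIGHT.sum()
        for e_line, wl in zip(C.TUNGSTEN_K_LINES_KEV, w):
            if e_line < tube_potential:
                i = int(np.searchsorted(edges, e_line) - 1)
                fl[i] += line_total * wl
    return PhotonSpectrum(edges, fl, label=f"{tube_potential:g} kVp")


def apply_filtration(spectrum: PhotonSpectrum, layers) -> PhotonSpectrum:
    """Attenuate per-bin fluence by exp(-sum mu_i(E) t_i); hardens the beam."""
    mid = spectrum.midpoints
    atten = np.zeros_like(mid)
    tags = []
    for layer in layers:
        if not isinstance(layer, FilterLayer):
            layer = FilterLayer(*layer)
        mu = mass_attenuation(layer.material, mid) * C.DENSITY_G_CM3[layer.material]
        atten += mu * layer.thickness_mm * 0.1
        tags.append(f"{layer.thickness_mm:g} mm {layer.material}")
    fl = spectrum.fluence * np.exp(-atten)
    label = spectrum.label + (" + " + " + ".join(tags) if tags else "")
    return PhotonSpectrum(spectrum.bin_edges.copy(), fl, label=label)


def linac6mv_spectrum(depth_cm: float, field: str = "in_field",
                      bin_width_keV: float = 50.0) -> PhotonSpectrum:
    """Analytic 6 MV therapy spectrum hardened to ``depth_cm`` of water.

    A 6 MeV-endpoint Kramers continuum filtered through a water-equivalent
    flattening filter (``LINAC6MV_FILTER_CM``), then attenuated through
    ``depth_cm`` of water (narrow-beam; in-phantom scatter build-up is not
    modelled).  Only the in-field primary spectrum is modelled; out-of-field
    fields require a user-supplied spectrum file.
    """
    if field != "in_field":
        raise ValueError("only in_field is modelled; supply an out-of-field "
                         "spectrum via a spectrum file")
    if not (0.0 <= depth_cm <= 30.0):
        raise ValueError("depth must be in [0, 30] cm")
    e_max = 6000.0
    edges = np.arange(50.0, e_max + 0.5 * bin_width_keV, bin_width_keV)
    if edges[-1] < e_max:
        edges = np.append(edges, e_max)
    mid = 0.5 * (edges[:-1] + edges[1:])
    fl = np.maximum(e_max / mid - 1.0, 0.0)
    mu = mass_attenuation("water", mid)  # rho = 1
    fl = fl * np.exp(-mu * (LINAC6MV_FILTER_CM + depth_cm))
    return PhotonSpectrum(edges, fl, label=f"6 MV, {depth_cm:g} cm depth, in-field")


def secondary_electron_spectrum(spectrum: PhotonSpectrum, n_samples: int,
                                seed: int, bin_width_keV: float | None = None,
                                ) -> ElectronSourceSpectrum:
    """Stage (i): first-collision electron source spectrum in water.

    Photons are drawn ∝ fluence × (photoelectric + incoherent) coefficient
    of water; the interaction type is drawn from the two coefficients at the
    sampled energy.  Photoelectric electrons carry E_gamma minus the
    effective K binding of water; Compton electrons are sampled from the
    Klein-Nishina differential.  The histogram of electron energies is the
    returned source spectrum.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(int(seed))
    mid = spectrum.midpoints
    pe, inc = water_interaction_coefficients(mid)
    w = spectrum.fluence * (pe + inc)
    if not np.any(w > 0):
        raise ValueError("spectrum has no interacting fluence")
    p = w / w.sum()
    idx = rng.choice(len(p), size=n_samples, p=p)
    e_lo = spectrum.bin_edges[idx]
    e_hi = spectrum.bin_edges[idx + 1]
    e_gamma = e_lo + rng.random(n_samples) * (e_hi - e_lo)
    pe_g, inc_g = water_interaction_coefficients(e_gamma)
    p_pe = pe_g / (pe_g + inc_g)
    is_pe = rng.random(n_samples) < p_pe
    t = np.empty(n_samples)
    t[is_pe] = np.maximum(e_gamma[is_pe] - C.WATER_K_BINDING_KEV,
                          0.5 * e_gamma[is_pe])
    for i in np.flatnonzero(~is_pe):
        t[i] = sample_compton_electron(float(e_gamma[i]), rng)
    if bin_width_keV is None:
        bin_width_keV = 1.0 if spectrum.bin_edges[-1] <= 300.0 else 10.0
    edges = np.arange(0.0, t.max() + bin_width_keV, bin_width_keV)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width_keV])
    hist, _ = np.histogram(t, bins=edges)
    if not np.any(hist > 0):
        hist[0] = 1
    return ElectronSourceSpectrum(edges, hist.astype(float),
                                  parent_label=spectrum.label)


def sample_source_energy(es: ElectronSourceSpectrum, rng: np.random.Generator) -> float:
    """Draw one electron energy (keV) ∝ bin weights, uniform within bin."""
    return float(es.sample_energies_keV(1, rng)[0])


# --------------------------------------------------------------------------
# spectrum file I/O: two-column "energy_keV value" text
# --------------------------------------------------------------------------

def write_spectrum(spec, path: str) -> None:
    kind = "electron" if isinstance(spec, ElectronSourceSpectrum) else "photon"
    label = spec.parent_label if kind == "electron" else spec.label
    values = spec.weight if kind == "electron" else spec.fluence
    buf = io.StringIO()
    buf.write(f"# label: {label}\n# kind: {kind}\n")
    buf.write("# columns: energy_keV value (energies are bin centers)\n")
    mid = 0.5 * (spec.bin_edges[:-1] + spec.bin_edges[1:])
    for e, v in zip(mid, values):
        buf.write("%.17g %.17g\n" % (e, v))
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _edges_from_centers(centers: np.ndarray) -> np.ndarray:
    if len(centers) == 1:
        h = max(0.5 * centers[0], 0.5)
        return np.array([max(centers[0] - h, 0.0), centers[0] + h])
    inner = 0.5 * (centers[:-1] + centers[1:])
    first = max(centers[0] - (inner[0] - centers[0]), 0.0)
    last = centers[-1] + (centers[-1] - inner[-1])
    return np.concatenate([[first], inner, [last]])


def read_spectrum(path: str):
    """Read a two-column spectrum file (comma or whitespace delimited)."""
    label, kind = "", "photon"
    e, v = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("label:"):
                    label = body.split(":", 1)[1].strip()
                elif body.startswith("kind:"):
                    kind = body.split(":", 1)[1].strip()
                continue
            tok = line.replace(",", " ").split()
            e.append(float(tok[0]))
            v.append(float(tok[1]))
    centers = np.asarray(e)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("spectrum energies must be ascending")
    edges = _edges_from_centers(centers)
    if kind == "electron":
        return ElectronSourceSpectrum(edges, np.asarray(v), parent_label=label)
    return PhotonSpectrum(edges, np.asarray(v), label=label)
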