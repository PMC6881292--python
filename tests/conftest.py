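import numpy as np
import pytest

from microtrack import default_water_set, degenerate_xs, simulate_track
from microtrack.scoring import SamplingGrid
from microtrack import xs as xsmod


@pytest.fixture(scope="session")
def water_set():
    """The default liquid-water cross-section set (tabulated once)."""
    s = default_water_set()
    s.tabulate()
    # warm the numba kernels once per session
    simulate_track(500.0, s, 1)
    return s


@pytest.fixture(scope="session")
def forced_set():
    """Degenerate single-excitation set: fixed 10 eV loss above 10 eV."""
    return degenerate_xs(10.0, 10.0, 1e-16)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_sites(tracks, grid: SamplingGrid, processes=None):
    """All-nodes x all-events reference scorer for small tracks.

    Enumerates every lattice node over each track's bounding box inflated
    by the site radius and sums deposits within the inclusive sphere.
    Returns a sorted list of (node_index_triple, eps) per track, pooled.
    """
    out = []
    for tr in tracks:
        mask = tr.edep > 0
        if processes is not None:
            kinds = {xsmod.NAME_KINDS[p] if isinstance(p, str) else int(p)
                     for p in processes}
            mask &= np.isin(tr.process, list(kinds))
        if not mask.any():
            continue
        pos = tr.position[mask]
        ed = tr.edep[mask]
        origin = np.asarray(grid.origin if grid.origin is not None else pos[0],
                            dtype=float)
        g, r = grid.spacing, grid.site_radius
        lo = np.floor((pos.min(axis=0) - r - origin) / g).astype(int)
        hi = np.ceil((pos.max(axis=0) + r - origin) / g).astype(int)
        for ix in range(lo[0], hi[0] + 1):
            for iy in range(lo[1], hi[1] + 1):
                for iz in range(lo[2], hi[2] + 1):
                    center = origin + np.array([ix, iy, iz]) * g
                    d2 = ((pos - center) ** 2).sum(axis=1)
                    # inclusive boundary with the same 1e-12 relative
                    # tolerance as the production scorer
                    eps = ed[d2 <= r * r * (1.0 + 1e-12)].sum()
                    if eps > 0:
                        out.append(((ix, iy, iz), float(eps)))
    return out
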