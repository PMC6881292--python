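"""Event-by-event electron transport in water.

Transports a primary electron and its full secondary cascade down to the
cutoff energy (default 1.0 eV), emitting point energy-deposition events at
interaction vertices.  The traversal is stack-based (no recursion) and every
track conserves energy by construction: the sum of recorded deposits equals
the primary energy to floating tolerance.

Fast path: a numba kernel working on the :class:`~microtrack.xs.TabulatedXS`
arrays.  Below ``e_local`` (default 100 eV) the electron is slowed down "in
place": only inelastic channels are sampled and deposits are placed at the
current position without elastic flights.  The residual range there is a few
nanometres, far below the site sizes this tool scores, while the per-process
energy bookkeeping is unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import xs as xsmod
from .xs import ATT, CUTOFF, ELASTIC, EXC, ION, KIND_NAMES, NAME_KINDS, VIB

_OK, _OVERFLOW_EVENTS, _OVERFLOW_STACK = 0, 1, 2


@dataclass
class ElectronState:
    """Kinematic state of one electron in flight."""

    kinetic_energy: float
    position: np.ndarray
    direction: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.kinetic_energy < 0:
            raise ValueError("kinetic energy must be >= 0")
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")


@dataclass
class Track:
    """One primary electron and its cascade as ordered point deposits.

    Positions are nm, deposits eV.  ``process`` holds the kind codes of
    :mod:`microtrack.xs` (5 = terminal sub-cutoff deposit); ``parent`` holds,
    for those terminal deposits, the kind of the channel that produced the
    stopping electron.  ``discarded`` is nonzero only when transport ran with
    a restricted channel set that drops sub-threshold energy.
    """

    primary_energy: float
    position: np.ndarray      # (n, 3) nm
    edep: np.ndarray          # (n,) eV
    process: np.ndarray       # (n,) uint8 kind codes
    generation: np.ndarray    # (n,) int32
    parent: np.ndarray        # (n,) uint8
    seed: int
    xs_label: str
    cutoff: float = 1.0
    track_id: int = 0
    discarded: float = 0.0

    @property
    def n_events(self) -> int:
        return len(self.edep)

    def total_edep(self) -> float:
        return float(self.edep.sum())

    def process_names(self) -> list[str]:
        return [KIND_NAMES[int(p)] for p in self.process]


# --------------------------------------------------------------------------
# numba kernel
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _sigma_row(sigma, log10_e0, dlog10, threshold, enabled, e, out):
    n_ch, n_e = sigma.shape
    x = (np.log10(e) - log10_e0) / dlog10
    if x < 0.0:
        x = 0.0
    if x > n_e - 1.0:
        x = n_e - 1.0
    i = int(x)
    j = i + 1 if i + 1 < n_e else i
    w = x - i
    tot = 0.0
    for c in range(n_ch):
        if not enabled[c] or e < threshold[c]:
            out[c] = 0.0
        else:
            s = sigma[c, i] * (1.0 - w) + sigma[c, j] * w
            out[c] = s if s > 0.0 else 0.0
        tot += out[c]
    return tot


@njit(cache=True, inline="always")
def _interp1(arr, log10_e0, dlog10, e):
    n = arr.shape[0]
    x = (np.log10(e) - log10_e0) / dlog10
    if x < 0.0:
        x = 0.0
    if x > n - 1.0:
        x = n - 1.0
    i = int(x)
    j = i + 1 if i + 1 < n else i
    w = x - i
    return arr[i] * (1.0 - w) + arr[j] * w


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    dperp = np.sqrt(dx * dx + dy * dy)
    if dperp < 1e-12:
        sign = 1.0 if dz >= 0.0 else -1.0
        nx = sint * cosp
        ny = sint * sinp
        nz = cost * sign
    else:
        nx = dx * cost + sint * (dx * dz * cosp - dy * sinp) / dperp
        ny = dy * cost + sint * (dy * dz * cosp + dx * sinp) / dperp
        nz = dz * cost - dperp * sint * cosp
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _elastic_cos(e, u):
    # Moliere-screened Rutherford deflection; oxygen dominates water's
    # elastic scattering, so Z=8 is used for the angular screening.
    z = 8.0
    tau = e / 510998.95
    beta2 = 1.0 - 1.0 / ((1.0 + tau) * (1.0 + tau))
    az2 = (7.2973525693e-3 * z) ** 2
    eta = 1.7e-5 * z ** (2.0 / 3.0) / (tau * (tau + 2.0)) * (1.13 + 3.76 * az2 / beta2)
    t = eta * u / (1.0 + eta - u)
    return 1.0 - 2.0 * t


@njit(cache=True)
def _simulate(e0, seed, sigma, log10_e0, dlog10, kind, threshold, binding, loss,
              hard_frac, soft_scale, density, cutoff, e_local, max_elastic, enabled,
              deposit_subthreshold, record_elastic,
              ev_x, ev_y, ev_z, ev_e, ev_p, ev_g, ev_par,
              st_E, st_x, st_y, st_z, st_dx, st_dy, st_dz, st_g):
    np.random.seed(seed)
    n_ch = sigma.shape[0]
    sig = np.empty(n_ch)
    cap_ev = ev_e.shape[0]
    cap_st = st_E.shape[0]
    n = 0
    discarded = 0.0
    # push the primary, starting at the origin along +z
    sp = 0
    st_E[sp] = e0
    st_x[sp] = 0.0
    st_y[sp] = 0.0
    st_z[sp] = 0.0
    st_dx[sp] = 0.0
    st_dy[sp] = 0.0
    st_dz[sp] = 1.0
    st_g[sp] = 0
    sp += 1
    while sp > 0:
        sp -= 1
        e = st_E[sp]
        x = st_x[sp]
        y = st_y[sp]
        z = st_z[sp]
        dx = st_dx[sp]
        dy = st_dy[sp]
        dz = st_dz[sp]
        gen = st_g[sp]
        last_kind = ION if gen > 0 else CUTOFF
        n_el = 0
        alive = True
        while alive:
            if e <= cutoff:
                if e > 0.0:
                    if deposit_subthreshold:
                        if n >= cap_ev:
                            return n, discarded, _OVERFLOW_EVENTS
                        ev_x[n] = x; ev_y[n] = y; ev_z[n] = z
                        ev_e[n] = e; ev_p[n] = CUTOFF; ev_g[n] = gen
                        ev_par[n] = last_kind
                        n += 1
                    else:
                        discarded += e
                break
            local = e < e_local
            tot = _sigma_row(sigma, log10_e0, dlog10, threshold, enabled, e, sig)
            if local and tot > 0.0:
                # drop elastic from the competition in local-slowdown mode
                for c in range(n_ch):
                    if kind[c] == ELASTIC:
                        tot -= sig[c]
                        sig[c] = 0.0
            if tot <= 0.0:
                if deposit_subthreshold:
                    if n >= cap_ev:
                        return n, discarded, _OVERFLOW_EVENTS
                    ev_x[n] = x; ev_y[n] = y; ev_z[n] = z
                    ev_e[n] = e; ev_p[n] = CUTOFF; ev_g[n] = gen
                    ev_par[n] = last_kind
                    n += 1
                else:
                    discarded += e
                break
            if not local:
                mfp_nm = 1.0e7 / (density * tot)
                step = -mfp_nm * np.log(np.random.random())
                x += dx * step
                y += dy * step
                z += dz * step
            # channel selection
            r = np.random.random() * tot
            c = 0
            acc = sig[0]
            while acc < r and c < n_ch - 1:
                c += 1
                acc += sig[c]
            k = kind[c]
            if k == ELASTIC:
                cost = _elastic_cos(e, np.random.random())
                phi = 2.0 * np.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cost, phi)
                n_el += 1
                if n_el > max_elastic:
                    if deposit_subthreshold:
                        if n >= cap_ev:
                            return n, discarded, _OVERFLOW_EVENTS
                        ev_x[n] = x; ev_y[n] = y; ev_z[n] = z
                        ev_e[n] = e; ev_p[n] = CUTOFF; ev_g[n] = gen
                        ev_par[n] = ELASTIC
                        n += 1
                    else:
                        discarded += e
                    break
                if record_elastic:
                    if n >= cap_ev:
                        return n, discarded, _OVERFLOW_EVENTS
                    ev_x[n] = x; ev_y[n] = y; ev_z[n] = z
                    ev_e[n] = 0.0; ev_p[n] = ELASTIC; ev_g[n] = gen
                    ev_par[n] = ELASTIC
                    n += 1
                continue
            if k == ION:
                b = binding[c]
                wmax = 0.5 * (e - b)
                w = 0.0
                if wmax > 0.0:
                    hf = _interp1(hard_frac, log10_e0, dlog10, e)
                    u = np.random.random()
                    if wmax > 50.0 and np.random.random() < hf:
                        # Moller knock-on tail, 1/W^2 on [50 eV, Wmax]
                        w = 1.0 / (1.0 / 50.0 - u * (1.0 / 50.0 - 1.0 / wmax))
                    else:
                        a = _interp1(soft_scale, log10_e0, dlog10, e)
                        a1 = 1.0 / (a * a)
                        a2 = 1.0 / ((wmax + a) * (wmax + a))
                        w = 1.0 / np.sqrt(a1 - u * (a1 - a2)) - a
                    if w < 0.0:
                        w = 0.0
                    if w > wmax:
                        w = wmax
                if n >= cap_ev:
                    return n, discarded, _OVERFLOW_EVENTS
                ev_x[n] = x; ev_y[n] = y; ev_z[n] = z
                ev_e[n] = b; ev_p[n] = ION; ev_g[n] = gen
                ev_par[n] = ION
                n += 1
                e -= b + w
                last_kind = ION
                if w > cutoff:
                    if sp >= cap_st:
                        return n, discarded, _OVERFLOW_STACK
                    # secondary: isotropic in the forward hemisphere of the
                    # current direction
                    while True:
                        sx = 2.0 * np.random.random() - 1.0
                        sy = 2.0 * np.random.random() - 1.0
                        sz = 2.0 * np.random.random() - 1.0
                        r2 = sx * sx + sy * sy + sz * sz
                        if 1e-6 < r2 <= 1.0:
                            break
                    rn = np.sqrt(r2)
                    sx /= rn; sy /= rn; sz /= rn
                    if sx * dx + sy * dy + sz * dz < 0.0:
                        sx = -sx; sy = -sy; sz = -sz
                    st_E[sp] = w
                    st_x[sp] = x; st_y[sp] = y; st_z[sp] = z
                    st_dx[sp] = sx; st_dy[sp] = sy; st_dz[sp] = sz
                    st_g[sp] = gen + 1
                    sp += 1
                elif w > 0.0:
                    if deposit_subthreshold:
                        if n >= cap_ev:
                            return n, discarded, _OVERFLOW_EVENTS
                        ev_x[n] = x; ev_y[n] = y; ev_z[n] = z
                        ev_e[n] = w; ev_p[n] = CUTOFF; ev_g[n] = gen + 1
                        ev_par[n] = ION
                        n += 1
                    else:
                        discarded += w
                continue
            if k == ATT:
                if n >= cap_ev:
                    return n, discarded, _OVERFLOW_EVENTS
                ev_x[n] = x; ev_y[n] = y; ev_z[n] = z
                ev_e[n] = e; ev_p[n] = ATT; ev_g[n] = gen
                ev_par[n] = ATT
                n += 1
                break
            # EXC or VIB: fixed loss, no secondary
            de = loss[c]
            if de > e:
                de = e
            if n >= cap_ev:
                return n, discarded, _OVERFLOW_EVENTS
            ev_x[n] = x; ev_y[n] = y; ev_z[n] = z
            ev_e[n] = de; ev_p[n] = k; ev_g[n] = gen
            ev_par[n] = k
            n += 1
            e -= de
            last_kind = k
    return n, discarded, _OK


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def _resolve_seed(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng) & 0x7FFFFFFF
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(0, 2**31 - 1))
    raise TypeError("rng must be an int seed or numpy Generator")


def _enabled_mask(xs_set: xsmod.CrossSectionSet, enabled_processes) -> np.ndarray:
    if enabled_processes is None:
        return np.ones(len(xs_set.channels), dtype=np.bool_)
    kinds = {NAME_KINDS[p] if isinstance(p, str) else int(p) for p in enabled_processes}
    return np.array([ch.kind in kinds for ch in xs_set.channels], dtype=np.bool_)


def simulate_track(e0: float, xs_set: xsmod.CrossSectionSet, rng,
                   cutoff: float = 1.0, e_local: float = 100.0,
                   max_elastic: int = 1_000_000, record_elastic: bool = False,
                   enabled_processes=None, deposit_subthreshold: bool = True,
                   track_id: int = 0) -> Track:
    """Simulate one primary of ``e0`` eV plus its full cascade.

    ``rng`` is an integer seed or a numpy Generator (a seed is drawn from
    it); a fixed seed gives a bit-identical track.  ``enabled_processes``
    optionally restricts the channel set by process name; with
    ``deposit_subthreshold=False`` energy that no enabled channel can absorb
    is dropped and reported in ``Track.discarded`` instead of deposited.
    """
    seed = _resolve_seed(rng)
    if e0 < 0:
        raise ValueError("primary energy must be >= 0")
    if cutoff < xs_set.energy_domain[0]:
        raise ValueError("cutoff below the cross-section energy domain")
    if e0 <= cutoff:
        # below-cutoff source: a single local deposit (not an error)
        return Track(
            primary_energy=e0,
            position=np.zeros((1, 3)),
            edep=np.array([e0]),
            process=np.array([CUTOFF], dtype=np.uint8),
            generation=np.zeros(1, dtype=np.int32),
            parent=np.array([CUTOFF], dtype=np.uint8),
            seed=seed, xs_label=xs_set.label, cutoff=cutoff, track_id=track_id,
        )
    if e0 > xs_set.energy_domain[1]:
        raise xsmod.DomainError(f"E0={e0} eV above the cross-section domain")
    tab = xs_set.tabulate()
    enabled = _enabled_mask(xs_set, enabled_processes)
    cap_ev = max(int(1.6 * e0) + 1024, 4096)
    cap_st = 1 << 14
    while True:
        ev_x = np.empty(cap_ev); ev_y = np.empty(cap_ev); ev_z = np.empty(cap_ev)
        ev_e = np.empty(cap_ev)
        ev_p = np.empty(cap_ev, dtype=np.uint8)
        ev_g = np.empty(cap_ev, dtype=np.int32)
        ev_par = np.empty(cap_ev, dtype=np.uint8)
        st = [np.empty(cap_st) for _ in range(7)] + [np.empty(cap_st, dtype=np.int32)]
        n, discarded, status = _simulate(
            float(e0), seed, tab.sigma, tab.log10_e0, tab.dlog10, tab.kind,
            tab.threshold, tab.binding, tab.loss, tab.hard_fraction,
            tab.soft_scale, tab.density, float(cutoff), float(e_local), int(max_elastic),
            enabled, deposit_subthreshold, record_elastic,
            ev_x, ev_y, ev_z, ev_e, ev_p, ev_g, ev_par, *st,
        )
        if status == _OVERFLOW_EVENTS:
            cap_ev *= 2
            continue
        if status == _OVERFLOW_STACK:
            cap_st *= 2
            continue
        break
    pos = np.column_stack([ev_x[:n], ev_y[:n], ev_z[:n]])
    return Track(
        primary_energy=float(e0), position=pos, edep=ev_e[:n].copy(),
        process=ev_p[:n].copy(), generation=ev_g[:n].copy(),
        parent=ev_par[:n].copy(), seed=seed, xs_label=xs_set.label,
        cutoff=cutoff, track_id=track_id, discarded=float(discarded),
    )


def simulate_batch(source, n: int, xs_set: xsmod.CrossSectionSet, seed: int,
                   **kwargs) -> list[Track]:
    """Simulate ``n`` independent primaries.

    ``source`` is a mono-energy in eV, or an object with a
    ``sample_energies_eV(n, rng)`` method (an electron source spectrum).
    Per-track sub-seeds derive deterministically from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(int(seed))
    sub = ss.generate_state(n + 1)
    rng = np.random.default_rng(sub[0])
    if np.isscalar(source):
        energies = np.full(n, float(source))
    else:
        energies = np.asarray(source.sample_energies_eV(n, rng), dtype=float)
    tracks = []
    for i in range(n):
        tracks.append(
            simulate_track(energies[i], xs_set, int(sub[i + 1]) & 0x7FFFFFFF,
                           track_id=i, **kwargs)
        )
    return tracks


def energy_balance(track: Track) -> float:
    """Residual primary_energy - sum(edep); ~0 for unrestricted transport."""
    return track.primary_energy - track.total_edep()


def process_energy_fractions(tracks, fold_cutoff_to_parent: bool = False) -> dict[str, float]:
    """Fraction of total deposited energy per process over a track list.

    Terminal sub-cutoff deposits are reported under ``"cutoff"`` by default;
    with ``fold_cutoff_to_parent`` they are attributed to the channel that
    produced the stopping electron.
    """
    totals: dict[int, float] = {}
    grand = 0.0
    for tr in tracks:
        proc = tr.parent if fold_cutoff_to_parent else tr.process
        for k in np.unique(proc):
            m = proc == k
            s = float(tr.edep[m].sum())
            totals[int(k)] = totals.get(int(k), 0.0) + s
            grand += s
    if grand <= 0.0:
        raise ValueError("zero total deposited energy")
    return {KIND_NAMES[k]: v / grand for k, v in sorted(totals.items())}


# --------------------------------------------------------------------------
# track file I/O
# --------------------------------------------------------------------------

def write_tracks(tracks, path: str) -> None:
    """Delimited-text track file; one deposition event per row."""
    buf = io.StringIO()
    buf.write("# columns: track_id generation process x_nm y_nm z_nm edep_eV\n")
    for tr in tracks:
        buf.write(
            "# track: id=%d primary_energy=%.17g seed=%d xs_label=%s "
            "cutoff=%.17g discarded=%.17g\n"
            % (tr.track_id, tr.primary_energy, tr.seed, tr.xs_label,
               tr.cutoff, tr.discarded)
        )
        for i in range(tr.n_events):
            buf.write(
                "%d %d %s %.17g %.17g %.17g %.17g\n"
                % (tr.track_id, tr.generation[i], KIND_NAMES[int(tr.process[i])],
                   tr.position[i, 0], tr.position[i, 1], tr.position[i, 2],
                   tr.edep[i])
            )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_tracks(path: str) -> list[Track]:
    tracks: list[Track] = []
    cur = None

    def flush():
        if cur is None:
            return
        rows = cur["rows"]
        pos = np.array([[r[3], r[4], r[5]] for r in rows]) if rows else np.zeros((0, 3))
        tracks.append(Track(
            primary_energy=cur["primary_energy"], position=pos,
            edep=np.array([r[6] for r in rows]),
            process=np.array([r[2] for r in rows], dtype=np.uint8),
            generation=np.array([r[1] for r in rows], dtype=np.int32),
            parent=np.array([r[2] for r in rows], dtype=np.uint8),
            seed=cur["seed"], xs_label=cur["xs_label"], cutoff=cur["cutoff"],
            track_id=cur["id"], discarded=cur["discarded"],
        ))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("track:"):
                    flush()
                    kv = dict(tok.split("=", 1) for tok in body.split(":", 1)[1].split())
                    cur = {
                        "id": int(kv["id"]),
                        "primary_energy": float(kv["primary_energy"]),
                        "seed": int(kv["seed"]),
                        "xs_label": kv["xs_label"],
                        "cutoff": float(kv["cutoff"]),
                        "discarded": float(kv["discarded"]),
                        "rows": [],
                    }
                continue
            t = line.replace(",", " ").split()
            cur["rows"].append((
                int(t[0]), int(t[1]), NAME_KINDS[t[2]],
                float(t[3]), float(t[4]), float(t[5]), float(t[6]),
            ))
    flush()
    return tracks
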