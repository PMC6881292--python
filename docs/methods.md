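# Methods

## Scope and model chain

`microtrack` computes microdosimetric lineal-energy statistics for
electrons and photon fields in liquid water, and relates them to DNA
double-strand-break (DSB) induction.  The chain has three stages:

1. **photon → electron source** (`spectra`): an analytic photon spectrum
   (kVp tube or 6 MV linac) or a user-supplied spectrum file is converted
   to a secondary-electron source spectrum by single-interaction sampling;
2. **electron transport** (`xs`, `transport`): every source electron and
   its full secondary cascade is followed collision by collision to a
   1 eV cutoff, emitting point energy deposits;
3. **site scoring** (`scoring`): deposits are scored in spherical sites on
   a per-track lattice and reduced to y, f(y), d(y), y_F and y_D; the
   `rbe` module handles the biological ratios.

All results carry the cross-section set label, site radius and seeds.

## Electron collision model

Five channels are simulated. Cross sections are tabulated on a 768-point
log grid over 1 eV–10 MeV and linearly interpolated, with hard threshold
masking.

- **Ionization** — relativistic binary-encounter-Bethe (RBEB; Kim, Santos
  & Parente 2000) per molecular orbital, with the vapor orbital constants
  of Hwang, Kim & Rudd (1996).  The model is parameter-free and matches
  measured water ionization cross sections at the ~10% level (peak
  ≈ 2.5×10⁻¹⁶ cm² near 100 eV).
- **Electronic excitation** — five discrete levels (8.22–13.77 eV) with a
  Born-like shape A·(R²/(E·E_j))·(1−E_j/E)⁵·ln(e+E/E_j).  The slow
  near-threshold rise keeps excitation weak below ~30 eV, the regime where
  event-by-event water codes disagree most; the overall scale is a
  design-time constant (see calibration below).
- **Elastic** — screened Rutherford with Molière screening, summed over
  the O and two H atoms, multiplied by a tabulated low-energy enhancement
  (×2.7 at 100 eV → ×1 at 300 keV).  Screened Rutherford alone undershoots
  measured and partial-wave integrated elastic cross sections of water
  several-fold below 10 keV; the enhancement restores the measured
  magnitudes, and with it the simulated penetration-to-CSDA-range detour
  factors (~0.4 at 1–10 keV) match published electron-range behaviour.
  Deflections are sampled from the screened-Rutherford angular kernel
  (Z = 8; oxygen dominates).
- **Vibrational excitation** — bending (0.198 eV) and stretching
  (0.453 eV) modes as interpolation tables at the resonance-enhanced upper
  range of the vapor compilations (Itikawa & Mason 2005).  Together with
  the weak low-energy electronic excitation this places the set in the
  vapor-like regime where sub-excitation electrons lose energy mainly
  vibrationally.
- **Dissociative attachment** — the ~6.5 eV resonance; the electron is
  absorbed and its remaining energy deposited locally.

### Ionization energy sharing: a two-constraint calibration

The ejected-electron energy W on [0, (E−B)/2] follows a two-component
model: with probability f(E) the exact Møller knock-on tail
dσ/dW ∝ 1/W² on [50 eV, Wmax], otherwise a glancing form ∝ (W+a)⁻³.
Two independent physical anchors fix the free functions per grid energy:

1. **f(E)** equals the Møller tail cross section above the 50 eV
   glancing/knock-on partition divided by the RBEB total — so the δ-ray
   production rate above 50 eV is exact close-collision physics at every
   W;
2. **a(E)** is solved by bisection so the set's collision stopping power
   follows a reference curve: the Bethe–Møller formula with I = 78 eV
   (ICRU 90 value; reproduces ICRU 37 water stopping within ~1–2%) above
   10 keV, and representative liquid-water dielectric-model values from
   300 eV to 10 keV.  Below 300 eV both are frozen (residual range is
   nanometres).

The same two anchors — exact δ-ray rates and ICRU-level stopping — are
what condensed-history codes are built on; here they discipline an
event-by-event sampler.  A test (`test_xs.py`) verifies the calibrated
stopping stays within 2% of the reference across 1 keV–1 MeV.

The faster outgoing electron is by convention the surviving primary
(Wmax = (E−B)/2).  Secondaries are emitted isotropically into the forward
hemisphere of the parent direction; inelastic collisions do not deflect
the primary (forward-peaked approximation; micrometre-scale scoring is
insensitive).  Above ~10 keV the RBEB form supplies the relativistic
kinematics.

## Transport

The traversal is stack-based with free flights sampled exponentially from
1/(NΣσ).  Below 100 eV the electron enters a **local-slowdown mode**:
elastic scattering is dropped from the channel competition and deposits
are placed at the current position without flights.  The residual range
below 100 eV is a few nanometres — invisible to sites of ≥100 nm radius —
while the per-process energy bookkeeping is exactly preserved; this cuts
the event count per track several-fold.  A configurable cap on
consecutive elastic events (10⁶) guarantees termination for pathological
channel sets.

Electrons reaching the 1 eV cutoff (or an energy where no enabled channel
has positive cross section) deposit their remaining energy locally,
tagged with the pseudo-process `cutoff`; the channel that produced the
stopping electron is recorded so fractions can optionally be folded into
the parent process.  Energy conservation per track is exact to floating
tolerance by construction and asserted at 10⁻⁶ relative in the tests.
Tracks are bit-reproducible from their seed (batch sub-seeds derive from
a single `SeedSequence`).

Radiative (bremsstrahlung) losses are not modelled: for 6 MV secondary
electrons the radiative fraction of the stopping power is ~5% at the
spectrum top and ~1% at its mean, within the stated accuracy of the tool.
The density-effect correction to stopping is likewise omitted (few
percent at MeV energies).

## Site scoring and estimators

Scoring positions form a cubic lattice of spacing g anchored, by default,
at the first deposit of each track (an optional explicit origin supports
the lattice-translation tests); a spherical site of radius r_d = g is
centred on every node, so neighbouring sites overlap — one deposit can
contribute to up to seven sites.  The boundary rule is inclusive,
|x − c| ≤ r_d, implemented with a 10⁻¹² relative tolerance on r² because
the anchor sits exactly on a node and its face neighbours lie at exactly
r_d.  A non-overlapping mode (g = 2 r_d) is available.

The production scorer hashes events into an open-addressing table keyed
by packed node indices (O(events)); its contract is exact agreement with
a brute-force all-nodes × all-events oracle, enforced in the tests on
random toy tracks.

Sites are scored per track (each primary is one independent event class)
and only occupied sites (ε > 0) enter the statistics — the standard
single-event convention, without which the d(y) moments are undefined.
The pooled-site moment estimator y_D = Σy²/Σy is computed per replicate;
the reported value is the mean over replicates (default 3) with its
standard deviation.  Default site diameter is 1.0 µm (r_d = 500 nm), the
conventional TEPC-equivalent site; r_d is fully configurable down to
nanometre scales and is recorded in every result.

A process filter on scoring supports the "energy-transfer restriction"
experiment: scoring only ionization + electronic-excitation deposits
("case 2") against all deposits ("case 1").  Restriction is applied at
scoring rather than in transport because re-depositing sub-threshold
energy locally (the transport-side sub-threshold rule) would leave site
energies nearly unchanged; the scoring filter expresses the intended
physics — which processes count as energy transfer.

## Photon stage

- **kVp tubes** — Kramers continuum ∝ (kVp/E − 1) behind 1 mm Al
  equivalent inherent filtration; tungsten K lines (59.3/58.0/67.2/69.1
  keV, Kα₁:Kα₂:Kβ weights) when the potential exceeds the 69.5 keV K
  edge, carrying a fluence fraction 0.15·(1 − 69.5/kVp).  Added Al/Cu/
  water layers attenuate per-bin by exp(−Σμᵢ(E)tᵢ) from baked-in NIST
  mass-attenuation tables; filtration therefore commutes and can only
  harden the beam.
- **6 MV linac** — a 6 MeV-endpoint Kramers continuum filtered through a
  water-equivalent flattening filter of 22 cm, chosen so the surface
  fluence-mean energy (~1.7 MeV) matches published Monte Carlo 6 MV
  spectra, then attenuated (narrow-beam) through the requested water
  depth.  Only the in-field primary beam is modelled; out-of-field
  fields, which are dominated by collimator and phantom scatter, must be
  supplied as spectrum files.
- **Electron conversion** — photons are drawn ∝ fluence × (photoelectric
  + incoherent) coefficient of water; the branch is drawn from the two
  coefficients (photoelectric from an XCOM-style table, incoherent as
  free-electron Klein–Nishina × electron density); photoelectrons carry
  E_γ minus the 543 eV oxygen K binding, Compton electrons are sampled by
  Kahn's method (validated against the closed-form Compton edge and the
  known mean transfer fractions).  The resulting histogram is the
  **first-collision source spectrum**; the full slowing-down physics is
  then supplied by the electron transport itself.  The alternative
  convention — sampling primaries from the equilibrium slowing-down
  fluence — was evaluated and rejected: combined with full re-transport
  it double-weights the high-energy part of the population.

No in-phantom photon scatter build-up is modelled anywhere: at depth the
real photon field acquires a soft scattered component that raises y_D,
so the analytic 6 MV depth model is expected to understate the measured
dose-mean lineal energy of a broad therapy beam (see Limitations).

## DSB effectiveness

RBE_DSB is the ratio of background-subtracted foci yields per nucleus at
equal dose, subject over the 200 kVp reference, with the per-nucleus
standard deviations propagated in quadrature (a flag switches to standard
errors).  The continuous-irradiation correction divides a measured yield
by G = (1 − e^(−aT))/(aT), the surviving fraction under uniform induction
with first-order repair over [0, T]; the closed form is validated against
numerical integration of the kinetics to 10⁻⁹ in the tests.  The
post-irradiation fixation delay is treated as common to all conditions
and cancels in the ratio; only the delivery-time differential is
corrected.  Flow-cytometry intensities are mapped to counts by a
least-squares linear calibration against microscopy, applied before
background subtraction.

## Synthetic data

The `synth` module generates everything the tests need: hand-specified
toy tracks (scoring oracles), degenerate one-channel cross-section sets
(hand-countable transport), and per-nucleus foci counts emulating the
eight benchmark irradiation conditions — reference mean 30.2 foci at
1 Gy, diagnostic fields 30.2–41.9, therapy fields 22.2–25.9, with a
normal per-nucleus dispersion of sd ≈ 1.05 × mean chosen to reproduce the
large propagated RBE intervals (±1.5 on a unity ratio).  Synthetic foci
are draws from an assumed dispersion model, not cell biology: they carry
no plate, batch or imaging structure, so passing RBE tests demonstrates
the estimator arithmetic, not robustness to real assay artefacts.
Likewise the toy tracks exercise scoring geometry, not transport physics.

## Numerical choices

- Cross-section grid: 768 log points, 1 eV–10 MeV; threshold-masked
  linear interpolation; channel probabilities normalised to Σ = 1 within
  10⁻¹².
- Per-track event buffers grow by doubling on overflow; the secondary
  stack likewise (no recursion).
- Site hashing: 64-bit keys packing three signed 21-bit node indices;
  linear probing at ≤60% load with doubling rehash.
- Histograms: 60 log-spaced bins spanning the pooled y range; f(y) and
  d(y) normalised to unit integral (asserted at 10⁻⁹).
- Seeds: a single user seed feeds `numpy.random.SeedSequence`; every
  stage (photon sampling, per-track transport, replicates) receives a
  derived sub-seed < 2³¹.  Fixed seed ⇒ bit-identical results end to end.
- Degenerate inputs: below-cutoff primaries become a single local
  deposit; empty site lists and zero-energy track sets raise errors
  rather than returning NaNs.

## Limitations

- **Cross-section provenance dominates y_D.**  Published event-by-event
  water codes differ by tens of percent in y_D at equal site size; the
  in-house code this tool emulates reports mono-electron y_D values about
  1.4× above Geant4-DNA-based references.  The default set here is
  calibrated to ICRU stopping and exact Møller δ-ray rates, which places
  it on the conservative side of that divide: kVp-field y_D values
  reproduce TEPC-benchmarked references within ~10%, while MeV-electron
  fields come out ~30% lower than the benchmark.  The provider contract
  (`CrossSectionSet`, serializable to text) exists so an alternative set
  can be dropped in; every result records the set label.
- **6 MV depth spectra are primary-only.**  Without in-phantom scatter
  the analytic depth model misses the soft photon component of a broad
  beam at depth, compounding the previous point for therapy fields.  The
  kVp > 6 MV ordering of y_D — the tool's directional statement — is
  robust to both effects.
- **Energy partition.**  With this set, ionization + electronic
  excitation carry ~80% of the deposited energy (slow channels ~20%),
  at the fast end of the 70–85% range spanned by published water codes;
  partitions below ~75% would require vibrational/attachment magnitudes
  beyond published data.
- No bremsstrahlung, no density effect, vapor-derived low-energy channel
  data applied to liquid water, walled-TEPC effects in the benchmark
  values are not modelled.
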