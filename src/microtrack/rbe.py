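"""DNA double-strand-break effectiveness analysis.

Relates measured γ-H2AX foci counts (a per-nucleus DSB proxy) to relative
biological effectiveness at the DSB endpoint,

    RBE_DSB = DSB_subject / DSB_reference,

with the 200 kVp X-ray field as the conventional reference, propagating the
per-nucleus standard deviations in quadrature.  Also provides the
continuous-irradiation repair correction of the microdosimetric-kinetic
family: during a protracted delivery of duration T, first-order repair at
rate a removes a fraction of the induced foci, so the measured yield
relates to the initial induction yield N0 by

    N_meas = N0 * G,    G = (1 - exp(-aT)) / (aT),

the same G factor that arises from uniform induction with first-order decay
over [0, T].  Flow-cytometry fluorescence is mapped to foci counts through
a least-squares linear calibration against microscopy counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class FociMeasurement:
    """Mean +- s.d. foci per nucleus for one irradiation condition."""

    mean_foci: float
    sd: float
    n_cells: int = 1
    modality: str = "microscopy"
    background_subtracted: bool = True
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.mean_foci < 0 or self.sd < 0:
            raise ValueError("mean and sd must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.modality not in ("microscopy", "flow"):
            raise ValueError("modality must be 'microscopy' or 'flow'")


@dataclass
class RepairParameters:
    """First-order DSB repair rate and dose-delivery time."""

    repair_rate_per_h: float
    delivery_time_min: float

    def __post_init__(self) -> None:
        if self.repair_rate_per_h < 0 or self.delivery_time_min < 0:
            raise ValueError("repair rate and delivery time must be >= 0")


@dataclass
class RBEResult:
    rbe: float
    rbe_sd: float
    subject_label: str = ""
    reference_label: str = ""


@dataclass
class IntensityCalibration:
    """Linear fluorescence-intensity -> foci-count map, fit by least squares."""

    slope: float
    intercept: float
    slope_se: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0 (positively "
                             "correlated intensity and count)")

    @classmethod
    def fit(cls, intensity, counts) -> "IntensityCalibration":
        x = np.asarray(intensity, dtype=float)
        y = np.asarray(counts, dtype=float)
        if len(x) < 2 or np.ptp(x) == 0:
            raise ValueError("need >= 2 distinct intensity values")
        res = stats.linregress(x, y)
        if res.slope <= 0:
            raise ValueError("degenerate calibration: non-positive slope")
        return cls(slope=float(res.slope), intercept=float(res.intercept),
                   slope_se=float(res.stderr))


def rbe_dsb(subject: FociMeasurement, reference: FociMeasurement,
            use_standard_error: bool = False) -> RBEResult:
    """RBE at the DSB endpoint: subject/reference foci-yield ratio.

    The uncertainty is the quadrature propagation of the per-nucleus
    standard deviations (matching how such intervals are conventionally
    quoted); ``use_standard_error`` divides each spread by sqrt(n_cells).
    """
    if reference.mean_foci <= 0:
        raise ValueError("reference yield must be > 0")
    rbe = subject.mean_foci / reference.mean_foci
    s_s, s_r = subject.sd, reference.sd
    if use_standard_error:
        s_s = s_s / np.sqrt(subject.n_cells)
        s_r = s_r / np.sqrt(reference.n_cells)
    rel = 0.0
    if subject.mean_foci > 0:
        rel = np.hypot(s_s / subject.mean_foci, s_r / reference.mean_foci)
    return RBEResult(rbe=float(rbe), rbe_sd=float(rbe * rel),
                     subject_label=subject.condition_label,
                     reference_label=reference.condition_label)


def repair_g_factor(params: RepairParameters) -> float:
    """G = (1 - e^{-aT})/(aT); the surviving fraction of foci at the end of
    a uniform continuous delivery with first-order repair.  G -> 1 as
    aT -> 0 (acute delivery or no repair)."""
    at = params.repair_rate_per_h * params.delivery_time_min / 60.0
    if at <= 0.0:
        return 1.0
    if at < 1e-8:
        return 1.0 - 0.5 * at
    return float(-np.expm1(-at) / at)


def mk_initial_yield(measured: float, params: RepairParameters) -> float:
    """Initial DSB induction yield from a yield measured after continuous
    delivery: N0 = N_meas / G."""
    if measured < 0:
        raise ValueError("measured yield must be >= 0")
    return measured / repair_g_factor(params)


def intensity_to_dsb(intensity, calibration: IntensityCalibration):
    """Map fluorescence intensity to foci count via the linear calibration."""
    x = np.asarray(intensity, dtype=float)
    out = calibration.slope * x + calibration.intercept
    return float(out) if out.ndim == 0 else out


def fit_rbe_vs_yd(points) -> dict:
    """Ordinary least squares of RBE_DSB on the dose-mean lineal energy y_D.

    ``points`` is a sequence of (y_D, RBEResult-or-float).  Returns slope,
    intercept, residuals and the slope sign.
    """
    yd = np.array([p[0] for p in points], dtype=float)
    rbe = np.array([p[1].rbe if isinstance(p[1], RBEResult) else float(p[1])
                    for p in points])
    if len(yd) < 2 or np.ptp(yd) == 0:
        raise ValueError("need >= 2 points with distinct y_D")
    res = stats.linregress(yd, rbe)
    fitted = res.intercept + res.slope * yd
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "slope_se": float(res.stderr),
        "residuals": rbe - fitted,
        "positive_slope": bool(res.slope > 0),
    }


# --------------------------------------------------------------------------
# foci-table I/O: one condition per row
# --------------------------------------------------------------------------

def write_foci(measurements, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: label mean sd n_cells modality\n")
        for m in measurements:
            fh.write("%s %.17g %.17g %d %s\n"
                     % (m.condition_label.replace(" ", "_") or "-",
                        m.mean_foci, m.sd, m.n_cells, m.modality))


def read_foci(path: str) -> list[FociMeasurement]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.replace(",", " ").split()
            out.append(FociMeasurement(
                condition_label=tok[0].replace("_", " "),
                mean_foci=float(tok[1]), sd=float(tok[2]),
                n_cells=int(tok[3]), modality=tok[4]))
    return out
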