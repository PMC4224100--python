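"""Component-timecourse post-processing and subject-level quality control.

The post-processing chain applied to back-reconstructed component
timecourses is, in order: polynomial detrending (up to cubic), multiple
regression of the six realignment parameters and their temporal
derivatives, median-absolute-deviation despiking with spline replacement,
and zero-phase low-pass filtering (0.15 Hz cutoff). QC excludes subjects
with maximum head translation above 2 mm or signal-to-fluctuation-noise
ratio (SFNR) below 275.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

__all__ = [
    "SubjectTimecourses",
    "MotionParams",
    "QCReport",
    "zscore_voxels",
    "detrend_poly",
    "regress_nuisance",
    "despike_mad",
    "lowpass_filter",
    "compute_qc",
    "postprocess_timecourses",
]

MAD_SCALE = 1.4826  # makes MAD consistent with the SD of a Gaussian

MAX_TRANSLATION_MM = 2.0
MIN_SFNR = 275.0


@dataclass
class SubjectTimecourses:
    """One subject's component signals: a T x C matrix sampled every TR seconds."""

    values: np.ndarray
    TR: float
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.component_ids:
            self.component_ids = [
                f"IC{c + 1}" for c in range(self.values.shape[1])
            ]
        if len(self.component_ids) != self.values.shape[1]:
            raise ValueError("component_ids length must equal column count")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def C(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "SubjectTimecourses":
        return SubjectTimecourses(
            values=values, TR=self.TR, component_ids=list(self.component_ids)
        )


@dataclass
class MotionParams:
    """Realignment parameters: T x 6 (3 translations in mm, 3 rotations in rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 6:
            raise ValueError("motion parameters must have 6 columns")


@dataclass
class QCReport:
    max_translation: float
    sfnr: float
    excluded: bool
    reason: str = ""


def zscore_voxels(X: np.ndarray) -> np.ndarray:
    """Z-score each voxel (row) timeseries to zero mean, unit sample variance.

    Constant rows cannot be normalized; they are zeroed with a warning.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant voxel series zeroed during z-scoring"
        )
        sd[flat] = 1.0
    out = (X - mu) / sd
    out[flat] = 0.0
    return out


def _poly_design(T: int, max_order: int) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, T)
    return np.vander(t, N=max_order + 1, increasing=True)


def _residualize(Y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ beta


def detrend_poly(
    tc: SubjectTimecourses, max_order: int = 3
) -> SubjectTimecourses:
    """Remove polynomial trends up to ``max_order`` (default cubic) per column."""
    if tc.T <= max_order + 1:
        raise ValueError("timecourse too short for requested detrend order")
    design = _poly_design(tc.T, max_order)
    return tc.copy_with(_residualize(tc.values, design))


def motion_derivatives(motion: MotionParams) -> np.ndarray:
    """First backward differences of the realignment parameters, first row zero."""
    d = np.zeros_like(motion.values)
    d[1:] = np.diff(motion.values, axis=0)
    return d


def regress_nuisance(
    tc: SubjectTimecourses, motion: MotionParams
) -> SubjectTimecourses:
    """Regress out the 6 realignment parameters and their temporal derivatives."""
    if motion.values.shape[0] != tc.T:
        raise ValueError("motion parameters not aligned with timecourses")
    design = np.column_stack(
        [np.ones(tc.T), motion.values, motion_derivatives(motion)]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient nuisance design; collinear regressors are "
            "effectively dropped by the least-squares solve"
        )
    return tc.copy_with(_residualize(tc.values, design))


def despike_mad(
    tc: SubjectTimecourses, z_thresh: float = 4.0
) -> tuple[SubjectTimecourses, dict[int, np.ndarray]]:
    """Flag outliers per column by robust z-score and replace them by a cubic
    spline fitted through the clean samples.

    A sample is flagged when ``|x - median| / (1.4826 * MAD) > z_thresh``.
    Boundary outliers, where the spline would extrapolate, take the nearest
    clean value. Returns the cleaned timecourses and a map of column index
    to flagged timepoint indices; non-flagged samples are never altered.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    out = tc.values.copy()
    flagged: dict[int, np.ndarray] = {}
    t = np.arange(tc.T)
    for c in range(tc.C):
        x = out[:, c]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            # flat column up to isolated deviations: any deviation is a spike
            dev = np.abs(x - med) > 0
        else:
            dev = np.abs(x - med) / (MAD_SCALE * mad) > z_thresh
        if not dev.any():
            continue
        if dev.mean() > 0.5:
            warnings.warn(
                f"column {c}: >50% of samples flagged; replacing flagged "
                "samples with the column median"
            )
            out[dev, c] = med
            flagged[c] = np.where(dev)[0]
            continue
        clean = ~dev
        spline = CubicSpline(t[clean], x[clean])
        bad = np.where(dev)[0]
        lo, hi = t[clean][0], t[clean][-1]
        for b in bad:
            if b < lo:
                out[b, c] = x[clean][0]
            elif b > hi:
                out[b, c] = x[clean][-1]
            else:
                out[b, c] = spline(b)
        flagged[c] = bad
    return tc.copy_with(out), flagged


def lowpass_filter(
    tc: SubjectTimecourses, cutoff_hz: float = 0.15, order: int = 5
) -> SubjectTimecourses:
    """Zero-phase Butterworth low-pass filter (forward-backward)."""
    nyquist = 0.5 / tc.TR
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist {nyquist} Hz"
        )
    sos = signal.butter(order, cutoff_hz / nyquist, btype="low", output="sos")
    filtered = signal.sosfiltfilt(sos, tc.values, axis=0)
    return tc.copy_with(np.ascontiguousarray(filtered))


def compute_qc(
    voxel_by_time: np.ndarray,
    motion: MotionParams,
    roi_mask: np.ndarray,
    max_translation_mm: float = MAX_TRANSLATION_MM,
    min_sfnr: float = MIN_SFNR,
    drift_order: int = 2,
) -> QCReport:
    """Motion and SFNR quality control.

    ``max_translation`` is the largest Euclidean norm of the translation
    vector over time. SFNR is the time-averaged spatial mean over the ROI
    voxels divided by the temporal SD of the spatial-mean series after
    polynomial drift removal. A subject is excluded iff max translation
    exceeds ``max_translation_mm`` or SFNR falls below ``min_sfnr`` (both
    strict inequalities).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask selects no voxels")
    roi = np.asarray(voxel_by_time, dtype=float)[roi_mask]
    mean_series = roi.mean(axis=0)  # spatial mean per timepoint
    sig = float(mean_series.mean())
    design = _poly_design(mean_series.size, drift_order)
    resid = _residualize(mean_series[:, None], design)[:, 0]
    noise = float(resid.std(ddof=1))
    sfnr = np.inf if noise == 0 else sig / noise
    trans = np.linalg.norm(motion.values[:, :3], axis=1)
    max_trans = float(trans.max())
    excluded = False
    reasons = []
    if max_trans > max_translation_mm:
        excluded = True
        reasons.append("motion")
    if sfnr < min_sfnr:
        excluded = True
        reasons.append("sfnr")
    return QCReport(
        max_translation=max_trans,
        sfnr=float(sfnr),
        excluded=excluded,
        reason="+".join(reasons),
    )


def postprocess_timecourses(
    tc: SubjectTimecourses,
    motion: MotionParams | None = None,
    detrend_order: int = 3,
    despike_z: float = 4.0,
    cutoff_hz: float = 0.15,
) -> tuple[SubjectTimecourses, dict[int, np.ndarray]]:
    """Full chain: detrend -> nuisance regression -> despike -> low-pass."""
    tc = detrend_poly(tc, detrend_order)
    if motion is not None:
        tc = regress_nuisance(tc, motion)
    tc, flagged = despike_mad(tc, despike_z)
    tc = lowpass_filter(tc, cutoff_hz)
    return tc, flagged
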