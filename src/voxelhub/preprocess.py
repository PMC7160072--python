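"""Denoising chain for aligned 4-D BOLD data.

The fixed stage order is: discard initial volumes -> motion QC ->
nuisance regression (Friston-24 + tissue signals + intercept + linear
trend) -> temporal band-pass (0.01-0.08 Hz) -> spatial Gaussian smoothing
(6 mm FWHM).  Smoothing may instead be deferred to the degree-centrality
z-map (``after_dc``), since smoothing before voxel-wise correlation
inflates local connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BoldImage, MaskImage, MotionTrace

__all__ = [
    "NuisanceDesign",
    "QcReport",
    "discard_initial_volumes",
    "compute_fd",
    "qc_subject",
    "qc_cohort",
    "build_friston24",
    "build_nuisance_design",
    "regress_nuisance",
    "extract_tissue_signal",
    "bandpass_filter",
    "smooth_gaussian",
    "FWHM_TO_SIGMA",
]

log = logging.getLogger(__name__)

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

MAX_TRANSLATION_MM = 2.0
MAX_ROTATION_DEG = 2.0
FD_SD_LIMIT = 2.5


@dataclass
class NuisanceDesign:
    """Regression design: ``columns`` is t x k, with one name per column."""

    columns: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.float64)
        if self.columns.ndim != 2:
            raise ValueError("design must be 2-D")
        if self.columns.shape[1] != len(self.names):
            raise ValueError("one name per design column required")

    @property
    def n_frames(self) -> int:
        return self.columns.shape[0]

    def hstack(self, other: "NuisanceDesign") -> "NuisanceDesign":
        if other.n_frames != self.n_frames:
            raise ValueError("frame count mismatch between designs")
        return NuisanceDesign(
            np.hstack([self.columns, other.columns]), self.names + other.names
        )


@dataclass
class QcReport:
    """Per-subject motion quality control verdict."""

    subject_id: str
    max_translation_mm: float
    max_rotation_deg: float
    mean_fd_mm: float
    excluded: bool
    reason: str


def discard_initial_volumes(b: BoldImage, n: int = 10) -> BoldImage:
    """Drop the first ``n`` frames (signal-equilibration volumes).

    240 acquired frames with the default n=10 leave 230 analysed frames.
    The caller trims the motion trace in lockstep
    (:meth:`MotionTrace.discard_initial`).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return b
    if n >= b.n_frames:
        raise ValueError(f"cannot discard {n} of {b.n_frames} frames")
    return BoldImage(b.data[..., n:], b.affine, b.tr_seconds)


def compute_fd(m: MotionTrace) -> np.ndarray:
    """Frame-wise displacement, translation-only variant.

    FD_t is the Euclidean norm of the frame-to-frame difference of the
    three translation parameters (mm); FD_0 = 0.  Rotations do not enter
    (they are screened separately by the 2.0 degree rule).
    """
    if m.n_frames < 2:
        raise ValueError("need at least 2 frames for FD")
    d = np.diff(m.translations_mm, axis=0)
    fd = np.zeros(m.n_frames)
    fd[1:] = np.linalg.norm(d, axis=1)
    return fd


def qc_subject(
    m: MotionTrace,
    cohort_fd_mean: float,
    cohort_fd_sd: float,
    subject_id: str = "",
) -> QcReport:
    """Apply the exclusion rules to one subject.

    Excluded if any |translation| >= 2.0 mm, any |rotation| >= 2.0 deg, or
    the subject's mean FD exceeds cohort mean + 2.5 cohort SD.
    """
    max_t = float(np.abs(m.translations_mm).max())
    max_r = float(np.abs(m.rotations_deg).max())
    mean_fd = float(compute_fd(m)[1:].mean())
    reasons = []
    if max_t >= MAX_TRANSLATION_MM:
        reasons.append("translation")
    if max_r >= MAX_ROTATION_DEG:
        reasons.append("rotation")
    if mean_fd > cohort_fd_mean + FD_SD_LIMIT * cohort_fd_sd:
        reasons.append("fd")
    return QcReport(
        subject_id=subject_id,
        max_translation_mm=max_t,
        max_rotation_deg=max_r,
        mean_fd_mm=mean_fd,
        excluded=bool(reasons),
        reason="+".join(reasons),
    )


def qc_cohort(traces: dict[str, MotionTrace]) -> list[QcReport]:
    """QC every subject against cohort-level FD statistics.

    The FD criterion is relative: a subject is flagged when its mean FD
    lies more than 2.5 SD above the cohort mean of mean FDs.
    """
    if not traces:
        raise ValueError("empty cohort")
    mean_fds = {s: float(compute_fd(m)[1:].mean()) for s, m in traces.items()}
    vals = np.array(list(mean_fds.values()))
    mu, sd = float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return [qc_subject(m, mu, sd, subject_id=s) for s, m in traces.items()]


def build_friston24(m: MotionTrace) -> NuisanceDesign:
    """Friston 24-parameter motion expansion.

    For each of the 6 rigid-body parameters p: [p_t, p_t^2, p_{t-1},
    p_{t-1}^2]; the lagged rows at t=0 are zero-filled.
    """
    p = m.params
    if p.shape[1] != 6:
        raise ValueError("expected a 6-column motion trace")
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    cols, names = [], []
    for i in range(6):
        cols += [p[:, i], p[:, i] ** 2, lag[:, i], lag[:, i] ** 2]
        names += [
            f"friston24_p{i + 1}",
            f"friston24_p{i + 1}_sq",
            f"friston24_p{i + 1}_lag",
            f"friston24_p{i + 1}_lag_sq",
        ]
    return NuisanceDesign(np.column_stack(cols), names)


def extract_tissue_signal(b: BoldImage, tissue_mask: MaskImage) -> np.ndarray:
    """Per-frame mean BOLD over a tissue mask (WM or CSF)."""
    tissue_mask.assert_same_grid(b)
    return b.data[tissue_mask.data].mean(axis=0)


def build_nuisance_design(
    m: MotionTrace,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> NuisanceDesign:
    """Full design: Friston-24 (+ WM, CSF) + intercept + linear trend."""
    d = build_friston24(m)
    t = d.n_frames
    extra_cols = []
    extra_names = []
    for sig, name in ((wm_signal, "wm"), (csf_signal, "csf")):
        if sig is not None:
            sig = np.asarray(sig, dtype=np.float64)
            if sig.shape != (t,):
                raise ValueError(f"{name} signal length {sig.shape} != {t} frames")
            extra_cols.append(sig)
            extra_names.append(name)
    trend = np.linspace(-1.0, 1.0, t)
    extra_cols += [np.ones(t), trend]
    extra_names += ["intercept", "linear_trend"]
    return d.hstack(NuisanceDesign(np.column_stack(extra_cols), extra_names))


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the first column that is collinear with its predecessors."""
    Xc = X - X.mean(axis=0)
    # intercept column is all-zero after centering; rank check on the rest
    keep = [i for i in range(X.shape[1]) if names[i] != "intercept"]
    rank = 0
    basis: list[np.ndarray] = []
    for i in keep:
        v = Xc[:, i].copy()
        for b in basis:
            v -= np.dot(b, v) * b
        nv = np.linalg.norm(v)
        scale = np.linalg.norm(Xc[:, i])
        if scale > 0 and nv > 1e-10 * scale:
            basis.append(v / nv)
            rank += 1
        else:
            raise np.linalg.LinAlgError(
                f"design is rank-deficient: column {names[i]!r} is collinear "
                "with earlier columns"
            )


def regress_nuisance(
    b: BoldImage, design: NuisanceDesign, mask: MaskImage
) -> BoldImage:
    """OLS-residualize every in-mask voxel series on the nuisance design.

    The design must contain an intercept and a linear trend.  Out-of-mask
    voxels are zeroed.  Idempotent: re-regressing the residuals on the
    same design changes nothing.
    """
    mask.assert_same_grid(b)
    if "intercept" not in design.names or "linear_trend" not in design.names:
        raise ValueError("nuisance design must include intercept and linear_trend")
    X = design.columns
    if X.shape[0] != b.n_frames:
        raise ValueError(f"design has {X.shape[0]} rows for {b.n_frames} frames")
    _check_full_rank(X, design.names)
    Y = b.data[mask.data].T  # t x N
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = np.zeros_like(b.data)
    out[mask.data] = resid.T
    return BoldImage(out, b.affine, b.tr_seconds)


def bandpass_filter(
    b: BoldImage, low_hz: float = 0.01, high_hz: float = 0.08
) -> BoldImage:
    """Zero-phase ideal band-pass in the frequency domain.

    Each voxel series is linearly detrended, transformed with an FFT, and
    every frequency bin outside [low, high] Hz (including DC) is zeroed —
    the REST/DPARSF "ideal filter".  Passband gain is 1 for on-grid
    frequencies; the response is exactly zero phase.
    """
    nyquist = 1.0 / (2.0 * b.tr_seconds)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyquist:.4f})"
        )
    t = b.n_frames
    x = b.data.reshape(-1, t)
    # linear detrend (removes the component the DC/lowest bins cannot represent)
    tt = np.arange(t, dtype=np.float64)
    tt -= tt.mean()
    slope = (x @ tt) / np.dot(tt, tt)
    x = x - slope[:, None] * tt - x.mean(axis=1, keepdims=True)
    freqs = np.fft.rfftfreq(t, d=b.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(x, axis=1)
    spec[:, ~keep] = 0.0
    y = np.fft.irfft(spec, n=t, axis=1)
    return BoldImage(y.reshape(b.data.shape), b.affine, b.tr_seconds)


def smooth_gaussian(img, fwhm_mm: float = 6.0):
    """Spatial Gaussian smoothing with per-axis sigma in voxel units.

    ``sigma_mm = fwhm / (2 sqrt(2 ln 2))`` converted per axis by the voxel
    size from the affine; boundaries are handled by reflection so the mean
    is preserved.  Accepts a :class:`BoldImage` (smoothes each frame) or a
    ``(3-D array, affine)`` pair; ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")

    if isinstance(img, BoldImage):
        if fwhm_mm == 0:
            return img
        sigma_vox = fwhm_mm * FWHM_TO_SIGMA / img.voxel_sizes_mm()
        out = ndimage.gaussian_filter(
            img.data, sigma=(*sigma_vox, 0.0), mode="reflect"
        )
        return BoldImage(out, img.affine, img.tr_seconds)

    data, affine = img
    data = np.asarray(data, dtype=np.float64)
    if fwhm_mm == 0:
        return data.copy()
    voxmm = np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxmm
    return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect")
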