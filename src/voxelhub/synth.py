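"""Synthetic two-group resting-state BOLD cohort with implanted hubs.

The generator emulates the study conditions every downstream stage is
verified against: a two-group cohort (19 patients vs 20 controls) of
240-frame, TR = 2 s scans on a 3 mm isotropic 30 x 36 x 30 grid, already
aligned on a common grid.  Connectivity effects are implanted through
*loadings* on shared band-limited (0.01-0.08 Hz) latent signals — not
through amplitude — because degree centrality measures correlation
structure:

    y_v(t) = baseline + sum_h lambda_{v,h} s_h(t) + lambda_net s_{p(v)}(t)
             + drift_v(t) + AR(1) noise

where lambda_{v,h} is the subject's hub loading tapered by a Gaussian of
the hub radius inside the hub sphere and 0 outside.  Patients receive a
reduced hub loading (the implanted DC deficit).  Per-subject hub-loading
jitter supplies realistic between-subject variance.

The background gray matter is organized into fixed "resting-state
network" parcels p(v) (a Voronoi parcellation, identical for every
subject of a cohort), each with its own band-limited latent at a
moderate loading.  This matters for the z-scored DC maps downstream: in
a phantom whose background is pure noise, voxel-wise DC is dominated by
chance threshold crossings whose subject-to-subject fluctuations are not
shared by hub voxels, so the within-mask z-normalization injects
variance and buries the implanted deficit; genuine background
connectivity makes the DC field — like a real one — dominated by stable
structure.  Hub spheres are carved out of the parcellation so the
implanted effect remains the only group difference.  An optional global
background latent (default off — a voxel's correlation to a hub
saturates under Pearson normalization, so it mostly adds between-subject
noise) can overlay weak whole-mask connectivity.

Clinical covariates mimic the study's demographics table; a chosen
variable (FEV1 %predicted by default) can be coupled to the standardized
within-group hub-loading jitter with a target partial correlation given
age/sex/education.  Everything is reproducible from the single seed in
the spec, and the JSON manifest records every injected effect.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import (
    BoldImage,
    CohortTable,
    MaskImage,
    MotionTrace,
    save_bold,
    save_cohort,
    save_mask,
    save_motion,
    world_to_voxel,
)

__all__ = [
    "HubSpec",
    "SynthSpec",
    "generate_subject_bold",
    "generate_cohort",
    "generate_covariates",
    "generate_null_zmaps",
    "band_limited_signal",
    "ar1_noise",
]

log = logging.getLogger(__name__)

BASELINE = 100.0

#: group-level moments used for the covariate model (mean, sd) per group
COVARIATE_MODEL = {
    "age": {"patient": (62.7, 5.9), "control": (60.8, 6.3)},
    "education": {"patient": (5.5, 3.2), "control": (6.3, 2.7)},
    "pack_years": {"patient": (27.9, 20.5), "control": (8.9, 6.3)},
    "fev1_pct": {"patient": (46.1, 20.6), "control": (97.1, 16.9)},
    "fvc_pct": {"patient": (67.5, 19.9), "control": (96.5, 15.8)},
    "fev1_fvc": {"patient": (55.8, 16.3), "control": (81.2, 8.3)},
    "sao2": {"patient": (95.5, 2.6), "control": (97.8, 1.8)},
    "paco2": {"patient": (49.3, 8.0), "control": (38.5, 4.3)},
    "ph": {"patient": (7.37, 0.05), "control": (7.40, 0.03)},
    "moca": {"patient": (18.4, 4.3), "control": (26.4, 3.2)},
    "mmse": {"patient": (22.4, 3.6), "control": (27.2, 2.2)},
    "naming": {"patient": (2.6, 0.5), "control": (2.9, 0.2)},
}
#: probability of male sex per group (14/19 vs 15/20)
P_MALE = {"patient": 14.0 / 19.0, "control": 15.0 / 20.0}


@dataclass
class HubSpec:
    """One implanted connectivity hub.

    ``loading_control``/``loading_patient`` are the mixing weights of the
    hub's latent signal at the hub center (tapered outward by a Gaussian
    with sigma = radius); a reduced patient loading implants a DC deficit.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float = 12.0
    loading_control: float = 0.8
    loading_patient: float = 0.4
    latent_band: tuple[float, float] = (0.01, 0.08)

    def __post_init__(self) -> None:
        if not (0.0 < self.loading_control <= 1.0):
            raise ValueError("loading_control must be in (0, 1]")
        if self.loading_patient < 0:
            raise ValueError("loading_patient must be >= 0")

    def group_loading(self, group: str) -> float:
        return self.loading_patient if group == "patient" else self.loading_control


def _default_hubs() -> list[HubSpec]:
    return [HubSpec(center_mm=(21.0, -24.0, 6.0))]


@dataclass
class SynthSpec:
    """Full generative description of a simulated cohort."""

    shape: tuple[int, int, int] = (30, 36, 30)
    voxel_size_mm: float = 3.0
    n_frames: int = 240
    tr_seconds: float = 2.0
    n_patients: int = 19
    n_controls: int = 20
    hubs: list[HubSpec] = field(default_factory=_default_hubs)
    ar1_phi: float = 0.3
    noise_sd: float = 0.5              # AR(1) innovation SD
    n_networks: int = 40               # background parcels (0 disables)
    network_loading: float = 0.35      # parcel-latent loading, all subjects
    background_loading: float = 0.0    # optional global latent, mean loading in GM
    background_loading_sd: float = 0.0
    hub_loading_sd: float = 0.1        # per-subject jitter around group loading
    drift_amplitude: float = 0.3
    motion_amplitude_mm: float = 0.2
    rho_target: float = 0.0
    clinical_target: str = "fev1_pct"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3 or self.n_controls < 3:
            raise ValueError("each group needs at least 3 subjects")
        if not (0.0 <= self.ar1_phi <= 0.95):
            raise ValueError("AR(1) phi must lie in [0, 0.95]")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")
        for h in self.hubs:
            if h.radius_mm < self.voxel_size_mm:
                raise ValueError("hub radius must be at least one voxel")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def affine(self) -> np.ndarray:
        """3 mm isotropic affine with the world origin at the grid center."""
        a = np.diag([self.voxel_size_mm] * 3 + [1.0])
        a[:3, 3] = -self.voxel_size_mm * (np.asarray(self.shape) - 1) / 2.0
        return a

    # ---- geometry -------------------------------------------------------

    def _radius_fraction(self) -> np.ndarray:
        """Normalized ellipsoidal radius of every voxel (1 = brain surface)."""
        idx = np.indices(self.shape).astype(float)
        center = (np.asarray(self.shape) - 1) / 2.0
        semi = np.asarray(self.shape) * 0.40  # semi-axes in voxels
        return np.sqrt(
            sum(((idx[k] - center[k]) / semi[k]) ** 2 for k in range(3))
        )

    def masks(self) -> dict[str, MaskImage]:
        """Phantom tissue compartments: GM shell, WM interior, CSF core."""
        r = self._radius_fraction()
        aff = self.affine()
        gm = (r <= 1.0) & (r > 0.55)
        wm = (r <= 0.55) & (r > 0.35)
        csf = r <= 0.35
        return {
            "gm": MaskImage(gm, aff),
            "wm": MaskImage(wm, aff),
            "csf": MaskImage(csf, aff),
        }

    def hub_masks(self) -> list[MaskImage]:
        """Ground-truth hub masks: sphere of the hub radius, clipped to GM."""
        gm = self.masks()["gm"]
        aff = self.affine()
        idx = np.indices(self.shape).reshape(3, -1).astype(float)
        world = aff[:3, :3] @ idx + aff[:3, 3:4]
        out = []
        for h in self.hubs:
            d2 = ((world - np.asarray(h.center_mm).reshape(3, 1)) ** 2).sum(axis=0)
            sphere = (d2 <= h.radius_mm**2).reshape(self.shape)
            hub = sphere & gm.data
            if not hub.any():
                raise ValueError(f"hub at {h.center_mm} lies outside the gray-matter mask")
            out.append(MaskImage(hub, aff))
        return out

    def network_labels(self) -> np.ndarray:
        """Fixed background parcellation of gray matter (0 = no parcel).

        A Voronoi tessellation around ``n_networks`` seed voxels drawn
        deterministically from the spec seed; identical for every subject
        of a cohort (it plays the role of anatomy).  Hub spheres are
        carved out so the implanted hubs stay the only group effect.
        """
        gm = self.masks()["gm"].data
        labels = np.zeros(self.shape, dtype=np.int32)
        if self.n_networks <= 0:
            return labels
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x9E3779B9]))
        gm_idx = np.argwhere(gm)
        k = min(self.n_networks, len(gm_idx))
        seeds = gm_idx[rng.choice(len(gm_idx), size=k, replace=False)]
        d2 = ((gm_idx[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels[tuple(gm_idx.T)] = d2.argmin(axis=1) + 1
        for hm in self.hub_masks():
            labels[hm.data] = 0
        return labels

    def hub_taper(self, hub: HubSpec) -> np.ndarray:
        """Gaussian taper of the hub loading: exp(-d^2 / 2 radius^2), 0 outside."""
        aff = self.affine()
        idx = np.indices(self.shape).reshape(3, -1).astype(float)
        world = aff[:3, :3] @ idx + aff[:3, 3:4]
        d2 = ((world - np.asarray(hub.center_mm).reshape(3, 1)) ** 2).sum(axis=0)
        taper = np.exp(-d2 / (2.0 * hub.radius_mm**2)).reshape(self.shape)
        taper[d2.reshape(self.shape) > hub.radius_mm**2] = 0.0
        return taper

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hubs"] = [dataclasses.asdict(h) for h in self.hubs]
        return d


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def band_limited_signal(
    n_frames: int, tr: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance signal whose spectral power lies entirely in ``band``.

    Built in the frequency domain: complex Gaussian coefficients at the
    in-band bins, zero elsewhere, inverse FFT, then standardized (which
    rescales but cannot move power out of the band).
    """
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError(f"no frequency bins inside band {band}")
    spec = np.zeros(freqs.size, dtype=complex)
    spec[keep] = rng.standard_normal(keep.sum()) + 1j * rng.standard_normal(keep.sum())
    x = np.fft.irfft(spec, n=n_frames)
    return (x - x.mean()) / x.std()


def ar1_noise(
    shape: tuple[int, ...], phi: float, innovation_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise along the last axis.

    x_t = phi x_{t-1} + e_t with e ~ N(0, innovation_sd^2); the process is
    started from its stationary distribution so the marginal variance is
    innovation_sd^2 / (1 - phi^2) from the first frame.
    """
    e = rng.standard_normal(shape) * innovation_sd
    if phi == 0.0:
        return e
    stationary_sd = innovation_sd / np.sqrt(1.0 - phi**2)
    e[..., 0] = rng.standard_normal(shape[:-1]) * stationary_sd
    return sps.lfilter([1.0], [1.0, -phi], e, axis=-1)


def _smooth_motion(n_frames: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Six slowly varying motion parameters well inside the QC limits."""
    raw = rng.standard_normal((n_frames, 6))
    # heavy moving-average smoothing -> slow drifts, small frame-to-frame FD
    kernel = np.hanning(21)
    kernel /= kernel.sum()
    smooth = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, raw)
    peak = np.abs(smooth).max(axis=0)
    peak[peak == 0] = 1.0
    return smooth / peak * amplitude


# ---------------------------------------------------------------------------
# subject- and cohort-level generation
# ---------------------------------------------------------------------------

def generate_subject_bold(
    spec: SynthSpec,
    group: str,
    subject_seed: int,
    hub_loadings: list[float] | None = None,
    background_loading: float | None = None,
    excludable: bool = False,
) -> tuple[BoldImage, MotionTrace]:
    """One subject's 4-D BOLD image and motion trace.

    ``hub_loadings`` overrides the group-default center loadings (used by
    :func:`generate_cohort` to add per-subject jitter); ``excludable``
    injects a translation spike above the 2.0 mm QC limit.
    """
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(subject_seed)
    t = spec.n_frames
    aff = spec.affine()
    masks = spec.masks()
    gm = masks["gm"].data

    if hub_loadings is None:
        hub_loadings = [h.group_loading(group) for h in spec.hubs]
    if background_loading is None:
        background_loading = spec.background_loading

    data = ar1_noise((*spec.shape, t), spec.ar1_phi, spec.noise_sd, rng)

    # hub latents: independent band-limited sources mixed by tapered loadings
    for h, L in zip(spec.hubs, hub_loadings):
        world_to_voxel(h.center_mm, aff, spec.shape)  # raises if outside grid
        s = band_limited_signal(t, spec.tr_seconds, h.latent_band, rng)
        lam = spec.hub_taper(h) * float(max(L, 0.0))
        lam[~gm] = 0.0
        nz = lam > 0
        data[nz] += lam[nz, None] * s

    # background network parcels: one latent each, fixed geometry/loading
    if spec.n_networks > 0 and spec.network_loading > 0:
        labels = spec.network_labels()
        for lab in range(1, labels.max() + 1):
            s_net = band_limited_signal(t, spec.tr_seconds, (0.01, 0.08), rng)
            data[labels == lab] += spec.network_loading * s_net

    # subject-wide background connectivity in GM (global latent)
    s_bg = band_limited_signal(t, spec.tr_seconds, (0.01, 0.08), rng)
    data[gm] += float(max(background_loading, 0.0)) * s_bg

    # shared tissue signals so WM/CSF nuisance extraction is meaningful
    for tissue in ("wm", "csf"):
        s_t = band_limited_signal(t, spec.tr_seconds, (0.01, 0.08), rng)
        data[masks[tissue].data] += 0.3 * s_t

    # slow drift (below the 0.01 Hz passband edge) + baseline
    tt = np.linspace(-1.0, 1.0, t)
    slow = np.cos(2 * np.pi * 0.004 * spec.tr_seconds * np.arange(t) + rng.uniform(0, 2 * np.pi))
    coef = rng.standard_normal((*spec.shape, 2)) * spec.drift_amplitude
    data += coef[..., :1] * tt + coef[..., 1:] * slow
    data += BASELINE

    motion = _smooth_motion(t, spec.motion_amplitude_mm, rng)
    if excludable:
        motion[t // 2, 0] = 2.5  # over the 2.0 mm translation limit
    return BoldImage(data, aff, spec.tr_seconds), MotionTrace(motion)


def generate_covariates(spec: SynthSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort covariate table plus ground-truth loading columns.

    Per-subject hub-loading jitter (standardized within group,
    ``hub_loading_z``) is drawn first; the configured clinical target
    variable is then built as ``mean + sd * (rho * z + sqrt(1 - rho^2) *
    eps)`` with jitter independent of age/sex/education, so the
    population partial correlation between the target and the jitter
    given those covariates equals ``rho_target`` exactly.
    """
    rows = []
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    for i, group in enumerate(groups):
        sid = f"{'pat' if group == 'patient' else 'con'}{i:03d}"
        z = rng.standard_normal()           # hub-loading jitter, standardized
        bg = max(spec.background_loading + spec.background_loading_sd * rng.standard_normal(), 0.0)
        row = {"subject_id": sid, "group": group, "hub_loading_z": z,
               "background_loading": bg}
        row["sex"] = "M" if rng.uniform() < P_MALE[group] else "F"
        for var, bygroup in COVARIATE_MODEL.items():
            mu, sd = bygroup[group]
            if var == spec.clinical_target:
                rho = spec.rho_target
                val = mu + sd * (rho * z + np.sqrt(1 - rho**2) * rng.standard_normal())
            else:
                val = mu + sd * rng.standard_normal()
            row[var] = val
        row["age"] = float(np.clip(row["age"], 40, 85))
        row["education"] = float(max(row["education"], 0.0))
        row["pack_years"] = float(max(row["pack_years"], 0.0))
        rows.append(row)
    df = pd.DataFrame(rows)
    # absolute loading per hub: group loading + jitter scaled by hub_loading_sd
    for k, h in enumerate(spec.hubs):
        base = np.where(df["group"] == "patient", h.loading_patient, h.loading_control)
        df[f"hub{k}_loading"] = np.maximum(base + spec.hub_loading_sd * df["hub_loading_z"], 0.0)
    return df


def generate_cohort(
    spec: SynthSpec, out_dir: str | Path
) -> tuple[CohortTable, dict]:
    """Write a full synthetic cohort to disk; returns (cohort, manifest).

    Layout: one ``bold_<id>.nii.gz`` + ``motion_<id>.txt`` per subject,
    tissue masks (``mask_gm/wm/csf.nii.gz``), ground-truth hub masks
    (``hub<k>_truth.nii.gz``), ``cohort.tsv`` and ``manifest.json``.
    Bit-identical across runs with the same spec (single seed, per-subject
    seeds spawned deterministically).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    cov = generate_covariates(spec, rng)

    ss = np.random.SeedSequence(spec.seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(cov))]

    masks = spec.masks()
    for name, m in masks.items():
        save_mask(m, out_dir / f"mask_{name}.nii.gz")
    for k, hm in enumerate(spec.hub_masks()):
        save_mask(hm, out_dir / f"hub{k}_truth.nii.gz")

    files = {}
    for i, row in cov.iterrows():
        sid = row["subject_id"]
        loadings = [float(row[f"hub{k}_loading"]) for k in range(len(spec.hubs))]
        bold, motion = generate_subject_bold(
            spec,
            row["group"],
            subject_seeds[i],
            hub_loadings=loadings,
            background_loading=float(row["background_loading"]),
        )
        bpath = out_dir / f"bold_{sid}.nii.gz"
        mpath = out_dir / f"motion_{sid}.txt"
        save_bold(bold, bpath)
        save_motion(motion, mpath)
        files[sid] = {"bold": bpath.name, "motion": mpath.name}

    cohort_cols = ["subject_id", "group", "age", "sex", "education", "pack_years"] + [
        v for v in COVARIATE_MODEL if v not in ("age", "education", "pack_years")
    ]
    cohort = CohortTable(cov[cohort_cols])
    save_cohort(cohort, out_dir / "cohort.tsv")

    manifest = {
        "spec": spec.to_dict(),
        "subject_seeds": dict(zip(cov["subject_id"], subject_seeds)),
        "files": files,
        "rho_target": spec.rho_target,
        "clinical_target": spec.clinical_target,
        "truth": cov[
            ["subject_id", "group", "hub_loading_z", "background_loading"]
            + [f"hub{k}_loading" for k in range(len(spec.hubs))]
        ].to_dict(orient="list"),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return cohort, manifest


def generate_null_zmaps(
    n_maps: int,
    mask: MaskImage,
    fwhm_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth Gaussian null maps (no effect anywhere) for calibration runs.

    White noise smoothed to the requested FWHM and standardized within the
    mask — the null input for checking the family-wise error rate of the
    cluster-inference stage.
    """
    from .preprocess import smooth_gaussian  # local import: avoids cycle

    out = np.empty((n_maps, *mask.data.shape))
    for i in range(n_maps):
        noise = rng.standard_normal(mask.data.shape)
        sm = smooth_gaussian((noise, mask.affine), fwhm_mm)
        vals = sm[mask.data]
        sm = (sm - vals.mean()) / vals.std(ddof=1)
        sm[~mask.data] = 0.0
        out[i] = sm
    return out
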