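"""Group-level voxel-wise inference with Gaussian-random-field correction.

Subject-level z-maps (DC or seed-FC) enter a voxel-wise GLM; the group
contrast t-map is converted to a Gaussian field by probability matching,
thresholded at a two-tailed voxel p, and supra-threshold connected
components are assigned cluster-level p-values from the expected
Euler-characteristic / expected-cluster-size theory of stationary
Gaussian fields (Friston-style):

    E[m]        = R * (4 ln 2)^{3/2} (2 pi)^{-2} (u^2 - 1) e^{-u^2 / 2}
    E[n]        = R * Phi(-u) / E[m]             (resels per cluster)
    P(N >= s)   = exp(-beta * s^{2/3}),  beta = (Gamma(5/2) / E[n])^{2/3}
    cluster p   = 1 - exp(-E[m] * P(N >= s))

with R the resel count of the analysis mask and field smoothness
estimated from the variance of spatial first differences of the
standardized GLM residuals.  Each sign is labeled and tested separately
(two-tailed inference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import gamma as gamma_fn

from .io import CohortTable, MaskImage, voxel_to_world

__all__ = [
    "GroupDesign",
    "Smoothness",
    "StatResult",
    "make_group_design",
    "one_sample_tmap",
    "two_sample_glm",
    "estimate_smoothness",
    "gaussianize_t",
    "grf_cluster_inference",
    "extract_cluster_mask",
    "compare_demographics",
]

log = logging.getLogger(__name__)

CLUSTER_COLUMNS = [
    "label", "peak_x_mm", "peak_y_mm", "peak_z_mm",
    "peak_t", "n_voxels", "cluster_p", "sign",
]


@dataclass
class GroupDesign:
    """n_subjects x p design with a contrast picking out the group effect.

    The group column is coded patient=1 / control=0 and covariates are
    mean-centered, so the contrast t is the adjusted patient-minus-control
    difference (negative t = reduced in patients).
    """

    matrix: np.ndarray
    names: list[str]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        n, p = self.matrix.shape
        if len(self.names) != p or self.contrast.shape != (p,):
            raise ValueError("names/contrast must match design columns")
        if np.linalg.matrix_rank(self.matrix) < p:
            raise np.linalg.LinAlgError("group design is rank deficient")
        if n <= p:
            raise ValueError(f"need n > p, got n={n}, p={p}")


@dataclass
class Smoothness:
    """Estimated residual-field smoothness."""

    fwhm_mm: np.ndarray        # per-axis, mm
    fwhm_vox: np.ndarray       # per-axis, voxels (floored at 1)
    resels: float              # mask voxels / prod(fwhm_vox)


@dataclass
class StatResult:
    """A group-level t-map plus everything cluster inference needs."""

    t_map: np.ndarray
    df: int
    mask: MaskImage
    residuals: np.ndarray               # n_subjects x (3-D), standardized
    smoothness: Smoothness | None = None
    clusters: pd.DataFrame | None = None


def make_group_design(
    cohort: CohortTable,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
) -> GroupDesign:
    """Two-sample design from a cohort table.

    Columns: intercept, group (patient=1/control=0), then the requested
    covariates mean-centered (sex coded 0/1 via the M/F indicator).
    """
    df = cohort.df
    n = len(df)
    cols = [np.ones(n), (df["group"].to_numpy() == "patient").astype(float)]
    names = ["intercept", "group"]
    for c in covariates:
        v = cohort.sex_indicator() if c == "sex" else df[c].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(c)
    p = len(names)
    contrast = np.zeros(p)
    contrast[1] = 1.0
    return GroupDesign(np.column_stack(cols), names, contrast)


def _stack(maps, mask: MaskImage) -> np.ndarray:
    """Subject maps -> n x N matrix of in-mask values."""
    arr = np.stack([np.asarray(m, dtype=np.float64) for m in maps])
    if arr.shape[1:] != mask.data.shape:
        raise ValueError("map grid does not match mask grid")
    return arr[:, mask.data]


def _embed(vals: np.ndarray, mask: MaskImage) -> np.ndarray:
    out = np.zeros(mask.data.shape)
    out[mask.data] = vals
    return out


def one_sample_tmap(maps, mask: MaskImage) -> StatResult:
    """Voxel-wise one-sample t-test against 0 (hub identification).

    t = mean / (sd / sqrt(n)), df = n - 1.  Voxels with zero SD across
    subjects are flagged and their t set to 0.
    """
    Y = _stack(maps, mask)
    n = Y.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        log.warning("%d voxels with zero between-subject SD; t set to 0", int(bad.sum()))
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~bad)
    resid = Y - mean
    rss = (resid**2).sum(axis=0)
    std_resid = np.divide(resid, np.sqrt(rss), out=np.zeros_like(resid), where=rss > 0)
    return StatResult(
        t_map=_embed(t, mask),
        df=n - 1,
        mask=mask,
        residuals=np.stack([_embed(r, mask) for r in std_resid]),
    )


def two_sample_glm(maps, design: GroupDesign, mask: MaskImage) -> StatResult:
    """Voxel-wise OLS with the group contrast (covariate-adjusted t).

    With no covariates this reduces exactly to the pooled-variance
    two-sample t statistic.  Residuals are standardized voxel-wise
    (divided by the root residual sum of squares) and retained for
    smoothness estimation.
    """
    Y = _stack(maps, mask)
    X = design.matrix
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"{Y.shape[0]} maps but design has {n} rows")
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    c = design.contrast
    cvar = float(c @ xtx_inv @ c)
    se = np.sqrt(rss / df * cvar)
    t = np.zeros(Y.shape[1])
    np.divide(c @ beta, se, out=t, where=se > 0)
    std_resid = np.divide(resid, np.sqrt(rss), out=np.zeros_like(resid), where=rss > 0)
    return StatResult(
        t_map=_embed(t, mask),
        df=df,
        mask=mask,
        residuals=np.stack([_embed(r, mask) for r in std_resid]),
    )


def estimate_smoothness(
    residuals: np.ndarray, mask: MaskImage, voxel_sizes_mm=None
) -> Smoothness:
    """Residual-field FWHM from spatial first differences.

    For standardized residual maps e (unit sum of squares over subjects at
    every voxel), the variance over subjects and in-mask voxel pairs of
    the difference along axis k estimates 2(1 - rho_k(1)), i.e. the
    variance of the discrete derivative de/dx_k.  For small lags this is
    the derivative variance and FWHM_k = sqrt(4 ln 2 / var(de/dx_k)); at
    the smoothness this package operates at (~2 voxels FWHM) the small-lag
    approximation biases FWHM upward, so the exact Gaussian-ACF relation
    rho(1) = exp(-2 ln 2 / FWHM^2) is inverted instead:

        FWHM_k = sqrt(2 ln 2 / -ln(1 - v_k / 2)),   v_k = var(de/dx_k)

    which agrees with the sqrt(4 ln 2 / v) form as v -> 0.  The estimate
    is floored at 1 voxel (difference-based estimators undershoot on
    unsmoothed fields) and converted to mm.
    """
    residuals = np.asarray(residuals, dtype=np.float64)
    if residuals.ndim != 4 or residuals.shape[0] < 3:
        raise ValueError("need >= 3 residual maps of shape (n, x, y, z)")
    if voxel_sizes_mm is None:
        voxel_sizes_mm = mask.voxel_sizes_mm()
    voxel_sizes_mm = np.asarray(voxel_sizes_mm, dtype=np.float64)
    m = mask.data
    fwhm_vox = np.empty(3)
    for k in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[k] = slice(None, -1)
        sl_hi[k] = slice(1, None)
        pair = m[tuple(sl_lo)] & m[tuple(sl_hi)]
        if not pair.any():
            fwhm_vox[k] = 1.0
            continue
        d = (
            residuals[(slice(None), *sl_hi)][:, pair]
            - residuals[(slice(None), *sl_lo)][:, pair]
        )
        v = float((d**2).mean() * residuals.shape[0])  # E over subjects of sum-sq = 1
        if v <= 0:
            raise ValueError("degenerate residual variance along axis %d" % k)
        rho1 = 1.0 - v / 2.0
        if rho1 <= 0:
            fwhm_vox[k] = 1.0  # rougher than white noise: floor
        else:
            fwhm_vox[k] = np.sqrt(2.0 * np.log(2.0) / -np.log(rho1))
    fwhm_vox = np.maximum(fwhm_vox, 1.0)
    resels = mask.n_voxels / float(np.prod(fwhm_vox))
    return Smoothness(
        fwhm_mm=fwhm_vox * voxel_sizes_mm, fwhm_vox=fwhm_vox, resels=resels
    )


def gaussianize_t(t_map: np.ndarray, df: int) -> np.ndarray:
    """Probability-matching transform of a t field to a Gaussian field.

    z = Phi^{-1}(F_t(t; df)) computed tail-wise via survival functions so
    extreme values do not underflow.
    """
    t_map = np.asarray(t_map, dtype=np.float64)
    z = np.empty_like(t_map)
    pos = t_map >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t_map[pos], df))
    z[~pos] = -stats.norm.isf(stats.t.sf(-t_map[~pos], df))
    return z


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _grf_cluster_p(size_resels: float, u: float, resels: float) -> float:
    """Cluster-level p for one excursion-set component (3-D field)."""
    ec_density = (
        (4 * np.log(2.0)) ** 1.5 / (2 * np.pi) ** 2 * (u**2 - 1) * np.exp(-(u**2) / 2)
    )
    e_m = max(resels * ec_density, 1e-12)       # expected number of clusters
    e_v = resels * stats.norm.sf(u)             # expected supra-threshold resels
    e_n = max(e_v / e_m, 1e-12)                 # expected resels per cluster
    beta = (gamma_fn(2.5) / e_n) ** (2.0 / 3.0)
    p_size = np.exp(-beta * size_resels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-e_m * p_size))


def grf_cluster_inference(
    s: StatResult,
    voxel_p: float = 0.01,
    cluster_p: float = 0.05,
    connectivity: int = 26,
) -> tuple[pd.DataFrame, np.ndarray]:
    """GRF-corrected cluster inference on a group t-map.

    The two-tailed ``voxel_p`` fixes the Gaussian cluster-forming
    threshold u = Phi^{-1}(1 - voxel_p/2); positive and negative
    excursions are labeled separately (26-connectivity by default) and
    each component's extent is tested against the GRF null.  Returns the
    surviving-cluster table (mirroring a peak/t/extent layout in world mm)
    and a signed integer label map (+label positive, -label negative).
    No supra-threshold voxels is an empty table, not an error.
    """
    if s.smoothness is None:
        s.smoothness = estimate_smoothness(s.residuals, s.mask)
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    u = float(stats.norm.isf(voxel_p / 2.0))
    z = gaussianize_t(s.t_map, s.df)
    z[~s.mask.data] = 0.0
    resels = s.smoothness.resels
    resel_per_voxel = 1.0 / float(np.prod(s.smoothness.fwhm_vox))

    rows = []
    label_map = np.zeros(s.t_map.shape, dtype=np.int32)
    next_label = 1
    for sign, excurs in ((1, z > u), (-1, -z > u)):
        lab, n_comp = ndimage.label(excurs, structure=_STRUCTURES[connectivity])
        for comp in range(1, n_comp + 1):
            sel = lab == comp
            size = int(sel.sum())
            p = _grf_cluster_p(size * resel_per_voxel, u, resels)
            if p >= cluster_p:
                continue
            tv = np.where(sel, s.t_map, 0.0)
            peak_flat = np.argmax(np.abs(tv))
            peak_idx = np.unravel_index(peak_flat, tv.shape)
            peak_mm = voxel_to_world(peak_idx, s.mask.affine)
            rows.append(
                {
                    "label": next_label,
                    "peak_x_mm": float(peak_mm[0]),
                    "peak_y_mm": float(peak_mm[1]),
                    "peak_z_mm": float(peak_mm[2]),
                    "peak_t": float(s.t_map[peak_idx]),
                    "n_voxels": size,
                    "cluster_p": p,
                    "sign": sign,
                }
            )
            label_map[sel] = sign * next_label
            next_label += 1
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    s.clusters = table
    return table, label_map


def extract_cluster_mask(
    label_map: np.ndarray, label: int, affine: np.ndarray
) -> MaskImage:
    """Boolean mask of one labeled cluster (label as in the cluster table)."""
    sel = np.abs(label_map) == int(label)
    if not sel.any():
        raise KeyError(f"no cluster with label {label}")
    return MaskImage(sel, affine)


def compare_demographics(
    cohort: CohortTable, variables: list[str] | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Group comparison of demographic/clinical variables.

    For each continuous variable, normality in each group is checked with
    a one-sample Kolmogorov-Smirnov test against a normal with the sample
    moments; both-normal variables get a pooled-variance t-test, others a
    Mann-Whitney U test.  The sex proportion is tested with a chi-square
    test on the 2x2 contingency table.  Returns one row per variable with
    group mean +/- SD and the p-value.
    """
    df = cohort.df
    pat = df[df["group"] == "patient"]
    con = df[df["group"] == "control"]
    if len(pat) < 3 or len(con) < 3:
        raise ValueError("need >= 3 subjects per group")
    if variables is None:
        variables = ["age", "education"] + cohort.clinical_variables

    def _normalish(x: np.ndarray) -> bool:
        sd = x.std(ddof=1)
        if sd == 0:
            return True
        return stats.kstest((x - x.mean()) / sd, "norm").pvalue > alpha

    rows = []
    # sex: chi-square on the contingency table
    tab = pd.crosstab(df["group"], df["sex"])
    chi2 = stats.chi2_contingency(tab.to_numpy())
    rows.append(
        {
            "variable": "sex",
            "patient": f"{int(tab.loc['patient'].get('M', 0))}M/{int(tab.loc['patient'].get('F', 0))}F",
            "control": f"{int(tab.loc['control'].get('M', 0))}M/{int(tab.loc['control'].get('F', 0))}F",
            "test": "chi2",
            "p": float(chi2.pvalue),
        }
    )
    for var in variables:
        x = pat[var].dropna().to_numpy(dtype=float)
        y = con[var].dropna().to_numpy(dtype=float)
        if x.size == 0 and y.size == 0:
            raise ValueError(f"variable {var!r} is entirely missing")
        if x.size < 3 or y.size < 3:
            rows.append({"variable": var, "patient": _msd(x), "control": _msd(y),
                         "test": "none", "p": np.nan})
            continue
        if _normalish(x) and _normalish(y):
            test = "t"
            p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        else:
            test = "mannwhitney"
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append(
            {"variable": var, "patient": _msd(x), "control": _msd(y), "test": test, "p": p}
        )
    return pd.DataFrame(rows)


def _msd(x: np.ndarray) -> str:
    if x.size == 0:
        return "/"
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"
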