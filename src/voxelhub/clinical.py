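"""Relating cluster-mean degree centrality to clinical variables.

For every significant cluster, the mean DC z-value is extracted per
subject and related to each clinical variable (FEV1, FEV1/FVC, pH, MoCA
subscores, ...) by partial correlation controlling age, sex and
education, restricted to the patient group.  The screen reports the raw
two-tailed p per cell plus Benjamini-Hochberg FDR q-values across all
screened cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable, MaskImage, NUISANCE_COLUMNS

__all__ = [
    "extract_cluster_means",
    "partial_correlation",
    "clinical_screen",
]


def extract_cluster_means(maps, cluster_mask: MaskImage) -> np.ndarray:
    """Per-subject mean of in-mask voxels, one value per input map."""
    sel = cluster_mask.data
    if not sel.any():
        raise ValueError("empty cluster mask")
    out = []
    for m in maps:
        m = np.asarray(m, dtype=np.float64)
        if m.shape != sel.shape:
            raise ValueError("map grid does not match cluster mask")
        out.append(m[sel].mean())
    return np.array(out)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are OLS-residualized on [1, covariates]; r is the
    Pearson correlation of the residuals, df = n - k - 2, and the
    two-tailed p comes from t = r sqrt(df / (1 - r^2)).  Returns
    (r, p, df); r is NaN (p = NaN) when either residual is constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    C = np.asarray(covariates, dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    n = x.shape[0]
    k = C.shape[1]
    if y.shape[0] != n or C.shape[0] != n:
        raise ValueError("x, y and covariates must have equal length")
    df = n - k - 2
    if df < 1:
        raise ValueError(f"insufficient degrees of freedom: n={n}, k={k}")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("covariate matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, np.column_stack([x, y]), rcond=None)
    rx, ry = (np.column_stack([x, y]) - X @ coef).T
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    if nx == 0 or ny == 0:
        return float("nan"), float("nan"), df
    r = float(np.clip(np.dot(rx, ry) / (nx * ny), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, df
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, p, df


def clinical_screen(
    cluster_means: pd.DataFrame,
    cohort: CohortTable,
    variables: list[str] | None = None,
    alpha: float = 0.05,
    group: str = "patient",
) -> pd.DataFrame:
    """All cluster x variable partial correlations in one group.

    Parameters
    ----------
    cluster_means : DataFrame
        One row per subject (indexed or keyed by ``subject_id``), one
        column per cluster label, holding mean DC z-values.
    cohort : CohortTable
        Supplies group membership, the age/sex/education covariates, and
        the clinical variables.
    variables : list of str, optional
        Clinical variables to screen; defaults to every clinical column.
    alpha : float
        Raw-p significance level for the ``significant`` flag; the
        ``significant_fdr`` flag uses Benjamini-Hochberg q < alpha across
        all screened cells.
    group : str
        Which group to screen (the patient group by default).

    Notes
    -----
    Constant variables yield r = NaN and are never flagged.  Rows of the
    output: (cluster, variable, r, p, df, q, significant, significant_fdr).
    """
    sub = cohort.subset(group)
    if variables is None:
        variables = cohort.clinical_variables
    missing = [v for v in variables if v not in sub.columns]
    if missing:
        raise ValueError(f"variables not in cohort table: {missing}")
    if "subject_id" in cluster_means.columns:
        cluster_means = cluster_means.set_index("subject_id")
    cm = cluster_means.loc[sub["subject_id"]]
    k = len(NUISANCE_COLUMNS)
    if len(sub) < k + 3:
        raise ValueError(f"need at least {k + 3} subjects in group {group!r}")
    cov = np.column_stack(
        [
            sub["age"].to_numpy(dtype=float),
            (sub["sex"].to_numpy() == "F").astype(float),
            sub["education"].to_numpy(dtype=float),
        ]
    )
    # a covariate constant within the group (e.g. single-sex patients)
    # carries no information and would make the design singular
    varying = cov.std(axis=0) > 0
    cov = cov[:, varying]
    rows = []
    for cluster in cm.columns:
        x = cm[cluster].to_numpy(dtype=float)
        for var in variables:
            y = sub[var].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0:
                r, p, df = float("nan"), float("nan"), len(sub) - k - 2
            else:
                r, p, df = partial_correlation(x, y, cov)
            rows.append({"cluster": cluster, "variable": var, "r": r, "p": p, "df": df})
    out = pd.DataFrame(rows)
    q = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        q[ok] = stats.false_discovery_control(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    out["significant"] = out["p"] < alpha
    out["significant_fdr"] = out["q"] < alpha
    return out
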