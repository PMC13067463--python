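"""Voxel-wise lesion-symptom statistics.

The mass-univariate model: at each voxel v that at least ``min_overlap``
patients' masks cover, regress the endpoint y on the binary lesion
indicator L[:, v],

    y_i = b0 + b1 * L[i, v] + e_i,

and test b1 > 0 with a one-tailed t statistic on n - 2 degrees of freedom.
For a binary indicator this t equals the pooled two-sample t comparing
lesioned against non-lesioned patients, which is how it is computed here
(vectorized over voxels). One-sided p-values are converted to Z-scores via
the standard-normal quantile; a positive Z means the observational group
(endpoint coded 1) is enriched at lesioned voxels.

Voxels where the lesion indicator is constant across patients, or where the
residual variance is zero (perfect separation), are flagged degenerate and
carry z = 0: they are excluded from inference, which keeps downstream TFCE
and permutation maxima finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import GridSpec, MaskVolume, validate_cohort_grid

__all__ = [
    "EmptyAnalysisError",
    "LesionMatrix",
    "StatMap",
    "Z_CLAMP",
    "assemble_lesion_matrix",
    "two_sample_t",
    "t_to_z",
    "voxelwise_glm",
    "dummy_code",
    "load_cohort_table",
]

#: |z| cap applied after the p -> z conversion; avoids infinities when the
#: one-sided p underflows (corresponds to p ~ 1e-16)
Z_CLAMP = 8.2


class EmptyAnalysisError(ValueError):
    """No voxel survives the minimum-overlap filter."""


@dataclass
class LesionMatrix:
    """Patients x included-voxels binary lesion matrix.

    ``voxel_index`` holds the (i, j, k) coordinates of the m included
    voxels; ``L[i, v] = 1`` iff patient i's mask covers voxel v. Every
    column sum is >= ``min_overlap`` by construction.
    """

    patients: list[str]
    voxel_index: np.ndarray  # (m, 3) int
    L: np.ndarray = field(repr=False)  # (n, m) uint8
    min_overlap: int = 1
    grid: GridSpec | None = None

    @property
    def n_patients(self) -> int:
        return self.L.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.L.shape[1]

    @property
    def n_lesioned(self) -> np.ndarray:
        """Per-voxel lesion counts (column sums)."""
        return self.L.sum(axis=0).astype(np.int64)

    def included_volume(self) -> np.ndarray:
        """Boolean 3D array marking the included voxels."""
        if self.grid is None:
            raise ValueError("lesion matrix has no grid attached")
        vol = np.zeros(self.grid.shape, dtype=bool)
        vol[tuple(self.voxel_index.T)] = True
        return vol

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-included-voxel vector back into a 3D map."""
        if self.grid is None:
            raise ValueError("lesion matrix has no grid attached")
        vol = np.full(self.grid.shape, fill, dtype=float)
        vol[tuple(self.voxel_index.T)] = values
        return vol

    def subset_patients(self, keep: np.ndarray, masks_data: np.ndarray | None = None) -> "LesionMatrix":
        """Rebuild the matrix for a patient subset, re-applying the
        minimum-overlap filter to the analyzed subgroup."""
        keep = np.asarray(keep)
        L = self.L[keep]
        counts = L.sum(axis=0)
        cols = counts >= self.min_overlap
        if not cols.any():
            raise EmptyAnalysisError(
                f"no voxel reaches min_overlap={self.min_overlap} in the subset "
                f"(max overlap {int(counts.max()) if counts.size else 0})"
            )
        return LesionMatrix(
            patients=[self.patients[i] for i in np.flatnonzero(keep)],
            voxel_index=self.voxel_index[cols],
            L=np.ascontiguousarray(L[:, cols]),
            min_overlap=self.min_overlap,
            grid=self.grid,
        )


@dataclass
class StatMap:
    """Per-voxel statistics over the included voxels of a lesion matrix."""

    grid: GridSpec
    voxel_index: np.ndarray
    t: np.ndarray
    df: int
    z: np.ndarray
    p_one_sided: np.ndarray
    n_lesioned: np.ndarray
    degenerate: np.ndarray
    included: np.ndarray = field(repr=False)

    @property
    def tested(self) -> np.ndarray:
        """Mask of voxels that enter inference (included, not degenerate)."""
        return ~self.degenerate

    @property
    def n_tested(self) -> int:
        return int(self.tested.sum())

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.grid.shape, fill, dtype=float)
        vol[tuple(self.voxel_index.T)] = values
        return vol

    def z_volume(self) -> np.ndarray:
        """Z map on the full grid, 0 outside included/tested voxels."""
        return self.embed(np.where(self.degenerate, 0.0, self.z))


def assemble_lesion_matrix(masks: list[MaskVolume], min_overlap: int = 10) -> LesionMatrix:
    """Stack cohort masks and keep voxels lesioned in >= ``min_overlap`` patients.

    The overlap filter stabilizes voxel-wise inference: sparsely covered
    voxels let a handful of patients drive large apparent effects.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    grid = validate_cohort_grid(masks)
    stack = np.stack([m.data for m in masks])  # (n, X, Y, Z)
    counts = stack.sum(axis=0)
    keep = counts >= min_overlap
    if not keep.any():
        raise EmptyAnalysisError(
            f"no voxel is lesioned in >= {min_overlap} patients "
            f"(max observed overlap: {int(counts.max())})"
        )
    voxel_index = np.argwhere(keep)
    L = stack.reshape(len(masks), -1)[:, keep.ravel()]
    return LesionMatrix(
        patients=[m.label for m in masks],
        voxel_index=voxel_index,
        L=np.ascontiguousarray(L, dtype=np.uint8),
        min_overlap=min_overlap,
        grid=grid,
    )


def two_sample_t(L: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled two-sample t of y (lesioned vs non-lesioned) per column of L.

    Equivalent to the slope t-statistic of the univariable regression
    y ~ 1 + L[:, v] with df = n - 2. Returns ``(t, degenerate)`` where
    degenerate marks constant columns and zero-pooled-variance columns;
    their t is set to 0.

    Vectorized over columns; also accepts a 2D stack of outcome vectors
    ``y`` of shape (B, n), returning t of shape (B, m) (degenerate then
    flags, per row, constant columns or zero variance under that outcome).
    """
    L = np.asarray(L, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    single = y.ndim == 1
    Y = np.atleast_2d(y)  # (B, n)
    n = L.shape[0]
    if Y.shape[1] != n:
        raise ValueError(f"outcome length {Y.shape[1]} != n patients {n}")
    n1 = L.sum(axis=0)  # (m,)
    n0 = n - n1
    const_col = (n1 == 0) | (n0 == 0)
    sum_y = Y.sum(axis=1, keepdims=True)  # (B, 1)
    sum_y2 = (Y**2).sum(axis=1, keepdims=True)
    s1 = Y @ L  # (B, m) sum of y over lesioned
    q1 = (Y**2) @ L
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m0 = (sum_y - s1) / n0
        # within-group sums of squares
        ss1 = q1 - n1 * m1**2
        ss0 = (sum_y2 - q1) - n0 * m0**2
        pooled_var = (ss1 + ss0) / (n - 2)
        se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n0))
        t = (m1 - m0) / se
    degenerate = const_col[None, :] | ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    if single:
        return t[0], degenerate[0]
    return t, degenerate


def t_to_z(t: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Convert one-sided t statistics to (p, z).

    p = P(T_df > t); z = Phi^{-1}(1 - p), clamped to |z| <= Z_CLAMP so that
    underflowing p-values never produce infinities.
    """
    p = stats.t.sf(t, df)
    z = stats.norm.isf(p)
    z = np.clip(z, -Z_CLAMP, Z_CLAMP)
    return p, z


def voxelwise_glm(
    lm: LesionMatrix,
    outcome: np.ndarray,
    alternative: str = "greater",
) -> StatMap:
    """Fit the univariable lesion model at every included voxel.

    ``alternative="greater"`` tests b1 > 0 (endpoint enriched at lesioned
    voxels, the standard direction); ``"less"`` tests the opposite tail by
    negating t before the p/z conversion.
    """
    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or len(y) != lm.n_patients:
        raise ValueError(
            f"outcome must be a length-{lm.n_patients} vector, got shape {y.shape}"
        )
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; no association can be tested")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if lm.n_patients < 3:
        raise ValueError("need at least 3 patients for df = n - 2 >= 1")
    t, degenerate = two_sample_t(lm.L, y)
    df = lm.n_patients - 2
    t_eff = t if alternative == "greater" else -t
    p, z = t_to_z(t_eff, df)
    p = np.where(degenerate, np.nan, p)
    z = np.where(degenerate, 0.0, z)
    return StatMap(
        grid=lm.grid,
        voxel_index=lm.voxel_index,
        t=t,
        df=df,
        z=z,
        p_one_sided=p,
        n_lesioned=lm.n_lesioned,
        degenerate=degenerate,
        included=lm.included_volume() if lm.grid is not None else np.zeros(0, bool),
    )


def dummy_code(raw_column: pd.Series | np.ndarray, reference) -> tuple[np.ndarray, dict]:
    """Dummy-code a two-level categorical column.

    The ``reference`` level maps to 0 and the single other level to 1.
    Returns the coded vector and the mapping (recorded in analysis
    manifests). More than two levels is an error: binarize explicitly
    first (e.g. Simpson grade <=3 vs >3).
    """
    col = pd.Series(raw_column).dropna()
    levels = sorted(col.unique().tolist(), key=str)
    if len(levels) != 2:
        raise ValueError(
            f"dummy_code requires exactly 2 categories, got {levels}; "
            "binarize the column explicitly before coding"
        )
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels}")
    other = levels[0] if levels[1] == reference else levels[1]
    mapping = {reference: 0, other: 1}
    coded = col.map(mapping).to_numpy(dtype=np.int8)
    return coded, mapping


REQUIRED_COLUMNS = ("patient_id", "mask")


def load_cohort_table(path) -> pd.DataFrame:
    """Load and validate the per-patient cohort TSV.

    Expected columns: ``patient_id`` (unique key), ``mask`` (file reference),
    endpoint columns (dummy-coded 0/1, missing allowed), ``volume_ml``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} lacks required columns {missing}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dupes}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df
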