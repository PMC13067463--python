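"""Multiple-comparison correction for voxel-wise lesion maps.

Four routes are provided:

* Bonferroni — reject where p < alpha / m. Family-wise error control by
  union bound; simple and famously conservative at neuroimaging m.
* Benjamini–Hochberg FDR — the step-up procedure controlling the expected
  fraction of false positives among the declared voxels.
* max-Z permutation — family-wise error control from the permutation null
  distribution of the map maximum Z.
* TFCE permutation — threshold-free cluster enhancement of the Z map
  followed by max-statistic permutation on the enhanced scores.

Bonferroni and FDR operate on the analytic one-sided p-values; only the
max-statistic routes use the permutation null. Permutations shuffle the
outcome vector jointly across all voxels, preserving the spatial
covariance of the lesion masks — the standard scheme in lesion mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .spatial import connectivity_structure
from .vlsm import LesionMatrix, StatMap, t_to_z, two_sample_t, voxelwise_glm

__all__ = [
    "TfceParams",
    "PermutationConfig",
    "CorrectionResult",
    "bonferroni",
    "bh_fdr",
    "tfce",
    "permutation_correct",
]


@dataclass(frozen=True)
class TfceParams:
    """TFCE tuning parameters.

    H and E are the height and extent exponents (defaults 2 and 0.5, the
    values in universal use); ``dh`` is the integration step — ``None``
    means max-statistic / 100, common TFCE practice.
    """

    H: float = 2.0
    E: float = 0.5
    dh: float | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.H < 0 or self.E < 0:
            raise ValueError("H and E must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings; ``statistic`` is ``maxZ`` or ``maxTFCE``."""

    n_permutations: int = 5000
    seed: int = 0
    statistic: str = "maxZ"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.statistic not in ("maxZ", "maxTFCE"):
            raise ValueError("statistic must be 'maxZ' or 'maxTFCE'")


@dataclass
class CorrectionResult:
    """Outcome of one multiple-comparison correction.

    ``rejected`` is per included voxel (aligned with the stat map's
    ``voxel_index``); ``significant`` is the same information scattered
    into a 3D array. ``critical_value`` is the per-voxel p threshold
    (Bonferroni/FDR) or the null-distribution quantile of the max
    statistic (permutation methods). ``p_corrected`` and ``null_max``
    are filled by the permutation methods only.
    """

    method: str
    alpha: float
    rejected: np.ndarray
    significant: np.ndarray = field(repr=False)
    critical_value: float = np.nan
    p_corrected: np.ndarray | None = None
    null_max: np.ndarray | None = None

    @property
    def n_significant(self) -> int:
        return int(self.rejected.sum())


def _scatter(statmap: StatMap, rejected: np.ndarray) -> np.ndarray:
    sig = np.zeros(statmap.grid.shape, dtype=bool)
    sig[tuple(statmap.voxel_index.T)] = rejected
    return sig


def bonferroni(statmap: StatMap, alpha: float = 0.05, m: int | None = None) -> CorrectionResult:
    """Bonferroni correction: reject where p < alpha / m.

    ``m`` defaults to the number of tested (included, non-degenerate)
    voxels. Degenerate voxels are never significant.
    """
    if m is None:
        m = statmap.n_tested
    if m < 1:
        raise ValueError("no tested voxels (m = 0)")
    crit = alpha / m
    rejected = ~statmap.degenerate & (np.nan_to_num(statmap.p_one_sided, nan=1.0) < crit)
    return CorrectionResult(
        method="bonferroni",
        alpha=alpha,
        rejected=rejected,
        significant=_scatter(statmap, rejected),
        critical_value=crit,
    )


def bh_fdr_reject(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up on a flat p-value vector.

    Sort ascending, find the largest k with p_(k) <= k * alpha / m, reject
    the k smallest. Returns (reject mask, critical p-value p_(k); 0.0 if
    nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), 0.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    ok = np.flatnonzero(ranked <= thresh)
    if ok.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    k = ok[-1] + 1
    crit = float(ranked[k - 1])
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject, crit


def bh_fdr(statmap: StatMap, alpha: float = 0.05) -> CorrectionResult:
    """FDR correction of a stat map's one-sided p-values (BH step-up)."""
    tested = statmap.tested
    rejected = np.zeros(statmap.p_one_sided.shape, dtype=bool)
    crit = 0.0
    if tested.any():
        rej_t, crit = bh_fdr_reject(statmap.p_one_sided[tested], alpha)
        rejected[tested] = rej_t
    return CorrectionResult(
        method="fdr",
        alpha=alpha,
        rejected=rejected,
        significant=_scatter(statmap, rejected),
        critical_value=crit,
    )


def tfce(stat_map: np.ndarray, params: TfceParams = TfceParams()) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... <= z(v) of
    e(h, v)^E * h^H * dh, where e(h, v) is the voxel extent of the
    connected component containing v in the supra-threshold map
    {z >= h}. Negative values are clamped to 0 (one-sided enhancement,
    matching the one-tailed tests); to enhance both signs, call twice
    on the map and its negation.
    """
    z = np.clip(np.asarray(stat_map, dtype=np.float64), 0.0, None)
    if not np.isfinite(z).all():
        raise ValueError("stat map must be finite")
    out = np.zeros_like(z)
    zmax = z.max()
    if zmax <= 0:
        return out
    dh = params.dh if params.dh is not None else zmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be > 0")
    structure = connectivity_structure(params.connectivity)
    # thresholds dh, 2dh, ..., up to and including zmax (within fp slack)
    n_steps = int(np.floor(zmax / dh + 1e-9))
    for step in range(1, n_steps + 1):
        h = step * dh
        supra = z >= h - 1e-12
        labels, k = ndimage.label(supra, structure=structure)
        if k == 0:
            break
        sizes = np.bincount(labels.ravel())
        out[supra] += sizes[labels[supra]] ** params.E * h**params.H * dh
    return out


def _null_max_z(
    lm: LesionMatrix,
    outcome: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    alternative: str,
    chunk: int = 64,
) -> np.ndarray:
    """Permutation null of the map maximum Z via max-t (monotone) shortcut.

    Z is a strictly increasing function of t at fixed df, so the maximum Z
    over tested voxels equals Z(max t); only the per-permutation maxima
    need converting. Degenerate columns (per permutation) are excluded.
    """
    df = lm.n_patients - 2
    sign = 1.0 if alternative == "greater" else -1.0
    max_t = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        Y = np.stack([rng.permutation(outcome) for _ in range(b)])
        t, degen = two_sample_t(lm.L, Y)
        t = sign * t
        t[degen] = -np.inf
        max_t[done : done + b] = t.max(axis=1)
        done += b
    _, max_z = t_to_z(max_t, df)
    return max_z


def _null_max_tfce(
    lm: LesionMatrix,
    outcome: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    alternative: str,
    tfce_params: TfceParams,
) -> np.ndarray:
    df = lm.n_patients - 2
    sign = 1.0 if alternative == "greater" else -1.0
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        y = rng.permutation(outcome)
        t, degen = two_sample_t(lm.L, y)
        _, z = t_to_z(sign * t, df)
        z = np.where(degen, 0.0, z)
        scores = tfce(lm.embed(z), tfce_params)
        out[b] = scores.max()
    return out


def permutation_correct(
    lm: LesionMatrix,
    outcome: np.ndarray,
    config: PermutationConfig = PermutationConfig(),
    tfce_params: TfceParams = TfceParams(),
    alpha: float = 0.05,
    alternative: str = "greater",
) -> CorrectionResult:
    """Max-statistic permutation correction (family-wise error control).

    For each of B seeded permutations of the outcome vector, the Z map
    (and its TFCE transform, if ``statistic='maxTFCE'``) is recomputed and
    its maximum recorded. The corrected p-value at voxel v is

        p_corr(v) = (1 + #{b : null_max_b >= obs(v)}) / (B + 1),

    which is never 0 and counts ties as exceedances (conservative).
    Significance: p_corr <= alpha. The null maxima are returned for
    diagnostics.
    """
    statmap = voxelwise_glm(lm, outcome, alternative=alternative)
    rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    if config.statistic == "maxZ":
        null_max = _null_max_z(lm, outcome, B, rng, alternative)
        obs = np.where(statmap.degenerate, -np.inf, statmap.z)
    else:
        null_max = _null_max_tfce(lm, outcome, B, rng, alternative, tfce_params)
        obs_scores = tfce(statmap.z_volume(), tfce_params)
        obs = obs_scores[tuple(statmap.voxel_index.T)]
        obs = np.where(statmap.degenerate, -np.inf, obs)
    sorted_null = np.sort(null_max)
    # count of null maxima >= obs(v), ties counted
    exceed = B - np.searchsorted(sorted_null, obs, side="left")
    p_corr = (1.0 + exceed) / (B + 1.0)
    p_corr = np.where(statmap.degenerate, 1.0, p_corr)
    rejected = p_corr <= alpha
    crit = float(np.quantile(null_max, 1.0 - alpha)) if B > 1 else float("inf")
    return CorrectionResult(
        method="tfce-perm" if config.statistic == "maxTFCE" else "maxz-perm",
        alpha=alpha,
        rejected=rejected,
        significant=_scatter(statmap, rejected),
        critical_value=crit,
        p_corrected=p_corr,
        null_max=null_max,
    )
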