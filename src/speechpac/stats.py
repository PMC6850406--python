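"""Group-level cluster-corrected permutation tests (real vs surrogate).

Paired design: each subject contributes a real and a surrogate array on
the same frequency grid (1-D coherence spectra or 2-D comodulograms).
Per-bin paired t statistics of (real - surrogate) are thresholded at a
two-sided cluster-forming p; suprathreshold bins are grouped by adjacency
(contiguity in 1-D, 4-connectivity in 2-D by default); the cluster
statistic is the sum of t within the cluster; and the null distribution is
the maximum |cluster statistic| over random per-subject sign flips of the
differences.  Cluster p-values are ``(1 + #{null >= observed}) /
(n_perm + 1)``, so the family-wise error rate is controlled at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import ndimage, stats as sstats

__all__ = [
    "PermutationConfig",
    "ClusterResult",
    "cluster_permutation_paired",
    "significant_mask",
]


@dataclass
class PermutationConfig:
    """Settings of the cluster permutation test.

    ``connectivity`` selects the 2-D adjacency (4 or 8 neighbors); 1-D
    inputs always use simple contiguity.
    """

    n_perm: int = 1000
    alpha: float = 0.05
    cluster_forming_p: float = 0.05
    seed: int = 0
    connectivity: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class ClusterResult:
    """One cluster of adjacent suprathreshold bins."""

    mask: np.ndarray
    cluster_stat: float
    p_value: float
    polarity: int  # +1: real > surrogate, -1: real < surrogate


def _t_map(d: np.ndarray) -> np.ndarray:
    """Per-bin paired t statistic across the subject axis (axis 0)."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if ndim == 1:
        return np.ones(3, dtype=bool)
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def _clusters_one_polarity(
    t: np.ndarray, t_crit: float, structure: np.ndarray, polarity: int
):
    supra = polarity * t > t_crit
    labels, n_lab = ndimage.label(supra, structure=structure)
    out = []
    for lab in range(1, n_lab + 1):
        mask = labels == lab
        out.append((mask, float(t[mask].sum())))
    return out


def _max_cluster_stat(
    t: np.ndarray, t_crit: float, structure: np.ndarray
) -> float:
    best = 0.0
    for polarity in (1, -1):
        for _, stat in _clusters_one_polarity(t, t_crit, structure, polarity):
            best = max(best, abs(stat))
    return best


def cluster_permutation_paired(
    real: Sequence[np.ndarray] | np.ndarray,
    surrogate: Sequence[np.ndarray] | np.ndarray,
    cfg: PermutationConfig | None = None,
) -> List[ClusterResult]:
    """Two-tailed paired cluster permutation test of real vs surrogate.

    ``real`` and ``surrogate`` are stacked per-subject arrays of identical
    shape (subject axis first).  Returns every suprathreshold cluster of
    both polarities with its permutation p-value; an empty list means no
    bin exceeded the cluster-forming threshold.  Requires >= 5 subjects
    (the sign-flip null has only 2^n states).
    """
    cfg = cfg or PermutationConfig()
    real = np.asarray(real, dtype=float)
    surrogate = np.asarray(surrogate, dtype=float)
    if real.shape != surrogate.shape:
        raise ValueError(
            f"shape mismatch: real {real.shape} vs surrogate {surrogate.shape}"
        )
    n = real.shape[0]
    if n < 5:
        raise ValueError(
            f"need >= 5 subjects for a sign-flip permutation null, got {n}"
        )
    d = real - surrogate
    grid_ndim = d.ndim - 1
    if grid_ndim not in (1, 2):
        raise ValueError("arrays must be 1-D or 2-D per subject")
    t_crit = float(sstats.t.ppf(1 - cfg.cluster_forming_p / 2, df=n - 1))
    structure = _structure(grid_ndim, cfg.connectivity)

    t_obs = _t_map(d)
    observed = []
    for polarity in (1, -1):
        for mask, stat in _clusters_one_polarity(
            t_obs, t_crit, structure, polarity
        ):
            observed.append((mask, stat, polarity))
    if not observed:
        return []

    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_perm)
    flip_shape = (n,) + (1,) * grid_ndim
    for p in range(cfg.n_perm):
        signs = rng.choice([-1.0, 1.0], size=n).reshape(flip_shape)
        null[p] = _max_cluster_stat(_t_map(signs * d), t_crit, structure)

    results = []
    for mask, stat, polarity in observed:
        p_val = (1.0 + np.sum(null >= abs(stat))) / (cfg.n_perm + 1.0)
        results.append(
            ClusterResult(
                mask=mask,
                cluster_stat=stat,
                p_value=float(p_val),
                polarity=polarity,
            )
        )
    return results


def significant_mask(
    clusters: List[ClusterResult], alpha: float = 0.05, shape=None
) -> np.ndarray:
    """Union of positive-polarity cluster masks with p < alpha.

    This is the mask consumed by the peak extractors (real > surrogate
    regions only).  ``shape`` supplies the grid shape when ``clusters`` is
    empty; otherwise it is inferred from the first cluster.
    """
    keep = [
        c for c in clusters if c.p_value < alpha and c.polarity > 0
    ]
    if not keep:
        if clusters:
            shape = clusters[0].mask.shape
        if shape is None:
            raise ValueError("shape required when no clusters are given")
        return np.zeros(shape, dtype=bool)
    mask = np.zeros_like(keep[0].mask, dtype=bool)
    for c in keep:
        mask |= c.mask
    return mask
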