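"""Single-subject gray-matter similarity networks at two levels.

Cube level (atlas-free): the gray matter is tiled by non-overlapping 3x3x3
voxel cubes anchored at the grid origin; every cube whose 27 voxels all lie
inside the mask becomes a node.  Edges encode the Spearman rank correlation
of the 27 positionally-corresponding intensity values of a cube pair, and
are retained when the correlation exceeds a per-subject permutation-derived
threshold chosen so the expected fraction of spurious (null) connections is
at most alpha (default 5%).

ROI level: each atlas parcel contributes a quantile profile — its masked
intensities sorted and resampled to a common length by linear interpolation
— and a pair of parcels is compared by rank-transforming the two profiles
jointly over their pooled values and Pearson-correlating the rank profiles
(a Spearman-style statistic that equals 1 exactly when the two intensity
multisets coincide).  Per-pair p-values come from a permutation null that
randomly re-assigns the pooled voxels of the pair to the two parcels;
Benjamini-Hochberg across all unordered pairs controls the edge FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .stats import bh_fdr
from .volume_io import AtlasVolume, GMVolume

__all__ = [
    "CubeParcellation",
    "SimilarityMatrix",
    "BinaryNetwork",
    "partition_cubes",
    "cube_values",
    "cube_similarity",
    "permutation_threshold",
    "binarize",
    "extract_cube_network",
    "roi_similarity",
    "fdr_edge_threshold",
]

CUBE = 3
CUBE_VOX = CUBE**3


@dataclass
class CubeParcellation:
    """3x3x3 cube nodes: origins, ROI assignment, and node count."""

    cube_origins: np.ndarray  # (n, 3) int voxel indices of each cube's corner
    cube_roi: np.ndarray      # (n,) int ROI label per cube (0 = unassigned)

    @property
    def n_nodes(self) -> int:
        return int(len(self.cube_origins))


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix at cube or ROI level.

    The diagonal is set to 1 by convention and excluded from all downstream
    statistics.  ``flagged`` lists degenerate nodes (constant cubes or
    too-small ROIs) whose similarities are 0 / missing.
    """

    rho: np.ndarray
    level: str  # "cube" | "roi"
    flagged: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.rho.shape[0])


@dataclass
class BinaryNetwork:
    """Thresholded adjacency with full provenance of how it was obtained."""

    adjacency: np.ndarray
    threshold_used: float
    null_method: str  # "permutation" | "fdr"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a

    @property
    def n(self) -> int:
        return int(self.adjacency.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def density(self) -> float:
        possible = self.n * (self.n - 1) / 2
        return self.n_edges / possible if possible else 0.0


def partition_cubes(
    volume: GMVolume, atlas: AtlasVolume | None = None, min_cubes: int = 10
) -> CubeParcellation:
    """Tile the grid with origin-anchored 3x3x3 cubes fully inside the mask.

    The ROI of a cube is the majority atlas label among its 27 voxels; ties
    go to the lowest label, and cubes whose majority is background get 0.
    """
    if atlas is not None and atlas.shape != volume.shape:
        raise ValueError(
            f"grid shape mismatch: volume {volume.shape} vs atlas {atlas.shape}"
        )
    nx, ny, nz = (s // CUBE for s in volume.shape)
    if min(nx, ny, nz) == 0:
        raise ValueError(f"grid {volume.shape} too small for any 3x3x3 cube")
    mask = volume.mask[: nx * CUBE, : ny * CUBE, : nz * CUBE]
    blocks = mask.reshape(nx, CUBE, ny, CUBE, nz, CUBE).transpose(0, 2, 4, 1, 3, 5)
    full = blocks.reshape(nx, ny, nz, CUBE_VOX).all(axis=-1)
    keep = np.argwhere(full)
    if len(keep) < min_cubes:
        raise ValueError(
            f"degenerate input: only {len(keep)} fully-masked cubes "
            f"(need >= {min_cubes})"
        )
    origins = keep * CUBE
    if atlas is None:
        rois = np.zeros(len(origins), dtype=np.int32)
    else:
        lab = atlas.labels[: nx * CUBE, : ny * CUBE, : nz * CUBE]
        lab_blocks = (
            lab.reshape(nx, CUBE, ny, CUBE, nz, CUBE)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(nx, ny, nz, CUBE_VOX)
        )
        rois = np.empty(len(origins), dtype=np.int32)
        for idx, (i, j, k) in enumerate(keep):
            vals, cnt = np.unique(lab_blocks[i, j, k], return_counts=True)
            rois[idx] = vals[np.argmax(cnt)]  # unique() is sorted: tie -> lowest
    return CubeParcellation(origins, rois)


def cube_values(volume: GMVolume, parcellation: CubeParcellation) -> np.ndarray:
    """(n_cubes, 27) intensity matrix, within-cube position order fixed."""
    out = np.empty((parcellation.n_nodes, CUBE_VOX))
    for idx, (i, j, k) in enumerate(parcellation.cube_origins):
        out[idx] = volume.intensities[i:i + CUBE, j:j + CUBE, k:k + CUBE].ravel()
    return out


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return rankdata(values, axis=1)


def cube_similarity(
    volume: GMVolume, parcellation: CubeParcellation
) -> SimilarityMatrix:
    """All-pairs Spearman similarity over the 27 corresponding voxel values.

    Cubes with constant intensity have undefined rank correlation; their
    similarities are set to 0 and the cube index is flagged.
    """
    if parcellation.n_nodes < 2:
        raise ValueError("need at least 2 cubes for a similarity matrix")
    vals = cube_values(volume, parcellation)
    ranks = _rank_rows(vals)
    sd = ranks.std(axis=1)
    flagged = list(np.flatnonzero(sd == 0))
    safe = ranks.copy()
    # give constant cubes a dummy non-constant row, zero their rho afterwards
    if flagged:
        safe[flagged] = np.arange(CUBE_VOX)
    rho = np.corrcoef(safe)
    if flagged:
        rho[flagged, :] = 0.0
        rho[:, flagged] = 0.0
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return SimilarityMatrix(rho, level="cube", flagged=flagged)


def permutation_threshold(
    volume: GMVolume,
    parcellation: CubeParcellation,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Per-subject similarity threshold admitting at most ``alpha`` spurious edges.

    The null distribution records the Spearman correlation of randomly chosen
    cube pairs after permuting the within-cube value order of one member —
    destroying positional correspondence while preserving each cube's
    marginal intensity distribution.  The threshold is the empirical
    (1 - alpha) quantile taken conservatively (next order statistic up), so
    the expected fraction of null pairs exceeding it is <= alpha.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100 for a stable quantile, got {n_perm}")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    rng = np.random.default_rng(seed)
    vals = cube_values(volume, parcellation)
    ranks = _rank_rows(vals)
    n = parcellation.n_nodes
    ii = rng.integers(0, n, size=n_perm)
    jj = rng.integers(0, n - 1, size=n_perm)
    jj[jj >= ii] += 1  # j != i, uniform over remaining
    a = ranks[ii]
    perm = np.argsort(rng.random((n_perm, CUBE_VOX)), axis=1)
    a = np.take_along_axis(a, perm, axis=1)
    b = ranks[jj]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        null_rho = np.where(denom > 0, (a * b).sum(axis=1) / denom, 0.0)
    if alpha == 1.0:  # retain everything: no similarity value can be below -1
        return float(min(null_rho.min(), -1.0) - 1e-9)
    return float(np.quantile(null_rho, 1.0 - alpha, method="higher"))


def binarize(
    similarity: SimilarityMatrix,
    threshold: float,
    null_method: str = "permutation",
    provenance: dict | None = None,
) -> BinaryNetwork:
    """Edges are pairs with similarity strictly above the threshold."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    adj = similarity.rho > threshold
    np.fill_diagonal(adj, False)
    prov = dict(provenance or {})
    prov.setdefault("level", similarity.level)
    return BinaryNetwork(adj, float(threshold), null_method, prov)


def extract_cube_network(
    volume: GMVolume,
    atlas: AtlasVolume | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[CubeParcellation, SimilarityMatrix, BinaryNetwork]:
    """Full single-subject cube-network extraction in one call."""
    parc = partition_cubes(volume, atlas)
    sim = cube_similarity(volume, parc)
    thr = permutation_threshold(volume, parc, n_perm=n_perm, alpha=alpha, seed=seed)
    net = binarize(
        sim, thr,
        null_method="permutation",
        provenance={"alpha": alpha, "n_perm": n_perm, "seed": seed},
    )
    return parc, sim, net


# ---------------------------------------------------------------- ROI level


def _quantile_profile(sorted_vals: np.ndarray, length: int) -> np.ndarray:
    """Linear resampling of an ascending value vector to ``length`` points."""
    n = sorted_vals.shape[-1]
    pos = np.linspace(0.0, n - 1.0, length)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = pos - lo
    return sorted_vals[..., lo] * (1.0 - w) + sorted_vals[..., hi] * w


def _profile_rank_corr(prof_a: np.ndarray, prof_b: np.ndarray) -> np.ndarray:
    """Pooled-rank correlation of two (stacks of) equal-length profiles."""
    both = np.concatenate([prof_a, prof_b], axis=-1)
    ranks = rankdata(both, axis=-1)
    length = prof_a.shape[-1]
    ra, rb = ranks[..., :length], ranks[..., length:]
    ra = ra - ra.mean(axis=-1, keepdims=True)
    rb = rb - rb.mean(axis=-1, keepdims=True)
    denom = np.sqrt((ra * ra).sum(axis=-1) * (rb * rb).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (ra * rb).sum(axis=-1) / denom, 0.0)


def roi_similarity(
    volume: GMVolume,
    atlas: AtlasVolume,
    profile_len: int = 100,
    min_voxels: int = 4,
) -> SimilarityMatrix:
    """ROI-pair similarity from jointly-ranked quantile profiles.

    Each ROI's masked intensities are sorted and resampled to
    ``profile_len`` points; pairs are compared with the pooled-rank
    correlation (1 exactly for identical multisets).  ROIs with fewer than
    ``min_voxels`` masked voxels are flagged and their similarities set NaN.
    """
    if volume.shape != atlas.shape:
        raise ValueError(
            f"grid shape mismatch: volume {volume.shape} vs atlas {atlas.shape}"
        )
    n = atlas.n_rois
    profiles = np.full((n, profile_len), np.nan)
    flagged = []
    for idx, rid in enumerate(atlas.roi_ids):
        vox = volume.intensities[(atlas.labels == rid) & volume.mask]
        if vox.size < min_voxels:
            flagged.append(idx)
            continue
        profiles[idx] = _quantile_profile(np.sort(vox), profile_len)
    rho = np.full((n, n), np.nan)
    ok = [i for i in range(n) if i not in flagged]
    for ai, i in enumerate(ok):
        js = ok[ai + 1:]
        if not js:
            continue
        r = _profile_rank_corr(
            np.broadcast_to(profiles[i], (len(js), profile_len)), profiles[js]
        )
        rho[i, js] = r
        rho[js, i] = r
    np.fill_diagonal(rho, 1.0)
    return SimilarityMatrix(rho, level="roi", flagged=flagged)


def fdr_edge_threshold(
    volume: GMVolume,
    atlas: AtlasVolume,
    n_perm: int = 100,
    q: float = 0.05,
    seed: int = 0,
    profile_len: int = 100,
    similarity: SimilarityMatrix | None = None,
) -> BinaryNetwork:
    """FDR-thresholded ROI network via pooled-reassignment permutation nulls.

    For each unordered ROI pair the null re-assigns the pooled masked voxels
    of the two ROIs to the two parcels at random and recomputes the profile
    similarity; p = (1 + #{null >= observed}) / (n_perm + 1).
    Benjamini-Hochberg across all pairs at level ``q`` defines the edges.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must be in [0, 1], got {q}")
    if similarity is None:
        similarity = roi_similarity(volume, atlas, profile_len=profile_len)
    n = similarity.n
    rng = np.random.default_rng(seed)
    roi_vox = [
        volume.intensities[(atlas.labels == rid) & volume.mask]
        for rid in atlas.roi_ids
    ]
    pairs, pvals = [], []
    ok = set(range(n)) - set(similarity.flagged)
    for i in range(n):
        for j in range(i + 1, n):
            if i not in ok or j not in ok:
                continue
            obs = similarity.rho[i, j]
            pooled = np.concatenate([roi_vox[i], roi_vox[j]])
            na = len(roi_vox[i])
            idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
            shuffled = pooled[idx]
            pa = _quantile_profile(np.sort(shuffled[:, :na], axis=1), profile_len)
            pb = _quantile_profile(np.sort(shuffled[:, na:], axis=1), profile_len)
            null = _profile_rank_corr(pa, pb)
            p = (1.0 + np.sum(null >= obs - 1e-12)) / (n_perm + 1.0)
            pairs.append((i, j))
            pvals.append(p)
    qvals, reject = bh_fdr(np.asarray(pvals), q)
    adj = np.zeros((n, n), dtype=bool)
    for (i, j), rej in zip(pairs, reject):
        adj[i, j] = adj[j, i] = rej
    pmat = np.full((n, n), np.nan)
    qmat = np.full((n, n), np.nan)
    for (i, j), p, qa in zip(pairs, pvals, qvals):
        pmat[i, j] = pmat[j, i] = p
        qmat[i, j] = qmat[j, i] = qa
    return BinaryNetwork(
        adj,
        threshold_used=float(q),
        null_method="fdr",
        provenance={
            "q": q, "n_perm": n_perm, "seed": seed,
            "profile_len": profile_len,
            "p_values": pmat, "q_values": qmat,
        },
    )
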