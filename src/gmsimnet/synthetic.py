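"""Synthetic three-group cohorts of gray-matter volumes with known structure.

The generator emulates the situation the pipeline targets: per-subject
smoothed gray-matter intensity maps whose *inter-regional similarity
structure* differs by diagnostic group (healthy controls, mild cognitive
impairment, dementia), plus a covariate table with demographics, cognitive
scores and CSF biomarker columns tied to a per-subject latent.

Model
-----
ROIs are axis-aligned blocks tiling the grid; each ROI belongs to one of
``n_modules`` contiguous modules.  Per subject, each module m draws a
27-component template ``T_m`` (one value per within-cube voxel position) and
each ROI r draws its own template ``U_r``; the ROI signal is the exchangeable
mixture

    S_r = sqrt(c) * T_{m(r)} + sqrt(1 - c) * U_r,      c = coupling[group]

so any two ROIs in the same module have latent correlation exactly c and
cross-module ROIs are independent.  Voxel intensity is

    x(v) = offset + amplitude_s * S_{roi(v)}[v mod 3] + noise_sd * eps(v)

with iid Gaussian eps.  Because the signal is indexed by within-cube voxel
position (grid-origin-anchored 3x3x3 tiling), the positional Spearman
similarity between two cubes recovers the module structure: its expectation
increases monotonically with c and vanishes as noise_sd grows.  The
per-subject amplitude ``amplitude_s = signal_amplitude * (1 + 0.3 * latent)``
makes network density (hence mean degree) increase with the subject latent,
which is the quantity the outcome scores and CSF columns are linked to.

Randomness fans out from one master seed into per-subject substreams, so
adding or removing a subject never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import AtlasVolume, GMVolume, write_atlas, write_volume

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_atlas",
    "generate_subject_volume",
    "generate_cohort_table",
    "simulate_cohort",
]

DEFAULT_COUPLING = {"HC": 0.2, "MCI": 0.5, "AD": 0.8}

#: Group-level means for the generated outcome and CSF columns (ADNI-like
#: orders of magnitude: MMSE points; A-beta, t-tau, p-tau in pg/mL).
GROUP_SCORE_MEAN = {"HC": 29.0, "MCI": 27.0, "AD": 22.0}
GROUP_ABETA_MEAN = {"HC": 1000.0, "MCI": 800.0, "AD": 650.0}
GROUP_TTAU_MEAN = {"HC": 240.0, "MCI": 300.0, "AD": 370.0}
GROUP_PTAU_MEAN = {"HC": 22.0, "MCI": 28.0, "AD": 37.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_per_group
        Subjects per group (>= 2).
    grid_shape
        Voxel grid of every volume.
    voxel_size_mm
        Voxel dimensions written into the NIfTI headers.
    n_rois
        Number of atlas parcels.
    coupling
        Ordered mapping group -> within-module inter-ROI latent correlation,
        each value in [0, 1).
    noise_sd
        SD of iid voxel noise (> 0).
    signal_amplitude
        Scale of the ROI signal relative to noise; 0 gives pure-noise volumes.
    n_modules
        Number of exchangeable-correlation ROI blocks.
    effect_assoc
        Slope linking the subject latent to the cognitive score column.
    effect_csf
        Slope linking the subject latent to the t-tau column (p-tau uses
        effect_csf / 10); negative by default so higher-latent (denser
        network) subjects carry lower tau, mirroring a protective direction.
    missing_csf_fraction
        Fraction of subjects whose CSF columns are set missing.
    seed
        Master seed; all randomness derives from it.
    """

    n_per_group: int = 20
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (0.94, 0.94, 1.2)
    n_rois: int = 90
    coupling: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    noise_sd: float = 1.0
    signal_amplitude: float = 1.0
    n_modules: int = 6
    effect_assoc: float = 1.0
    effect_csf: float = -80.0
    score_noise_sd: float = 2.0
    missing_csf_fraction: float = 0.2
    intensity_offset: float = 10.0
    latent_gain: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g, c in self.coupling.items():
            if not (0.0 <= c < 1.0):
                raise ValueError(f"coupling[{g!r}] must be in [0, 1), got {c}")
        if not (0.0 <= self.missing_csf_fraction <= 1.0):
            raise ValueError("missing_csf_fraction must be in [0, 1]")
        if self.n_modules < 1 or self.n_modules > self.n_rois:
            raise ValueError("n_modules must be in [1, n_rois]")

    @property
    def groups(self) -> list[str]:
        return list(self.coupling)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    roi_latent_corr: dict[str, np.ndarray]
    true_assoc_slope: float
    true_csf_slope: float
    subject_latents: dict[str, float]
    roi_module: np.ndarray = None  # type: ignore[assignment]


def roi_module_assignment(n_rois: int, n_modules: int) -> np.ndarray:
    """Module index (0-based) for ROI labels 1..n_rois, contiguous blocks."""
    r = np.arange(n_rois)
    return (r * n_modules) // n_rois


def module_correlation_matrix(n_rois: int, n_modules: int, c: float) -> np.ndarray:
    """Block-exchangeable correlation: c within a module, 0 across, 1 diag."""
    mod = roi_module_assignment(n_rois, n_modules)
    corr = np.where(mod[:, None] == mod[None, :], c, 0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _factor_triple(n: int, grid_shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """Factor n into (a, b, c) so block edge lengths are as equal as possible."""
    best, best_score = None, np.inf
    for a in range(1, n + 1):
        if n % a:
            continue
        for b in range(1, n // a + 1):
            if (n // a) % b:
                continue
            c = n // (a * b)
            lens = [grid_shape[0] / a, grid_shape[1] / b, grid_shape[2] / c]
            score = max(lens) / min(lens) + 1e-3 * max(lens)
            if min(lens) < 1:
                continue
            if score < best_score:
                best, best_score = (a, b, c), score
    if best is None:
        raise ValueError(f"cannot factor {n} ROIs onto grid {grid_shape}")
    return best


def _axis_bounds(extent: int, parts: int) -> np.ndarray:
    return np.round(np.linspace(0, extent, parts + 1)).astype(int)


def generate_atlas(
    grid_shape: tuple[int, int, int], n_rois: int = 90, seed: int = 0
) -> AtlasVolume:
    """Tile the grid with ``n_rois`` axis-aligned blocks and label them 1..n.

    The block layout is deterministic; the seed only permutes which label
    lands on which block.  Raises a sizing error when the grid cannot give
    every ROI at least two grid-origin-anchored 3x3x3 cubes (by majority
    vote), naming a sufficient grid.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    a, b, c = _factor_triple(n_rois, grid_shape)
    xb, yb, zb = (_axis_bounds(grid_shape[i], p) for i, p in enumerate((a, b, c)))
    labels = np.zeros(grid_shape, dtype=np.int32)
    perm = np.random.default_rng(seed).permutation(n_rois) + 1
    block = 0
    for i in range(a):
        for j in range(b):
            for k in range(c):
                labels[xb[i]:xb[i + 1], yb[j]:yb[j + 1], zb[k]:zb[k + 1]] = perm[block]
                block += 1
    # capacity check: every ROI must win >= 2 cubes of the origin-anchored tiling
    counts = _cube_majority_counts(labels, n_rois)
    if counts.min() < 2:
        min_grid = tuple(int(6 * p + 3) for p in (a, b, c))
        raise ValueError(
            f"grid {grid_shape} too small for {n_rois} ROIs: ROI(s) "
            f"{list(np.flatnonzero(counts < 2) + 1)} receive fewer than two "
            f"3x3x3 cubes; a grid of at least {min_grid} (blocks {a}x{b}x{c}) "
            "is sufficient"
        )
    return AtlasVolume(labels)


def _cube_majority_counts(labels: np.ndarray, n_rois: int) -> np.ndarray:
    nx, ny, nz = (s // 3 for s in labels.shape)
    trimmed = labels[: nx * 3, : ny * 3, : nz * 3]
    cubes = trimmed.reshape(nx, 3, ny, 3, nz, 3).transpose(0, 2, 4, 1, 3, 5)
    cubes = cubes.reshape(-1, 27)
    counts = np.zeros(n_rois, dtype=int)
    for cube in cubes:
        vals, cnt = np.unique(cube, return_counts=True)
        lab = vals[np.argmax(cnt)]  # ties resolved to lowest label by np.unique order
        if lab > 0:
            counts[lab - 1] += 1
    return counts


def generate_subject_volume(
    atlas: AtlasVolume,
    group: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    latent: float = 0.0,
) -> GMVolume:
    """Draw one subject's gray-matter volume under the group's coupling.

    Voxels outside the atlas are exactly zero; the mask is the atlas support.
    """
    if group not in config.coupling:
        raise KeyError(
            f"unknown group {group!r}: config defines {list(config.coupling)}"
        )
    c = config.coupling[group]
    labels = atlas.labels
    if labels.shape != tuple(config.grid_shape):
        raise ValueError(
            f"atlas shape {labels.shape} != config grid {tuple(config.grid_shape)}"
        )
    n_rois = atlas.n_rois
    mod = roi_module_assignment(n_rois, config.n_modules)

    t_mod = rng.standard_normal((config.n_modules, 27))
    u_roi = rng.standard_normal((n_rois, 27))
    s_roi = np.sqrt(c) * t_mod[mod] + np.sqrt(1.0 - c) * u_roi  # (n_rois, 27)

    amplitude = config.signal_amplitude * max(0.2, 1.0 + config.latent_gain * latent)

    ii, jj, kk = np.indices(labels.shape)
    pos27 = (ii % 3) * 9 + (jj % 3) * 3 + (kk % 3)
    inside = labels > 0
    intens = np.zeros(labels.shape, dtype=np.float64)
    intens[inside] = (
        config.intensity_offset
        + amplitude * s_roi[labels[inside] - 1, pos27[inside]]
        + config.noise_sd * rng.standard_normal(int(inside.sum()))
    )
    return GMVolume(intens, config.voxel_size_mm, mask=inside)


def _subject_rng(config: SimulationConfig, group_index: int, i: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, group_index, i])


def generate_cohort_table(
    config: SimulationConfig,
    subject_latents: dict[str, tuple[str, float]],
) -> tuple[pd.DataFrame, GroundTruth]:
    """Build the per-subject covariate/outcome table from simulated latents.

    ``subject_latents`` maps subject_id -> (group, latent).  Demographics are
    drawn from group-overlapping distributions (no true group differences in
    age, sex or education); the cognitive score and CSF columns carry the
    configured latent slopes on top of group-level means.
    """
    rng = np.random.default_rng([config.seed, 104729])
    rows = []
    for sid, (group, latent) in subject_latents.items():
        age = rng.normal(73.0, 6.0)
        sex = int(rng.random() < 0.5)
        edu = float(np.clip(rng.normal(16.0, 2.6), 6.0, 20.0))
        score = (
            GROUP_SCORE_MEAN.get(group, 26.0)
            + config.effect_assoc * latent
            + rng.normal(0.0, config.score_noise_sd)
        )
        has_csf = rng.random() >= config.missing_csf_fraction
        if has_csf:
            abeta = GROUP_ABETA_MEAN.get(group, 800.0) + rng.normal(0.0, 150.0)
            ttau = (
                GROUP_TTAU_MEAN.get(group, 300.0)
                + config.effect_csf * latent
                + rng.normal(0.0, 60.0)
            )
            ptau = (
                GROUP_PTAU_MEAN.get(group, 28.0)
                + (config.effect_csf / 10.0) * latent
                + rng.normal(0.0, 7.0)
            )
        else:
            abeta = ttau = ptau = np.nan
        rows.append(
            dict(
                subject_id=sid, group=group, age=age, sex=sex, education=edu,
                score_cog=score, csf_abeta=abeta, csf_ttau=ttau, csf_ptau=ptau,
            )
        )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        roi_latent_corr={
            g: module_correlation_matrix(config.n_rois, config.n_modules, c)
            for g, c in config.coupling.items()
        },
        true_assoc_slope=config.effect_assoc,
        true_csf_slope=config.effect_csf,
        subject_latents={sid: lat for sid, (_, lat) in subject_latents.items()},
        roi_module=roi_module_assignment(config.n_rois, config.n_modules),
    )
    return table, truth


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    return_volumes: bool = True,
) -> dict:
    """Generate the full cohort: atlas, per-subject volumes, table, truth.

    When ``out_dir`` is given, writes ``atlas.nii.gz``, one
    ``sub-<id>_gm.nii.gz`` per subject, ``cohort.tsv`` and
    ``ground_truth.json``.  Identical config + seed reproduce byte-identical
    outputs.
    """
    atlas = generate_atlas(config.grid_shape, config.n_rois, seed=config.seed)
    volumes: dict[str, GMVolume] = {}
    latents: dict[str, tuple[str, float]] = {}
    for gi, group in enumerate(config.groups):
        for i in range(config.n_per_group):
            rng = _subject_rng(config, gi, i)
            latent = float(rng.standard_normal())
            sid = f"{group}{i:03d}"
            vol = generate_subject_volume(atlas, group, config, rng, latent)
            latents[sid] = (group, latent)
            if return_volumes or out_dir is not None:
                volumes[sid] = vol
    table, truth = generate_cohort_table(config, latents)

    result = {
        "atlas": atlas,
        "volumes": volumes if return_volumes else None,
        "table": table,
        "truth": truth,
        "config": config,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_atlas(atlas, out / "atlas.nii.gz", config.voxel_size_mm)
        paths = {}
        for sid, vol in volumes.items():
            p = out / f"sub-{sid}_gm.nii.gz"
            write_volume(vol, p)
            paths[sid] = str(p)
        table.to_csv(out / "cohort.tsv", sep="\t", index=False)
        truth_json = {
            "true_assoc_slope": truth.true_assoc_slope,
            "true_csf_slope": truth.true_csf_slope,
            "subject_latents": truth.subject_latents,
            "coupling": dict(config.coupling),
            "n_modules": config.n_modules,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
        result["paths"] = paths
    return result
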