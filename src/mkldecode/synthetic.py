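"""Synthetic data with the statistical structure of a blocked threat-perception fMRI study.

The generators emulate the study design the decoding pipeline assumes:
38 subjects viewing threat or neutral pictures directed towards or away
from the viewer, 4 runs of 198 volumes at TR = 2 s, 56 blocks of 15 s
(14 per condition) separated by 12-s fixation baselines, a 120-region
style anatomical parcellation (any region count), and a per-subject
threat-perception index obtained by summing four 1-9 ratings (threat
magnitude, proximity, inescapability, impossibility of hiding).

Condition effects are region-localised: informative voxels carry a mean
threat-vs-neutral amplitude difference delta plus an amplitude modulation
gamma per standard-deviation unit of the subject's threat-perception
index, on top of per-subject offsets and Gaussian noise.  Everything is
deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .glm import ContrastImage, HRFSpec, _convolved_regressor, gaussian_smooth

__all__ = [
    "AtlasParcellation",
    "StudyDesign",
    "EffectSpec",
    "RATING_DIMENSIONS",
    "LOBE_GROUPS",
    "make_synthetic_atlas",
    "make_contrast_dataset",
    "make_bold_session",
    "make_stimulus_image",
    "sample_ratings",
]

RATING_DIMENSIONS = ("threat_magnitude", "proximity", "inescapability",
                     "impossibility_of_hiding")

LOBE_GROUPS = ("frontal", "parietal", "temporal", "occipital",
               "subcortical", "cerebellum")


@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation volume plus its region table.

    ``label_volume`` uses 0 for background and contiguous ids 1..R for
    regions; ``region_table`` rows are (region_id, region_name,
    lobe_group).  Every region id in the table occurs in the volume and
    vice versa, and every region has at least one voxel.
    """

    label_volume: np.ndarray
    region_table: pd.DataFrame
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("atlas label volume must be 3-D")
        ids_in_volume = set(np.unique(self.label_volume)) - {0}
        ids_in_table = set(self.region_table["region_id"])
        if ids_in_volume != ids_in_table:
            raise ValueError("region table ids do not match label volume ids")
        expected = set(range(1, len(ids_in_table) + 1))
        if ids_in_table != expected:
            raise ValueError("region ids must be contiguous from 1")

    @property
    def region_ids(self) -> list[int]:
        return list(self.region_table["region_id"])

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    @property
    def mask(self) -> np.ndarray:
        return self.label_volume > 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


@dataclass(frozen=True)
class StudyDesign:
    """Block-design study layout; defaults mirror the emulated protocol."""

    n_subjects: int = 38
    conditions: tuple[str, ...] = ("threat_towards", "threat_away",
                                   "neutral_towards", "neutral_away")
    n_runs: int = 4
    volumes_per_run: int = 198
    tr_seconds: float = 2.0
    block_duration_s: float = 15.0
    baseline_duration_s: float = 12.0
    blocks_per_condition: int = 14

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")
        if self.total_blocks % self.n_runs:
            raise ValueError("blocks must divide evenly across runs")
        blocks_per_run = self.total_blocks // self.n_runs
        needed = (self.baseline_duration_s
                  + blocks_per_run * (self.block_duration_s + self.baseline_duration_s))
        if needed > self.volumes_per_run * self.tr_seconds:
            raise ValueError("block schedule does not fit within the run duration")
        if self.blocks_per_condition < self.n_runs:
            raise ValueError("each condition must appear in every run")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def total_blocks(self) -> int:
        return self.blocks_per_condition * self.n_conditions

    @property
    def threat_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c.startswith("threat"))

    def subject_ids(self) -> list[str]:
        width = len(str(self.n_subjects))
        return [f"sub{str(i + 1).zfill(width)}" for i in range(self.n_subjects)]


@dataclass(frozen=True)
class EffectSpec:
    """Generative effect parameters for the synthetic study.

    delta: mean amplitude added to threat conditions in informative
    voxels (signal units).  gamma: additional amplitude per standard
    deviation of the subject's threat-perception index.  sigma: voxel
    noise SD.  subject_offset_sd: SD of a per-subject global offset.
    smoothness_fwhm_mm: optional Gaussian-correlated noise component.
    nan_fraction: fraction of border voxels set to NaN in a random subset
    of subjects (off by default; exercises the common-mask rule).
    baseline / drift_amplitude / ar_coef parameterise the BOLD simulator.
    """

    informative_region_ids: tuple[int, ...] = (1,)
    delta: float = 1.0
    gamma: float = 0.0
    sigma: float = 0.5
    subject_offset_sd: float = 0.2
    smoothness_fwhm_mm: float = 0.0
    nan_fraction: float = 0.0
    baseline: float = 100.0
    drift_amplitude: float = 0.0
    ar_coef: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.delta, self.sigma, self.subject_offset_sd) < 0:
            raise ValueError("delta, sigma and subject_offset_sd must be >= 0")
        if not 0 <= self.nan_fraction < 1:
            raise ValueError("nan_fraction must be in [0, 1)")

    def validate_against(self, atlas: AtlasParcellation) -> None:
        extra = set(self.informative_region_ids) - set(atlas.region_ids)
        if extra:
            raise ValueError(f"informative regions not in atlas: {sorted(extra)}")


def make_synthetic_atlas(grid_shape: tuple[int, int, int], n_regions: int,
                         seed: int = 0,
                         voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0),
                         ) -> AtlasParcellation:
    """Random contiguous parcellation of an ellipsoidal brain-like mask.

    Region centres are drawn uniformly inside the mask and every mask
    voxel is assigned to its nearest centre (a Voronoi tessellation, so
    regions are connected blobs).  Lobe groups are assigned round-robin.
    """
    if n_regions < 2:
        raise ValueError("need at least two regions")
    shape = tuple(int(s) for s in grid_shape)
    centre = (np.array(shape) - 1) / 2.0
    semi = np.maximum(np.array(shape) * 0.45, 0.5)
    idx = np.indices(shape).reshape(3, -1).T
    inside = ((idx - centre) / semi) ** 2
    mask_flat = inside.sum(axis=1) <= 1.0
    coords = idx[mask_flat]
    if len(coords) < n_regions:
        raise ValueError(
            f"grid {shape} has only {len(coords)} brain voxels; "
            f"cannot host {n_regions} regions")
    rng = np.random.default_rng(seed)
    seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    labels = cKDTree(seeds).query(coords)[1] + 1
    volume = np.zeros(shape, dtype=np.int32)
    volume[tuple(coords.T)] = labels
    width = len(str(n_regions))
    table = pd.DataFrame({
        "region_id": np.arange(1, n_regions + 1),
        "region_name": [f"region_{str(i + 1).zfill(width)}" for i in range(n_regions)],
        "lobe_group": [LOBE_GROUPS[i % len(LOBE_GROUPS)] for i in range(n_regions)],
    })
    return AtlasParcellation(label_volume=volume, region_table=table,
                             voxel_size=voxel_size)


def sample_ratings(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-subject four-dimension threat ratings and their summed index.

    Each rating is a discretised truncated normal on 1-9 (mean 3, SD 2),
    chosen so the summed index has mean/SD near the reported towards-
    context values (about 12.4 and 7.5 before truncation tightening).
    """
    lo, hi, mu, sd = 1.0, 9.0, 3.0, 2.0
    a, b = (lo - mu) / sd, (hi - mu) / sd
    raw = truncnorm.rvs(a, b, loc=mu, scale=sd,
                        size=(design.n_subjects, 4), random_state=rng)
    ratings = np.clip(np.rint(raw), 1, 9).astype(int)
    df = pd.DataFrame(ratings, columns=[f"rating_{i + 1}" for i in range(4)])
    df.insert(0, "subject_id", design.subject_ids())
    df["index"] = df[[f"rating_{i + 1}" for i in range(4)]].sum(axis=1)
    return df


def _standardized_index(ratings: pd.DataFrame) -> np.ndarray:
    idx = ratings["index"].to_numpy(dtype=float)
    sd = idx.std(ddof=0)
    return (idx - idx.mean()) / sd if sd > 0 else np.zeros_like(idx)


def make_contrast_dataset(design: StudyDesign, atlas: AtlasParcellation,
                          effect: EffectSpec, seed: int = 0,
                          ) -> tuple[list[ContrastImage], pd.DataFrame]:
    """Per-subject, per-condition contrast images plus the ratings table.

    Threat-condition images receive ``delta + gamma * z(index)`` in
    informative voxels; neutral conditions have zero mean.  A per-subject
    offset and iid Gaussian noise (optionally smoothed) are added inside
    the atlas mask; voxels outside the mask are NaN.  Images are ordered
    subject-major, condition order as declared in the design.
    """
    effect.validate_against(atlas)
    rng = np.random.default_rng(seed)
    ratings = sample_ratings(design, rng)
    z = _standardized_index(ratings)
    mask = atlas.mask
    informative = np.isin(atlas.label_volume, effect.informative_region_ids)
    images: list[ContrastImage] = []
    affine = atlas.affine
    for s, subject in enumerate(design.subject_ids()):
        offset = rng.normal(0.0, effect.subject_offset_sd)
        inject_nan = effect.nan_fraction > 0 and rng.random() < 0.5
        for condition in design.conditions:
            vol = np.full(mask.shape, np.nan)
            noise = rng.normal(0.0, effect.sigma, size=mask.shape)
            if effect.smoothness_fwhm_mm > 0:
                smooth = gaussian_smooth(rng.normal(0.0, 1.0, size=mask.shape),
                                         effect.smoothness_fwhm_mm, atlas.voxel_size)
                sd = smooth.std()
                if sd > 0:
                    noise = (noise + effect.sigma * smooth / sd) / np.sqrt(2.0)
            vol[mask] = offset + noise[mask]
            if condition in design.threat_conditions:
                vol[mask & informative] += effect.delta + effect.gamma * z[s]
            if inject_nan:
                vol = _inject_border_nans(vol, mask, effect.nan_fraction, rng)
            images.append(ContrastImage(data=vol, affine=affine,
                                        subject_id=subject, condition=condition))
    return images, ratings


def _inject_border_nans(vol: np.ndarray, mask: np.ndarray, fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    """NaN out a random fraction of mask-border voxels (inside the mask)."""
    from scipy import ndimage as ndi
    border = mask & ~ndi.binary_erosion(mask)
    coords = np.argwhere(border)
    n = max(1, int(round(fraction * len(coords))))
    pick = coords[rng.choice(len(coords), size=min(n, len(coords)), replace=False)]
    out = vol.copy()
    out[tuple(pick.T)] = np.nan
    return out


@dataclass
class BoldSession:
    """One subject's simulated acquisition: runs, events, motion, ratings."""

    runs: list[np.ndarray]
    events: pd.DataFrame         # run, onset_s, duration_s, condition
    motion: pd.DataFrame         # run, trans_x..rot_z, one row per volume
    ratings: pd.Series           # rating_1..4 and index for this subject
    amplitudes: dict[str, float]  # injected amplitude per condition


def _block_schedule(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Pseudo-randomised block order: every condition in every run,
    ``blocks_per_condition`` blocks per condition overall."""
    blocks_per_run = design.total_blocks // design.n_runs
    # round-robin allocation of condition counts to runs, then shuffle
    counts = np.zeros((design.n_runs, design.n_conditions), dtype=int)
    order = rng.permutation(design.n_conditions)
    slot = 0
    for c in order:
        for _ in range(design.blocks_per_condition):
            counts[slot % design.n_runs, c] += 1
            slot += 1
    rows = []
    for run in range(design.n_runs):
        conds: list[str] = []
        for c, cnt in enumerate(counts[run]):
            conds.extend([design.conditions[c]] * cnt)
        rng.shuffle(conds)
        assert len(conds) == blocks_per_run
        period = design.block_duration_s + design.baseline_duration_s
        for k, cond in enumerate(conds):
            rows.append({"run": run + 1,
                         "onset_s": design.baseline_duration_s + k * period,
                         "duration_s": design.block_duration_s,
                         "condition": cond})
    return pd.DataFrame(rows)


def _ar1_noise(n: int, sd: float, rho: float, rng: np.random.Generator,
               shape: tuple[int, ...]) -> np.ndarray:
    white = rng.normal(0.0, sd, size=shape + (n,))
    if rho == 0 or sd == 0:
        return white
    out = np.empty_like(white)
    out[..., 0] = white[..., 0] / np.sqrt(1 - rho ** 2)
    for t in range(1, n):
        out[..., t] = rho * out[..., t - 1] + white[..., t]
    return out


def make_bold_session(design: StudyDesign, atlas: AtlasParcellation,
                      effect: EffectSpec, seed: int = 0,
                      subject_id: str = "sub01") -> BoldSession:
    """Simulate one subject's 4-D block-design BOLD acquisition.

    Each run is baseline + sum over conditions of amplitude x
    (boxcar ⊛ canonical HRF) + a slow cosine drift + AR(1) noise.
    Informative voxels in threat conditions carry amplitude
    ``delta + gamma * z``, with z a standard-normal draw standing in for
    the subject's standardised threat-perception index; other voxels
    respond with zero amplitude.  Events are reported in absolute run
    time (including the volumes a GLM will later drop).
    """
    effect.validate_against(atlas)
    rng = np.random.default_rng(seed)
    ratings_row = sample_ratings(design, rng).iloc[0]
    z = rng.standard_normal()
    events = _block_schedule(design, rng)
    mask = atlas.mask
    informative = mask & np.isin(atlas.label_volume, effect.informative_region_ids)
    threat_amp = effect.delta + effect.gamma * z
    amplitudes = {c: (threat_amp if c in design.threat_conditions else 0.0)
                  for c in design.conditions}

    n = design.volumes_per_run
    tr = design.tr_seconds
    t_scan = np.arange(n) * tr
    hrf = HRFSpec()
    runs = []
    motion_rows = []
    for run in range(1, design.n_runs + 1):
        ev = events[events["run"] == run]
        series = np.zeros(mask.shape + (n,))
        series += effect.baseline
        for cond in design.conditions:
            sel = ev[ev["condition"] == cond]
            reg = _convolved_regressor(sel["onset_s"].to_numpy(),
                                       sel["duration_s"].to_numpy(), n, tr, hrf)
            if cond in design.threat_conditions:
                series[informative] += amplitudes[cond] * reg
            # neutral amplitude is zero: nothing to add
        if effect.drift_amplitude > 0:
            drift = effect.drift_amplitude * np.cos(
                2 * np.pi * t_scan / (n * tr) + rng.uniform(0, 2 * np.pi))
            series[mask] += drift
        if effect.sigma > 0:
            series[mask] += _ar1_noise(n, effect.sigma, effect.ar_coef, rng,
                                       (int(mask.sum()),))
        runs.append(series)
        phase = rng.uniform(0, 2 * np.pi, size=6)
        scale = np.concatenate([rng.uniform(0.05, 0.3, 3),
                                rng.uniform(0.001, 0.005, 3)])
        mot = scale * np.sin(np.outer(t_scan, 2 * np.pi / rng.uniform(120, 400, 6))
                             + phase)
        df = pd.DataFrame(mot, columns=["trans_x", "trans_y", "trans_z",
                                        "rot_x", "rot_y", "rot_z"])
        df.insert(0, "run", run)
        motion_rows.append(df)

    return BoldSession(runs=runs, events=events,
                       motion=pd.concat(motion_rows, ignore_index=True),
                       ratings=ratings_row, amplitudes=amplitudes)


def make_stimulus_image(kind: str, width: int = 64, height: int = 64,
                        seed: int = 0, value: int = 128,
                        period: int = 8) -> np.ndarray:
    """Analytic RGB test pictures for the picture-metric routines.

    kinds: ``uniform`` (all pixels = value), ``vertical_gradient``
    (columns ramp 0..255 left to right), ``checkerboard`` (levels 0/255,
    given square period), ``noise`` (seeded uniform random RGB).
    Returns an (height, width, 3) uint8 array.
    """
    if width < 1 or height < 1:
        raise ValueError("image must be at least 1x1")
    if kind == "uniform":
        img = np.full((height, width, 3), value, dtype=np.uint8)
    elif kind == "vertical_gradient":
        col = np.linspace(0, 255, width)
        img = np.repeat(col[None, :, None], height, axis=0)
        img = np.repeat(img, 3, axis=2).astype(np.uint8)
    elif kind == "checkerboard":
        if period < 1:
            raise ValueError("checkerboard period must be >= 1")
        yy, xx = np.indices((height, width))
        board = (((yy // period) + (xx // period)) % 2) * 255
        img = np.repeat(board[:, :, None], 3, axis=2).astype(np.uint8)
    elif kind == "noise":
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
    else:
        raise ValueError(f"unknown stimulus kind: {kind!r}")
    return img


# ---------------------------------------------------------------------------
# persistence: NIfTI volumes, CSV tables, YAML scenarios

def save_dataset(out_dir: str | Path, images: list[ContrastImage],
                 ratings: pd.DataFrame, atlas: AtlasParcellation) -> None:
    """Write contrast images and atlas as NIfTI-1 plus CSV side tables."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(atlas.label_volume.astype(np.int16), atlas.affine),
             out / "atlas.nii.gz")
    atlas.region_table.to_csv(out / "regions.csv", index=False)
    ratings.to_csv(out / "ratings.csv", index=False)
    rows = []
    for img in images:
        name = f"{img.subject_id}_{img.condition}_gtbaseline.nii.gz"
        nib.save(nib.Nifti1Image(img.data.astype(np.float32), img.affine),
                 out / name)
        rows.append({"subject_id": img.subject_id, "condition": img.condition,
                     "file": name})
    pd.DataFrame(rows).to_csv(out / "images.csv", index=False)


def load_dataset(in_dir: str | Path) -> tuple[list[ContrastImage], pd.DataFrame,
                                              AtlasParcellation]:
    """Inverse of :func:`save_dataset`."""
    import nibabel as nib

    src = Path(in_dir)
    atlas_img = nib.load(src / "atlas.nii.gz")
    table = pd.read_csv(src / "regions.csv")
    voxel_size = tuple(float(v) for v in atlas_img.header.get_zooms()[:3])
    atlas = AtlasParcellation(label_volume=np.asarray(atlas_img.dataobj).astype(int),
                              region_table=table, voxel_size=voxel_size)
    ratings = pd.read_csv(src / "ratings.csv")
    manifest = pd.read_csv(src / "images.csv")
    images = []
    for _, row in manifest.iterrows():
        img = nib.load(src / row["file"])
        images.append(ContrastImage(data=np.asarray(img.dataobj, dtype=float),
                                    affine=img.affine,
                                    subject_id=row["subject_id"],
                                    condition=row["condition"]))
    return images, ratings, atlas


def scenario_from_yaml(path: str | Path) -> tuple[StudyDesign, EffectSpec, int]:
    """Read a YAML scenario (design + effect + seed) for the generators."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    design_kwargs = dict(cfg.get("design", {}))
    if "conditions" in design_kwargs:
        design_kwargs["conditions"] = tuple(design_kwargs["conditions"])
    effect_kwargs = dict(cfg.get("effect", {}))
    if "informative_region_ids" in effect_kwargs:
        effect_kwargs["informative_region_ids"] = tuple(
            effect_kwargs["informative_region_ids"])
    known = {f.name for f in dataclasses.fields(StudyDesign)}
    unknown = set(design_kwargs) - known
    if unknown:
        raise ValueError(f"unknown design fields: {sorted(unknown)}")
    return (StudyDesign(**design_kwargs), EffectSpec(**effect_kwargs),
            int(cfg.get("seed", 0)))
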