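"""First-level general linear model for block-design BOLD time series.

Produces per-condition, condition-versus-baseline contrast images from a
4-D time series: block regressors convolved with a canonical double-gamma
hemodynamic response function, a discrete-cosine drift basis with a fixed
high-pass cut-off, optional nuisance covariates (e.g. motion parameters),
and a per-run constant.  Estimation is voxelwise ordinary least squares;
runs are modelled independently and per-condition contrast estimates are
averaged across runs so that units do not depend on the number of runs.

Registration-type preprocessing (realignment, coregistration, spatial
normalisation) is out of scope: input series are assumed already aligned
to a common grid.  Serial-correlation prewhitening is deliberately not
applied; OLS point estimates of block amplitudes are unbiased under
stationary noise and are all the downstream pattern analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sp_linalg
from scipy import ndimage
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "ContrastImage",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm_and_contrast",
    "gaussian_smooth",
    "build_common_mask",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma haemodynamic response parameters (seconds).

    Defaults are the conventional canonical shape: response peak around
    5 s, undershoot around 15 s, peak:undershoot ratio 6, 32-s support.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.length_s < 24.0:
            raise ValueError("HRF support must be at least 24 s")
        if min(self.peak_delay, self.undershoot_delay,
               self.peak_dispersion, self.undershoot_dispersion) <= 0:
            raise ValueError("HRF delays and dispersions must be positive")


@dataclass
class DesignMatrix:
    """Time-by-regressor design with named columns.

    ``interest_idx`` are the condition (boxcar ⊛ HRF) columns;
    ``nuisance_idx`` covers drift, motion covariates and the constant.
    """

    matrix: np.ndarray
    names: list[str]
    interest_idx: list[int]
    nuisance_idx: list[int]
    tr_seconds: float
    n_scans: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.n_scans, len(self.names)):
            raise ValueError("design matrix shape inconsistent with names/n_scans")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class ContrastImage:
    """3-D contrast map with grid affine and sample metadata.

    Finite inside its mask; NaN marks voxels with no valid estimate.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_id: str
    condition: str
    contrast_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("contrast image must be 3-D")
        if not self.contrast_name:
            self.contrast_name = f"{self.condition} > baseline"


def canonical_hrf(tr: float, spec: HRFSpec | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF at one value per TR.

    h(t) = g(t; peak) − g(t; undershoot) / ratio, with each g a gamma
    density parameterised by delay (mean = shape·scale) and dispersion
    (scale).  The kernel has ``ceil(length_s / tr)`` samples starting at
    t = 0 and integrates to a positive value.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    spec = spec or HRFSpec()
    n = int(np.ceil(spec.length_s / tr))
    t = np.arange(n) * tr
    peak = gamma_dist.pdf(t, spec.peak_delay / spec.peak_dispersion,
                          scale=spec.peak_dispersion)
    under = gamma_dist.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                           scale=spec.undershoot_dispersion)
    return peak - under / spec.ratio


def _dct_drift_basis(n_scans: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors with periods >= cutoff_s.

    Basis k (k >= 1) is cos(pi k (2i+1) / (2N)) with period 2·N·tr / k;
    the number of retained terms is floor(2·N·tr / cutoff_s).  Columns
    are mutually orthogonal and orthogonal to the constant.
    """
    total_s = n_scans * tr
    k_max = int(np.floor(2.0 * total_s / cutoff_s))
    i = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * i + 1) / (2 * n_scans))
            for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def _convolved_regressor(onsets: np.ndarray, durations: np.ndarray,
                         n_scans: int, tr: float, spec: HRFSpec,
                         oversample: int = 16) -> np.ndarray:
    """Boxcar ⊛ HRF evaluated at scan acquisition times (microtime grid)."""
    dt = tr / oversample
    n_fine = n_scans * oversample
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        a = int(np.round(onset / dt))
        b = int(np.round((onset + dur) / dt))
        box[a:min(b, n_fine)] = 1.0
    hrf_len = int(np.ceil(spec.length_s / dt))
    t = np.arange(hrf_len) * dt
    kern = (gamma_dist.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
            - gamma_dist.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                             scale=spec.undershoot_dispersion) / spec.ratio)
    conv = np.convolve(box, kern * dt)[:n_fine]
    return conv[::oversample]


def build_design_matrix(events: pd.DataFrame, n_scans: int, tr: float,
                        hp_cutoff_s: float = 128.0,
                        nuisance: pd.DataFrame | None = None,
                        hrf: HRFSpec | None = None) -> DesignMatrix:
    """Assemble a single-run design matrix.

    Parameters
    ----------
    events : DataFrame with columns ``onset_s``, ``duration_s``,
        ``condition``.  One convolved boxcar column is created per
        distinct condition (sorted order).  May be empty.
    n_scans, tr : scan count and repetition time for this run.
    hp_cutoff_s : high-pass cut-off period for the cosine drift basis.
    nuisance : optional covariates of no interest, one column per series.
    """
    if hp_cutoff_s < 2 * tr:
        raise ValueError("high-pass cutoff must be at least 2 TR")
    hrf = hrf or HRFSpec()
    total_s = n_scans * tr
    if len(events):
        ends = events["onset_s"].to_numpy() + events["duration_s"].to_numpy()
        if (events["onset_s"] < 0).any() or (ends > total_s).any():
            raise ValueError("events fall outside the scan window")

    cols: list[np.ndarray] = []
    names: list[str] = []
    for cond in sorted(events["condition"].unique()) if len(events) else []:
        sel = events[events["condition"] == cond]
        cols.append(_convolved_regressor(sel["onset_s"].to_numpy(),
                                         sel["duration_s"].to_numpy(),
                                         n_scans, tr, hrf))
        names.append(str(cond))
    interest_idx = list(range(len(names)))

    drift = _dct_drift_basis(n_scans, tr, hp_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    if nuisance is not None:
        for c in nuisance.columns:
            cols.append(np.asarray(nuisance[c], dtype=float))
            names.append(f"nuisance_{c}")
    cols.append(np.ones(n_scans))
    names.append("constant")
    nuisance_idx = [i for i in range(len(names)) if i not in interest_idx]

    return DesignMatrix(matrix=np.column_stack(cols), names=names,
                        interest_idx=interest_idx, nuisance_idx=nuisance_idx,
                        tr_seconds=tr, n_scans=n_scans)


def _check_full_rank(design: DesignMatrix) -> None:
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR on the normalized matrix
        norms = np.linalg.norm(X, axis=0)
        Xn = X / np.where(norms > 0, norms, 1.0)
        _, R, piv = sp_linalg.qr(Xn, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [design.names[piv[i]] for i in range(len(diag))
               if diag[i] < 1e-10 * diag[0]]
        bad = bad or [design.names[i] for i, nrm in enumerate(norms) if nrm == 0]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_glm_and_contrast(series: np.ndarray, design: DesignMatrix,
                         contrast_vector: np.ndarray,
                         affine: np.ndarray | None = None,
                         subject_id: str = "", condition: str = "") -> ContrastImage:
    """Voxelwise OLS fit and contrast image for one run.

    ``series`` is a 4-D array (x, y, z, t).  Voxels containing any
    non-finite sample get NaN in the output.  The contrast image is
    ``contrast_vector · β̂`` per voxel.
    """
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, z, t)")
    if series.shape[3] != design.n_scans:
        raise ValueError("series length does not match design n_scans")
    contrast_vector = np.asarray(contrast_vector, dtype=float)
    if contrast_vector.shape != (len(design.names),):
        raise ValueError("contrast vector length must equal number of regressors")
    _check_full_rank(design)

    shape = series.shape[:3]
    Y = series.reshape(-1, design.n_scans).T  # t x voxels
    finite = np.all(np.isfinite(Y), axis=0)
    out = np.full(Y.shape[1], np.nan)
    if finite.any():
        beta, *_ = np.linalg.lstsq(design.matrix, Y[:, finite], rcond=None)
        out[finite] = contrast_vector @ beta
    if affine is None:
        affine = np.eye(4)
    return ContrastImage(data=out.reshape(shape), affine=affine,
                         subject_id=subject_id, condition=condition)


def fit_subject_contrasts(runs: list[np.ndarray], run_events: list[pd.DataFrame],
                          tr: float, run_nuisance: list[pd.DataFrame] | None = None,
                          hp_cutoff_s: float = 128.0, drop_initial: int = 3,
                          hrf: HRFSpec | None = None,
                          affine: np.ndarray | None = None,
                          subject_id: str = "") -> dict[str, ContrastImage]:
    """Model each run independently and average per-condition contrasts.

    The first ``drop_initial`` volumes of every run are discarded and
    event onsets shifted accordingly (non-equilibrium magnetisation).
    Returns one condition-versus-baseline ContrastImage per condition
    (baseline is the unmodelled inter-block interval).
    """
    if run_nuisance is None:
        run_nuisance = [None] * len(runs)
    conditions = sorted(pd.concat(run_events)["condition"].unique())
    per_cond: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    shift = drop_initial * tr
    for series, events, nuis in zip(runs, run_events, run_nuisance):
        series = series[..., drop_initial:]
        events = events.copy()
        events["onset_s"] = events["onset_s"] - shift
        if nuis is not None:
            nuis = nuis.iloc[drop_initial:].reset_index(drop=True)
        design = build_design_matrix(events, series.shape[3], tr,
                                     hp_cutoff_s=hp_cutoff_s, nuisance=nuis, hrf=hrf)
        for cond in conditions:
            cvec = np.zeros(len(design.names))
            cvec[design.names.index(cond)] = 1.0
            img = fit_glm_and_contrast(series, design, cvec, affine=affine,
                                       subject_id=subject_id, condition=cond)
            per_cond[cond].append(img.data)
    out = {}
    for cond, maps in per_cond.items():
        out[cond] = ContrastImage(data=np.mean(maps, axis=0),
                                  affine=affine if affine is not None else np.eye(4),
                                  subject_id=subject_id, condition=cond)
    return out


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float,
                    voxel_size: tuple[float, float, float] | float) -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in millimetres."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return volume.copy()
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / vs
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_vox)


def build_common_mask(images: list[ContrastImage]) -> np.ndarray:
    """Boolean mask of voxels finite in every supplied image.

    A voxel that is NaN for any one subject or condition is excluded for
    all of them, so every sample shares one feature space.
    """
    if not images:
        raise ValueError("need at least one image")
    shape = images[0].data.shape
    mask = np.ones(shape, dtype=bool)
    for img in images:
        if img.data.shape != shape:
            raise ValueError("images are not on a common grid")
        mask &= np.isfinite(img.data)
    return mask
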