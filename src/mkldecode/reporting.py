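"""Region ranking, lobe summaries and weight-map export.

The kernel weight of a region measures its contribution to the learned
prediction function.  Weights are averaged across the outer
cross-validation folds, renormalised to percentages summing to 100 (a
no-op unless some fold dropped regions), and ranked in descending
order with ties broken by region id.  A selection frequency — the
fraction of folds in which the region received nonzero weight — is
added as a stability diagnostic (an extension beyond the ranking
itself).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mkl import MKLModel, WeightMap
from .synthetic import AtlasParcellation

__all__ = ["rank_regions", "summarize_by_lobe", "export_weight_maps"]


def rank_regions(fold_models: list[MKLModel],
                 region_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fold-averaged region weights, as a ranked percentage table.

    Columns: region_id, mean_pct, rank, selection_freq (+ region_name
    and lobe_group when a region table is supplied).  ``mean_pct`` sums
    to 100 over retained regions.
    """
    if not fold_models:
        raise ValueError("need at least one fold model")
    ref_ids = fold_models[0].region_ids
    weights = np.zeros((len(fold_models), len(ref_ids)))
    for i, m in enumerate(fold_models):
        if m.region_ids != ref_ids:
            raise ValueError("fold models have inconsistent region sets")
        weights[i] = m.kernel_weights
    mean_w = weights.mean(axis=0)
    mean_pct = 100.0 * mean_w / mean_w.sum()
    df = pd.DataFrame({
        "region_id": ref_ids,
        "mean_pct": mean_pct,
        "selection_freq": (weights > 0).mean(axis=0),
    })
    df = df.sort_values(["mean_pct", "region_id"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    if region_table is not None:
        df = df.merge(region_table, on="region_id", how="left")
        missing = df["lobe_group"].isna()
        if missing.any():
            raise ValueError("regions missing from the region table: "
                             f"{sorted(df.loc[missing, 'region_id'])}")
        df = df[["region_id", "region_name", "lobe_group", "mean_pct",
                 "rank", "selection_freq"]]
    return df.reset_index(drop=True)


def summarize_by_lobe(ranking: pd.DataFrame,
                      region_table: pd.DataFrame | None = None) -> pd.Series:
    """Summed weight percentage per cerebral lobe, descending.

    The grand total equals the ranking's total (100 up to rounding).
    """
    df = ranking
    if "lobe_group" not in df.columns:
        if region_table is None:
            raise ValueError("ranking lacks lobe_group; supply a region table")
        df = df.merge(region_table, on="region_id", how="left")
    if df["lobe_group"].isna().any():
        unmapped = sorted(df.loc[df["lobe_group"].isna(), "region_id"])
        raise ValueError(f"regions not mapped to a lobe: {unmapped}")
    sums = df.groupby("lobe_group")["mean_pct"].sum()
    return sums.sort_values(ascending=False)


def export_weight_maps(weight_map: WeightMap, atlas: AtlasParcellation,
                       out_dir: str | Path,
                       ranking: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write region-level and voxel-level weight volumes plus a CSV table.

    The region-level volume assigns every voxel its region's weight
    percentage (0 outside); the voxel-level volume holds the primal
    voxel weights.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import nibabel as nib

    shape = atlas.label_volume.shape
    region_vol = np.zeros(shape)
    for rid, pct in weight_map.region_percent.items():
        region_vol[atlas.label_volume == rid] = pct
    voxel_vol = weight_map.volume(shape)
    if (voxel_vol[atlas.label_volume == 0] != 0).any():
        raise ValueError("voxel weights fall outside the atlas")
    paths = {
        "region": out / "region_weights.nii.gz",
        "voxel": out / "voxel_weights.nii.gz",
        "table": out / "region_ranking.csv",
    }
    nib.save(nib.Nifti1Image(region_vol.astype(np.float32), atlas.affine),
             paths["region"])
    nib.save(nib.Nifti1Image(voxel_vol.astype(np.float32), atlas.affine),
             paths["voxel"])
    if ranking is None:
        ranking = pd.DataFrame({
            "region_id": list(weight_map.region_percent),
            "mean_pct": list(weight_map.region_percent.values()),
        }).sort_values("mean_pct", ascending=False)
    ranking.to_csv(paths["table"], index=False)
    return paths
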