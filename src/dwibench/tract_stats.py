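"""Probability-weighted per-tract statistics, tract-volume QC by coefficient
of variation, and left/right merging."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import TractAtlas, merge_name

log = logging.getLogger(__name__)

FEATURES = ("mean", "sd")


def tract_weighted_stats(
    maps,
    atlas: TractAtlas,
    prob_floor: float = 0.5,
    *,
    weighted_sd: bool = True,
) -> pd.DataFrame:
    """Per-tract probability-weighted mean and SD of each scalar map.

    Voxels whose tract probability is below ``prob_floor`` are excluded
    entirely; the remaining voxels contribute with weight p:
    mean = sum(p x) / sum(p), sd = sqrt(sum(p (x - mean)^2) / sum(p))
    (population form; set ``weighted_sd=False`` for unweighted SD over the
    included voxels). Tracts with no qualifying voxel get NaN values and a
    log entry.

    Returns a tidy frame with columns tract, parameter, feature, value,
    n_voxels.
    """
    rows = []
    for t, name in enumerate(atlas.tract_names):
        p = atlas.probabilities[..., t]
        sel = p >= prob_floor
        n_vox = int(sel.sum())
        if n_vox == 0:
            log.warning("tract %s has no voxels with p >= %g", name, prob_floor)
        w = p[sel]
        for param in maps.parameters:
            x = maps[param][sel]
            if n_vox == 0:
                mean = sd = np.nan
            else:
                mean = float(np.sum(w * x) / np.sum(w))
                if weighted_sd:
                    sd = float(np.sqrt(np.sum(w * (x - mean) ** 2) / np.sum(w)))
                else:
                    sd = float(np.std(x))
            rows.append({"tract": name, "parameter": param, "feature": "mean",
                         "value": mean, "n_voxels": n_vox})
            rows.append({"tract": name, "parameter": param, "feature": "sd",
                         "value": sd, "n_voxels": n_vox})
    return pd.DataFrame(rows)


def merge_lr(table: pd.DataFrame, atlas: TractAtlas) -> pd.DataFrame:
    """Average left/right tract pairs into one merged row per tract.

    Paired tracts are replaced by the arithmetic mean of their values (per
    subject/parameter/feature and any other grouping columns present);
    midline tracts pass through. If one side is missing (NaN), the available
    side is used and a note logged.
    """
    df = table.copy()
    df["merged"] = [
        merge_name(t) if t in atlas.pairs else t for t in df["tract"]
    ]
    group_cols = [c for c in df.columns if c not in ("tract", "value", "n_voxels", "merged")]
    n_missing = int(df["value"].isna().sum())
    if n_missing:
        log.info("merge_lr: %d missing side value(s); using available side", n_missing)
    agg = {"value": "mean"}
    if "n_voxels" in df.columns:
        agg["n_voxels"] = "sum"
    out = (
        df.groupby(["merged"] + group_cols, sort=False, dropna=False)
        .agg(agg)
        .reset_index()
        .rename(columns={"merged": "tract"})
    )
    return out


def tract_volumes(atlas: TractAtlas, prob_floor: float = 0.5) -> pd.DataFrame:
    """Tract volumes in mm^3: voxels with p >= prob_floor times voxel volume
    (the same inclusion rule the statistics use)."""
    vol_vox = atlas.voxel_size**3
    counts = (atlas.probabilities >= prob_floor).reshape(-1, atlas.n_tracts).sum(axis=0)
    return pd.DataFrame({"tract": atlas.tract_names, "volume_mm3": counts * vol_vox})


def tract_volume_cov(
    atlases: list[TractAtlas],
    design: pd.DataFrame,
    threshold: float = 0.25,
    prob_floor: float = 0.5,
) -> pd.DataFrame:
    """Tract-volume coefficient of variation across healthy controls.

    Volumes are computed per subject, left/right pairs averaged into a merged
    tract, and CoV = SD/mean taken over the HC subjects only (the cohort
    expected to vary least). Tracts with CoV > ``threshold`` — or with a
    zero-volume occurrence, which leaves the CoV undefined — are flagged
    excluded.

    ``design`` must align with ``atlases`` row-by-row and carry subject_id and
    group columns.
    """
    hc_idx = [i for i, g in enumerate(design["group"]) if str(g).upper() == "HC"]
    if len(hc_idx) < 3:
        raise ValueError("tract-volume QC needs at least 3 HC subjects")
    per_subj = []
    for i in hc_idx:
        v = tract_volumes(atlases[i], prob_floor)
        v["subject_id"] = design["subject_id"].iloc[i]
        per_subj.append(v)
    vols = pd.concat(per_subj, ignore_index=True)
    atlas = atlases[hc_idx[0]]
    vols["tract"] = [merge_name(t) if t in atlas.pairs else t for t in vols["tract"]]
    merged = vols.groupby(["subject_id", "tract"], sort=False)["volume_mm3"].mean().reset_index()
    rows = []
    for tract, grp in merged.groupby("tract", sort=False):
        v = grp["volume_mm3"].to_numpy(float)
        if np.any(v == 0):
            rows.append({"tract": tract, "mean_volume_mm3": v.mean(), "cov": np.nan,
                         "excluded": True, "reason": "zero-volume occurrence"})
            continue
        cov = float(np.std(v, ddof=1) / np.mean(v))
        rows.append({"tract": tract, "mean_volume_mm3": float(v.mean()), "cov": cov,
                     "excluded": bool(cov > threshold),
                     "reason": "cov>threshold" if cov > threshold else ""})
    return pd.DataFrame(rows)
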