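"""Orchestration of the full factorial experiment:
protocol x pipeline x smoothing sigma -> per-tract effect sizes.

For each protocol the cohort is simulated once (same subjects and noise
realizations for every pipeline, so pipeline deltas are paired); each
pipeline's steps are applied with prefix caching; smoothing is applied after
the segmentation masks are fixed and immediately before model fitting; the
model is DTI for single-shell schemes and DKI for multi-shell ones.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import STUDY_GROUP_SIZES, StudyConfig, TractAtlas, standard_schemes
from .effect_size import group_comparison, step_impact
from .modelfit import fit_wlls, scalar_metrics
from .preprocess import PipelineConfig, apply_pipeline, enumerate_pipelines, smooth_gaussian
from .simulate import ArtifactSpec, PopulationSpec, build_atlas, simulate_cohort
from .tract_stats import merge_lr, tract_volume_cov, tract_weighted_stats

log = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Grid of group comparisons keyed by (protocol, pipeline, sigma)."""

    comparisons: pd.DataFrame
    qc: pd.DataFrame
    manifest: dict
    failures: list = field(default_factory=list)
    subject_features: pd.DataFrame | None = None

    def cell(self, protocol: str, pipeline: str, sigma: float) -> pd.DataFrame:
        c = self.comparisons
        return c[(c["protocol"] == protocol) & (c["pipeline"] == pipeline)
                 & (np.isclose(c["sigma"], sigma))]


def default_affected_tracts(atlas: TractAtlas, fraction: float = 0.25) -> tuple[str, ...]:
    """Pick ~``fraction`` of merged tracts (both sides of a pair) as affected."""
    merged = atlas.merged_names()
    n_pick = max(1, round(fraction * len(merged)))
    picked = merged[:n_pick]
    out = []
    for name in atlas.tract_names:
        base = name
        for suf in ("_left", "_right"):
            if name.endswith(suf):
                base = name[: -len(suf)]
        if base in picked:
            out.append(name)
    return tuple(out)


def _jitter_atlas(atlas: TractAtlas, amount: float, seed: int) -> TractAtlas:
    """Per-subject segmentation variability: raise each tract's probability
    map to a random power exp(N(0, amount)), mimicking under/over-segmentation."""
    if amount <= 0:
        return atlas
    rng = np.random.default_rng(seed)
    gamma = np.exp(rng.normal(0.0, amount, atlas.n_tracts))
    probs = atlas.probabilities ** gamma[None, None, None, :]
    return TractAtlas(
        probabilities=probs, tract_names=list(atlas.tract_names),
        laterality=dict(atlas.laterality), pairs=dict(atlas.pairs),
        orientations=atlas.orientations, voxel_size=atlas.voxel_size,
    )


def run_study(config: StudyConfig, *, keep_subject_features: bool = False) -> StudyResult:
    """Execute the full grid. Any cell failure is isolated and recorded;
    the rest of the grid completes. Deterministic given ``config.seed``."""
    t_start = time.time()
    schemes = standard_schemes()
    pipelines = (
        [PipelineConfig(steps=p) for p in config.pipelines]
        if config.pipelines is not None
        else enumerate_pipelines()
    )
    sim = dict(config.simulation)
    pop_kwargs = dict(sim.get("population", {}))
    art_kwargs = dict(sim.get("artifacts", {}))
    atlas_jitter = float(sim.get("atlas_jitter", 0.0))
    all_rows, qc_frames, failures = [], [], []
    subj_rows = []
    for p_idx, protocol in enumerate(config.protocols):
        if protocol not in schemes:
            failures.append({"protocol": protocol, "stage": "scheme", "reason": "unknown protocol"})
            continue
        scheme = schemes[protocol]
        n_hc, n_sle = config.group_sizes or STUDY_GROUP_SIZES[protocol]
        proto_seed = int(np.random.SeedSequence([config.seed, p_idx]).generate_state(1)[0] % 2**31)
        atlas = build_atlas(config.grid_shape, config.n_tracts, seed=proto_seed)
        pop = PopulationSpec(n_hc=n_hc, n_sle=n_sle, **pop_kwargs)
        if not pop.affected_tracts:
            pop.affected_tracts = default_affected_tracts(atlas)
        artifacts = ArtifactSpec(**art_kwargs)
        datasets, design, _ = simulate_cohort(scheme, atlas, pop, artifacts, seed=proto_seed)
        subject_atlases = [
            _jitter_atlas(atlas, atlas_jitter, proto_seed + 7919 * (i + 1))
            for i in range(len(datasets))
        ]
        try:
            qc = tract_volume_cov(subject_atlases, design,
                                  threshold=config.thresholds["cov_max"],
                                  prob_floor=config.thresholds["mask_prob"])
            qc.insert(0, "protocol", protocol)
            qc_frames.append(qc)
            excluded = set(qc.loc[qc["excluded"], "tract"])
        except Exception as exc:  # pragma: no cover - defensive
            failures.append({"protocol": protocol, "stage": "qc", "reason": str(exc)})
            excluded = set()
        model = "dki" if scheme.dki_capable else "dti"
        caches = [dict() for _ in datasets]
        for pipe in pipelines:
            features_by_sigma: dict[float, list] = {s: [] for s in config.smoothing_sigmas}
            for i, ds in enumerate(datasets):
                try:
                    corrected = apply_pipeline(ds, pipe, cache=caches[i],
                                               eddy_kwargs=dict(config.registration))
                except Exception as exc:
                    for s in config.smoothing_sigmas:
                        failures.append({"protocol": protocol, "pipeline": pipe.name,
                                         "sigma": s, "subject": ds.subject_id,
                                         "stage": "preprocess", "reason": str(exc)})
                    continue
                for sigma in config.smoothing_sigmas:
                    try:
                        sm = smooth_gaussian(corrected, sigma)
                        fit = fit_wlls(sm, model=model)
                        maps = scalar_metrics(fit)
                        stats = tract_weighted_stats(
                            maps, subject_atlases[i], config.thresholds["mask_prob"]
                        )
                        stats = merge_lr(stats, subject_atlases[i])
                        stats.insert(0, "subject_id", ds.subject_id)
                        features_by_sigma[sigma].append(stats)
                    except Exception as exc:
                        failures.append({"protocol": protocol, "pipeline": pipe.name,
                                         "sigma": sigma, "subject": ds.subject_id,
                                         "stage": "fit", "reason": str(exc)})
            for sigma, frames in features_by_sigma.items():
                if not frames:
                    failures.append({"protocol": protocol, "pipeline": pipe.name,
                                     "sigma": sigma, "stage": "compare",
                                     "reason": "no subject features"})
                    continue
                table = pd.concat(frames, ignore_index=True)
                if keep_subject_features:
                    st = table.copy()
                    st.insert(0, "sigma", sigma)
                    st.insert(0, "pipeline", pipe.name)
                    st.insert(0, "protocol", protocol)
                    subj_rows.append(st)
                cmp_df = group_comparison(
                    table, design,
                    alpha=config.thresholds["alpha"],
                    n_tests=int(config.thresholds["n_tracts_for_bonferroni"]),
                    excluded_tracts=excluded,
                )
                cmp_df.insert(0, "sigma", sigma)
                cmp_df.insert(0, "pipeline", pipe.name)
                cmp_df.insert(0, "protocol", protocol)
                cmp_df["threshold_unc"] = cmp_df.attrs["threshold_unc"]
                cmp_df["threshold_bonf"] = cmp_df.attrs["threshold_bonf"]
                all_rows.append(cmp_df)
    comparisons = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    qc = pd.concat(qc_frames, ignore_index=True) if qc_frames else pd.DataFrame()
    manifest = {
        "seed": int(config.seed),
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "elapsed_s": round(time.time() - t_start, 2),
        "n_cells": int(len(config.protocols) * len(pipelines) * len(config.smoothing_sigmas)),
        "n_failures": len(failures),
    }
    return StudyResult(
        comparisons=comparisons, qc=qc, manifest=manifest, failures=failures,
        subject_features=pd.concat(subj_rows, ignore_index=True) if subj_rows else None,
    )


def step_impact_table(result: StudyResult, protocol: str, sigma: float = 0.0) -> pd.DataFrame:
    """Assemble the 8 pipelines of one protocol/sigma into a per-step impact
    table (requires the full pipeline enumeration in the result)."""
    by_steps = {}
    c = result.comparisons
    sel = c[(c["protocol"] == protocol) & np.isclose(c["sigma"], sigma)]
    for name, grp in sel.groupby("pipeline", sort=False):
        steps = () if name == "none" else tuple(name.split("+"))
        by_steps[steps] = grp
    return step_impact(by_steps)


SWEEP_PATTERNS = ("decline", "little influence", "rise-then-decline", "rise")


def smoothing_sweep_report(result: StudyResult, *, tol: float = 0.01) -> pd.DataFrame:
    """Classify each d-vs-sigma curve (tract-averaged, per protocol/pipeline/
    parameter/feature) into the four canonical smoothing patterns:
    monotone decline, little influence (range < tol), rise to an interior
    peak then decline (peak sigma reported), or overall rise."""
    c = result.comparisons
    sigmas = sorted(c["sigma"].unique())
    if len(sigmas) < 3:
        raise ValueError("smoothing sweep needs at least 3 sigma levels")
    rows = []
    grouped = (
        c[~c["excluded"]]
        .groupby(["protocol", "pipeline", "parameter", "feature", "sigma"], sort=False)["d"]
        .mean()
        .reset_index()
    )
    for (proto, pipe, param, feature), grp in grouped.groupby(
        ["protocol", "pipeline", "parameter", "feature"], sort=False
    ):
        grp = grp.sort_values("sigma")
        d = grp["d"].to_numpy(float)
        s = grp["sigma"].to_numpy(float)
        rng_d = d.max() - d.min()
        peak = int(np.argmax(d))
        if rng_d < tol:
            pattern, peak_sigma = "little influence", np.nan
        elif 0 < peak < len(d) - 1 and d[peak] - d[0] >= tol and d[peak] - d[-1] >= tol:
            pattern, peak_sigma = "rise-then-decline", float(s[peak])
        elif d[-1] - d[0] >= tol:
            pattern, peak_sigma = "rise", np.nan
        else:
            pattern, peak_sigma = "decline", np.nan
        rows.append({
            "protocol": proto, "pipeline": pipe, "parameter": param, "feature": feature,
            "pattern": pattern, "peak_sigma": peak_sigma,
            "d_at_0": float(d[0]), "d_at_max_sigma": float(d[-1]), "range": float(rng_d),
        })
    return pd.DataFrame(rows)
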