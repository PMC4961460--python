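"""Config-driven orchestration of the full analysis chain.

simulate -> prep -> tuning -> spaces -> compare -> featcorr, on one or more
seeded synthetic sessions ("10 sessions per animal" by default), writing CSV
tables, Newick trees and JSON summaries plus a run manifest with config hash
and file checksums.  Cross-session aggregation follows each stage's rule:
tuned-fraction curves and feature-correlation curves are averaged with
s.e.m., Mahalanobis matrices are averaged before clustering, Procrustes
similarities are reported per session.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as compare_mod
from . import featcorr as featcorr_mod
from . import io as session_io
from . import prep, spaces, tuning
from .config import AnalysisConfig, PipelineConfig, config_hash, config_to_dict
from .synth import SessionData, generate_session

logger = logging.getLogger("graspspace")

AREAS = ("AIP", "F5", "M1")
AREA_PAIRS = (("AIP", "F5"), ("AIP", "M1"), ("F5", "M1"))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_curve(path: Path, curve: tuning.TunedFractionCurve) -> None:
    frame = pd.DataFrame(
        {
            "time": curve.time,
            "segment": ["cue"] * curve.boundary
            + ["go"] * (len(curve.time) - curve.boundary),
            "fraction": curve.fraction,
        }
    )
    if curve.sem is not None:
        frame["sem"] = curve.sem
    frame.to_csv(path, index=False)


def reduce_to_common_dim(
    jspace_values: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce J-space and canonical N-space scores to their highest common
    dimension (27 when the population supports it; fewer conditions or units
    cap the canonical space, in which case the J-space is PCA-reduced)."""
    common = min(jspace_values.shape[1], scores.shape[1])
    if jspace_values.shape[1] > common:
        jspace_values = spaces.pca(jspace_values, n_components=common).scores
    return jspace_values, scores[:, :common]


def simulate_sessions(config: PipelineConfig, seed: int) -> list[SessionData]:
    return [
        generate_session(config.generator, seed + i) for i in range(config.n_sessions)
    ]


def run_pipeline(config: PipelineConfig, outdir: str | Path, seed: int) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = config.analysis
    manifest: dict = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config_to_dict(config),
        "n_sessions": config.n_sessions,
        "stages": [],
        "files": {},
    }

    def finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        logger.info("stage complete: %s", name)

    def fail(name: str, err: Exception) -> None:
        manifest["failed_stage"] = name
        manifest["error"] = f"{type(err).__name__}: {err}"
        _write_manifest(outdir, manifest)

    try:
        sessions = simulate_sessions(config, seed)
        for i, session in enumerate(sessions):
            session_io.write_session(session, outdir / "sessions" / f"session_{i:02d}")
        finish_stage("simulate")

        # ---- prep: N-space / J-space tables per session -------------------
        nspaces: dict[str, list[dict[str, prep.NSpaceMatrix]]] = {}
        jspaces: list[prep.JSpaceMatrix] = []
        for i, session in enumerate(sessions):
            sdir = outdir / "sessions" / f"session_{i:02d}"
            jspace = prep.build_jspace(session, analysis.lowpass_cutoff_hz)
            jspaces.append(jspace)
            pd.DataFrame(
                jspace.values,
                index=pd.Index(jspace.trial_ids, name="trial_id"),
            ).to_csv(sdir / "jspace.csv")
            per_epoch = {}
            for epoch in ("cue", "hold"):
                nspace = prep.epoch_means(
                    session, epoch, analysis.baseline_epoch
                )
                per_epoch[epoch] = nspace
                pd.DataFrame(
                    nspace.values,
                    index=pd.Index(nspace.trial_ids, name="trial_id"),
                    columns=nspace.unit_ids,
                ).to_csv(sdir / f"nspace_{epoch}.csv")
            nspaces.setdefault("by_session", []).append(per_epoch)
        finish_stage("prep")

        # ---- tuning -------------------------------------------------------
        latencies: dict[str, float] = {}
        for area in AREAS:
            curves = []
            for session in sessions:
                tensor = prep.build_rate_tensor(
                    session,
                    bin_width=analysis.sliding_bin_s,
                    sigma=analysis.sliding_sigma_s,
                    window_cue=analysis.window_cue,
                    window_go=analysis.window_go,
                    unit_index=session.unit_index(area),
                )
                curves.append(tuning.sliding_anova(tensor, analysis.alpha))
            mean_curve = tuning.average_curves(curves)
            _write_curve(outdir / f"tuned_fraction_{area}.csv", mean_curve)
            latencies[area] = tuning.response_latency(mean_curve)
        (outdir / "latencies.json").write_text(
            json.dumps({k: v for k, v in latencies.items()}, indent=2) + "\n"
        )

        md_session = sessions[0]
        md_nspace = prep.epoch_means(md_session, analysis.md_epoch, analysis.baseline_epoch)
        for area in AREAS:
            unit = int(md_session.unit_index(area)[0])
            md = tuning.modulation_depth(md_nspace, unit)
            md.matrix.to_csv(outdir / f"mdmap_{unit}.csv")
        finish_stage("tuning")

        # ---- spaces -------------------------------------------------------
        dist_sums: dict[tuple[str, str], np.ndarray] = {}
        dist_index = None
        for i, session in enumerate(sessions):
            for epoch in ("cue", "hold"):
                nspace = nspaces["by_session"][i][epoch]
                for area in AREAS:
                    cols = np.searchsorted(
                        nspace.unit_ids, session.unit_index(area)
                    )
                    sub = nspace.values[:, cols]
                    dist = spaces.mahalanobis_condition_distances(
                        sub, nspace.condition_ids, analysis.shrinkage, epoch=epoch
                    )
                    key = (area, epoch)
                    dist_index = dist.matrix.index
                    dist_sums[key] = dist_sums.get(key, 0.0) + dist.matrix.to_numpy()
                    if i == 0:
                        transform = spaces.cda(
                            sub, nspace.condition_ids, analysis.shrinkage
                        )
                        scores = transform.transform(sub)
                        frame = pd.DataFrame(
                            scores,
                            index=pd.Index(nspace.trial_ids, name="trial_id"),
                        )
                        frame.insert(0, "condition_id", nspace.condition_ids)
                        frame.to_csv(outdir / f"canonical_scores_{area}_{epoch}.csv")
        for (area, epoch), total in dist_sums.items():
            avg = pd.DataFrame(
                total / len(sessions), index=dist_index, columns=dist_index
            )
            avg.to_csv(outdir / f"cond_dist_{area}_{epoch}.csv")
        finish_stage("spaces")

        # ---- compare ------------------------------------------------------
        catalog = sessions[0].conditions
        for (area, epoch), total in dist_sums.items():
            avg = pd.DataFrame(
                total / len(sessions), index=dist_index, columns=dist_index
            )
            dendro = compare_mod.hca(avg)
            (outdir / f"dendrogram_{area}_{epoch}.nwk").write_text(
                compare_mod.to_newick(dendro) + "\n"
            )
            pd.DataFrame(
                dendro.merges, columns=["cluster_a", "cluster_b", "height", "size"]
            ).to_csv(outdir / f"dendrogram_{area}_{epoch}.csv", index=False)

        epoch = analysis.procrustes_epoch
        procrustes_summary: dict[str, dict] = {}
        for area in AREAS:
            values = []
            for i, session in enumerate(sessions):
                nspace = prep.epoch_means(session, epoch, analysis.baseline_epoch,
                                          unit_index=session.unit_index(area))
                transform = spaces.cda(
                    nspace.values,
                    nspace.condition_ids,
                    analysis.shrinkage,
                    n_components=analysis.n_components,
                )
                scores = transform.transform(nspace.values)
                reference, target = reduce_to_common_dim(jspaces[i].values, scores)
                result = compare_mod.procrustes_similarity(
                    reference,
                    target,
                    analysis.procrustes_scaling,
                    analysis.procrustes_reflection,
                    reference_id="jspace",
                    target_id=f"{area}_{epoch}",
                )
                values.append(result.dissimilarity)
            procrustes_summary[area] = {
                "per_session": values,
                "median": float(np.median(values)),
            }
            (outdir / f"procrustes_{area}_{epoch}.json").write_text(
                json.dumps(procrustes_summary[area], indent=2) + "\n"
            )
        finish_stage("compare")

        # ---- featcorr -----------------------------------------------------
        r_curves: dict[tuple[str, str], list[np.ndarray]] = {}
        time_axis = None
        boundary = None
        for session in sessions:
            series = {}
            for area in AREAS:
                tensor = prep.build_rate_tensor(
                    session,
                    bin_width=analysis.featcorr_bin_s,
                    sigma=analysis.featcorr_sigma_s,
                    window_cue=analysis.window_cue,
                    window_go=analysis.window_go,
                    unit_index=session.unit_index(area),
                )
                series[area] = featcorr_mod.trial_distance_series(tensor, area)
            for a, b in AREA_PAIRS:
                tc = featcorr_mod.correlate_areas(series[a], series[b])
                r_curves.setdefault((a, b), []).append(tc.r)
                time_axis, boundary = tc.time, tc.boundary
        for (a, b), rs in r_curves.items():
            stack = np.array(rs)
            frame = pd.DataFrame(
                {
                    "time": time_axis,
                    "segment": ["cue"] * boundary
                    + ["go"] * (len(time_axis) - boundary),
                    "r": np.nanmean(stack, axis=0),
                }
            )
            if len(rs) > 1:
                frame["sem"] = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(len(rs))
            frame.to_csv(outdir / f"featcorr_{a}-{b}.csv", index=False)
        finish_stage("featcorr")
    except Exception as err:   # noqa: BLE001 - manifest must record the failure
        stage_names = ("simulate", "prep", "tuning", "spaces", "compare", "featcorr")
        done = set(manifest["stages"])
        current = next((s for s in stage_names if s not in done), "unknown")
        fail(current, err)
        raise

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(outdir))] = _checksum(path)
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
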