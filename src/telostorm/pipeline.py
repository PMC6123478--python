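"""End-to-end orchestration: simulate → drift-correct → cluster → filter →
Rg → group statistics → report.

An experiment is declared in a structured config (YAML or a plain dict):
per-group ground-truth structure parameters, acquisition statistics, the
cluster filter policy, and analysis options.  A single global seed is
expanded into independent per-nucleus substreams
(``numpy.random.SeedSequence.spawn``), so the same config + seed reproduces
the run bit-for-bit and stages can be re-run independently.

The run report embeds the resolved config, its hash and per-stage record
counts (localizations → clusters found → clusters surviving each filter,
which are non-increasing by construction).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from telostorm.drift import correct_drift
from telostorm.localizations import LocalizationTable
from telostorm.shape import (
    ClusterFilterPolicy,
    GroupShapeTable,
    TelomereCluster,
    cluster_localizations,
    filter_clusters,
    fraction_irregular,
    radius_of_gyration,
    rg_count_correlation,
    summarize_shape_distribution,
)
from telostorm.simulate import (
    AcquisitionParams,
    StructureModel,
    radius_for_target_rg,
    simulate_localizations,
)
from telostorm.stats import GroupSamples, anova_tukey, comparisons_frame

log = logging.getLogger("telostorm.pipeline")


class ConfigError(ValueError):
    """Raised with the full list of config violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid experiment config:\n- " + "\n- ".join(violations))


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage name."""


_ACQ_DEFAULTS = {
    "sigma_xy": 30.0,
    "sigma_z": 70.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))),
    "n_frames": 35_000,
    "z_depth": 700.0,
    "blink_mean": 3.0,
    "background_density": 0.0,
}
_FILTER_DEFAULTS = {"min_points": 200, "focal_window": 250.0}
_CLUSTER_DEFAULTS = {"linkage_radius": 75.0, "min_cluster_seed": 10}
_ANALYSIS_DEFAULTS = {"dims": 3, "reference_group": None}
_DRIFT_DEFAULTS = {
    "correct": False,
    "frames_per_bin": 500,
    "pixel_size": 30.0,
    "inject_linear_nm": None,  # [dx, dy, dz] total drift over the acquisition
}
_STRUCTURE_DEFAULTS = {
    "shape": "sphere",
    "target_rg_nm": None,
    "radius_mean_nm": None,
    "size_cv": 0.25,
    "n_emitters": 200,
    "axes_ratio": [1.0, 1.0, 1.0],
}
_GROUP_DEFAULTS = {"n_nuclei": 3, "telomeres_per_nucleus": 15}
_FOV_NM = 8000.0
_MIN_SEPARATION_NM = 600.0


@dataclass
class ExperimentConfig:
    """Validated, fully-resolved experiment description."""

    seed: int
    groups: list[dict]
    acquisition: dict
    filter: dict
    clustering: dict
    analysis: dict
    drift: dict
    output_dir: str | None = None
    write_molecule_lists: bool = False

    def resolved(self) -> dict:
        return {
            "seed": self.seed,
            "groups": self.groups,
            "acquisition": self.acquisition,
            "filter": self.filter,
            "clustering": self.clustering,
            "analysis": self.analysis,
            "drift": self.drift,
            "output_dir": self.output_dir,
            "write_molecule_lists": self.write_molecule_lists,
        }

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def acquisition_params(self) -> AcquisitionParams:
        return AcquisitionParams(**self.acquisition)

    def filter_policy(self) -> ClusterFilterPolicy:
        return ClusterFilterPolicy(**self.filter)


def _merge_known(section: dict, defaults: dict, name: str, violations: list[str]) -> dict:
    out = dict(defaults)
    for key, val in (section or {}).items():
        if key not in defaults:
            violations.append(f"{name}: unknown key {key!r}")
        else:
            out[key] = val
    return out


def validate_config(raw: "str | dict | Path") -> ExperimentConfig:
    """Parse and validate a config, raising :class:`ConfigError` listing every
    violation; defaults are filled for omitted keys."""
    if isinstance(raw, Path) or (isinstance(raw, str) and "\n" not in raw and raw.endswith((".yml", ".yaml"))):
        raw = Path(raw).read_text()
    if isinstance(raw, str):
        raw = yaml.safe_load(raw)
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    v: list[str] = []
    known_top = {
        "seed", "groups", "acquisition", "filter", "clustering", "analysis",
        "drift", "output_dir", "write_molecule_lists",
    }
    for key in raw:
        if key not in known_top:
            v.append(f"unknown top-level key {key!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        v.append("seed must be a non-negative integer")

    acq = _merge_known(raw.get("acquisition"), _ACQ_DEFAULTS, "acquisition", v)
    for key in ("sigma_xy", "sigma_z", "background_density"):
        if acq[key] < 0:
            v.append(f"acquisition.{key} must be >= 0")
    if acq["n_frames"] < 1:
        v.append("acquisition.n_frames must be >= 1")
    if acq["blink_mean"] < 1:
        v.append("acquisition.blink_mean must be >= 1")

    filt = _merge_known(raw.get("filter"), _FILTER_DEFAULTS, "filter", v)
    if filt["min_points"] < 0:
        v.append("filter.min_points must be >= 0")
    if filt["focal_window"] <= 0:
        v.append("filter.focal_window must be > 0")

    clus = _merge_known(raw.get("clustering"), _CLUSTER_DEFAULTS, "clustering", v)
    if clus["linkage_radius"] <= 0:
        v.append("clustering.linkage_radius must be > 0")

    ana = _merge_known(raw.get("analysis"), _ANALYSIS_DEFAULTS, "analysis", v)
    if ana["dims"] not in (2, 3):
        v.append("analysis.dims must be 2 or 3")

    drift = _merge_known(raw.get("drift"), _DRIFT_DEFAULTS, "drift", v)
    if drift["frames_per_bin"] < 1:
        v.append("drift.frames_per_bin must be >= 1")

    groups_raw = raw.get("groups")
    groups: list[dict] = []
    if not groups_raw:
        v.append("groups: at least one group is required")
    else:
        labels = [g.get("label") for g in groups_raw]
        if len(set(labels)) != len(labels):
            v.append("groups: duplicate group labels")
        for g in groups_raw:
            label = g.get("label")
            if not label:
                v.append("groups: every group needs a label")
                continue
            merged = dict(_GROUP_DEFAULTS)
            for key, val in g.items():
                if key in ("label", "structure"):
                    continue
                if key not in _GROUP_DEFAULTS:
                    v.append(f"group {label}: unknown key {key!r}")
                else:
                    merged[key] = val
            if merged["n_nuclei"] < 1 or merged["telomeres_per_nucleus"] < 1:
                v.append(f"group {label}: n_nuclei and telomeres_per_nucleus must be >= 1")
            struct = _merge_known(g.get("structure"), _STRUCTURE_DEFAULTS, f"group {label}.structure", v)
            if struct["target_rg_nm"] is None and struct["radius_mean_nm"] is None:
                v.append(f"group {label}: structure needs target_rg_nm or radius_mean_nm")
            if struct["target_rg_nm"] is not None and struct["target_rg_nm"] <= 0:
                v.append(f"group {label}: target_rg_nm must be > 0")
            if struct["radius_mean_nm"] is not None and struct["radius_mean_nm"] <= 0:
                v.append(f"group {label}: radius_mean_nm must be > 0")
            if struct["size_cv"] < 0:
                v.append(f"group {label}: size_cv must be >= 0")
            if struct["n_emitters"] < 1:
                v.append(f"group {label}: n_emitters must be >= 1")
            if len(struct["axes_ratio"]) != 3 or any(a <= 0 for a in struct["axes_ratio"]):
                v.append(f"group {label}: axes_ratio must be three positive numbers")
            groups.append({"label": label, **merged, "structure": struct})

    reference = ana.get("reference_group")
    if reference is None and groups:
        ana["reference_group"] = groups[0]["label"]
    elif groups and reference not in {g["label"] for g in groups}:
        v.append(f"analysis.reference_group {reference!r} is not a group label")

    if v:
        raise ConfigError(v)
    return ExperimentConfig(
        seed=seed,
        groups=groups,
        acquisition=acq,
        filter=filt,
        clustering=clus,
        analysis=ana,
        drift=drift,
        output_dir=raw.get("output_dir"),
        write_molecule_lists=bool(raw.get("write_molecule_lists", False)),
    )


def _structure_scale(struct: dict, acq: AcquisitionParams) -> float:
    """Mean size scale so the observed RMS Rg matches the group target."""
    ratios = np.asarray(struct["axes_ratio"], float)
    if struct["radius_mean_nm"] is not None:
        return float(struct["radius_mean_nm"])
    target = float(struct["target_rg_nm"])
    # E[Rg_obs²] = scale²·Σratio²/5·(1+cv²) + 2σ_xy² + σ_z²  for uniform ellipsoids
    base = radius_for_target_rg(target, acq, size_cv=struct["size_cv"])  # sphere solution
    return base * float(np.sqrt(3.0 / np.sum(ratios**2)))


def _build_nucleus_structures(
    group: dict, acq: AcquisitionParams, rng: np.random.Generator
) -> list[StructureModel]:
    struct = group["structure"]
    scale = _structure_scale(struct, acq)
    ratios = np.asarray(struct["axes_ratio"], float)
    n = group["telomeres_per_nucleus"]
    half_z = acq.z_depth / 2.0
    z_span = min(250.0, 0.8 * half_z)
    centers: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(10_000):
            cand = np.array(
                [
                    rng.uniform(0.0, _FOV_NM),
                    rng.uniform(0.0, _FOV_NM),
                    rng.uniform(-z_span, z_span),
                ]
            )
            if all(np.linalg.norm(cand[:2] - c[:2]) >= _MIN_SEPARATION_NM for c in centers):
                centers.append(cand)
                break
        else:
            raise PipelineError("[simulate] could not place telomeres with minimum separation")
    if struct["size_cv"] > 0:
        s2 = np.log(1.0 + struct["size_cv"] ** 2)
        sizes = scale * rng.lognormal(-s2 / 2.0, np.sqrt(s2), size=n)
    else:
        sizes = np.full(n, scale)
    models = []
    for i, (c, s) in enumerate(zip(centers, sizes)):
        orientation = None
        if struct["shape"] != "sphere":
            orientation = Rotation.random(random_state=rng).as_matrix()
        models.append(
            StructureModel(
                structure_id=i,
                center=c,
                shape=struct["shape"],
                axes=s * ratios,
                orientation=orientation,
                n_emitters=struct["n_emitters"],
            )
        )
    return models


def _linear_drift_fn(total_nm: np.ndarray, n_frames: int):
    total_nm = np.asarray(total_nm, float)

    def drift(frames: np.ndarray) -> np.ndarray:
        frac = np.asarray(frames, float)[:, None] / max(n_frames - 1, 1)
        return frac * total_nm[None, :]

    return drift


@dataclass
class RunReport:
    """Provenance and per-stage record counts of one experiment run."""

    seed: int
    config_hash: int | str
    config: dict
    stage_counts: dict
    group_summary: list[dict]
    nucleus_summary: list[dict]
    fractions_irregular: dict
    cutoff_nm: float
    rg_count_correlation: dict
    comparisons: list[dict]
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, default=str)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def run_shape_experiment(config: ExperimentConfig) -> tuple[RunReport, GroupShapeTable]:
    """Execute the full shape workflow for every group in the config.

    Per nucleus: simulate localizations from ground-truth structures, apply
    (and optionally inject) drift, cluster with DBSCAN, filter by the policy,
    and record one Rg per surviving cluster.  Group-level outputs: shape
    table, distribution summaries, irregular fractions against the reference
    group's mean, Rg–N correlations, and Tukey HSD comparisons of group mean
    Rg.  Deterministic given config + seed.
    """
    from telostorm import __version__

    acq = config.acquisition_params()
    policy = config.filter_policy()
    dims = config.analysis["dims"]
    root = np.random.SeedSequence(config.seed)
    group_streams = root.spawn(len(config.groups))

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    inject = config.drift["inject_linear_nm"]
    drift_fn = _linear_drift_fn(inject, acq.n_frames) if inject else None

    clusters_by_group: dict[str, list[TelomereCluster]] = {}
    stage_counts: dict[str, dict] = {}
    for group, g_stream in zip(config.groups, group_streams):
        label = group["label"]
        counts = {"localizations": 0, "clusters_found": 0,
                  "after_min_points": 0, "after_focal_filter": 0}
        kept: list[TelomereCluster] = []
        nuc_streams = g_stream.spawn(group["n_nuclei"])
        for nuc_idx, n_stream in enumerate(nuc_streams):
            rng = np.random.default_rng(n_stream)
            try:
                structures = _build_nucleus_structures(group, acq, rng)
                acq_n = AcquisitionParams(
                    **{**config.acquisition, "drift": drift_fn}
                )
                sim = simulate_localizations(structures, acq_n, rng=rng)
                table = sim.table
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[simulate] group {label} nucleus {nuc_idx}: {exc}") from exc
            counts["localizations"] += len(table)
            if config.drift["correct"]:
                try:
                    table, trace = correct_drift(
                        table,
                        frames_per_bin=config.drift["frames_per_bin"],
                        pixel_size=config.drift["pixel_size"],
                    )
                except Exception as exc:
                    raise PipelineError(
                        f"[drift] group {label} nucleus {nuc_idx}: {exc}"
                    ) from exc
                if out_dir:
                    trace.to_csv(out_dir / f"drift_{label}_n{nuc_idx}.csv")
            if out_dir and config.write_molecule_lists:
                table.to_csv(out_dir / f"molecules_{label}_n{nuc_idx}.csv")
            try:
                clusters = cluster_localizations(
                    table,
                    linkage_radius=config.clustering["linkage_radius"],
                    min_cluster_seed=config.clustering["min_cluster_seed"],
                    nucleus_id=nuc_idx,
                )
            except Exception as exc:
                raise PipelineError(f"[cluster] group {label} nucleus {nuc_idx}: {exc}") from exc
            counts["clusters_found"] += len(clusters)
            by_points = [c for c in clusters if c.n > policy.min_points]
            counts["after_min_points"] += len(by_points)
            surviving = filter_clusters(clusters, policy)
            counts["after_focal_filter"] += len(surviving)
            kept.extend(surviving)
            log.info(
                "group %s nucleus %d: %d locs, %d clusters, %d kept",
                label, nuc_idx, len(table), len(clusters), len(surviving),
            )
        # re-number telomeres uniquely within the group
        for tid, c in enumerate(kept):
            c.telomere_id = tid
        clusters_by_group[label] = kept
        stage_counts[label] = counts

    try:
        shape_table = GroupShapeTable.from_clusters(clusters_by_group, dims=dims)
        fractions, cutoff = fraction_irregular(shape_table, config.analysis["reference_group"])
        group_summary, nucleus_summary = summarize_shape_distribution(shape_table)
        correlations = rg_count_correlation(shape_table)
    except Exception as exc:
        raise PipelineError(f"[shape-stats] {exc}") from exc

    comparisons: list[dict] = []
    eligible = {g: v for g, v in shape_table.rg_by_group().items() if len(v) >= 2}
    if len(eligible) >= 2:
        try:
            tukey = anova_tukey(GroupSamples(eligible, unit="telomere Rg (nm)"))
            comparisons = comparisons_frame([tukey]).to_dict(orient="records")
        except Exception as exc:
            raise PipelineError(f"[compare] {exc}") from exc

    report = RunReport(
        seed=config.seed,
        config_hash=config.config_hash,
        config=config.resolved(),
        stage_counts=stage_counts,
        group_summary=group_summary.to_dict(orient="records"),
        nucleus_summary=nucleus_summary.to_dict(orient="records"),
        fractions_irregular=fractions,
        cutoff_nm=cutoff,
        rg_count_correlation=correlations,
        comparisons=comparisons,
        version=__version__,
    )
    if out_dir:
        shape_table.to_csv(out_dir / "shape_table.csv")
        group_summary.to_csv(out_dir / "group_summary.csv", index=False)
        nucleus_summary.to_csv(out_dir / "nucleus_summary.csv", index=False)
        if comparisons:
            pd.DataFrame(comparisons).to_csv(out_dir / "comparisons.csv", index=False)
        report.save(out_dir / "report.json")
    return report, shape_table
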