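"""End-to-end orchestration: manifest of z-stacks → ratios → group stats.

The per-stack chain is the eight-step quantification: read → greyscale →
intensity profile → threshold → binarise → point cloud → (subsample) →
DBSCAN → main cluster → alpha-shape volumes → cell/body ratio.  Per-stack
failures are isolated and logged so one bad acquisition never aborts a
run.  ``simulate_experiment`` writes a phantom experiment (control /
induced / optional induced+inhibitor) consumable by ``run_pipeline``,
standing in for a doxycycline-induction + trastuzumab-rescue study.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import geometry, pointcloud, segmentation, stackio
from .phantom import PhantomSpec, generate_phantom, write_phantom
from .stats import ComparisonResult, compare_groups

__all__ = ["RunReport", "analyze_stack", "run_pipeline", "simulate_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class StackFailure:
    spheroid_id: str
    stack_path: str
    reason: str


@dataclass
class RunReport:
    """Everything one pipeline run produced, reproducible from config + seed."""

    results: pd.DataFrame  # per-spheroid rows: spheroid_id, group, volumes, ratio
    comparison: Optional[ComparisonResult]
    failures: List[StackFailure]
    config: stackio.RunConfig
    version: str = _version
    qc_flags: Dict[str, List[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config": self.config.model_dump(),
            "n_spheroids": int(len(self.results)),
            "results": self.results.to_dict(orient="records"),
            "failures": [vars(f) for f in self.failures],
            "qc_flags": self.qc_flags,
        }
        if self.comparison is not None:
            payload["comparison"] = {
                "f_statistic": self.comparison.f_statistic,
                "anova_p": self.comparison.anova_p,
                "group_means": self.comparison.group_means,
                "group_sds": self.comparison.group_sds,
                "pairwise": self.comparison.pairwise.to_dict(orient="records"),
            }
        return json.dumps(payload, indent=2, default=float)


def analyze_stack(stack: stackio.ImageStack, config: stackio.RunConfig,
                  spheroid_id: str = "", threshold: Optional[float] = None
                  ) -> geometry.VolumeResult:
    """Run the quantification chain on one stack already in memory.

    ``threshold`` overrides the per-stack threshold (used by the pooled-
    histogram mode, where one global threshold serves every stack).
    """
    grey = segmentation.to_greyscale(stack)
    if threshold is None:
        profile = segmentation.build_profile(grey)
        threshold = segmentation.compute_threshold(profile, method=config.threshold_method)
    mask = segmentation.binarize(grey, threshold)
    cloud = pointcloud.mask_to_points(mask, grey.pitch)
    cloud = pointcloud.subsample(cloud, config.max_points, seed=config.seed)
    eps = config.eps_um or pointcloud.default_eps_um(grey.pitch, config.eps_factor)
    labeling = pointcloud.cluster_points(cloud, eps_um=eps, min_points=config.min_points)
    main = pointcloud.extract_main_cluster(cloud, labeling)
    params = geometry.AlphaParameters.from_pitch(
        grey.pitch, cell_factor=config.cell_factor, body_factor=config.body_factor)
    return geometry.compute_volumes(main, params, spheroid_id=spheroid_id)


def run_pipeline(config: stackio.RunConfig) -> RunReport:
    """Analyse every stack in the manifest, then compare groups.

    Writes results.csv, pairwise_stats.csv, report.json and a log file
    under ``config.out_dir``.  A stack that fails at any stage is logged
    and flagged; an empty result set raises.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("lumenfill")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        manifest = stackio.read_manifest(config.manifest)
        rows, failures = [], []
        qc: Dict[str, List[str]] = {}

        pooled_threshold = None
        if config.pooled_histogram:
            stacks = []
            for _, row in manifest.iterrows():
                try:
                    stacks.append(segmentation.to_greyscale(
                        stackio.read_stack(row.stack_path, config.pitch_override)))
                except Exception:  # unreadable stacks are reported per-row below
                    pass
            if stacks:
                pooled_threshold = segmentation.compute_threshold(
                    segmentation.pooled_profile(stacks), method=config.threshold_method)
                logger.info("pooled threshold: %.3f over %d stacks",
                            pooled_threshold, len(stacks))

        for _, row in manifest.iterrows():
            sid = str(row.spheroid_id)
            try:
                stack = stackio.read_stack(row.stack_path, config.pitch_override)
                res = analyze_stack(stack, config, spheroid_id=sid,
                                    threshold=pooled_threshold)
                rows.append({
                    "spheroid_id": sid, "group": row.group,
                    "stack_path": row.stack_path,
                    "cell_volume_um3": res.cell_volume_um3,
                    "body_volume_um3": res.body_volume_um3,
                    "ratio": res.ratio,
                })
                logger.info("%s (%s): ratio = %.4f", sid, row.group, res.ratio)
            except Exception as exc:
                failures.append(StackFailure(sid, str(row.stack_path), str(exc)))
                qc.setdefault("failed_stacks", []).append(sid)
                logger.warning("%s failed: %s", sid, exc)

        if not rows:
            raise RuntimeError(
                f"no stack produced a result ({len(failures)} failures); see run.log")
        results = pd.DataFrame(rows)

        comparison = None
        groups = {g: sub["ratio"].tolist() for g, sub in results.groupby("group")}
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            comparison = compare_groups(groups)
            logger.info("ANOVA F = %.4g, p = %.4g",
                        comparison.f_statistic, comparison.anova_p)
        else:
            qc.setdefault("warnings", []).append(
                "group comparison skipped: need >= 2 groups with n >= 2")

        report = RunReport(results=results, comparison=comparison,
                           failures=failures, config=config, qc_flags=qc)
        results.to_csv(out_dir / "results.csv", index=False)
        if comparison is not None:
            comparison.pairwise.to_csv(out_dir / "pairwise_stats.csv", index=False)
        (out_dir / "report.json").write_text(report.to_json())
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


def simulate_experiment(
    out_dir: str | Path,
    n_per_group: int = 6,
    hollow_spec: Optional[PhantomSpec] = None,
    filled_spec: Optional[PhantomSpec] = None,
    include_rescue: bool = True,
    seed: int = 0,
) -> Path:
    """Write a phantom induction experiment and return its manifest path.

    Groups: ``control`` (hollow bilayer), ``induced`` (filled lumen) and,
    when ``include_rescue`` is set, ``induced+inhibitor`` reusing the
    hollow geometry — an induced culture whose filling was blocked.
    Per-phantom seeds are derived deterministically from ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hollow = hollow_spec or PhantomSpec(fill_fraction=0.0)
    filled = filled_spec or PhantomSpec(fill_fraction=1.0)

    conditions = [("control", hollow), ("induced", filled)]
    if include_rescue:
        conditions.append(("induced+inhibitor", hollow))

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(conditions) * n_per_group) % (2**31)
    rows = []
    i = 0
    for group, base in conditions:
        for rep in range(n_per_group):
            spec = base.model_copy(update={"seed": int(child_seeds[i])})
            i += 1
            stack, truth = generate_phantom(spec)
            sid = f"{group.replace('+', '_')}_{rep:02d}"
            tiff = write_phantom(stack, truth, spec, out_dir / f"{sid}.tif")
            rows.append({"stack_path": tiff.name, "group": group, "spheroid_id": sid,
                         "true_ratio": truth.true_ratio})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
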