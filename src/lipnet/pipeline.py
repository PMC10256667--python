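"""Config-driven orchestration of the two analysis tracks.

A single YAML document describes a run: where the images come from (a
synthetic scene block and/or an input TIFF), how cells are gated, and the
options of the co-localization and branched-network (IBNA) tracks.  The
pipeline validates the config before any computation, executes
simulate -> segment -> per-cell co-localization -> per-cell IBNA ->
per-cell normalization -> condition fold change, and writes a combined
JSON report plus per-cell CSV tables.  Runs are deterministic: the same
config and seed produce byte-identical reports (timestamps go to the log,
never into the report files).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import (
    ThresholdPair,
    coloc_pixel_map,
    coloc_report,
    cytoplasm_intensity,
    estimate_background,
    fold_change,
)
from .exceptions import ConfigError
from .ibna import (
    analyze_network,
    normalize_per_cell,
    render_tagged_skeleton,
    segment_cells,
)
from .imgio import MultiChannelImage, read_image, read_mask, write_image
from .synth import (
    CHANNEL_NAMES,
    SceneParams,
    generate_condition_pair,
    generate_scene,
)

log = logging.getLogger(__name__)

_MODES = ("simulate", "coloc", "ibna", "full")


@dataclass
class SegmentationOptions:
    nucleus_ch: str = "nucleus"
    cyto_ch: str = "clld"
    smooth_sigma: float = 1.5
    min_nucleus_area: int = 25
    min_cell_area: int = 100


@dataclass
class ColocOptions:
    ch_a: str = "aunc"
    ch_b: str = "clld"
    gate: str = "cytoplasm"  # "cytoplasm" | "cell" | "image"
    mask_path: str | None = None
    t_a: float | None = None
    t_b: float | None = None


@dataclass
class IbnaOptions:
    channel: str = "clld"
    threshold: str = "otsu"  # "otsu" or a number as string/float
    smooth_sigma: float = 1.2
    min_object_px: int = 9
    fill_holes_px: int = 12
    prune_px: float = 4.0
    junction_merge_px: float = 4.0


@dataclass
class RunConfig:
    """Validated run description; see :func:`validate_config` for the rules."""

    mode: str = "full"
    seed: int = 0
    out_dir: str = "lipnet_out"
    log_level: str = "INFO"
    scene: SceneParams | None = None
    condition_pair: bool = False
    image: str | None = None
    channel_names: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES))
    segmentation: SegmentationOptions = field(default_factory=SegmentationOptions)
    coloc: ColocOptions = field(default_factory=ColocOptions)
    ibna: IbnaOptions = field(default_factory=IbnaOptions)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        problems = validate_config(raw)
        if problems:
            raise ConfigError("; ".join(problems))
        kw = dict(raw)
        if "scene" in kw and kw["scene"] is not None:
            kw["scene"] = SceneParams(**kw["scene"])
        for key, sub in (
            ("segmentation", SegmentationOptions),
            ("coloc", ColocOptions),
            ("ibna", IbnaOptions),
        ):
            if key in kw and kw[key] is not None:
                kw[key] = sub(**kw[key])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(raw: dict) -> list[str]:
    """Return a list of problems (empty iff the config is valid).

    Every problem names the offending field and the reason.
    """
    problems: list[str] = []
    if not isinstance(raw, dict):
        return ["config: must be a mapping"]
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            problems.append(f"{key}: unknown field")
    mode = raw.get("mode", "full")
    if mode not in _MODES:
        problems.append(f"mode: {mode!r} is not one of {_MODES}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        problems.append("seed: must be an integer")
    scene = raw.get("scene")
    if scene is not None:
        if not isinstance(scene, dict):
            problems.append("scene: must be a mapping of SceneParams fields")
        else:
            valid = {f.name for f in dataclasses.fields(SceneParams)}
            bad = [k for k in scene if k not in valid]
            problems.extend(f"scene.{k}: unknown field" for k in bad)
            if not bad:
                try:
                    problems.extend(
                        f"scene.{p.split(' ', 1)[0]}: {p}" for p in SceneParams(**scene).problems()
                    )
                except TypeError as exc:
                    problems.append(f"scene: {exc}")
    if mode in ("coloc", "ibna", "full") and scene is None and not raw.get("image"):
        problems.append(f"image: required for mode={mode!r} without a scene block")
    if mode == "simulate" and scene is None:
        problems.append("scene: required for mode='simulate'")
    for key, sub in (
        ("segmentation", SegmentationOptions),
        ("coloc", ColocOptions),
        ("ibna", IbnaOptions),
    ):
        block = raw.get(key)
        if block is None:
            continue
        if not isinstance(block, dict):
            problems.append(f"{key}: must be a mapping")
            continue
        valid = {f.name for f in dataclasses.fields(sub)}
        problems.extend(f"{key}.{k}: unknown field" for k in block if k not in valid)
    cblock = raw.get("coloc") or {}
    if isinstance(cblock, dict):
        gate = cblock.get("gate", "cytoplasm")
        if gate not in ("cytoplasm", "cell", "image"):
            problems.append(f"coloc.gate: {gate!r} is not one of cytoplasm/cell/image")
        if (cblock.get("t_a") is None) != (cblock.get("t_b") is None):
            problems.append("coloc.t_a/t_b: provide both manual thresholds or neither")
    iblock = raw.get("ibna") or {}
    if isinstance(iblock, dict):
        thr = iblock.get("threshold", "otsu")
        if thr != "otsu":
            try:
                float(thr)
            except (TypeError, ValueError):
                problems.append(f"ibna.threshold: {thr!r} is neither 'otsu' nor a number")
    return problems


@dataclass
class RunReport:
    """Aggregated per-cell and condition-level results with provenance."""

    conditions: list[dict]
    fold_change: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "conditions": self.conditions,
            "fold_change": self.fold_change,
            "provenance": self.provenance,
        }


def _acquire(config: RunConfig):
    """Yield (label, image, truth-or-None) pairs according to the config."""
    if config.scene is not None:
        scene = dataclasses.replace(config.scene, seed=config.seed)
        if config.condition_pair:
            (img1, t1), (img2, t2) = generate_condition_pair(scene)
            return [("condition_1", img1, t1), ("condition_2", img2, t2)]
        img, truth = generate_scene(scene)
        return [("scene", img, truth)]
    img = read_image(config.image, config.channel_names)
    return [("image", img, None)]


def _analyze_condition(label: str, img: MultiChannelImage, config: RunConfig) -> dict:
    seg_o = config.segmentation
    t0 = time.perf_counter()
    seg = segment_cells(
        img,
        seg_o.nucleus_ch,
        seg_o.cyto_ch,
        smooth_sigma=seg_o.smooth_sigma,
        min_nucleus_area=seg_o.min_nucleus_area,
        min_cell_area=seg_o.min_cell_area,
    )
    log.info("[%s] segmentation: %d cells (%.2fs)", label, seg.n_cells, time.perf_counter() - t0)

    c_o, i_o = config.coloc, config.ibna
    a = img.plane(c_o.ch_a)
    b = img.plane(c_o.ch_b)
    roi = read_mask(c_o.mask_path) if c_o.mask_path else None
    manual = (
        ThresholdPair(
            t_a=float(c_o.t_a),
            t_b=float(c_o.t_b),
            slope=float("nan"),
            intercept=float("nan"),
        )
        if c_o.t_a is not None
        else None
    )
    bg = estimate_background(a, seg.cell_labels > 0)

    cells = []
    run_coloc = config.mode in ("coloc", "full")
    run_ibna = config.mode in ("ibna", "full")
    for i in range(seg.n_cells):
        t0 = time.perf_counter()
        cyto = seg.cytoplasm_mask(i)
        entry: dict = {"cell_id": i + 1, "condition": label}
        mean, sd, n = cytoplasm_intensity(a, cyto)
        entry["intensity"] = {
            "channel": c_o.ch_a,
            "mean_bg_subtracted": mean - bg,
            "sd": sd,
            "n_pixels": n,
            "background": bg,
        }
        if run_coloc:
            gate = {"cytoplasm": cyto, "cell": seg.cell_mask(i), "image": None}[c_o.gate]
            if roi is not None:
                gate = roi if gate is None else (gate & roi)
            rep = coloc_report(a, b, mask=gate, thresholds=manual)
            pix = coloc_pixel_map(a, b, rep.thresholds)
            if gate is not None:
                pix = pix & gate
            entry["coloc"] = rep.to_dict()
            entry["coloc"]["pixel_map_count"] = int(pix.sum())
        if run_ibna:
            manual_t = None if i_o.threshold == "otsu" else float(i_o.threshold)
            metrics, graph, classes, skeleton = analyze_network(
                img.plane(i_o.channel),
                mask=cyto,
                method="otsu" if i_o.threshold == "otsu" else "manual",
                manual_t=manual_t,
                smooth_sigma=i_o.smooth_sigma,
                min_object_px=i_o.min_object_px,
                fill_holes_px=i_o.fill_holes_px,
                prune_px=i_o.prune_px,
                junction_merge_px=i_o.junction_merge_px,
            )
            entry["ibna"] = metrics.to_dict()
        log.info("[%s] cell %d analyzed (%.2fs)", label, i + 1, time.perf_counter() - t0)
        cells.append(entry)

    out: dict = {"label": label, "n_cells": seg.n_cells, "cells": cells}
    if run_ibna and seg.n_cells > 0:
        total = None
        for entry in cells:
            m = entry["ibna"]
            if total is None:
                total = dict(m)
            else:
                for key in (
                    "n_branches",
                    "n_actual_junctions",
                    "n_endpoint_px",
                    "n_slab_px",
                    "n_junction_px",
                    "total_skeleton_px",
                ):
                    total[key] += m[key]
        lengths = [
            e["ibna"]["avg_branch_length"] * e["ibna"]["n_branches"]
            for e in cells
            if e["ibna"]["avg_branch_length"] is not None
        ]
        nb = sum(e["ibna"]["n_branches"] for e in cells)
        total["avg_branch_length"] = (sum(lengths) / nb) if nb else None
        out["ibna_total"] = total
        from .ibna import NetworkMetrics

        norm = normalize_per_cell(
            NetworkMetrics(**{k: total[k] for k in total if k in {
                "n_branches", "n_actual_junctions", "n_endpoint_px", "n_slab_px",
                "n_junction_px", "avg_branch_length", "total_skeleton_px",
            }}),
            seg.n_cells,
        )
        out["ibna_per_cell"] = norm.to_dict()
    return out


def run_full(config: RunConfig) -> RunReport:
    """Execute the configured run and write all artifacts to ``out_dir``.

    Returns the in-memory :class:`RunReport`; on disk it writes
    ``report.json`` (byte-deterministic), ``cells.csv``, the resolved config
    echo and, for simulate runs, the scene TIFFs and truth JSON.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lipnet")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        (out_dir / "config_echo.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True)
        )
        try:
            inputs = _acquire(config)
        except Exception:
            log.exception("stage 'acquire' failed")
            raise

        if config.mode == "simulate":
            for label, img, truth in inputs:
                write_image(img, out_dir / f"{label}.tif")
                _write_truth(truth, out_dir / f"{label}_truth.json")
            report = RunReport(
                conditions=[{"label": lab, "n_cells": t.n_cells} for lab, _, t in inputs],
                fold_change=None,
                provenance=_provenance(config),
            )
            _write_report(report, out_dir)
            return report

        conditions = []
        for label, img, truth in inputs:
            try:
                conditions.append(_analyze_condition(label, img, config))
            except Exception:
                log.exception("stage 'analyze' failed for %s", label)
                raise

        fc = None
        if len(conditions) == 2:
            m1 = [c["intensity"]["mean_bg_subtracted"] for c in conditions[0]["cells"]]
            m2 = [c["intensity"]["mean_bg_subtracted"] for c in conditions[1]["cells"]]
            if m1 and m2:
                ratio, lo, hi = fold_change(m1, m2, seed=config.seed)
                fc = {"ratio": ratio, "ci_low": lo, "ci_high": hi, "n_boot": 2000}
        report = RunReport(conditions=conditions, fold_change=fc, provenance=_provenance(config))
        _write_report(report, out_dir)
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


def _provenance(config: RunConfig) -> dict:
    return {"software": "lipnet", "version": __version__, "seed": config.seed,
            "config": config.to_dict()}


def _write_report(report: RunReport, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    rows = []
    for cond in report.conditions:
        for cell in cond.get("cells", []):
            row = {"condition": cond["label"], "cell_id": cell["cell_id"]}
            row.update(
                {f"intensity_{k}": v for k, v in cell.get("intensity", {}).items() if k != "channel"}
            )
            row.update({f"coloc_{k}": v for k, v in cell.get("coloc", {}).items() if k != "quadrants"})
            row.update({f"ibna_{k}": v for k, v in cell.get("ibna", {}).items()})
            rows.append(row)
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "cells.csv", index=False)


def _write_truth(truth, path: Path) -> None:
    payload = {
        "n_cells": truth.n_cells,
        "true_coloc_fraction": truth.true_coloc_fraction,
        "true_intensity_means": truth.true_intensity_means,
        "true_cytoplasm_means": truth.true_cytoplasm_means,
        "skeletons": [
            {
                "nodes": [
                    {"id": n.id, "kind": n.kind, "pixels": [list(p) for p in n.pixels]}
                    for n in g.nodes
                ],
                "edges": [
                    {"u": e.u, "v": e.v, "length": e.length, "n_path_px": len(e.path)}
                    for e in g.edges
                ],
            }
            for g in truth.true_skeletons
        ],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    import tifffile

    tifffile.imwrite(
        path.with_name(path.stem + "_labels.tif"),
        np.stack([
            truth.cell_labels.astype(np.uint16),
            truth.nucleus_labels.astype(np.uint16),
        ]),
    )
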