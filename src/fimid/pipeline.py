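"""End-to-end orchestration: preprocess -> fibers -> myofibrils -> summaries.

`run_quantification` executes the full measurement chain for a list of
calibrated stacks and writes deterministic result tables plus a manifest
recording the software version, configuration hash, and per-fiber counts.
Identical inputs and configuration produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fibers import (
    FiberRecord,
    autofluorescence_score,
    classify_fiber_type,
    isolate_fiber,
    segment_fibers,
)
from .io_imaging import (
    FOCUS_METRIC,
    ChannelStack,
    deconvolve,
    merge_channels,
    read_stack,
    select_focus_plane,
)
from .quant import (
    DEFAULT_FILTERS,
    UnquantifiableFiberError,
    binarize_boundary,
    detect_candidates,
    filter_candidates,
    filter_rate_summary,
    intermyofibrillar_area,
    quantify_fiber,
)

log = logging.getLogger("fimid")

__all__ = ["RunConfig", "run_quantification", "quantify_stack"]


@dataclass
class RunConfig:
    """All knobs of a quantification run, with defaults.

    Round-trips losslessly through YAML (`to_yaml` / `from_yaml`).
    """

    inputs: list[str] = field(default_factory=list)
    out_dir: str = "fimid_out"
    pixel_size_um: float | None = None  # None: require metadata
    seed: int = 0
    # channel-name map
    boundary_channel: str = "serca"
    auto_channel: str = "auto"
    outline_channel: str = "dystrophin"
    merge_auto: bool = True  # mouse-style merged analysis; False: SERCA only
    fiber_masks: list[str] = field(default_factory=list)  # optional label TIFFs
    # preprocessing
    deconvolve: bool = True
    psf_sigma_px: float = 1.0
    deconv_iterations: int = 15
    # fiber segmentation / typing
    min_fiber_area_um2: float = 50.0
    puncta_threshold: float = 1000.0
    type_cutoff: float = 0.05
    # boundary binarization
    window_px: int = 31
    sensitivity: float = 0.5
    # candidate filters
    enclosure_min: float = DEFAULT_FILTERS["enclosure_min"]
    aspect_max: float = DEFAULT_FILTERS["aspect_max"]
    solidity_min: float = DEFAULT_FILTERS["solidity_min"]
    area_min_um2: float = DEFAULT_FILTERS["area_min_um2"]
    area_max_um2: float = DEFAULT_FILTERS["area_max_um2"]
    reach_px: int = DEFAULT_FILTERS["reach_px"]
    qc_overlay: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_fiber_masks(path: str, pixel_size_um: float) -> list[FiberRecord]:
    """Fiber records from a label-image TIFF of manual traces."""
    import tifffile

    lbl = np.asarray(tifffile.imread(path))
    records = []
    for fid, lab in enumerate(np.unique(lbl[lbl > 0])):
        mask = lbl == lab
        records.append(
            FiberRecord(
                fiber_id=fid,
                mask=mask,
                csa_um2=float(mask.sum()) * pixel_size_um**2,
            )
        )
    return records


def quantify_stack(
    stack: ChannelStack,
    config: RunConfig,
    fibers: list[FiberRecord] | None = None,
    overlay_path=None,
) -> tuple[list[dict], list[dict]]:
    """Quantify every fiber in one stack.

    Returns (fiber rows, object rows) as plain dicts ready for tabulation.
    Fibers with no accepted objects are reported with
    ``status='unquantifiable'`` rather than dropped.
    """
    px = stack.pixel_size_um
    if config.deconvolve:
        stack = deconvolve(
            stack, config.boundary_channel, config.psf_sigma_px, config.deconv_iterations
        )
    z = select_focus_plane(stack, config.boundary_channel)
    boundary_plane = stack.plane(config.boundary_channel, z)
    auto_plane = stack.plane(config.auto_channel, z)
    if config.merge_auto:
        analysis_plane = merge_channels(
            boundary_plane, auto_plane, ceiling=stack.bit_depth
        )
    else:
        analysis_plane = boundary_plane

    if fibers is None:
        outline_plane = stack.plane(config.outline_channel, z)
        fibers = segment_fibers(outline_plane, px, config.min_fiber_area_um2)
    log.info("focus plane %d (%s); %d fiber(s)", z, FOCUS_METRIC, len(fibers))

    bmask = binarize_boundary(analysis_plane, config.window_px, config.sensitivity)

    fiber_rows: list[dict] = []
    object_rows: list[dict] = []
    for fib in fibers:
        score = autofluorescence_score(auto_plane, fib, config.puncta_threshold)
        fib.autofluorescence_score = score
        fib.type_label = classify_fiber_type(score, config.type_cutoff)
        candidates = detect_candidates(bmask, fib.mask, px, config.reach_px)
        candidates = filter_candidates(
            candidates,
            enclosure_min=config.enclosure_min,
            aspect_max=config.aspect_max,
            solidity_min=config.solidity_min,
            area_min_um2=config.area_min_um2,
            area_max_um2=config.area_max_um2,
        )
        inter = intermyofibrillar_area(bmask, fib.mask, px)
        inter = min(inter, fib.csa_um2)
        for obj in candidates:
            object_rows.append(
                {
                    "fiber_id": fib.fiber_id,
                    "object_id": obj.object_id,
                    "area_um2": obj.area_um2,
                    "major_axis_um": obj.major_axis_um,
                    "minor_axis_um": obj.minor_axis_um,
                    "aspect_ratio": obj.aspect_ratio,
                    "solidity": obj.solidity,
                    "enclosure_fraction": obj.enclosure_fraction,
                    "centroid_row": obj.centroid[0],
                    "centroid_col": obj.centroid[1],
                    "status": obj.status,
                }
            )
        row = {
            "fiber_id": fib.fiber_id,
            "fiber_csa_um2": fib.csa_um2,
            "fiber_type": fib.type_label,
            "autofluorescence_score": score,
            "status": "ok",
        }
        try:
            q = quantify_fiber(
                fib.fiber_id, fib.csa_um2, candidates, inter, len(candidates)
            )
            row.update(
                n_candidates=q.n_candidates,
                n_accepted=q.n_accepted,
                filter_rate=q.filter_rate,
                mean_myofibril_csa_um2=q.mean_myofibril_csa_um2,
                intermyofibrillar_area_um2=q.intermyofibrillar_area_um2,
                myofibril_occupied_area_um2=q.myofibril_occupied_area_um2,
                myofibril_count=q.myofibril_count,
            )
            if q.filter_rate > 0.8:
                log.warning(
                    "fiber %d: filter rate %.2f > 0.8 — check image quality",
                    fib.fiber_id,
                    q.filter_rate,
                )
        except UnquantifiableFiberError:
            row.update(
                n_candidates=len(candidates),
                n_accepted=0,
                filter_rate=1.0 if candidates else float("nan"),
                mean_myofibril_csa_um2=float("nan"),
                intermyofibrillar_area_um2=inter,
                myofibril_occupied_area_um2=fib.csa_um2 - inter,
                myofibril_count=float("nan"),
                status="unquantifiable",
            )
        fiber_rows.append(row)
    if overlay_path is not None:
        _write_overlay(overlay_path, analysis_plane, object_rows)
    return fiber_rows, object_rows


def _write_overlay(path, analysis_plane, object_rows) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(analysis_plane, cmap="gray")
    acc = [r for r in object_rows if r["status"] == "accepted"]
    rej = [r for r in object_rows if r["status"] != "accepted"]
    if acc:
        ax.scatter(
            [r["centroid_col"] for r in acc],
            [r["centroid_row"] for r in acc],
            s=4, c="lime", label=f"accepted ({len(acc)})",
        )
    if rej:
        ax.scatter(
            [r["centroid_col"] for r in rej],
            [r["centroid_row"] for r in rej],
            s=4, c="red", label=f"rejected ({len(rej)})",
        )
    ax.legend(loc="lower right", fontsize=7)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def run_quantification(
    config: RunConfig,
    stacks: list[ChannelStack] | None = None,
) -> dict:
    """Run the full pipeline and write result tables + manifest.

    ``stacks`` may be passed directly (e.g. freshly simulated); otherwise
    ``config.inputs`` paths are read. Per-image failures are logged and
    recorded in the manifest; remaining images are still processed.

    Outputs under ``config.out_dir``: ``objects.csv``, ``fibers.csv``,
    ``summary.json``, ``manifest.json`` and optional QC overlay PNGs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_fibers: list[dict] = []
    all_objects: list[dict] = []
    errors: list[dict] = []

    if stacks is None:
        loaded: list[tuple[str, ChannelStack]] = []
        for p in config.inputs:
            try:
                loaded.append((str(p), read_stack(p, config.pixel_size_um)))
            except Exception as exc:  # keep going; record the failure
                log.error("failed to read %s: %s", p, exc)
                errors.append({"input": str(p), "stage": "read", "error": str(exc)})
        named = loaded
    else:
        named = [(f"stack_{i}", s) for i, s in enumerate(stacks)]

    next_fiber_id = 0
    for img_idx, (name, stack) in enumerate(named):
        masks = None
        if config.fiber_masks:
            masks = _load_fiber_masks(
                config.fiber_masks[img_idx], stack.pixel_size_um
            )
        overlay = out / f"qc_{img_idx:03d}.png" if config.qc_overlay else None
        try:
            fiber_rows, object_rows = quantify_stack(stack, config, masks, overlay)
        except Exception as exc:
            log.error("failed to quantify %s: %s", name, exc)
            errors.append({"input": name, "stage": "quantify", "error": str(exc)})
            continue
        # re-key fiber ids globally so rows stay traceable across images
        remap = {r["fiber_id"]: next_fiber_id + i for i, r in enumerate(fiber_rows)}
        for r in fiber_rows:
            r["input"] = name
            r["fiber_id"] = remap[r["fiber_id"]]
        for r in object_rows:
            r["input"] = name
            r["fiber_id"] = remap[r["fiber_id"]]
        next_fiber_id += len(fiber_rows)
        all_fibers.extend(fiber_rows)
        all_objects.extend(object_rows)

    fibers_df = pd.DataFrame(all_fibers)
    objects_df = pd.DataFrame(all_objects)
    fibers_df.to_csv(out / "fibers.csv", index=False)
    objects_df.to_csv(out / "objects.csv", index=False)

    ok = fibers_df[fibers_df["status"] == "ok"] if len(fibers_df) else fibers_df
    n_cand = int(fibers_df["n_candidates"].sum()) if len(fibers_df) else 0
    n_acc = int(fibers_df["n_accepted"].sum()) if len(fibers_df) else 0
    summary = {
        "n_images": len(named),
        "n_fibers": int(len(fibers_df)),
        "n_quantified": int(len(ok)),
        "pooled_filter_rate": (n_cand - n_acc) / n_cand if n_cand else None,
        "mean_fiber_csa_um2": float(ok["fiber_csa_um2"].mean()) if len(ok) else None,
        "mean_myofibril_csa_um2": (
            float(ok["mean_myofibril_csa_um2"].mean()) if len(ok) else None
        ),
        "mean_myofibril_count": (
            float(ok["myofibril_count"].mean()) if len(ok) else None
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        "software": "fimid",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "focus_metric": FOCUS_METRIC,
        "n_fibers": int(len(fibers_df)),
        "errors": errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "fibers": fibers_df,
        "objects": objects_df,
        "summary": summary,
        "manifest": manifest,
    }
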