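"""Configuration-driven orchestration: simulate/ingest -> reconstruct ->
normalize -> segment -> quantify -> stats.

A run is described by a :class:`RunConfig` (single YAML file), executes
deterministically for a given seed, and leaves a self-describing output
tree: reconstructed TIFFs, overlay PNGs, the Xe factor table, region
masks, raw and normalized quantification tables, group summaries, test
results and a JSON manifest recording the config hash, seed and
per-stage provenance.  Region means are normalized *after* segmentation,
matching the order of the measurement procedure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ImcQuantError
from .normalization import (XeFit, factors_for_batch, factors_to_frame,
                            fit_batch, normalize_quant)
from .panel import Panel, default_panel
from .raw_io import (MultichannelImage, read_raw_scan, reconstruct,
                     render_overlay, save_overlay_png,
                     write_multichannel_tiff, read_multichannel_tiff)
from .region_quant import (ClassifierParams, NucleusParams, TissueClass,
                           classify_regions, positive_fraction, records_to_frame,
                           region_channel_means, segment_nuclei, QuantRecord)
from .stats import (propagate_group_errors, summaries_to_frame, mouse_means,
                    one_way_anova, t_test, plot_group_bars)
from .synthetic import SimulationConfig, simulate_cohort, save_ground_truth, export_raw

log = logging.getLogger("imcquant.pipeline")

#: default overlay: collagen red, epithelium green, nuclei blue
DEFAULT_OVERLAY = {"169Tm": "FF0000", "162Dy": "00FF00", "191Ir": "0000FF"}
FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    mode: str = "simulate"                       # "simulate" | "raw_files"
    out_dir: str = "imcquant_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    raw_files: list = field(default_factory=list)   # [{"raw":..., "sidecar":..., "mouse_id":..., "group":...}]
    panel_file: Optional[str] = None
    xe_channel: str = "134Xe"
    bin_width: Optional[float] = None
    reference_image: Optional[str] = None
    normalize: bool = True
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    nucleus: NucleusParams = field(default_factory=NucleusParams)
    overlay_colors: dict = field(default_factory=lambda: dict(DEFAULT_OVERLAY))
    positive_channels: tuple = ("127I", "147Sm")   # IdU, gH2AX
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "raw_files"):
            raise ConfigError(f"unknown input mode {self.mode!r}")
        if self.mode == "raw_files" and not self.raw_files:
            raise ConfigError("raw_files mode requires a list of raw/sidecar paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulation", None)
        cfg = cls(**{k: v for k, v in doc.items()
                     if k in {f.name for f in dataclasses.fields(cls)}
                     and k not in ("simulation", "classifier", "nucleus")})
        if sim:
            from .synthetic import GroupSpec
            if "groups" in sim:
                sim["groups"] = tuple(GroupSpec(**g) for g in sim["groups"])
            if "drift_range" in sim:
                sim["drift_range"] = tuple(sim["drift_range"])
            cfg.simulation = SimulationConfig(**sim)
        if "classifier" in doc:
            cfg.classifier = ClassifierParams(**doc["classifier"])
        if "nucleus" in doc:
            cfg.nucleus = NucleusParams(**doc["nucleus"])
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _label_legend() -> dict:
    return {int(c): c.name.lower() for c in TissueClass}


def run_pipeline(config: RunConfig, panel: Optional[Panel] = None,
                 resume: bool = False) -> dict:
    """Execute the full pipeline; returns the run manifest (also written
    to ``<out_dir>/manifest.json``).

    ``resume`` reuses previously written reconstructed TIFFs (and, in
    simulate mode, ground-truth files) instead of regenerating them;
    downstream stages are recomputed.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    panel = panel or (Panel.from_yaml(config.panel_file) if config.panel_file
                      else default_panel())
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    stage_times: dict[str, float] = {}

    def _stage(name):
        stage_times[name] = time.time()
        log.info("stage %s", name)

    try:
        # ------------------------------------------------ acquire
        _stage("acquire")
        images: list[MultichannelImage] = []
        image_ids: list[str] = []
        meta_rows: list[dict] = []
        tiff_dir = out / "images"
        tiff_dir.mkdir(exist_ok=True)
        if config.mode == "simulate":
            raw_dir = out / "raw"
            raw_dir.mkdir(exist_ok=True)
            truth_dir = out / "ground_truth"
            truth_dir.mkdir(exist_ok=True)
            cohort = simulate_cohort(config.simulation, seed=config.seed,
                                     panel=panel)
            for image, truth in cohort:
                iid = truth.image_id
                tif = tiff_dir / f"{iid}.tiff"
                if not (resume and tif.exists()):
                    export_raw(image, raw_dir / f"{iid}.txt")
                    write_multichannel_tiff(image, tif)
                    save_ground_truth(truth, truth_dir / f"{iid}_truth.tiff")
                else:
                    image = read_multichannel_tiff(tif)
                    image.provenance.update(image_id=iid, mouse_id=truth.mouse_id,
                                            group=truth.group)
                images.append(image)
                image_ids.append(iid)
                meta_rows.append({"image_id": iid, "mouse_id": truth.mouse_id,
                                  "group": truth.group,
                                  "drift_factor": truth.drift_factor})
        else:
            for i, spec in enumerate(config.raw_files):
                raw = read_raw_scan(spec["raw"], spec["sidecar"])
                image = reconstruct(raw, panel)
                iid = (spec.get("image_id")
                       or image.provenance.get("image_id")
                       or Path(spec["raw"]).stem)
                image.provenance["image_id"] = iid
                write_multichannel_tiff(image, tiff_dir / f"{iid}.tiff")
                images.append(image)
                image_ids.append(iid)
                meta_rows.append({
                    "image_id": iid,
                    "mouse_id": spec.get("mouse_id",
                                         image.provenance.get("mouse_id", iid)),
                    "group": spec.get("group", image.provenance.get("group", "all")),
                    "drift_factor": None,
                })
        meta = pd.DataFrame(meta_rows)
        _write_tsv(meta, out / "images.tsv")
        manifest["stages"]["acquire"] = {"n_images": len(images)}

        # ------------------------------------------------ overlays
        _stage("overlay")
        ov_dir = out / "overlays"
        ov_dir.mkdir(exist_ok=True)
        colors = {c: v for c, v in config.overlay_colors.items()
                  if c in images[0].channel_names}
        for image, iid in zip(images, image_ids):
            if colors:
                save_overlay_png(render_overlay(image, colors),
                                 ov_dir / f"{iid}.png")
        manifest["stages"]["overlay"] = {"channels": list(colors)}

        # ------------------------------------------------ normalization factors
        _stage("normalize")
        fits = fit_batch(images, image_ids, channel=config.xe_channel,
                         bin_width=config.bin_width)
        factors = factors_for_batch(fits, reference_id=config.reference_image)
        ref_fit = next(f for f in fits
                       if f.image_id == factors[0].reference_id)
        _write_tsv(factors_to_frame(factors), out / "factors.tsv")
        manifest["stages"]["normalize"] = {
            "reference_id": factors[0].reference_id,
            "applied": config.normalize,
        }

        # ------------------------------------------------ segmentation
        _stage("segment")
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        masks = []
        import tifffile
        for image, iid in zip(images, image_ids):
            mask = classify_regions(image, panel, config.classifier)
            masks.append(mask)
            tifffile.imwrite(mask_dir / f"{iid}_mask.tiff",
                             mask.labels.astype(np.uint8))
        with open(mask_dir / "legend.json", "w") as jh:
            json.dump(_label_legend(), jh, indent=1)
        manifest["stages"]["segment"] = {"n_masks": len(masks)}

        # ------------------------------------------------ quantify
        _stage("quantify")
        raw_records: list[QuantRecord] = []
        for image, iid, mask, row in zip(images, image_ids, masks, meta_rows):
            recs = region_channel_means(image, mask, image_id=iid,
                                        mouse_id=row["mouse_id"],
                                        group=row["group"])
            nuclei = segment_nuclei(image, panel, config.nucleus, mask=mask)
            for chan in config.positive_channels:
                if nuclei.n_nuclei and chan in image.channel_names:
                    # IdU fractions are gated on EF5: hypoxic nuclei do
                    # not cycle and are removed from the denominator
                    gate = "159Tb" if (chan == "127I"
                                       and "159Tb" in image.channel_names) \
                        else None
                    pct = positive_fraction(nuclei, chan, region="epithelium",
                                            exclude_channel=gate) \
                        if (nuclei.table["region"] == "epithelium").any() \
                        else positive_fraction(nuclei, chan)
                    recs.append(QuantRecord(iid, row["mouse_id"], row["group"],
                                            "epithelium_nuclei", chan,
                                            float("nan"), 0.0,
                                            max(nuclei.n_nuclei, 1),
                                            pct_positive=pct))
            raw_records.extend(recs)
        raw_frame = records_to_frame(raw_records)
        _write_tsv(raw_frame, out / "quant_raw.tsv")

        fit_by_id = {f.image_id: f for f in fits}
        nf_by_id = {f.image_id: f for f in factors}
        norm_records = []
        for rec in raw_records:
            if np.isnan(rec.mean):       # positive-fraction rows stay as-is
                norm_records.append(rec)
                continue
            norm_records.append(normalize_quant(rec, nf_by_id[rec.image_id],
                                                ref_fit))
        norm_frame = records_to_frame(norm_records)
        _write_tsv(norm_frame, out / "quant_normalized.tsv")
        manifest["stages"]["quantify"] = {"n_records": len(raw_records)}

        # ------------------------------------------------ stats
        _stage("stats")
        work = norm_frame if config.normalize else raw_frame
        work = work[np.isfinite(work["mean"])]
        summaries = propagate_group_errors(work)
        _write_tsv(summaries_to_frame(summaries), out / "group_summary.tsv")

        mm = mouse_means(work)
        tests = []
        for (region, channel), sub in mm.groupby(["region", "channel"]):
            groups = [g["mean"].to_numpy() for _, g in sub.groupby("group")]
            names = list(sub["group"].unique())
            if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
                res = one_way_anova(groups, names)
                tests.append({"region": region, "channel": channel,
                              "test": res.test, "statistic": res.statistic,
                              "p_value": res.p_value, "df": str(res.df),
                              "groups": ",".join(names)})
                if len(groups) == 2:
                    tt = t_test(groups[0], groups[1], names=tuple(names))
                    tests.append({"region": region, "channel": channel,
                                  "test": tt.test, "statistic": tt.statistic,
                                  "p_value": tt.p_value, "df": str(tt.df),
                                  "groups": ",".join(names)})
        _write_tsv(pd.DataFrame(tests), out / "test_results.tsv")

        drug = [s for s in summaries
                if s.region in ("viable_collagen", "viable_noncollagen")]
        if drug:
            plot_group_bars(drug, out / "pt_collagen_bars.png",
                            title="Pt: collagen vs non-collagen viable tissue")
        manifest["stages"]["stats"] = {"n_tests": len(tests)}

    except ImcQuantError:
        raise
    except Exception as exc:     # annotate which stage broke
        stage = max(stage_times, key=stage_times.get) if stage_times else "?"
        raise ImcQuantError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    now = time.time()
    order = sorted(stage_times, key=stage_times.get)
    walls = {}
    for i, name in enumerate(order):
        end = stage_times[order[i + 1]] if i + 1 < len(order) else now
        walls[name] = round(end - stage_times[name], 3)
    manifest["stage_wall_times_s"] = walls
    manifest["total_wall_time_s"] = round(now - t_start, 3)
    with open(out / "manifest.json", "w") as jh:
        json.dump(manifest, jh, indent=1, default=str)
    return manifest
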