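"""Experiment orchestration: simulate -> SNR -> patch -> train -> audit -> report.

A run is driven by a schema-validated configuration (YAML or dict).  Every
stage writes its artifacts under the run directory and registers them in a
``RunManifest`` with SHA-256 checksums, so that reruns with the same config
and seed produce byte-identical CSV/JSON outputs and the provenance of every
figure is recorded.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import occlusion_audit as occ
from .classifier import (
    ModelSpec,
    TrainConfig,
    TrainedModel,
    build_model,
    predict_split,
    save_checkpoint,
    train,
)
from .evaluation import chi_square_2x2, confusion_and_metrics, render_maps
from .io import save_cube
from .patchwork import PatchDataset, assemble_splits, save_patch_dataset
from .radiometry import ChannelSpec
from .synthetic import generate_dataset, make_illuminants, make_sensor, sample_reflectance_library
from .experiments import system_snr_table

logger = logging.getLogger(__name__)


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "views": ["rgb3", "msi18"],
    "occlusion_view": "msi21",
    "radiometry": {"pixel_area_um2": 1.0, "exposure_ms": 30.0,
                   "filter_nir_uv_block": True},
    "library": {"n_classes": 11, "separability": 0.02, "band_nm": None,
                "scale_jitter_sd": 0.005, "perturb_amplitude": 0.003,
                "n_basis": 10},
    "scene": {"height": 256, "width": 256, "coverage_range": [0.3, 0.8],
              "texture_sd": 0.05, "background_reflectance": 0.02,
              "poisson": True},
    "dataset": {"n_specimens": [6, 2, 1], "scenes_per_class": [1, 1, 1],
                "save_example_scene": True},
    "model": {"n_blocks": 3, "layers_per_block": 4, "growth": 12,
              "stem_channels": 16, "stem_stride": 2, "stem_pool": True,
              "compression": 0.5},
    "training": {"learning_rate": 0.001, "l2_weight": 0.001, "epochs": 40,
                 "batch_size": 128},
    "occlusion": {"threshold_db": 20.0, "nullity_bound": 0.01},
}


class ConfigError(ValueError):
    pass


def validate_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    """Merge a user config over the defaults, rejecting unknown keys."""

    def merge(default: Any, user: Any, path: str) -> Any:
        if isinstance(default, dict):
            if not isinstance(user, Mapping):
                raise ConfigError(f"{path or 'config'}: expected a mapping")
            unknown = set(user) - set(default)
            if unknown:
                raise ConfigError(f"unknown config keys at {path or 'root'}: "
                                  f"{sorted(unknown)}")
            out = copy.deepcopy(default)
            for k, v in user.items():
                out[k] = merge(default[k], v, f"{path}.{k}" if path else k)
            return out
        return user

    return merge(DEFAULT_CONFIG, config or {}, "")


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return validate_config(None)
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def register(self, stage: str, files: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "seconds": round(seconds, 3),
            "files": {str(f): _sha256(f) for f in files},
        }

    def all_files(self) -> list[str]:
        return [f for st in self.stages.values() for f in st["files"]]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "version": self.version, "stages": self.stages}, indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class Pipeline:
    """Stage runner; stages cache their products on disk under ``out_dir``."""

    def __init__(self, config: Mapping[str, Any] | None, out_dir: str | Path,
                 seed: int | None = None):
        self.config = validate_config(config)
        if seed is not None:
            self.config["seed"] = int(seed)
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        cfg_json = json.dumps(self.config, sort_keys=True)
        self.manifest = RunManifest(
            config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
            seed=self.config["seed"])
        (self.out / "config.yaml").write_text(yaml.safe_dump(self.config))
        self._dataset: PatchDataset | None = None
        self._models: dict[str, TrainedModel] = {}
        self._system = None

    # -- building blocks ----------------------------------------------------
    def system(self):
        if self._system is None:
            rcfg = self.config["radiometry"]
            self._system = (make_illuminants(), make_sensor(),
                            ChannelSpec(pixel_area_um2=rcfg["pixel_area_um2"],
                                        exposure_ms=rcfg["exposure_ms"],
                                        filter_nir_uv_block=rcfg["filter_nir_uv_block"]))
        return self._system

    def stage_snr(self) -> None:
        t0 = time.time()
        lights, sensor, spec = self.system()
        table = system_snr_table(lights, sensor, spec)
        wide = self.out / "snr_table.csv"
        long = self.out / "snr_long.csv"
        table.to_csv(wide)
        table.to_long_csv(long)
        self.manifest.register("snr", [wide, long], time.time() - t0)

    def stage_simulate(self) -> PatchDataset:
        t0 = time.time()
        cfg = self.config
        lights, sensor, spec = self.system()
        lcfg = cfg["library"]
        band = lcfg["band_nm"]
        lib = sample_reflectance_library(
            n_classes=lcfg["n_classes"], separability=lcfg["separability"],
            band_nm=tuple(band) if band else None, seed=cfg["seed"],
            n_basis=lcfg["n_basis"], scale_jitter_sd=lcfg["scale_jitter_sd"],
            perturb_amplitude=lcfg["perturb_amplitude"])
        scfg = cfg["scene"]
        dcfg = cfg["dataset"]
        files = []
        example_saved = [False]

        def scene_stream():
            manifest_rows = []
            for rec in generate_dataset(
                    lib, lights, sensor, spec, seed=cfg["seed"],
                    n_specimens=tuple(dcfg["n_specimens"]),
                    scenes_per_class=tuple(dcfg["scenes_per_class"]),
                    height=scfg["height"], width=scfg["width"],
                    coverage_range=tuple(scfg["coverage_range"]),
                    texture_sd=scfg["texture_sd"],
                    background_reflectance=scfg["background_reflectance"],
                    poisson=scfg["poisson"]):
                if dcfg["save_example_scene"] and not example_saved[0]:
                    paths = save_cube(rec.cube, rec.mask,
                                      self.out / "example_scene" / rec.scene_id)
                    files.extend(paths.values())
                    example_saved[0] = True
                manifest_rows.append({
                    "scene_id": rec.scene_id, "specimen_id": rec.specimen_id,
                    "split": rec.split, "class_label": rec.class_label})
                yield rec
            pd.DataFrame(manifest_rows).to_csv(self.out / "scene_manifest.csv",
                                               index=False)

        ds = assemble_splits(scene_stream(), class_names=lib.class_names)
        store = self.out / "patches"
        save_patch_dataset(ds, store)
        files += [self.out / "scene_manifest.csv", store / "descriptor.json",
                  store / "patch_counts.csv"]
        self.manifest.register("simulate", files, time.time() - t0)
        self._dataset = ds
        return ds

    def dataset(self) -> PatchDataset:
        if self._dataset is None:
            self.stage_simulate()
        return self._dataset

    def stage_train(self, view: str) -> TrainedModel:
        t0 = time.time()
        ds = self.dataset().select_channels(view)
        mcfg = self.config["model"]
        tcfg = self.config["training"]
        spec = ModelSpec(input_channels=ds.n_channels, n_classes=ds.n_classes,
                         seed=self.config["seed"], **mcfg)
        trained = train(build_model(spec), ds,
                        TrainConfig(seed=self.config["seed"] + 1, **tcfg))
        ckpt = self.out / f"model_{view}.npz"
        log = self.out / f"training_log_{view}.csv"
        save_checkpoint(trained, ckpt)
        trained.history.to_csv(log, index=False)
        self.manifest.register(f"train[{view}]", [ckpt, log], time.time() - t0)
        self._models[view] = trained
        return trained

    def model(self, view: str) -> TrainedModel:
        if view not in self._models:
            self.stage_train(view)
        return self._models[view]

    def stage_evaluate(self, view: str) -> dict:
        t0 = time.time()
        ds = self.dataset().select_channels(view)
        trained = self.model(view)
        preds = predict_split(trained, ds, "test")
        cm, metrics = confusion_and_metrics(preds)
        files = []
        cm_path = self.out / f"confusion_{view}.csv"
        cm.to_csv(cm_path)
        met_path = self.out / f"metrics_{view}.csv"
        metrics.to_frame().to_csv(met_path, index=False)
        summary = {
            "view": view,
            "micro_accuracy": metrics.micro_accuracy,
            "macro_accuracy": metrics.macro_accuracy,
            "micro_probability": metrics.micro_probability,
            "macro_probability": metrics.macro_probability,
            "n_test_patches": int(preds.labels.size),
            "n_correct": int((preds.predicted == preds.labels).sum()),
        }
        js_path = self.out / f"metrics_{view}.json"
        js_path.write_text(json.dumps(summary, indent=2))
        files += [cm_path, met_path, js_path]
        # visual diagnostics for the first test scene
        s = ds.splits["test"]
        if len(s) > 0:
            scene0 = s.scene_ids[0]
            sel = s.scene_ids == scene0
            sub = predict_split(trained, ds, "test")
            from .classifier import PredictionBatch  # local to avoid cycle confusion
            scene_preds = PredictionBatch(
                probs=sub.probs[sel], labels=sub.labels[sel],
                class_names=ds.class_names, coords=s.coords[sel])
            h = self.config["scene"]["height"]
            w = self.config["scene"]["width"]
            for mode, tag in (("label_map", "labels"), ("probability_heatmap", "prob")):
                m = render_maps((h, w), scene_preds, mode=mode)
                p = self.out / f"map_{tag}_{view}.png"
                m.save(p)
                files.append(p)
        self.manifest.register(f"evaluate[{view}]", files, time.time() - t0)
        return summary

    def stage_occlude(self) -> occ.SnrOcclusionReport:
        t0 = time.time()
        view = self.config["occlusion_view"]
        ds = self.dataset().select_channels(view)
        trained = self.model(view)
        means = occ.compute_channel_means(ds)
        x_test, y_test = ds.model_inputs("test")
        omap = occ.occlusion_map(trained, x_test, y_test, means, ds.class_names)
        lights, sensor, spec = self.system()
        snr = system_snr_table(lights, sensor, spec).as_series()
        ocfg = self.config["occlusion"]
        report = occ.snr_threshold_report(snr[list(omap.channel_ids)], omap,
                                          threshold_db=ocfg["threshold_db"],
                                          nullity_bound=ocfg["nullity_bound"])
        files = []
        for path, writer in [
                (self.out / "occlusion_map.csv", lambda p: omap.to_csv(p, signed=True)),
                (self.out / "occlusion_map_abs.csv", lambda p: omap.to_csv(p, signed=False)),
                (self.out / "snr_occlusion_report.csv", report.to_csv),
                (self.out / "snr_occlusion_report.json", report.to_json)]:
            writer(path)
            files.append(path)
        files.append(self._plot_occlusion(omap, report))
        self.manifest.register("occlude", files, time.time() - t0)
        return report

    def _plot_occlusion(self, omap: occ.OcclusionMap,
                        report: occ.SnrOcclusionReport) -> Path:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(14, 5))
        lim = np.nanmax(np.abs(omap.delta)) or 1.0
        im = ax0.imshow(omap.delta, cmap="RdBu_r", vmin=-lim, vmax=lim)
        ax0.set_xticks(range(len(omap.channel_ids)))
        ax0.set_xticklabels(omap.channel_ids, rotation=90, fontsize=7)
        ax0.set_yticks(range(len(omap.class_names)))
        ax0.set_yticklabels(omap.class_names, fontsize=8)
        ax0.set_title("Occlusion sensitivity (signed dP correct)")
        fig.colorbar(im, ax=ax0)
        t = report.table
        ax1.scatter(t["snr_db"], t["occlusion_sensitivity"])
        ax1.axvline(report.threshold_db, linestyle=":", color="k")
        ax1.set_xlabel("channel SNR (dB)")
        ax1.set_ylabel("occlusion sensitivity (mean |dP|)")
        ax1.set_title(f"Spearman rho = {report.rho:.2f}")
        path = self.out / "snr_vs_occlusion.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path

    # -- orchestration ------------------------------------------------------
    def run_experiment(self) -> RunManifest:
        """All stages in order for every configured channel view."""
        self.stage_snr()
        self.stage_simulate()
        summaries = {}
        for view in self.config["views"]:
            self.stage_train(view)
            summaries[view] = self.stage_evaluate(view)
        if self.config["occlusion_view"]:
            ov = self.config["occlusion_view"]
            if ov not in self._models:
                self.stage_train(ov)
            self.stage_occlude()
        if len(summaries) >= 2:
            views = list(summaries)
            a, b = summaries[views[0]], summaries[views[1]]
            chi2, p = chi_square_2x2(
                a["n_correct"], a["n_test_patches"] - a["n_correct"],
                b["n_correct"], b["n_test_patches"] - b["n_correct"])
            cmp_path = self.out / "accuracy_comparison.json"
            cmp_path.write_text(json.dumps({
                "views": views[:2],
                "micro_accuracy": {views[0]: a["micro_accuracy"],
                                   views[1]: b["micro_accuracy"]},
                "chi2_statistic": chi2, "chi2_p": p}, indent=2))
            self.manifest.register("compare", [cmp_path], 0.0)
        self.write_report()
        self.manifest.save(self.out / "manifest.json")
        return self.manifest

    def write_report(self) -> Path:
        """Single human-readable summary; missing artifacts listed as absent."""
        lines = ["# MSI channel audit report", ""]

        def section(title: str, path: Path, fmt=None):
            lines.append(f"## {title}")
            if not path.exists():
                lines.append("_absent_")
            elif fmt:
                lines.append(fmt(path))
            else:
                lines.append(path.read_text().strip())
            lines.append("")

        section("Channel SNR (dB)", self.out / "snr_table.csv",
                lambda p: "```\n" + p.read_text().strip() + "\n```")
        section("Accuracy comparison", self.out / "accuracy_comparison.json",
                lambda p: "```json\n" + p.read_text().strip() + "\n```")
        rep = self.out / "snr_occlusion_report.json"
        if rep.exists():
            payload = json.loads(rep.read_text())
            lines += ["## SNR vs occlusion",
                      f"Spearman rho = {payload['rho']:.4f}; threshold "
                      f"{payload['threshold_db']} dB; below-threshold channels "
                      f"{payload['flagged_channels']} "
                      f"(inert: {payload['flagged_null']})", ""]
        else:
            lines += ["## SNR vs occlusion", "_absent_", ""]
        for title, name in [("Occlusion heatmap", "snr_vs_occlusion.png"),
                            ("Patch counts", "patches/patch_counts.csv")]:
            section(title, self.out / name,
                    (lambda p: f"![{p.name}]({p.name})") if name.endswith("png")
                    else (lambda p: "```\n" + p.read_text().strip() + "\n```"))
        path = self.out / "report.md"
        path.write_text("\n".join(lines))
        return path


def run_experiment(config: Mapping[str, Any] | None, out_dir: str | Path,
                   seed: int | None = None) -> RunManifest:
    return Pipeline(config, out_dir, seed=seed).run_experiment()
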