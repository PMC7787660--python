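"""End-to-end orchestration: synthesize → register → quantify → report.

``run_pipeline`` executes the full correlative analysis on a synthetic
scene with a fixed seed: ground-truth generation, element-map rendering,
frame misalignment and fiducial-based registration, LOD table from blank
measurements, masked colocalization matrix, S/Zn stoichiometry over
filament ROIs, and the grouped fluorescence comparison. Every stage writes
its own JSON (plus TIFF/CSV assets) into the run directory; a stage whose
configuration hash is unchanged is skipped on rerun.
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

from . import colocalization as coloc
from . import fluor_quant, stoichiometry, synthetic_scene, xrf_quant
from .registration import fit_affine_from_fiducials
from .synthetic_scene import SceneConfig

__all__ = ["RunConfig", "run_pipeline", "make_overlay", "select_filament_rois"]

logger = logging.getLogger(__name__)


def _default_effects() -> dict[str, float]:
    return {"control": 1.0, "treated": 0.7, "rescued": 1.0}


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    seed: int = 0
    mirror: bool = True
    n_blanks: int = 12
    lod_k: float = 3.0
    n_rois: int = 21
    roi_window_px: int = 5
    coloc_policy: str = "union"
    coloc_elements: tuple[str, ...] = ("P", "S", "Zn")
    n_images_per_group: int = 20
    effects: dict[str, float] = field(default_factory=_default_effects)
    fluor_baseline: float = 100.0
    fluor_sigma_log: float = 0.30
    s_per_molecule: int = 49
    fasta_path: str | None = None
    stages: tuple[str, ...] = ("scene", "lod", "registration", "coloc", "stoichiometry", "fluor")

    def __post_init__(self) -> None:
        if not isinstance(self.scene, SceneConfig):
            self.scene = SceneConfig(**self.scene)
        self.scene = dataclasses.replace(self.scene, seed=int(self.seed))
        unknown = set(self.stages) - {"scene", "lod", "registration", "coloc",
                                      "stoichiometry", "fluor"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    # --- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["coloc_elements"] = list(self.coloc_elements)
        d["scene"]["field_size_nm"] = list(self.scene.field_size_nm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scene" in d and isinstance(d["scene"], dict):
            scene_known = {f.name for f in dataclasses.fields(SceneConfig)}
            bad = set(d["scene"]) - scene_known
            if bad:
                raise ValueError(f"unknown scene config keys: {sorted(bad)}")
            blanks = d["scene"].get("blank_level_ng_mm2")
            d["scene"] = SceneConfig(**d["scene"])
            if blanks is not None:
                d["scene"].blank_level_ng_mm2 = dict(blanks)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "coloc_elements" in d:
            d["coloc_elements"] = tuple(d["coloc_elements"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _stage_hash(name: str, config: RunConfig) -> str:
    payload = json.dumps({"stage": name, "config": config.to_dict()}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _stage_cached(outdir: Path, name: str, config: RunConfig) -> bool:
    hash_file = outdir / f"{name}.hash"
    out_file = outdir / f"{name}.json"
    return (
        hash_file.exists()
        and out_file.exists()
        and hash_file.read_text() == _stage_hash(name, config)
    )


def _finish_stage(outdir: Path, name: str, config: RunConfig, result: dict) -> dict:
    (outdir / f"{name}.json").write_text(json.dumps(result, indent=1, default=float))
    (outdir / f"{name}.hash").write_text(_stage_hash(name, config))
    logger.info("stage %s done (hash %s)", name, _stage_hash(name, config)[:12])
    return result


def select_filament_rois(
    scene, n: int = 21, window_px: int = 5, min_separation_px: int = 8, seed: int = 0
) -> list[np.ndarray]:
    """ROI masks centred on filament pixels, spaced apart.

    Each ROI is the intersection of the filament mask with a
    ``window_px``-wide square window, i.e. a short stretch of microtubule.
    """
    rng = np.random.default_rng(seed)
    fil = scene.masks["dendrite"]
    coords = np.argwhere(fil)
    order = rng.permutation(len(coords))
    chosen: list[np.ndarray] = []
    rois: list[np.ndarray] = []
    half = window_px // 2
    for idx in order:
        r, c = coords[idx]
        if any(abs(r - rr) + abs(c - cc) < min_separation_px for rr, cc in chosen):
            continue
        window = np.zeros_like(fil)
        window[max(0, r - half): r + half + 1, max(0, c - half): c + half + 1] = True
        mask = window & fil
        if mask.sum() < 4:
            continue
        chosen.append((r, c))
        rois.append(mask)
        if len(rois) == n:
            break
    return rois


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all configured stages; returns the aggregated report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"seed": config.seed, "stages": {}}

    scene = synthetic_scene.generate_scene(config.scene)
    maps_noisy = synthetic_scene.render_element_maps(scene, noise=True)

    # --- scene assets -------------------------------------------------------
    if "scene" in config.stages:
        if _stage_cached(outdir, "scene", config):
            report["stages"]["scene"] = json.loads((outdir / "scene.json").read_text())
        else:
            for el, em in maps_noisy.items():
                em.write_tiff(outdir / f"xrf_{el}.tif")
            sted, sted_px = synthetic_scene.render_protein_image(scene, "tubulin", "sted")
            import tifffile

            tifffile.imwrite(outdir / "sted_tubulin.tif", sted.astype(np.float32))
            scene.fiducials.to_csv(outdir / "fiducials_optical.csv")
            result = {
                "pixel_size_nm": config.scene.pixel_size_nm,
                "sted_pixel_size_nm": sted_px,
                "elements": list(maps_noisy),
                "n_filament_pixels": int(scene.masks["dendrite"].sum()),
            }
            report["stages"]["scene"] = _finish_stage(outdir, "scene", config, result)

    # --- LOD ----------------------------------------------------------------
    if "lod" in config.stages:
        if _stage_cached(outdir, "lod", config):
            report["stages"]["lod"] = json.loads((outdir / "lod.json").read_text())
        else:
            blanks = synthetic_scene.simulate_blank_measurements(config.scene, n=config.n_blanks)
            pd.DataFrame(blanks).to_csv(outdir / "blanks.csv", index=False)
            table = xrf_quant.lod_report(
                blanks, k=config.lod_k, pixel_size_nm=config.scene.pixel_size_nm
            )
            table.to_csv(outdir / "lod_table.csv")
            result = {"k": config.lod_k, "n_blanks": config.n_blanks,
                      "table": table.reset_index().to_dict(orient="records")}
            report["stages"]["lod"] = _finish_stage(outdir, "lod", config, result)

    # --- registration ---------------------------------------------------------
    registered_maps = maps_noisy
    if "registration" in config.stages:
        frame = synthetic_scene.make_misaligned_frame(
            scene, maps=maps_noisy, mirror=config.mirror
        )
        fitted = fit_affine_from_fiducials(frame.src_fiducials, frame.dst_fiducials)
        resid = np.abs(
            fitted.apply(frame.src_fiducials.as_array()) - frame.dst_fiducials.as_array()
        ).max()
        true_vs_fit = np.abs(fitted.matrix - frame.transform.matrix).max()
        if _stage_cached(outdir, "registration", config):
            report["stages"]["registration"] = json.loads(
                (outdir / "registration.json").read_text()
            )
        else:
            fitted.to_json(outdir / "transform.json")
            frame.dst_fiducials.to_csv(outdir / "fiducials_synchrotron.csv")
            result = {
                "fiducial_residual_nm": float(resid),
                "linear_part_max_error": float(true_vs_fit),
                "mirror_detected": fitted.is_mirror,
                "mirror_requested": config.mirror,
                "determinant": fitted.determinant,
            }
            report["stages"]["registration"] = _finish_stage(
                outdir, "registration", config, result
            )

    # --- colocalization -------------------------------------------------------
    atoms_maps = {
        el: xrf_quant.areal_density_to_atoms(em) for el, em in registered_maps.items()
    }
    if "coloc" in config.stages:
        if _stage_cached(outdir, "coloc", config):
            report["stages"]["coloc"] = json.loads((outdir / "coloc.json").read_text())
        else:
            results = []
            els = [e for e in config.coloc_elements if e in atoms_maps]
            for i, a in enumerate(els):
                for b in els[i + 1:]:
                    res = coloc.masked_pearson(
                        atoms_maps[a], atoms_maps[b], policy=config.coloc_policy, names=(a, b)
                    )
                    results.append(dataclasses.asdict(res))
            result = {"policy": config.coloc_policy, "pairs": results}
            report["stages"]["coloc"] = _finish_stage(outdir, "coloc", config, result)

    # --- stoichiometry ----------------------------------------------------------
    if "stoichiometry" in config.stages:
        if _stage_cached(outdir, "stoichiometry", config):
            report["stages"]["stoichiometry"] = json.loads(
                (outdir / "stoichiometry.json").read_text()
            )
        else:
            rois = select_filament_rois(
                scene, n=config.n_rois, window_px=config.roi_window_px, seed=config.seed
            )
            ratios, excluded = stoichiometry.compute_roi_ratios(
                atoms_maps["S"], atoms_maps["Zn"], rois,
                pixel_size_nm=config.scene.pixel_size_nm,
            )
            s_per_mol = (
                stoichiometry.sulfur_atoms_from_fasta(config.fasta_path)
                if config.fasta_path
                else config.s_per_molecule
            )
            summary = stoichiometry.StoichiometrySummary(
                numerator_element="S",
                denominator_element="Zn",
                ratios=ratios,
                n_excluded=excluded,
                s_per_molecule=s_per_mol,
            )
            pd.DataFrame({"ratio_S_Zn": ratios}).to_csv(outdir / "roi_ratios.csv", index=False)
            result = {
                "ratio_mean": summary.ratio_mean,
                "ratio_sd": summary.ratio_sd,
                "n_rois": summary.n,
                "n_excluded": excluded,
                "s_per_molecule": s_per_mol,
                "molecules_per_metal": summary.molecules_per_metal(),
            }
            report["stages"]["stoichiometry"] = _finish_stage(
                outdir, "stoichiometry", config, result
            )

    # --- grouped fluorescence ---------------------------------------------------
    if "fluor" in config.stages:
        if _stage_cached(outdir, "fluor", config):
            report["stages"]["fluor"] = json.loads((outdir / "fluor.json").read_text())
        else:
            images = synthetic_scene.generate_group_images(
                config.n_images_per_group,
                config.effects,
                seed=config.seed + 5000,
                baseline=config.fluor_baseline,
                sigma_log=config.fluor_sigma_log,
            )
            rows = []
            for im in images:
                thr = fluor_quant.mode_threshold(im.image)
                meas = fluor_quant.measure_image(im.image, thr, im.soma_mask)
                rows.append(
                    {"group": im.group, "replicate": im.replicate,
                     "value": meas.mean_intensity, "n_pixels": meas.n_pixels,
                     "excluded": meas.excluded}
                )
            df = pd.DataFrame(rows)
            df = df[~df["excluded"]].copy()
            df["normalized"] = fluor_quant.normalize_to_control(
                df, value_col="value", replicate_col="replicate"
            )
            df.to_csv(outdir / "fluor_per_image.csv", index=False)
            groups = {
                g: sub["normalized"].to_numpy() for g, sub in df.groupby("group")
            }
            rep = fluor_quant.compare_groups(groups)
            result = {
                "groups": rep.groups,
                "normality_p": rep.normality_p,
                "variance_homogeneity_p": rep.variance_homogeneity_p,
                "omnibus_test": rep.omnibus_test,
                "omnibus_p": rep.omnibus_p,
                "decision_path": rep.decision_path,
                "pairwise": (
                    rep.pairwise.to_dict(orient="records") if rep.pairwise is not None else None
                ),
            }
            report["stages"]["fluor"] = _finish_stage(outdir, "fluor", config, result)

    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def make_overlay(
    channels: dict[str, np.ndarray],
    colors: dict[str, tuple[float, float, float]] | None = None,
    pixel_size_nm: float = 40.0,
    path: str | Path | None = None,
) -> np.ndarray:
    """Min-max scaled multichannel composite (RGBA), missing pixels transparent.

    Display scaling never alters the underlying data; raw maps stay as
    written by the stages.
    """
    default_colors = [(0.0, 1.0, 0.0), (1.0, 0.0, 0.0), (0.0, 0.4, 1.0)]
    names = list(channels)
    shapes = {channels[n].shape for n in names}
    if len(shapes) != 1:
        raise ValueError("all channels must share a grid; resample first")
    shape = shapes.pop()
    rgba = np.zeros((*shape, 4))
    any_valid = np.zeros(shape, dtype=bool)
    for i, name in enumerate(names):
        data = np.asarray(channels[name], dtype=float)
        valid = np.isfinite(data)
        any_valid |= valid
        lo = np.nanmin(data) if valid.any() else 0.0
        hi = np.nanmax(data) if valid.any() else 1.0
        scaled = np.zeros(shape)
        if hi > lo:
            scaled[valid] = (data[valid] - lo) / (hi - lo)
        elif valid.any():
            scaled[valid] = 1.0
        color = (colors or {}).get(name, default_colors[i % len(default_colors)])
        for c in range(3):
            rgba[..., c] = np.clip(rgba[..., c] + color[c] * scaled, 0, 1)
    rgba[..., 3] = any_valid.astype(float)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(rgba)
        ax.set_axis_off()
        # scale bar: 1 µm
        bar_px = 1000.0 / pixel_size_nm
        ax.plot([5, 5 + bar_px], [shape[0] - 6, shape[0] - 6], color="w", lw=3)
        ax.text(5, shape[0] - 10, "1 µm", color="w", fontsize=9)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return rgba
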