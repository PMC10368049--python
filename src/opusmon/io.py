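"""On-disk containers, pipeline configuration and the end-to-end runner.

RF records and derived images live in HDF5 (self-describing, metadata-rich);
depth traces are CSV, agreement reports JSON, and display exports PNG.
The pipeline configuration is a YAML/JSON document whose blocks mirror the
in-memory parameter dataclasses field-for-field; unknown keys are rejected
with a named error so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .records import RFRecord, MModeImage, DepthTrace, GroundTruth
from .simulate import SimulationConfig, simulate_mmode
from .preprocess import FilterSpec
from .mmode import FCMParams, track_lesion_depth
from .evaluate import compare_depths

logger = logging.getLogger("opusmon")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration content."""


# ---------------------------------------------------------------------------
# RF record container
# ---------------------------------------------------------------------------

def write_record(path: str | Path, record: RFRecord,
                 truth: Optional[GroundTruth] = None) -> None:
    """Write an RF record (and optional simulation ground truth) to HDF5.

    The RF matrix is stored as float64 so the round-trip is bit-exact.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("record")
        g.create_dataset("rf", data=record.data, dtype="f8")
        g.attrs["sampling_rate"] = record.sampling_rate
        g.attrs["sound_speed"] = record.sound_speed
        g.attrs["t0"] = record.t0
        if record.is_mmode:
            g.attrs["prf"] = record.prf
        else:
            g.attrs["lateral_step"] = record.lateral_step
        if truth is not None:
            tg = f.create_group("ground_truth")
            tg.create_dataset("time_s", data=truth.time_s, dtype="f8")
            tg.create_dataset("lesion_extent_mm", data=truth.lesion_extent_mm, dtype="f8")
            tg.attrs["fibre_tip_depth_mm"] = truth.fibre_tip_depth_mm
            tg.attrs["laser_on_index"] = truth.laser_on_index
            tg.attrs["laser_off_index"] = truth.laser_off_index
            tg.attrs["crosstalk_n_samples"] = truth.crosstalk_n_samples


def read_record(path: str | Path) -> RFRecord:
    with h5py.File(path, "r") as f:
        g = f["record"]
        return RFRecord(
            data=g["rf"][()],
            sampling_rate=float(g.attrs["sampling_rate"]),
            sound_speed=float(g.attrs["sound_speed"]),
            prf=float(g.attrs["prf"]) if "prf" in g.attrs else None,
            lateral_step=(
                float(g.attrs["lateral_step"]) if "lateral_step" in g.attrs else None
            ),
            t0=float(g.attrs["t0"]),
        )


def read_ground_truth(path: str | Path) -> Optional[GroundTruth]:
    with h5py.File(path, "r") as f:
        if "ground_truth" not in f:
            return None
        tg = f["ground_truth"]
        return GroundTruth(
            time_s=tg["time_s"][()],
            lesion_extent_mm=tg["lesion_extent_mm"][()],
            fibre_tip_depth_mm=float(tg.attrs["fibre_tip_depth_mm"]),
            laser_on_index=int(tg.attrs["laser_on_index"]),
            laser_off_index=int(tg.attrs["laser_off_index"]),
            crosstalk_n_samples=int(tg.attrs["crosstalk_n_samples"]),
        )


def write_mmode_image(path: str | Path, image: MModeImage) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("mmode_image")
        g.create_dataset("pixels", data=image.pixels, dtype="f8")
        g.create_dataset("depth_axis_mm", data=image.depth_axis_mm, dtype="f8")
        g.create_dataset("time_axis_s", data=image.time_axis_s, dtype="f8")
        g.attrs["laser_on_index"] = image.laser_on_index
        g.attrs["laser_off_index"] = image.laser_off_index
        g.attrs["dynamic_range_db"] = image.dynamic_range_db


def read_mmode_image(path: str | Path) -> MModeImage:
    with h5py.File(path, "r") as f:
        g = f["mmode_image"]
        return MModeImage(
            pixels=g["pixels"][()],
            depth_axis_mm=g["depth_axis_mm"][()],
            time_axis_s=g["time_axis_s"][()],
            laser_on_index=int(g.attrs["laser_on_index"]),
            laser_off_index=int(g.attrs["laser_off_index"]),
            dynamic_range_db=float(g.attrs["dynamic_range_db"]),
        )


def write_depth_trace(path: str | Path, trace: DepthTrace) -> None:
    pd.DataFrame({"time_s": trace.time_s, "depth_mm": trace.depth_mm}).to_csv(
        path, index=False
    )


def read_depth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

def _from_block(cls, block: Dict[str, Any], name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config block {name!r}"
        )
    return cls(**block)


@dataclass
class PipelineConfig:
    """Nested parameter blocks for a full monitoring run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    fcm: FCMParams = field(default_factory=FCMParams)
    structuring_radius: int = 1
    closing_radius: Optional[int] = None  # None: sized from the axial speckle scale
    dynamic_range_db: float = 40.0
    glm_shifts: int = 1
    seed: Optional[int] = None  # overrides simulation.rng_seed when given

    _BLOCKS = {"simulation": SimulationConfig, "filter": FilterSpec, "fcm": FCMParams}
    _SCALARS = {"structuring_radius", "closing_radius", "dynamic_range_db",
                "glm_shifts", "seed"}

    @classmethod
    def from_dict(cls, doc: Dict[str, Any]) -> "PipelineConfig":
        unknown = set(doc) - set(cls._BLOCKS) - cls._SCALARS
        if unknown:
            raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs: Dict[str, Any] = {}
        for name, sub_cls in cls._BLOCKS.items():
            if name in doc:
                block = doc[name]
                if not isinstance(block, dict):
                    raise ConfigError(f"config block {name!r} must be a mapping")
                kwargs[name] = _from_block(sub_cls, block, name)
        for name in cls._SCALARS:
            if name in doc:
                kwargs[name] = doc[name]
        cfg = cls(**kwargs)
        if cfg.seed is not None:
            cfg.simulation = dataclasses.replace(cfg.simulation, rng_seed=int(cfg.seed))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> Dict[str, Any]:
        return {
            "simulation": dataclasses.asdict(self.simulation),
            "filter": dataclasses.asdict(self.filter),
            "fcm": dataclasses.asdict(self.fcm),
            "structuring_radius": self.structuring_radius,
            "closing_radius": self.closing_radius,
            "dynamic_range_db": self.dynamic_range_db,
            "glm_shifts": self.glm_shifts,
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Dict[str, Any]:
    """Simulate, process, segment and evaluate one monitoring procedure.

    Writes the artifact bundle (RF record, M-mode image, mask, depth CSV,
    report JSON) under ``out_dir`` and returns the in-memory results.
    Deterministic for a fixed config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    logger.info("simulate: %d samples x %d acquisitions, seed %d",
                sim.n_samples, sim.resolve_n_acquisitions(), sim.rng_seed)
    record, truth = simulate_mmode(sim)
    write_record(out / "record.h5", record, truth)

    logger.info("process+segment: band %g-%g Hz, c=%d clusters",
                config.filter.low_cut, config.filter.high_cut, config.fcm.n_clusters)
    image, mask, trace = track_lesion_depth(
        record,
        laser_on_s=sim.laser_on_time,
        laser_off_s=sim.laser_on_time + sim.laser_duration,
        filter_spec=config.filter,
        fcm_params=config.fcm,
        structuring_radius=config.structuring_radius,
        closing_radius=config.closing_radius,
        dynamic_range_db=config.dynamic_range_db,
        glm_shifts=config.glm_shifts,
        glm_fit_depth_mm=sim.surface_depth + 0.5,
    )
    write_mmode_image(out / "mmode_image.h5", image)
    with h5py.File(out / "lesion_mask.h5", "w") as f:
        f.create_dataset("mask", data=mask.mask)
    write_depth_trace(out / "depth_trace.csv", trace)

    report = {
        "final_depth_mm": trace.final_depth_mm,
        "true_final_extent_mm": truth.final_extent_mm,
        "depth_error_mm": trace.final_depth_mm - truth.final_extent_mm,
        "n_acquisitions": record.n_acquisitions,
        "fcm_iterations": mask.n_iter,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("final depth %.2f mm (truth %.2f mm)",
                trace.final_depth_mm, truth.final_extent_mm)
    return {
        "record": record,
        "truth": truth,
        "image": image,
        "mask": mask,
        "trace": trace,
        "report": report,
    }


def export_mmode_png(image: MModeImage, path: str | Path,
                     mask: Optional[np.ndarray] = None) -> None:
    """Display export: M-mode image in dB with an optional mask boundary."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    extent = [image.time_axis_s[0], image.time_axis_s[-1],
              image.depth_axis_mm[-1], image.depth_axis_mm[0]]
    im = ax.imshow(image.pixels, aspect="auto", cmap="gray", extent=extent,
                   vmin=-image.dynamic_range_db, vmax=0)
    if mask is not None and mask.any():
        ax.contour(mask, levels=[0.5], colors="g", linewidths=0.8,
                   extent=extent, origin="upper")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("depth (mm)")
    fig.colorbar(im, ax=ax, label="dB")
    fig.savefig(path, dpi=150)
    plt.close(fig)
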