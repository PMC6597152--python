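"""Text formats, configuration and dataset manifests.

All on-disk formats are plain text: contours as CSV (frame, point_index,
x_um, y_um), gridded maps as whitespace-delimited grids with a JSON sidecar,
datasets as a directory with a JSON manifest.  Lengths are um, times hours;
density unit conventions are recorded in sidecars.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import ExperimentDataset
from .kinematics import DensityRatioMap, DisplacementField
from .model import ModelConfig, ParameterSet, PriorSpec
from .simulator import BoundaryContour, FrameSeries, Grid, Schedule

__all__ = [
    "RunConfig",
    "write_contours",
    "read_contours",
    "write_ratio_map",
    "read_ratio_map",
    "write_displacement_field",
    "read_displacement_field",
    "write_dataset",
    "read_dataset",
    "write_series",
]


@dataclass
class RunConfig:
    """Everything needed to re-run a pipeline stage.

    Defaults equal the printed protocol constants wherever one exists:
    w=1000, threshold=1500, delta=5, 5-minute frames, 10 h, and the broad
    uniform prior bounds.
    """

    grid: Grid = field(default_factory=lambda: Grid.square(3000.0, 10.0, x0=-1500.0, y0=-1500.0))
    schedule: Schedule = field(default_factory=Schedule)
    model: ModelConfig = field(default_factory=ModelConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    threshold: float = 1500.0
    n_accept: int = 200
    budget: int | None = None
    w: float = 1000.0
    fraction: float = 0.2
    level: float = 0.95
    delta: int = 5
    seed: int = 0
    outdir: str = "out"
    verbosity: int = 1

    def to_dict(self) -> dict:
        return {
            "grid": dataclasses.asdict(self.grid),
            "schedule": dataclasses.asdict(self.schedule),
            "model": dataclasses.asdict(self.model),
            "priors": self.priors.to_dict(),
            "threshold": self.threshold, "n_accept": self.n_accept,
            "budget": self.budget, "w": self.w, "fraction": self.fraction,
            "level": self.level, "delta": self.delta, "seed": self.seed,
            "outdir": self.outdir, "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "grid" in kwargs:
            kwargs["grid"] = Grid(**kwargs["grid"])
        if "schedule" in kwargs:
            kwargs["schedule"] = Schedule(**kwargs["schedule"])
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "priors" in kwargs:
            kwargs["priors"] = PriorSpec.from_dict(kwargs["priors"])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=False) \
            if path.suffix in {".yaml", ".yml"} else json.dumps(self.to_dict(), indent=2)
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        d = yaml.safe_load(path.read_text()) if path.suffix in {".yaml", ".yml"} \
            else json.loads(path.read_text())
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# contours


def write_contours(contours: list[BoundaryContour], path: str | Path) -> None:
    rows = []
    for f, c in enumerate(contours):
        for i, (x, y) in enumerate(c.points):
            rows.append((f, i, x, y))
    pd.DataFrame(rows, columns=["frame", "point_index", "x_um", "y_um"]) \
        .to_csv(path, index=False)


def read_contours(path: str | Path) -> list[BoundaryContour]:
    """Per-frame contours from CSV; resorts shuffled point indices (warning)."""
    df = pd.read_csv(path)
    expected = ["frame", "point_index", "x_um", "y_um"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}, "
                         f"got {','.join(map(str, df.columns))}")
    if df[expected].isna().any().any():
        bad = int(df[df[expected].isna().any(axis=1)].index[0]) + 2  # 1-based + header
        raise ValueError(f"{path}: malformed row at line {bad}")
    contours = []
    for f in sorted(df["frame"].unique()):
        sub = df[df["frame"] == f]
        if not sub["point_index"].is_monotonic_increasing:
            warnings.warn(f"{path}: frame {f} points out of order; re-sorting")
            sub = sub.sort_values("point_index")
        pts = sub[["x_um", "y_um"]].to_numpy()
        if len(pts) < 8:
            raise ValueError(f"{path}: frame {f} has {len(pts)} points (minimum 8)")
        contours.append(BoundaryContour(pts))
    return contours


# ---------------------------------------------------------------------------
# ratio maps


def write_ratio_map(m: DensityRatioMap, basepath: str | Path) -> None:
    base = Path(basepath)
    np.savetxt(base.with_suffix(".xi.txt"), m.xi)
    np.savetxt(base.with_suffix(".mask.txt"), m.mask.astype(int), fmt="%d")
    sidecar = {"pixel_size_um": m.pixel_size_um, "origin": list(m.origin),
               "frame_j": m.frame_j, "delta": m.delta,
               "units": "ratio (dimensionless); grid row-major, x along columns"}
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_ratio_map(basepath: str | Path) -> DensityRatioMap:
    base = Path(basepath)
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sc = json.loads(sidecar_path.read_text())
    xi = np.atleast_2d(np.loadtxt(base.with_suffix(".xi.txt")))
    mask = np.atleast_2d(np.loadtxt(base.with_suffix(".mask.txt"))).astype(bool)
    if xi.shape != mask.shape:
        raise ValueError(f"{base}: ratio grid {xi.shape} and mask {mask.shape} differ")
    if not mask.any():
        warnings.warn(f"{base}: mask is empty")
    return DensityRatioMap(xi=np.where(mask, xi, 0.0), mask=mask,
                           frame_j=sc["frame_j"], delta=sc["delta"],
                           pixel_size_um=sc["pixel_size_um"],
                           origin=tuple(sc["origin"]))


def write_displacement_field(u: DisplacementField, basepath: str | Path) -> None:
    """Paired delimited-text grids (one per component) plus a JSON sidecar."""
    base = Path(basepath)
    np.savetxt(base.with_suffix(".ux.txt"), u.u_x)
    np.savetxt(base.with_suffix(".uy.txt"), u.u_y)
    sidecar = {"pixel_size_um": u.pixel_size_um, "frame_j": u.frame_j,
               "delta": u.delta, "units": "um; row-major, x along columns"}
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_displacement_field(basepath: str | Path) -> DisplacementField:
    base = Path(basepath)
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sc = json.loads(sidecar_path.read_text())
    return DisplacementField(u_x=np.atleast_2d(np.loadtxt(base.with_suffix(".ux.txt"))),
                             u_y=np.atleast_2d(np.loadtxt(base.with_suffix(".uy.txt"))),
                             pixel_size_um=sc["pixel_size_um"],
                             frame_j=sc["frame_j"], delta=sc["delta"])


# ---------------------------------------------------------------------------
# datasets and simulation output


def write_dataset(dataset: ExperimentDataset, outdir: str | Path,
                  ground_truth: dict | None = None) -> Path:
    """Write a dataset directory with a machine-readable manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_contours(dataset.contours, outdir / "contours.csv")
    write_contours([dataset.initial_contour], outdir / "initial_contour.csv")
    maps = []
    for j, m in sorted(dataset.ratio_maps.items()):
        base = outdir / f"ratio_{j:04d}"
        write_ratio_map(m, base)
        maps.append({"j": j, "base": base.name})
    manifest = {
        "times_h": dataset.times.tolist(),
        "delta": dataset.delta,
        "pixel_size_um": dataset.pixel_size_um,
        "contours": "contours.csv",
        "initial_contour": "initial_contour.csv",
        "ratio_maps": maps,
    }
    if ground_truth is not None:
        gt = {"theta_star": ground_truth["theta_star"].to_dict(),
              "seed": ground_truth["seed"]}
        proto = ground_truth.get("protocol")
        if proto is not None:
            pd_ = dataclasses.asdict(proto)
            pd_["theta_star"] = proto.theta_star.to_dict()
            gt["protocol"] = pd_
        manifest["ground_truth"] = gt
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"


def read_dataset(path: str | Path) -> tuple[ExperimentDataset, dict | None]:
    """Load a dataset directory (path to the directory or its manifest)."""
    path = Path(path)
    manifest_path = path if path.name == "manifest.json" else path / "manifest.json"
    root = manifest_path.parent
    mf = json.loads(manifest_path.read_text())
    contours = read_contours(root / mf["contours"])
    init = read_contours(root / mf["initial_contour"])[0] if mf.get("initial_contour") else None
    maps = {entry["j"]: read_ratio_map(root / entry["base"])
            for entry in mf["ratio_maps"]}
    ds = ExperimentDataset(times=np.array(mf["times_h"]), contours=contours,
                           ratio_maps=maps, delta=mf["delta"],
                           pixel_size_um=mf.get("pixel_size_um"),
                           init_contour=init)
    return ds, mf.get("ground_truth")


def write_series(series: FrameSeries, outdir: str | Path,
                 params: ParameterSet | None = None,
                 config: RunConfig | None = None) -> Path:
    """Export a simulation: contours CSV, density grids, metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_contours(series.contours, outdir / "contours.csv")
    for k, rho in enumerate(series.densities):
        np.savetxt(outdir / f"density_{k:04d}.txt", rho)
    meta = {
        "times_h": series.times.tolist(),
        "grid": dataclasses.asdict(series.grid),
        "escaped": series.escaped,
        "center_node": list(series.center_node),
        "center_density": series.center_density.tolist(),
        "density_unit": "cells/mm^2",
    }
    if params is not None:
        meta["params"] = params.to_dict()
    (outdir / "series.json").write_text(json.dumps(meta, indent=2))
    return outdir / "series.json"
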