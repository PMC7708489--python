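"""Readers/writers for acquisitions and results, configuration and manifests.

HDF5 is the canonical interchange format (lossless round trip of stacks,
patterns and complex matrices; complex data is stored as paired real
datasets for portability).  Multi-page TIFF export is provided for
interoperability with microscopy tools; frames are quantized to uint16 with
the scale recorded in the image description, so the round trip is accurate
to half a scale unit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .optics_sim import EmitterMap, PhasePatternSet, SimulationConfig, SpeckleStack

__all__ = [
    "ConfigError",
    "write_stack_h5",
    "read_stack_h5",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_emitters_csv",
    "read_emitters_csv",
    "write_complex_matrix",
    "read_complex_matrix",
    "config_to_yaml",
    "config_from_yaml",
    "sha256_file",
    "RunManifest",
]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration input."""


def write_stack_h5(
    path: str | Path,
    stack: SpeckleStack,
    patterns: PhasePatternSet | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=stack.images)
        if patterns is not None:
            f.create_dataset("phases", data=patterns.phases)
        meta = f.create_group("meta")
        meta.attrs["grid_shape"] = stack.grid_shape
        for k, v in stack.meta.items():
            try:
                meta.attrs[k] = v
            except TypeError:
                meta.attrs[k] = json.dumps(v)


def read_stack_h5(path: str | Path) -> tuple[SpeckleStack, PhasePatternSet | None]:
    with h5py.File(path, "r") as f:
        images = f["images"][()]
        meta_grp = f["meta"]
        grid_shape = tuple(int(s) for s in meta_grp.attrs["grid_shape"])
        meta = {k: meta_grp.attrs[k] for k in meta_grp.attrs if k != "grid_shape"}
        patterns = (
            PhasePatternSet(f["phases"][()]) if "phases" in f else None
        )
    return SpeckleStack(images=images, grid_shape=grid_shape, meta=meta), patterns


def write_stack_tiff(path: str | Path, stack: SpeckleStack) -> None:
    """Quantize frames to uint16 (shared linear scale) and write one page per frame."""
    peak = float(stack.images.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    frames = np.round(stack.images.T.reshape(stack.n_patterns, *stack.grid_shape) * scale)
    desc = json.dumps({"scale": scale, "grid_shape": stack.grid_shape})
    tifffile.imwrite(path, frames.astype(np.uint16), description=desc)


def read_stack_tiff(path: str | Path) -> SpeckleStack:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        desc = json.loads(tif.pages[0].description)
    if frames.ndim == 2:
        frames = frames[None]
    scale = float(desc["scale"])
    grid_shape = tuple(int(s) for s in desc["grid_shape"])
    images = (frames / scale).reshape(frames.shape[0], -1).T
    return SpeckleStack(images=images, grid_shape=grid_shape, meta={"source": str(path)})


def write_emitters_csv(path: str | Path, emitters: EmitterMap) -> None:
    with open(path, "w") as f:
        f.write("id,row,col,brightness\n")
        for k, (pos, b) in enumerate(zip(emitters.positions, emitters.brightness)):
            f.write(f"{k},{pos[0]},{pos[1]},{b}\n")


def read_emitters_csv(path: str | Path) -> EmitterMap:
    data = np.genfromtxt(path, delimiter=",", names=True)
    data = np.atleast_1d(data)
    positions = np.stack([data["row"], data["col"]], axis=1).astype(int)
    return EmitterMap(positions=positions, brightness=data["brightness"])


def write_complex_matrix(group: h5py.Group, name: str, matrix: np.ndarray) -> None:
    group.create_dataset(f"{name}_re", data=matrix.real)
    group.create_dataset(f"{name}_im", data=matrix.imag)


def read_complex_matrix(group: h5py.Group, name: str) -> np.ndarray:
    return group[f"{name}_re"][()] + 1j * group[f"{name}_im"][()]


def config_to_yaml(config: SimulationConfig) -> str:
    d = dataclasses.asdict(config)
    d["grid_shape"] = list(d["grid_shape"])
    if d["photon_budget"] == float("inf"):
        d["photon_budget"] = "inf"
    return yaml.safe_dump(d, sort_keys=True)


def config_from_yaml(text: str) -> SimulationConfig:
    try:
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ConfigError("simulation config must be a YAML mapping")
        if str(d.get("photon_budget", "inf")).lower() in ("inf", ".inf", "null", "none"):
            d["photon_budget"] = float("inf")
        d["grid_shape"] = tuple(d["grid_shape"])
        return SimulationConfig(**d)
    except (TypeError, KeyError, ValueError, yaml.YAMLError) as exc:
        raise ConfigError(f"bad simulation config: {exc}") from exc


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one pipeline run.

    Stores the configuration snapshot, the master seed, the named substreams
    derived from it, the package version, per-stage wall times, and a SHA-256
    hash of every file written.  A rerun with the same manifest reproduces
    noiseless outputs bit-exactly.
    """

    config_yaml: str
    master_seed: int
    substreams: dict = dataclasses.field(default_factory=dict)
    versions: dict = dataclasses.field(default_factory=dict)
    stage_timings: dict = dataclasses.field(default_factory=dict)
    file_hashes: dict = dataclasses.field(default_factory=dict)

    def record_file(self, path: str | Path) -> None:
        self.file_hashes[str(Path(path).name)] = sha256_file(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as f:
            return cls(**yaml.safe_load(f))
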