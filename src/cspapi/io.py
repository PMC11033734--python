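"""Serialization: JSON for matrices/phantoms/metrics, HDF5 for arrays.

Every saved object carries a ``schema_version`` field that is checked on
load, and matrices are re-validated against the block-structure constraint
so a corrupted or hand-edited file is rejected with the offending
row/block named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .cs_design import CSStructure, GroupMatrix, is_feasible, make_cs_matrix
from .wave_model import DetectorData, Disk, DiskPhantom, ImageGrid, SensorGeometry, TimeGrid

SCHEMA_VERSION = 1

__all__ = [
    "save_matrix",
    "load_matrix",
    "export_matrix_csv",
    "save_phantom",
    "load_phantom",
    "save_detector_data",
    "load_detector_data",
    "save_image",
    "load_image",
    "save_image_png",
    "save_metrics",
    "RunManifest",
    "write_manifest",
]


def _check_version(doc: dict, path) -> None:
    v = doc.get("schema_version")
    if v != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema_version {v!r}")


# ---------------------------------------------------------------- matrices


def save_matrix(
    path,
    matrix: GroupMatrix,
    s: int | None = None,
    achieved_sin: float | None = None,
    seed: int | None = None,
) -> None:
    """Write a group matrix (as its selection list) with its metadata."""
    st = matrix.structure
    doc = {
        "schema_version": SCHEMA_VERSION,
        "structure": {
            "m0": st.m0,
            "block_size": st.block_size,
            "blocks_per_group": st.blocks_per_group,
            "num_groups": st.num_groups,
        },
        "selection": matrix.selection().tolist(),
        "sparsity": s,
        "sin": achieved_sin,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_matrix(path) -> tuple[GroupMatrix, dict]:
    """Load and re-validate a matrix; returns (matrix, metadata)."""
    doc = json.loads(Path(path).read_text())
    _check_version(doc, path)
    st = CSStructure(**doc["structure"])
    gm = make_cs_matrix(np.array(doc["selection"]), st)
    if not is_feasible(gm.entries, st):
        raise ValueError(f"{path}: matrix violates the block constraint")
    meta = {k: doc.get(k) for k in ("sparsity", "sin", "seed")}
    return gm, meta


def export_matrix_csv(path, entries: np.ndarray) -> None:
    """Dense 0/1 CSV export of an (assembled) measurement matrix."""
    np.savetxt(path, np.asarray(entries, dtype=int), fmt="%d", delimiter=",")


# ---------------------------------------------------------------- phantoms


def save_phantom(path, phantom: DiskPhantom) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "disks": [
            {
                "center": list(d.center),
                "radius": d.radius,
                "amplitude": d.amplitude,
                "profile": d.profile,
                "kappa": d.kappa,
            }
            for d in phantom.disks
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_phantom(path) -> DiskPhantom:
    doc = json.loads(Path(path).read_text())
    _check_version(doc, path)
    return DiskPhantom(
        [
            Disk(
                center=tuple(d["center"]),
                radius=d["radius"],
                amplitude=d["amplitude"],
                profile=d.get("profile", "uniform"),
                kappa=d.get("kappa", 1.0),
            )
            for d in doc["disks"]
        ]
    )


# ---------------------------------------------------------------- arrays


def save_detector_data(path, data: DetectorData) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("values", data=data.values)
        ds.attrs["kind"] = data.kind
        ds.attrs["R"] = data.geometry.R
        ds.attrs["n"] = data.geometry.n
        ds.attrs["omega"] = data.geometry.omega
        ds.attrs["q"] = data.grid.q
        ds.attrs["schema_version"] = SCHEMA_VERSION


def load_detector_data(path) -> DetectorData:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["values"]
        if ds.attrs.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported schema_version")
        geom = SensorGeometry(
            R=float(ds.attrs["R"]), n=int(ds.attrs["n"]), omega=float(ds.attrs["omega"])
        )
        grid = TimeGrid(q=int(ds.attrs["q"]), R=float(ds.attrs["R"]))
        return DetectorData(str(ds.attrs["kind"]), ds[()], geom, grid)


def save_image(path, image: ImageGrid) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("values", data=image.values)
        ds.attrs["Nr"] = image.Nr
        ds.attrs["R"] = image.R
        ds.attrs["schema_version"] = SCHEMA_VERSION


def load_image(path) -> ImageGrid:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["values"]
        if ds.attrs.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported schema_version")
        return ImageGrid(Nr=int(ds.attrs["Nr"]), R=float(ds.attrs["R"]), values=ds[()])


def save_image_png(path, image: ImageGrid) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, image.values, origin="lower", cmap="viridis")


# ---------------------------------------------------------------- metrics


def save_metrics(path_csv, records, path_json=None) -> None:
    """Delimited metrics table (plus optional machine-readable JSON)."""
    import pandas as pd

    rows = [r.as_dict() for r in records]
    pd.DataFrame(rows).to_csv(path_csv, index=False)
    if path_json is not None:
        Path(path_json).write_text(json.dumps(rows, indent=1))


# ---------------------------------------------------------------- manifest


@dataclasses.dataclass
class RunManifest:
    """Record of one CLI run: resolved options, seeds, file checksums."""

    command: str
    options: dict
    seeds: dict
    outputs: dict = dataclasses.field(default_factory=dict)
    timestamp: str = ""
    package_version: str = ""


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, command: str, options: dict, seeds: dict, outputs) -> None:
    from . import __version__

    manifest = RunManifest(
        command=command,
        options={k: (str(v) if isinstance(v, Path) else v) for k, v in options.items()},
        seeds=seeds,
        outputs={str(p): _sha256(p) for p in outputs if Path(p).exists()},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        package_version=__version__,
    )
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=1))
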