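"""File formats: labeled point-cloud CSV/PLY, manifests, result tables.

CSV dialect: header ``x,y,z,label`` exactly, coordinates in mm with a
decimal point, one point per row.  PLY dialect: one ASCII 1.0 file per
structure, named ``<id>_<label>.ply``, vertex elements with float
x/y/z properties.  A ground-truth JSON sidecar accompanies simulated
phantoms.  No global anatomical registration is assumed in any file —
the scapular frame is always re-derived from the points themselves.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .phantom import ScapulaPhantom

__all__ = [
    "VALID_LABELS",
    "WALCH_CLASSES",
    "SIRVEAUX_CLASSES",
    "CloudFormatError",
    "read_labeled_clouds",
    "read_cloud_csv",
    "read_cloud_ply_set",
    "write_cloud_csv",
    "write_cloud_ply_set",
    "write_phantom",
    "read_ground_truth",
    "read_manifest",
    "results_to_frame",
]

VALID_LABELS = frozenset(
    {"glenoid", "blade", "ridge", "humeral_head", "paleoglenoid", "neoglenoid"}
)
WALCH_CLASSES = frozenset({"A1", "A2", "B1", "B2", "B3", "C"})
SIRVEAUX_CLASSES = frozenset({"E0", "E1", "E2", "E3", "E4"})


class CloudFormatError(ValueError):
    """A cloud file does not conform to the expected dialect."""


def read_cloud_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Read one ``x,y,z,label`` CSV into clouds keyed by label."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"label": str})
    except Exception as exc:  # malformed CSV structure
        raise CloudFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if list(df.columns) != ["x", "y", "z", "label"]:
        raise CloudFormatError(
            f"{path}: expected columns x,y,z,label, got {list(df.columns)}"
        )
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna().to_numpy())
        if len(bad):
            # +2: header line plus 1-based numbering
            raise CloudFormatError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = coerced
    unknown = ~df["label"].isin(sorted(VALID_LABELS)).to_numpy()
    if unknown.any():
        line = int(np.flatnonzero(unknown)[0]) + 2
        raise CloudFormatError(
            f"{path}: unknown label {df['label'].iloc[line - 2]!r} at line {line}"
        )
    clouds: dict[str, np.ndarray] = {}
    for label, group in df.groupby("label", sort=False):
        clouds[str(label)] = group[["x", "y", "z"]].to_numpy(dtype=float)
    return clouds


def read_cloud_ply_set(paths: list[str | Path]) -> dict[str, np.ndarray]:
    """Read per-structure ASCII PLY files named ``<id>_<label>.ply``."""
    clouds: dict[str, np.ndarray] = {}
    for path in paths:
        path = Path(path)
        label = path.stem.rsplit("_", 1)[-1]
        if label == "humeralhead" or path.stem.endswith("humeral_head"):
            label = "humeral_head"
        if label not in VALID_LABELS:
            raise CloudFormatError(f"{path}: cannot infer a known label from filename")
        try:
            mesh = trimesh.load(str(path), file_type="ply")
        except Exception as exc:
            raise CloudFormatError(f"{path}: cannot parse PLY ({exc})") from exc
        vertices = np.asarray(mesh.vertices, dtype=float)
        if vertices.ndim != 2 or vertices.shape[1] != 3 or len(vertices) == 0:
            raise CloudFormatError(f"{path}: no vertices found")
        clouds[label] = vertices
    return clouds


def read_labeled_clouds(source) -> dict[str, np.ndarray]:
    """Read labeled clouds from one CSV path or a list of PLY paths."""
    if isinstance(source, (str, Path)):
        return read_cloud_csv(source)
    return read_cloud_ply_set(list(source))


def write_cloud_csv(
    path: str | Path,
    clouds: dict[str, np.ndarray],
    glenoid_sublabels: np.ndarray | None = None,
) -> None:
    """Write clouds to one CSV; biconcave glenoids keep their sublabels."""
    frames = []
    for label, pts in clouds.items():
        pts = np.asarray(pts, dtype=float)
        if label == "glenoid" and glenoid_sublabels is not None:
            labels = np.asarray(glenoid_sublabels, dtype=object)
        else:
            labels = np.full(len(pts), label, dtype=object)
        frames.append(
            pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2], "label": labels})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def _write_ascii_ply(path: Path, pts: np.ndarray) -> None:
    header = (
        "ply\nformat ascii 1.0\n"
        f"element vertex {len(pts)}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "end_header\n"
    )
    body = "\n".join(" ".join(f"{c:.9g}" for c in row) for row in pts)
    path.write_text(header + body + "\n")


def write_cloud_ply_set(
    out_dir: str | Path, stem: str, clouds: dict[str, np.ndarray]
) -> list[Path]:
    """Write one ASCII PLY per structure; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, pts in clouds.items():
        path = out_dir / f"{stem}_{label}.ply"
        _write_ascii_ply(path, np.asarray(pts, dtype=float))
        paths.append(path)
    return paths


def write_phantom(
    out_dir: str | Path, stem: str, phantom: ScapulaPhantom, fmt: str = "csv"
) -> dict[str, object]:
    """Write one phantom (clouds + ground-truth JSON sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        cloud_path: object = out_dir / f"{stem}.csv"
        write_cloud_csv(cloud_path, phantom.clouds, phantom.glenoid_sublabels)
    elif fmt == "ply":
        cloud_path = write_cloud_ply_set(out_dir, stem, phantom.clouds)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'ply')")
    gt_path = out_dir / f"{stem}.groundtruth.json"
    phantom.write_ground_truth(gt_path)
    return {"clouds": cloud_path, "ground_truth": gt_path}


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (id, side, walch_class, sirveaux_class, path)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"id", "side", "path"}
    missing = required - set(df.columns)
    if missing:
        raise CloudFormatError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise CloudFormatError(f"{path}: duplicate subject id {dup!r}")
    bad_side = ~df["side"].isin(["left", "right"])
    if bad_side.any():
        raise CloudFormatError(
            f"{path}: side must be left|right, got {df.loc[bad_side, 'side'].iloc[0]!r}"
        )
    for col, vocab in (("walch_class", WALCH_CLASSES), ("sirveaux_class", SIRVEAUX_CLASSES)):
        if col in df.columns:
            values = df[col].fillna("")
            bad = ~values.isin(sorted(vocab) + [""])
            if bad.any():
                raise CloudFormatError(
                    f"{path}: invalid {col} {values[bad].iloc[0]!r}"
                )
    return df


def results_to_frame(results: list[tuple[str, object]]) -> pd.DataFrame:
    """Flatten (subject id, MorphometryResult) pairs into a long table."""
    rows = []
    for subject_id, res in results:
        rows.append(
            {
                "id": subject_id,
                "variant": res.variant.value,
                "version_deg": res.version,
                "inclination_deg": res.inclination,
                "subluxation_pct": res.subluxation,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)
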