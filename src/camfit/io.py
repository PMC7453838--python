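"""File formats: camera configs, click tables, chain outputs, run manifests.

One documented CSV dialect per entity (UTF-8, header required):

clicks
    ``type,pair_id,u_px,v_px`` with ``type`` in {foot, head, horizon};
    foot/head rows pair up by ``pair_id`` (horizon rows ignore it).
landmarks
    ``u_px,v_px,lat,lon`` or ``u_px,v_px,x_m,y_m`` (local tangent frame).
correspondences
    ``pair_id,camera,u_px,v_px`` with ``camera`` in {a, b}.

Camera configs are YAML (JSON is a YAML subset and also accepted) with keys
``focal_length_mm``, ``sensor_size_mm`` [w, h], ``image_size_px`` [w, h],
``projection``, ``distortion`` [k1, k2, k3] and ``pose`` {elevation_m,
tilt_deg, roll_deg, heading_deg, pos_x_m, pos_y_m}.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .camera import Camera, CameraIntrinsics, CameraPose
from .georef import LandmarkSet, latlon_to_local
from .heights import ClickSet
from .stereo import CorrespondenceSet, ScaleConstraint

__all__ = ["read_camera", "write_camera", "read_clicks", "write_clicks",
           "read_landmarks", "write_landmarks", "read_correspondences",
           "write_correspondences", "RunManifest", "ParseError"]


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line numbers."""


# ------------------------------------------------------------------- camera

def write_camera(path, intrinsics: CameraIntrinsics,
                 pose: CameraPose | None = None) -> None:
    data = {
        "focal_length_mm": float(intrinsics.focal_length_mm),
        "sensor_size_mm": [float(intrinsics.sensor_width_mm),
                           float(intrinsics.sensor_height_mm)],
        "image_size_px": [int(intrinsics.image_width_px),
                          int(intrinsics.image_height_px)],
        "projection": intrinsics.projection.value,
        "distortion": [float(k) for k in intrinsics.distortion],
    }
    if pose is not None:
        data["pose"] = {
            "elevation_m": float(pose.elevation_m),
            "tilt_deg": float(pose.tilt_deg),
            "roll_deg": float(pose.roll_deg),
            "heading_deg": float(pose.heading_deg),
            "pos_x_m": float(pose.pos_x_m), "pos_y_m": float(pose.pos_y_m),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_camera(path):
    """Read a camera config; returns ``(intrinsics, pose_or_None)``."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: camera config must be a mapping")
    try:
        intr = CameraIntrinsics(
            focal_length_mm=float(data["focal_length_mm"]),
            sensor_width_mm=float(data["sensor_size_mm"][0]),
            sensor_height_mm=float(data["sensor_size_mm"][1]),
            image_width_px=int(data["image_size_px"][0]),
            image_height_px=int(data["image_size_px"][1]),
            projection=data.get("projection", "rectilinear"),
            distortion=tuple(data.get("distortion", (0.0, 0.0, 0.0))),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise ParseError(f"{path}: missing or malformed camera key: {exc}") from exc
    pose = None
    if "pose" in data:
        p = data["pose"]
        try:
            pose = CameraPose(
                elevation_m=float(p["elevation_m"]),
                tilt_deg=float(p["tilt_deg"]),
                roll_deg=float(p.get("roll_deg", 0.0)),
                heading_deg=float(p.get("heading_deg", 0.0)),
                pos_x_m=float(p.get("pos_x_m", 0.0)),
                pos_y_m=float(p.get("pos_y_m", 0.0)),
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: malformed pose: {exc}") from exc
    return intr, pose


# ------------------------------------------------------------------- tables

def _read_table(path, required_cols) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")
    return df


def _numeric(df: pd.DataFrame, path, cols) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # header=1
            raise ParseError(f"{path}: non-numeric values in column "
                             f"'{col}' at line(s) {lines}")
        if converted.isna().any():
            lines = (np.flatnonzero(converted.isna().to_numpy()) + 2).tolist()
            raise ParseError(f"{path}: missing values in column '{col}' at "
                             f"line(s) {lines}")
        out[col] = converted
    return out


def write_clicks(path, clicks: ClickSet) -> None:
    rows = []
    for i, (f, h) in enumerate(zip(clicks.foot, clicks.head)):
        rows.append(("foot", i, f[0], f[1]))
        rows.append(("head", i, h[0], h[1]))
    if clicks.horizon is not None:
        for i, p in enumerate(clicks.horizon):
            rows.append(("horizon", i, p[0], p[1]))
    pd.DataFrame(rows, columns=["type", "pair_id", "u_px", "v_px"]).to_csv(
        path, index=False)


def read_clicks(path, click_noise_px: float = 1.0) -> ClickSet:
    """Parse a click table into a validated :class:`ClickSet`."""
    df = _read_table(path, ["type", "pair_id", "u_px", "v_px"])
    df = _numeric(df, path, ["u_px", "v_px"])
    kinds = df["type"].astype(str).str.lower()
    known = kinds.isin(["foot", "head", "horizon"])
    if not known.all():
        lines = (np.flatnonzero(~known.to_numpy()) + 2).tolist()
        raise ParseError(f"{path}: unknown click type at line(s) {lines} "
                         "(expected foot/head/horizon)")
    foot = df[kinds == "foot"].set_index("pair_id")
    head = df[kinds == "head"].set_index("pair_id")
    if foot.index.duplicated().any() or head.index.duplicated().any():
        raise ParseError(f"{path}: duplicated pair_id within foot or head rows")
    unpaired = set(foot.index).symmetric_difference(head.index)
    if unpaired:
        raise ParseError(f"{path}: unpaired foot/head pair_id(s) "
                         f"{sorted(unpaired)}")
    if len(foot) == 0:
        raise ParseError(f"{path}: no foot/head pairs found")
    ids = sorted(foot.index)
    horizon = df[kinds == "horizon"][["u_px", "v_px"]].to_numpy()
    return ClickSet(foot=foot.loc[ids, ["u_px", "v_px"]].to_numpy(),
                    head=head.loc[ids, ["u_px", "v_px"]].to_numpy(),
                    horizon=horizon if len(horizon) else None,
                    click_noise_px=click_noise_px)


def write_landmarks(path, lm: LandmarkSet, local: bool = True) -> None:
    if local:
        df = pd.DataFrame({"u_px": lm.image_points[:, 0],
                           "v_px": lm.image_points[:, 1],
                           "x_m": lm.target_points[:, 0],
                           "y_m": lm.target_points[:, 1]})
    else:
        from .georef import local_to_latlon
        lat, lon = local_to_latlon(lm.target_points[:, 0],
                                   lm.target_points[:, 1],
                                   lm.ref_lat, lm.ref_lon)
        df = pd.DataFrame({"u_px": lm.image_points[:, 0],
                           "v_px": lm.image_points[:, 1],
                           "lat": lat, "lon": lon})
    df.to_csv(path, index=False)


def read_landmarks(path, local: bool | None = None) -> LandmarkSet:
    """Parse landmarks; geographic targets are converted to a local frame.

    ``local`` forces the dialect; by default it is inferred from the columns.
    """
    df = _read_table(path, ["u_px", "v_px"])
    has_local = {"x_m", "y_m"}.issubset(df.columns)
    has_geo = {"lat", "lon"}.issubset(df.columns)
    if local is None:
        local = has_local
    if local and not has_local:
        raise ParseError(f"{path}: expected x_m,y_m columns")
    if not local and not has_geo:
        raise ParseError(f"{path}: expected lat,lon columns")
    cols = ["u_px", "v_px"] + (["x_m", "y_m"] if local else ["lat", "lon"])
    df = _numeric(df, path, cols)
    uv = df[["u_px", "v_px"]].to_numpy()
    if local:
        return LandmarkSet(uv, df[["x_m", "y_m"]].to_numpy())
    return LandmarkSet.from_latlon(uv, df["lat"].to_numpy(),
                                   df["lon"].to_numpy())


def write_correspondences(path, corr: CorrespondenceSet) -> None:
    rows = []
    for i, (a, b) in enumerate(zip(corr.points_a, corr.points_b)):
        rows.append((i, "a", a[0], a[1]))
        rows.append((i, "b", b[0], b[1]))
    pd.DataFrame(rows, columns=["pair_id", "camera", "u_px", "v_px"]).to_csv(
        path, index=False)


def read_correspondences(path, scale: ScaleConstraint) -> CorrespondenceSet:
    df = _read_table(path, ["pair_id", "camera", "u_px", "v_px"])
    df = _numeric(df, path, ["u_px", "v_px"])
    cams = df["camera"].astype(str).str.lower()
    if not cams.isin(["a", "b"]).all():
        lines = (np.flatnonzero(~cams.isin(["a", "b"]).to_numpy()) + 2).tolist()
        raise ParseError(f"{path}: camera must be 'a' or 'b' at line(s) {lines}")
    a = df[cams == "a"].set_index("pair_id")
    b = df[cams == "b"].set_index("pair_id")
    unpaired = set(a.index).symmetric_difference(b.index)
    if unpaired:
        raise ParseError(f"{path}: unpaired correspondence id(s) "
                         f"{sorted(unpaired)}")
    ids = sorted(a.index)
    return CorrespondenceSet(points_a=a.loc[ids, ["u_px", "v_px"]].to_numpy(),
                             points_b=b.loc[ids, ["u_px", "v_px"]].to_numpy(),
                             scale=scale)


# ----------------------------------------------------------------- manifest

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record tying a result to its command, inputs and seed.

    Re-running the recorded command with identical input hashes and seed
    reproduces identical outputs for seeded commands.
    """

    command: str
    arguments: dict
    seed: int | None
    input_hashes: dict
    software_version: str = __version__
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc).isoformat())

    @classmethod
    def create(cls, command: str, arguments: dict, seed,
               input_files) -> "RunManifest":
        hashes = {str(p): _sha256(p) for p in input_files if Path(p).exists()}
        args = {k: (str(v) if isinstance(v, Path) else v)
                for k, v in arguments.items()}
        return cls(command=command, arguments=args, seed=seed,
                   input_hashes=hashes)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
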