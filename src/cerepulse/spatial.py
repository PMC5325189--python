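"""Channel geometry, source-detector distance filtering, and ROIs.

Each optical channel is a source-detector pair with 3-D positions in a
declared head frame.  Channels are retained for analysis only when their
source-detector separation lies in the closed interval [2, 6] cm (shorter
pairs see mostly scalp; longer pairs have too little light).  A channel's
representative cortical location is the source-detector midpoint; its
standard-space (Talairach) X/Y coordinates come from an affine placement
declared in the geometry file (no MRI co-registration is performed here), and
depth is ignored for box-ROI membership.  Regional ROIs are consumed as
Brodmann-area labels carried by the geometry file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyRoiError

SD_DISTANCE_BOUNDS_CM = (2.0, 6.0)
#: global axial-surface ROI, Talairach X in [-45, 45], Y in [-80, 50]
GLOBAL_BOX = (-45.0, 45.0, -80.0, 50.0)

GEOMETRY_COLUMNS = [
    "channel_id",
    "src_x_mm", "src_y_mm", "src_z_mm",
    "det_x_mm", "det_y_mm", "det_z_mm",
    "region_label",
]


@dataclass
class RoiSpec:
    """A region of interest: a Talairach box or a set of area labels."""

    name: str
    kind: str  # "box" | "labels"
    box: tuple | None = None  # (x_min, x_max, y_min, y_max)
    labels: frozenset | None = None

    def __post_init__(self) -> None:
        if self.kind == "box":
            if self.box is None or len(self.box) != 4:
                raise ValueError("box ROI needs (x_min, x_max, y_min, y_max)")
            x0, x1, y0, y1 = self.box
            if not (x0 < x1 and y0 < y1):
                raise ValueError("box min must be below max on each axis")
        elif self.kind == "labels":
            if not self.labels:
                raise ValueError("label ROI needs a non-empty label set")
            self.labels = frozenset(self.labels)
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")


GLOBAL_ROI = RoiSpec("global", "box", box=GLOBAL_BOX)
FRONTOPARIETAL_ROI = RoiSpec("frontoparietal", "labels", labels=frozenset({"BA9", "BA7"}))
VISUAL_ROI = RoiSpec("visual", "labels", labels=frozenset({"BA17", "BA18"}))


def with_derived(geom: pd.DataFrame) -> pd.DataFrame:
    """Add derived geometry columns: distance, midpoint, Talairach X/Y.

    The Talairach placement of synthetic montages is the identity mapping of
    the midpoint X/Y (the montage is generated directly in standard-space
    millimetres); real montages may carry precomputed ``talairach_x/y``
    columns which are preserved.
    """
    g = geom.copy()
    src = g[["src_x_mm", "src_y_mm", "src_z_mm"]].to_numpy(float)
    det = g[["det_x_mm", "det_y_mm", "det_z_mm"]].to_numpy(float)
    g["sd_distance_cm"] = np.linalg.norm(det - src, axis=1) / 10.0
    mid = (src + det) / 2.0
    g["mid_x_mm"], g["mid_y_mm"], g["mid_z_mm"] = mid.T
    if "talairach_x" not in g.columns:
        g["talairach_x"] = mid[:, 0]
    if "talairach_y" not in g.columns:
        g["talairach_y"] = mid[:, 1]
    return g


def filter_channels(
    geom: pd.DataFrame, bounds_cm: tuple[float, float] = SD_DISTANCE_BOUNDS_CM
):
    """Retain channels with source-detector distance inside the closed bounds.

    Returns the retained geometry plus a per-channel ledger (one row per
    input channel, status retained/excluded), so retained + excluded always
    equals the input count.
    """
    if len(geom) == 0:
        return geom.copy(), pd.DataFrame(columns=["channel_id", "status", "reason"])
    g = geom if "sd_distance_cm" in geom.columns else with_derived(geom)
    d = g["sd_distance_cm"].to_numpy(float)
    if np.any(d <= 0):
        raise ValueError("source-detector distance must be positive")
    ok = (d >= bounds_cm[0]) & (d <= bounds_cm[1])
    ledger = pd.DataFrame(
        {
            "channel_id": g["channel_id"],
            "status": np.where(ok, "retained", "excluded"),
            "reason": np.where(ok, "", "sd_distance_out_of_bounds"),
            "sd_distance_cm": d,
        }
    )
    return g[ok].reset_index(drop=True), ledger


def assign_units(geom: pd.DataFrame, roi: RoiSpec) -> list:
    """Channel ids belonging to an ROI (closed box bounds; exact label match).

    A unit may belong to several ROIs; an ROI resolving to zero units raises
    :class:`EmptyRoiError`.
    """
    g = geom if "talairach_x" in geom.columns else with_derived(geom)
    if roi.kind == "box":
        x0, x1, y0, y1 = roi.box
        member = (
            (g["talairach_x"] >= x0)
            & (g["talairach_x"] <= x1)
            & (g["talairach_y"] >= y0)
            & (g["talairach_y"] <= y1)
        )
    else:
        member = g["region_label"].isin(roi.labels)
    ids = list(g.loc[member, "channel_id"])
    if not ids:
        raise EmptyRoiError(f"ROI {roi.name!r} resolves to zero units")
    return ids


def project_to_surface_map(
    values: pd.Series,
    geom: pd.DataFrame,
    grid_step_mm: float = 5.0,
    power: float = 2.0,
    radius_mm: float = 40.0,
    extent=None,
):
    """Inverse-distance-weighted projection of per-unit values onto a 2-D grid.

    A simplified rendering stand-in for tomographic reconstruction: each grid
    node takes the IDW mean of units within ``radius_mm`` (NaN beyond).

    Returns
    -------
    (x, y, Z) : 1-D grid axes (mm) and the masked value grid (len(y), len(x)).
    """
    g = geom if "talairach_x" in geom.columns else with_derived(geom)
    g = g.set_index("channel_id")
    units = [u for u in values.index if u in g.index]
    if not units:
        raise ValueError("no unit with a location")
    px = g.loc[units, "talairach_x"].to_numpy(float)
    py = g.loc[units, "talairach_y"].to_numpy(float)
    if len(units) > 1 and np.ptp(px) == 0 and np.ptp(py) == 0:
        raise ValueError("all units co-located: interpolation is degenerate")
    v = values.loc[units].to_numpy(float)

    if extent is None:
        extent = (px.min() - radius_mm, px.max() + radius_mm,
                  py.min() - radius_mm, py.max() + radius_mm)
    x = np.arange(extent[0], extent[1] + grid_step_mm / 2, grid_step_mm)
    y = np.arange(extent[2], extent[3] + grid_step_mm / 2, grid_step_mm)
    gx, gy = np.meshgrid(x, y)
    d = np.sqrt((gx[..., None] - px) ** 2 + (gy[..., None] - py) ** 2)
    d = np.maximum(d, 1e-9)
    w = d ** -power
    w[d > radius_mm] = 0.0
    wsum = w.sum(axis=-1)
    Z = np.where(wsum > 0, (w * v).sum(axis=-1) / np.where(wsum > 0, wsum, 1.0), np.nan)
    return x, y, Z


def save_map_csv(path, x, y, Z) -> None:
    df = pd.DataFrame(Z, index=pd.Index(y, name="y_mm"), columns=pd.Index(x, name="x_mm"))
    df.to_csv(path, float_format="%.6f")


def load_geometry(path) -> pd.DataFrame:
    geom = pd.read_csv(path)
    missing = [c for c in GEOMETRY_COLUMNS if c not in geom.columns]
    if missing:
        raise ValueError(f"geometry file missing columns: {missing}")
    return with_derived(geom)


def save_geometry(path, geom: pd.DataFrame) -> None:
    cols = [c for c in GEOMETRY_COLUMNS if c in geom.columns]
    geom[cols].to_csv(path, index=False, float_format="%.3f")


def load_rois_yaml(path) -> list[RoiSpec]:
    """Read ROI definitions from YAML: a list of {name, kind, box|labels}."""
    with open(path) as f:
        spec = yaml.safe_load(f)
    rois = []
    for item in spec:
        rois.append(
            RoiSpec(
                name=item["name"],
                kind=item["kind"],
                box=tuple(item["box"]) if "box" in item else None,
                labels=frozenset(item["labels"]) if "labels" in item else None,
            )
        )
    return rois
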