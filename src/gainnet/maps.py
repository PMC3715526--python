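"""Slope maps over parameter planes and zero-slope boundary extraction.

A :class:`SlopeMap` is the common currency of the three tiers: a grid of
d(mean excitatory activity)/d(intensity) values over two connectivity
parameters.  The zero-slope contour of such a map is the gain-control
boundary.  Maps serialize to delimited text with a small metadata header so
all tiers share one on-disk format.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["SlopeMap", "BoundaryCurve", "extract_zero_contour",
           "boundary_distance", "sign_agreement", "plot_slope_map"]


@dataclass
class SlopeMap:
    """Grid of response slopes: ``slopes[i, j]`` at ``(y_values[i], x_values[j])``."""

    x_name: str
    x_values: np.ndarray
    y_name: str
    y_values: np.ndarray
    slopes: np.ndarray
    stderr: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_values = np.asarray(self.x_values, float)
        self.y_values = np.asarray(self.y_values, float)
        self.slopes = np.asarray(self.slopes, float)
        if self.slopes.shape != (self.y_values.size, self.x_values.size):
            raise ValueError("slope matrix shape must be (len(y), len(x))")

    def to_csv(self, path) -> None:
        """Write as delimited text with a '#'-prefixed JSON metadata header."""
        header = {
            "x_name": self.x_name, "y_name": self.y_name,
            "x_values": self.x_values.tolist(), "y_values": self.y_values.tolist(),
            "meta": self.meta, "has_stderr": self.stderr is not None,
        }
        rows = []
        for i, yv in enumerate(self.y_values):
            for j, xv in enumerate(self.x_values):
                row = {"x": xv, "y": yv, "slope": self.slopes[i, j]}
                if self.stderr is not None:
                    row["stderr"] = self.stderr[i, j]
                rows.append(row)
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            pd.DataFrame(rows).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SlopeMap":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("# "))
            df = pd.read_csv(io.StringIO(fh.read()))
        x = np.asarray(header["x_values"])
        y = np.asarray(header["y_values"])
        slopes = np.full((y.size, x.size), np.nan)
        err = np.full_like(slopes, np.nan) if header["has_stderr"] else None
        for _, row in df.iterrows():
            i = int(np.argmin(np.abs(y - row["y"])))
            j = int(np.argmin(np.abs(x - row["x"])))
            slopes[i, j] = row["slope"]
            if err is not None:
                err[i, j] = row.get("stderr", np.nan)
        return cls(header["x_name"], x, header["y_name"], y, slopes,
                   stderr=err, meta=header["meta"])


@dataclass
class BoundaryCurve:
    """Ordered points of a zero-slope contour in the (x, y) plane."""

    x: np.ndarray
    y: np.ndarray
    method: str  # "analytic" | "interpolated"
    status: str = "ok"

    @property
    def empty(self) -> bool:
        return self.x.size == 0

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def extract_zero_contour(smap: SlopeMap, level: float = 0.0) -> BoundaryCurve:
    """Linear-interpolation contour of ``slope = level``.

    For every x column the first adjacent y pair bracketing a strict sign
    change is interpolated; columns without a sign change (or with missing
    cells at the crossing) contribute no point — the contour may be partial
    and is never extrapolated.  A single-signed map yields an empty curve
    with an explanatory status.
    """
    xs, ys = [], []
    S = smap.slopes - level
    for j, xv in enumerate(smap.x_values):
        col = S[:, j]
        for i in range(col.size - 1):
            a, b = col[i], col[i + 1]
            if np.isnan(a) or np.isnan(b):
                continue
            if (a > 0 and b < 0) or (a < 0 and b > 0):
                w = a / (a - b)
                ys.append(smap.y_values[i] + w * (smap.y_values[i + 1] - smap.y_values[i]))
                xs.append(xv)
                break
    if not xs:
        finite = S[np.isfinite(S)]
        status = ("single-signed map: no zero crossing"
                  if finite.size and (np.all(finite >= 0) or np.all(finite <= 0))
                  else "no bracketed crossing found")
        return BoundaryCurve(np.array([]), np.array([]), "interpolated", status)
    order = np.argsort(xs)
    return BoundaryCurve(np.asarray(xs)[order], np.asarray(ys)[order], "interpolated")


def plot_slope_map(smap: SlopeMap, contour: Optional[BoundaryCurve] = None,
                   ax=None, **pcolormesh_kw):
    """Optional visualization: slope map as a diverging colormesh with the
    zero contour overlaid.  Requires matplotlib (not a core dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lim = np.nanmax(np.abs(smap.slopes))
    pcolormesh_kw.setdefault("cmap", "RdBu_r")
    pcolormesh_kw.setdefault("vmin", -lim)
    pcolormesh_kw.setdefault("vmax", lim)
    mesh = ax.pcolormesh(smap.x_values, smap.y_values, smap.slopes,
                         shading="nearest", **pcolormesh_kw)
    if contour is None:
        contour = extract_zero_contour(smap)
    if not contour.empty:
        ax.plot(contour.x, contour.y, "k-", lw=2)
    ax.set_xlabel(smap.x_name)
    ax.set_ylabel(smap.y_name)
    plt.colorbar(mesh, ax=ax, label="d(mean E activity)/dI")
    return ax


def boundary_distance(a: BoundaryCurve, b: BoundaryCurve,
                      x_scale: float = 1.0, y_scale: float = 1.0) -> float:
    """Symmetric Hausdorff distance between two boundary curves.

    Coordinates are divided by the given scales first (use the grid cell
    size to express the result in cell units).
    """
    if a.empty or b.empty:
        return np.inf
    pa = a.points() / [x_scale, y_scale]
    pb = b.points() / [x_scale, y_scale]
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def sign_agreement(map_a: SlopeMap, map_b: SlopeMap,
                   exclude_band: float = 0.0) -> float:
    """Fraction of grid cells on which the two maps agree in slope sign.

    Cells where either |slope| is below ``exclude_band`` times that map's
    maximum |slope| are excluded (the near-boundary band where the sign is
    not meaningful).  Maps must share identical axes.
    """
    if (map_a.x_name != map_b.x_name or map_a.y_name != map_b.y_name
            or map_a.x_values.size != map_b.x_values.size
            or map_a.y_values.size != map_b.y_values.size
            or not np.allclose(map_a.x_values, map_b.x_values)
            or not np.allclose(map_a.y_values, map_b.y_values)):
        raise ValueError("maps have incomparable axes")
    A, B = map_a.slopes, map_b.slopes
    ok = np.isfinite(A) & np.isfinite(B)
    if exclude_band > 0:
        ok &= np.abs(A) >= exclude_band * np.nanmax(np.abs(A))
        ok &= np.abs(B) >= exclude_band * np.nanmax(np.abs(B))
    if not ok.any():
        raise ValueError("no comparable cells outside the exclusion band")
    return float(np.mean(np.sign(A[ok]) == np.sign(B[ok])))
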