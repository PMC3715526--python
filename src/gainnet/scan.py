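"""Parameter sweeps across the three tiers and tier-to-tier comparison.

A :class:`SweepConfig` names a tier (``meanfield`` | ``rate`` | ``hh``),
two grid axes, repetition count and a master seed; :func:`run_sweep` fills
the grid by dispatching to the tier and returns a
:class:`gainnet.maps.SlopeMap`.  Per-cell seeds are derived from
``(seed, i, j, rep)`` so the whole sweep is reproducible bit-for-bit, and a
sweep writing to a cache file can be resumed: completed cells are skipped.

The axes understood are the connectivity primitives (``p_EI``, ``p_II``,
``p_IE``, ``p_EE``, the strengths ``g_*``, the shared inhibitory strength
``g_I`` meaning g_EI = g_II) and the sparseness ``f``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import defaults
from .maps import BoundaryCurve, SlopeMap, boundary_distance, extract_zero_contour, sign_agreement
from .meanfield import GainParams, MeanFieldParams, gain_slope_intensity
from .netgen import ConnectivitySpec, PopulationSpec, RampProtocol
from .ratenet import build_rate_network, intensity_sweep

__all__ = [
    "SweepConfig",
    "SlopeMap",
    "BoundaryCurve",
    "run_sweep",
    "extract_zero_contour",
    "compare_tiers",
    "scaled_connectivity",
    "write_manifest",
]

_AXES = ("f", "p_EE", "p_EI", "p_IE", "p_II",
         "g_EE", "g_EI", "g_IE", "g_II", "g_I")


@dataclass
class SweepConfig:
    """Declarative description of one slope-map sweep."""

    tier: str
    x_name: str
    x_values: Sequence[float]
    y_name: str
    y_values: Sequence[float]
    reps: int = 1
    seed: int = 0
    f: float = defaults.F_REF
    I_values: Sequence[float] = (3.5, 5.0, 6.5, 8.0)
    pops: PopulationSpec = field(default_factory=lambda: defaults.POPS)
    conn: ConnectivitySpec = field(default_factory=lambda: defaults.CONN)
    gain: GainParams = field(default_factory=GainParams)
    protocol: RampProtocol = field(default_factory=RampProtocol)
    hh_window: float = 25.0
    cache: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tier not in ("meanfield", "rate", "hh"):
            raise ValueError(f"unknown tier {self.tier!r}")
        for ax in (self.x_name, self.y_name):
            if ax not in _AXES:
                raise ValueError(f"unknown axis {ax!r}; pick from {_AXES}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, (tuple, list, np.ndarray)) else
                       (asdict(v) if hasattr(v, "__dataclass_fields__") else v))
                   for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


def _apply_axis(conn: ConnectivitySpec, f: float, name: str, value: float):
    if name == "f":
        return conn, float(value)
    if name == "g_I":
        return conn.replace(g_EI=float(value), g_II=float(value)), f
    return conn.replace(**{name: float(value)}), f


def scaled_connectivity(conn: ConnectivitySpec, ref_pops: PopulationSpec,
                        pops: PopulationSpec) -> ConnectivitySpec:
    """Rescale strengths so a smaller network keeps the reference couplings.

    The mean-field theory fixes J_XY = p_XY N_Y g_XY; shrinking a
    population while holding J requires g to grow by the size ratio.
    """
    sE = ref_pops.N_E / pops.N_E
    sI = ref_pops.N_I / pops.N_I
    return conn.replace(g_EE=conn.g_EE * sE, g_IE=conn.g_IE * sE,
                        g_EI=conn.g_EI * sI, g_II=conn.g_II * sI)


def _cell_meanfield(config: SweepConfig, conn, f) -> float:
    params = MeanFieldParams(config.pops, conn, config.gain)
    I_ref = float(np.median(config.I_values))
    return gain_slope_intensity(params, f, I_ref)


def _cell_rate(config: SweepConfig, conn, f, i, j, rep) -> float:
    ss = np.random.SeedSequence((config.seed, i, j, rep))
    net = build_rate_network(config.pops, conn, config.gain, f, ss)
    _, slope, valid = intensity_sweep(net, config.I_values)
    return slope if valid else np.nan


def _cell_hh(config: SweepConfig, conn, f, i, j, rep) -> float:
    from .hhnet import build_hh_network, count_slope, run_ramp_experiment

    ss = np.random.SeedSequence((config.seed, i, j, rep))
    net = build_hh_network(config.pops, conn, f, ss)
    try:
        exp = run_ramp_experiment(net, config.protocol, window=config.hh_window)
    except RuntimeError:
        return np.nan
    return count_slope(exp["counts_E"], exp["current_E"])


def _load_cache(path) -> dict:
    done = {}
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                i, j, slope, err = line.split(",")
                done[(int(i), int(j))] = (float(slope), float(err))
    except FileNotFoundError:
        pass
    return done


def run_sweep(config: SweepConfig, progress: bool = False) -> SlopeMap:
    """Fill the configured grid with response slopes.

    Deterministic given ``config.seed``; per-cell failures become NaN cells
    and the sweep continues.  With ``config.cache`` set, completed cells are
    appended to a text file and skipped on rerun.
    """
    xv = np.asarray(config.x_values, float)
    yv = np.asarray(config.y_values, float)
    slopes = np.full((yv.size, xv.size), np.nan)
    errs = np.full_like(slopes, np.nan)
    done = _load_cache(config.cache) if config.cache else {}
    cache_fh = open(config.cache, "a") if config.cache else None
    try:
        for i, y in enumerate(yv):
            for j, x in enumerate(xv):
                if (i, j) in done:
                    slopes[i, j], errs[i, j] = done[(i, j)]
                    continue
                conn, f = _apply_axis(config.conn, config.f, config.y_name, y)
                conn, f = _apply_axis(conn, f, config.x_name, x)
                if config.tier == "meanfield":
                    cell = [_cell_meanfield(config, conn, f)]
                else:
                    runner = _cell_rate if config.tier == "rate" else _cell_hh
                    cell = [runner(config, conn, f, i, j, rep)
                            for rep in range(config.reps)]
                cell = [c for c in cell if np.isfinite(c)]
                if cell:
                    slopes[i, j] = float(np.mean(cell))
                    errs[i, j] = (float(np.std(cell, ddof=1) / np.sqrt(len(cell)))
                                  if len(cell) > 1 else np.nan)
                if cache_fh is not None:
                    cache_fh.write(f"{i},{j},{float(slopes[i, j])!r},{float(errs[i, j])!r}\n")
                    cache_fh.flush()
                if progress:
                    print(f"[{config.tier}] cell ({i},{j}) "
                          f"{config.y_name}={y:g} {config.x_name}={x:g} "
                          f"slope={slopes[i, j]:.4g}")
    finally:
        if cache_fh is not None:
            cache_fh.close()
    meta = dict(tier=config.tier, seed=config.seed, reps=config.reps,
                f=config.f, I_values=list(np.asarray(config.I_values, float)),
                config_digest=config.digest())
    return SlopeMap(config.x_name, xv, config.y_name, yv, slopes,
                    stderr=errs, meta=meta)


def compare_tiers(map_a: SlopeMap, map_b: SlopeMap,
                  exclude_band: float = 0.1) -> dict:
    """Boundary distance and sign-agreement report between two tiers' maps.

    Maps must share axes.  The boundary distance is the symmetric Hausdorff
    distance between the two zero-slope contours in grid-cell units; the
    sign agreement excludes the near-boundary band where either |slope| is
    below ``exclude_band`` of that map's maximum.
    """
    ca = extract_zero_contour(map_a)
    cb = extract_zero_contour(map_b)
    dx = float(np.mean(np.diff(map_a.x_values))) if map_a.x_values.size > 1 else 1.0
    dy = float(np.mean(np.diff(map_a.y_values))) if map_a.y_values.size > 1 else 1.0
    return dict(
        boundary_hausdorff_cells=boundary_distance(ca, cb, x_scale=dx, y_scale=dy),
        sign_agreement=sign_agreement(map_a, map_b, exclude_band=exclude_band),
        contour_a_points=int(ca.x.size),
        contour_b_points=int(cb.x.size),
    )


def write_manifest(path, config: SweepConfig, extra: Optional[dict] = None) -> None:
    """Record config hash, seeds and package version next to sweep outputs."""
    from . import __version__

    manifest = dict(config_digest=config.digest(), tier=config.tier,
                    seed=config.seed, reps=config.reps, version=__version__)
    manifest.update(extra or {})
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
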