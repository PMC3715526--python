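"""Synthetic network and stimulus generation.

This module produces everything the simulation tiers consume: random
Bernoulli connectivity between an excitatory (projection-neuron-like) and an
inhibitory (local-interneuron-like) population, stimulated-subset selection,
and piecewise-linear ramp stimulus protocols.

Connectivity convention
-----------------------
``p_XY`` / ``g_XY`` denote the probability and strength of a connection
*from population Y onto population X*; e.g. ``p_EI`` is the probability that
a given inhibitory neuron connects onto a given excitatory neuron.  Weight
matrices are stored as ``(n_post, n_pre)`` arrays with entries 0 or ``g``;
the inhibitory sign is applied at current-summation time, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "PopulationSpec",
    "ConnectivitySpec",
    "StimulusSpec",
    "RampProtocol",
    "sample_connectivity",
    "select_stimulated",
    "round_half_away",
    "ramp_current",
    "save_spec",
    "load_spec",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Sizes of the excitatory (PN) and inhibitory (LN) populations."""

    N_E: int
    N_I: int

    def __post_init__(self) -> None:
        if self.N_E < 1 or self.N_I < 1:
            raise ValueError("population sizes must be >= 1")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I


@dataclass(frozen=True)
class ConnectivitySpec:
    """Per-pair Bernoulli connection probabilities and synaptic strengths.

    Strengths are non-negative magnitudes; inhibition enters with a minus
    sign in the current sum of the consuming tier.
    """

    p_EE: float
    p_EI: float
    p_IE: float
    p_II: float
    g_EE: float
    g_EI: float
    g_IE: float
    g_II: float

    def __post_init__(self) -> None:
        for name in ("p_EE", "p_EI", "p_IE", "p_II"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("g_EE", "g_EI", "g_IE", "g_II"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "ConnectivitySpec":
        d = asdict(self)
        d.update(kw)
        return ConnectivitySpec(**d)


@dataclass(frozen=True)
class StimulusSpec:
    """A constant-intensity stimulus delivered to a fraction f of each population.

    ``S_E`` and ``S_I`` are the index sets of stimulated excitatory and
    inhibitory neurons; their sizes are exactly ``round(f * N)``.
    """

    I: float
    f: float
    S_E: tuple = field(default_factory=tuple)
    S_I: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f outside [0, 1]")
        if self.I < 0.0:
            raise ValueError("stimulus intensity must be >= 0")


@dataclass(frozen=True)
class RampProtocol:
    """Piecewise-linear stimulus: quiet settle, linear up-ramp, linear down-ramp.

    Durations in ms; current 0 -> I_peak -> 0.  ``dt_update`` records the
    stimulus-update interval used by fixed-update integrators; the adaptive
    HH tier re-evaluates the ramp every integration step.
    """

    t_settle: float = 200.0
    t_up: float = 500.0
    t_down: float = 500.0
    I_peak: float = 1.0
    dt_update: float = 0.1

    def __post_init__(self) -> None:
        for name in ("t_settle", "t_up", "t_down", "dt_update"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.I_peak < 0.0:
            raise ValueError("I_peak must be >= 0")

    @property
    def t_total(self) -> float:
        return self.t_settle + self.t_up + self.t_down


def round_half_away(x: float) -> int:
    """round(x) with halves away from zero (0.5 -> 1), as in |S| = round(f*N)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def sample_connectivity(
    n_pre: int,
    n_post: int,
    p: float,
    g: float,
    rng_seed,
    zero_diagonal: bool = False,
) -> np.ndarray:
    """Realize a Bernoulli weight matrix of shape ``(n_post, n_pre)``.

    Each entry is independently ``g`` with probability ``p`` and 0 otherwise.
    ``zero_diagonal=True`` removes self-connections for recurrent
    (within-population) blocks.

    ``rng_seed`` may be an int or any ``numpy.random.Generator`` seed source.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if g < 0.0:
        raise ValueError("g must be non-negative")
    rng = np.random.default_rng(rng_seed)
    W = np.where(rng.random((n_post, n_pre)) < p, float(g), 0.0)
    if zero_diagonal and n_pre == n_post:
        np.fill_diagonal(W, 0.0)
    return W


def select_stimulated(n: int, f: float, rng_seed) -> np.ndarray:
    """Sample round(f*n) distinct neuron indices uniformly without replacement."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f={f} outside [0, 1]")
    k = round_half_away(f * n)
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(n, size=k, replace=False)
    return np.sort(idx)


def ramp_current(t, protocol: RampProtocol):
    """Stimulus current at time(s) ``t`` (ms) under a ramp protocol.

    Zero during the settle period, linear 0 -> I_peak over ``t_up``, linear
    I_peak -> 0 over ``t_down``, zero afterwards.  Total function of t.
    """
    t = np.asarray(t, dtype=float)
    t1 = protocol.t_settle
    t2 = t1 + protocol.t_up
    t3 = t2 + protocol.t_down
    up = protocol.I_peak * (t - t1) / protocol.t_up
    down = protocol.I_peak * (t3 - t) / protocol.t_down
    out = np.where(
        (t >= t1) & (t < t2), up, np.where((t >= t2) & (t <= t3), down, 0.0)
    )
    return out if out.ndim else float(out)


_SPEC_CLASSES = {
    "PopulationSpec": PopulationSpec,
    "ConnectivitySpec": ConnectivitySpec,
    "StimulusSpec": StimulusSpec,
    "RampProtocol": RampProtocol,
}


def save_weights(path, meta: dict | None = None, **matrices) -> None:
    """Save realized weight matrices in a compressed array container.

    A sidecar ``<path>.meta.yaml`` records seeds/parameters passed in
    ``meta`` so a realization is traceable to its generator inputs.
    """
    np.savez_compressed(path, **matrices)
    if meta is not None:
        with open(str(path) + ".meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


def load_weights(path) -> dict:
    """Load matrices saved by :func:`save_weights` (metadata under '_meta')."""
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
        out = {k: z[k] for k in z.files}
    try:
        with open(str(path) + ".meta.yaml") as fh:
            out["_meta"] = yaml.safe_load(fh)
    except FileNotFoundError:
        pass
    return out


def save_spec(spec, path) -> None:
    """Serialize any netgen spec dataclass to a YAML key-value file."""
    payload = {"kind": type(spec).__name__, "fields": asdict(spec)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_spec(path):
    """Load a spec previously written by :func:`save_spec`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    cls = _SPEC_CLASSES[payload["kind"]]
    fields_ = payload["fields"]
    if cls is StimulusSpec:
        fields_["S_E"] = tuple(fields_.get("S_E", ()))
        fields_["S_I"] = tuple(fields_.get("S_I", ()))
    return cls(**fields_)
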