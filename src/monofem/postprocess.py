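"""Activation maps, conduction velocity and diagonal profiles.

Activation time of a point is the first discrete sample at which the
normalized potential exceeds the threshold (0.5 by default) — no
sub-step interpolation, matching the first-crossing rule used to define
isochrones; an optional linear-interpolation mode refines the estimate
between the bracketing samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import Mesh

__all__ = ["ActivationMap", "activation_map", "conduction_velocity", "probe_cv",
           "diagonal_profile", "profile_on_axis", "activation_to_frame"]

NEVER = np.inf  #: sentinel for nodes that never cross the threshold


@dataclass
class ActivationMap:
    """Per-node first-crossing times (ms); ``inf`` marks never-activated."""

    times: np.ndarray
    threshold: float = 0.5

    @property
    def all_activated(self) -> bool:
        return bool(np.all(np.isfinite(self.times)))


def activation_map(times, values, threshold: float = 0.5,
                   interpolate: bool = False) -> ActivationMap:
    """First-crossing times from a time-ordered sample matrix.

    ``values`` has shape (n_times, n_points); the activation time of a
    point is the first sample time with value > threshold (optionally
    linearly interpolated between the bracketing samples).  Re-crossings
    (e.g. reentrant waves) are ignored: only the first counts.
    """
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if times.size == 0 or values.shape[0] == 0:
        raise ValueError("empty trace")
    if values.shape[0] != times.size:
        raise ValueError(f"{values.shape[0]} samples vs {times.size} time points")
    above = values > threshold
    first = np.argmax(above, axis=0)
    crossed = above[first, np.arange(values.shape[1])]
    act = np.where(crossed, times[first], NEVER)
    if interpolate:
        interior = crossed & (first > 0)
        idx = np.flatnonzero(interior)
        i1 = first[idx]
        v0, v1 = values[i1 - 1, idx], values[i1, idx]
        frac = (threshold - v0) / (v1 - v0)
        act[idx] = times[i1 - 1] + frac * (times[i1] - times[i1 - 1])
    return ActivationMap(times=act, threshold=threshold)


def conduction_velocity(t1: float, t2: float, x1: float, x2: float) -> float:
    """CV between two probes in cm/s: ``(x2-x1)/(t2-t1)`` with x in mm, t in ms.

    1 mm/ms = 100 cm/s.  Rejects non-activated probes and non-positive
    activation-time differences.
    """
    if not (np.isfinite(t1) and np.isfinite(t2)):
        raise ValueError(f"probe never activated (t1={t1}, t2={t2})")
    if t2 <= t1:
        raise ValueError(f"non-positive activation-time difference: t1={t1}, t2={t2} ms")
    return (x2 - x1) / (t2 - t1) * 100.0


def probe_cv(result, x1: float = 18.0, x2: float = 22.0) -> float:
    """CV (cm/s) from a RunResult's two probes via their activation times."""
    act = result.activation[result.probe_nodes]
    return conduction_velocity(act[0], act[1], x1, x2)


def diagonal_profile(act: ActivationMap, mesh: Mesh,
                     half_width: float | None = None) -> pd.DataFrame:
    """Activation times along the corner-to-opposite-corner diagonal.

    Selects the nodes within half an element size of the line from
    (0,0,0) to (Lx,Ly,Lz), sorted by arc length.  Returns a DataFrame
    with columns (distance_mm, activation_ms, node, x, y, z).
    """
    L = np.asarray(mesh.dimensions)
    direction = L / np.linalg.norm(L)
    if half_width is None:
        half_width = 0.5 * mesh.h
    s = mesh.nodes @ direction                      # arc-length coordinate
    perp = mesh.nodes - np.outer(s, direction)
    dist = np.linalg.norm(perp, axis=1)
    sel = np.flatnonzero(dist <= half_width + 1e-9)
    if sel.size == 0:
        raise ValueError("no nodes within the diagonal corridor")
    order = sel[np.argsort(s[sel])]
    return pd.DataFrame({
        "distance_mm": s[order],
        "activation_ms": act.times[order],
        "node": order,
        "x": mesh.nodes[order, 0],
        "y": mesh.nodes[order, 1],
        "z": mesh.nodes[order, 2],
    }).reset_index(drop=True)


def profile_on_axis(profile: pd.DataFrame, s_grid: np.ndarray) -> np.ndarray:
    """Resample a diagonal profile onto a shared distance axis (linear interp).

    Lets profiles from different meshes be compared pointwise.
    """
    return np.interp(np.asarray(s_grid, dtype=float),
                     profile["distance_mm"].to_numpy(),
                     profile["activation_ms"].to_numpy())


def activation_to_frame(act: ActivationMap, mesh: Mesh) -> pd.DataFrame:
    """Node table (node id, x, y, z, activation_ms) for CSV export."""
    return pd.DataFrame({
        "node": np.arange(mesh.n_nodes),
        "x": mesh.nodes[:, 0],
        "y": mesh.nodes[:, 1],
        "z": mesh.nodes[:, 2],
        "activation_ms": act.times,
    })
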