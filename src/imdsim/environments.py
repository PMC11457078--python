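"""Lattice environments of bacterial colonies with tunable patchiness.

An environment is a square lattice seeded with ``density`` colonies that
are grouped around ``patchiness`` cluster centers (a Thomas-style cluster
process on a torus).  ``patchiness = 1`` concentrates every colony in a
single Gaussian blob — the most heterogeneous arrangement — while
``patchiness = density`` degenerates to independent uniform placement.
The torus removes edge artifacts for the long random walks simulated in
:mod:`imdsim.encounters`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

__all__ = [
    "EnvironmentSpec",
    "Environment",
    "generate_environment",
    "patchiness_statistic",
    "save_environment",
    "load_environment",
]


@dataclass(frozen=True)
class EnvironmentSpec:
    """Specification of a colony lattice.

    ``density`` is the total number of colonies; ``density = 0`` is
    allowed as a sterile control environment.  ``cluster_sd`` is the
    isotropic Gaussian scatter (in cells) of colonies around their
    cluster center.
    """

    density: int
    patchiness: int = 1
    size: int = 100
    cluster_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.size < 2:
            problems.append(f"size must be >= 2, got {self.size}")
        if not (0 <= self.density <= self.size * self.size):
            problems.append(f"density must be in [0, size^2], got {self.density}")
        if self.patchiness < 1:
            problems.append(f"patchiness must be >= 1, got {self.patchiness}")
        if self.density > 0 and self.patchiness > self.density:
            problems.append(
                f"patchiness ({self.patchiness}) cannot exceed density ({self.density})"
            )
        if not (math.isfinite(self.cluster_sd) and self.cluster_sd > 0):
            problems.append(f"cluster_sd must be positive, got {self.cluster_sd}")
        if problems:
            raise ValueError("invalid EnvironmentSpec: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class Environment:
    """A realized colony lattice: per-cell colony multiplicities."""

    spec: EnvironmentSpec
    counts: np.ndarray  # (size, size) int array

    @property
    def n_colonies(self) -> int:
        return int(self.counts.sum())

    @property
    def colony_cells(self) -> set:
        rows, cols = np.nonzero(self.counts)
        return {(int(r), int(c)) for r, c in zip(rows, cols)}

    def positions(self) -> np.ndarray:
        """(n_colonies, 2) array of colony coordinates, repeated by count."""
        rows, cols = np.nonzero(self.counts)
        reps = self.counts[rows, cols]
        return np.repeat(np.column_stack([rows, cols]), reps, axis=0)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Environment)
            and self.spec == other.spec
            and np.array_equal(self.counts, other.counts)
        )


def generate_environment(spec: EnvironmentSpec) -> Environment:
    """Draw a colony lattice from the cluster process defined by ``spec``.

    Cluster centers are placed uniformly at random; the ``density``
    colonies are split across centers as evenly as possible, with the
    remainder going to centers chosen at random without replacement.
    Each colony lands at its center plus an isotropic Gaussian offset
    (sd ``cluster_sd``) rounded to the nearest cell with toroidal wrap.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = np.zeros((spec.size, spec.size), dtype=np.int64)
    d, p = spec.density, spec.patchiness
    if d == 0:
        return Environment(spec=spec, counts=counts)
    centers = rng.integers(0, spec.size, size=(p, 2))
    per_center = np.full(p, d // p, dtype=np.int64)
    remainder = d % p
    if remainder:
        per_center[rng.choice(p, size=remainder, replace=False)] += 1
    parents = np.repeat(np.arange(p), per_center)
    offsets = np.rint(rng.normal(0.0, spec.cluster_sd, size=(d, 2))).astype(np.int64)
    cells = (centers[parents] + offsets) % spec.size
    np.add.at(counts, (cells[:, 0], cells[:, 1]), 1)
    return Environment(spec=spec, counts=counts)


def _toroidal_delta(x: np.ndarray, size: int) -> np.ndarray:
    x = np.abs(x)
    return np.minimum(x, size - x)


def patchiness_statistic(env: Environment) -> float:
    """Mean nearest-neighbor distance among colonies (toroidal metric).

    Colonies sharing a cell have nearest-neighbor distance zero, so the
    statistic shrinks as colonies cluster.  Requires at least two
    colonies.
    """
    pos = env.positions().astype(float)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("patchiness_statistic requires at least two colonies")
    size = env.spec.size
    nn = np.empty(n)
    block = 512
    for start in range(0, n, block):
        chunk = pos[start : start + block]
        dr = _toroidal_delta(chunk[:, None, 0] - pos[None, :, 0], size)
        dc = _toroidal_delta(chunk[:, None, 1] - pos[None, :, 1], size)
        dist = np.sqrt(dr * dr + dc * dc)
        idx = np.arange(start, min(start + block, n))
        dist[idx - start, idx] = np.inf  # exclude self
        nn[start : start + block] = dist.min(axis=1)
    return float(nn.mean())


def save_environment(env: Environment, path) -> None:
    """Write colonies as text (``row col count`` per line) plus a spec sidecar."""
    path = Path(path)
    rows, cols = np.nonzero(env.counts)
    lines = [f"{r} {c} {env.counts[r, c]}" for r, c in zip(rows, cols)]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    sidecar = path.with_suffix(path.suffix + ".spec.json")
    sidecar.write_text(json.dumps(env.spec.to_dict(), sort_keys=True, indent=1))


def load_environment(path) -> Environment:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".spec.json")
    spec = EnvironmentSpec(**json.loads(sidecar.read_text()))
    counts = np.zeros((spec.size, spec.size), dtype=np.int64)
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        r, c, k = (int(tok) for tok in line.split())
        counts[r, c] = k
    env = Environment(spec=spec, counts=counts)
    if env.n_colonies != spec.density:
        raise ValueError(
            f"colony file at {path} holds {env.n_colonies} colonies "
            f"but the spec says {spec.density}"
        )
    return env
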