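"""Hypercube wireframes and the irregularity perturbation.

A d-dimensional hypercube wireframe has 2**d vertices (all sign
combinations of half the side length) and d * 2**(d-1) edges (vertex
pairs that differ in exactly one coordinate).  The stimuli of the
rigidity-judgment task are such wireframes, optionally made irregular by
shifting every vertex in a random direction by a fixed fraction of the
side length.  For 4D objects the shift is, by default, applied on the
three spatial coordinates (x, y, z) only, leaving w untouched; the
``space`` argument allows full-4D displacement for sensitivity studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "WireframeObject",
    "make_hypercube",
    "perturb_vertices",
    "save_obj",
    "save_json",
    "load_json",
    "STANDARD_IRREGULARITY_LEVELS",
]

#: Irregularity levels used in the experiments, as fractions of side length
#: (0.12 <-> a 12 cm shift on a 100 cm object).
STANDARD_IRREGULARITY_LEVELS = (0.0, 0.12, 0.18, 0.24)


@dataclass(frozen=True)
class WireframeObject:
    """A (possibly perturbed) hypercube wireframe.

    Attributes
    ----------
    dimension
        Spatial dimension of the object (the task uses 3 and 4).
    vertices
        ``(V, dimension)`` array of vertex coordinates in cm.
    edges
        ``(E, 2)`` integer array of vertex-index pairs.
    side_length
        Edge length of the unperturbed object, cm.
    irregularity_level
        Fraction of ``side_length`` by which each vertex was displaced
        (0 for a regular object).
    seed
        Seed used for the perturbation, if any.
    """

    dimension: int
    vertices: np.ndarray
    edges: np.ndarray
    side_length: float
    irregularity_level: float = 0.0
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=int))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != self.dimension:
            raise ValueError(
                f"vertices must be (V, {self.dimension}), got {self.vertices.shape}"
            )

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every edge, in the native dimension."""
        diff = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(diff, axis=1)


def make_hypercube(dimension: int, side_length: float = 100.0) -> WireframeObject:
    """Construct a regular ``dimension``-cube wireframe centred on the origin.

    Vertices are every sign combination of ``±side_length/2``; edges join
    vertex pairs at Hamming distance 1 in the sign pattern, so a cube has
    8 vertices / 12 edges and a hypercube (tesseract) 16 / 32.

    Parameters
    ----------
    dimension
        Spatial dimension, at least 2.
    side_length
        Edge length in cm (the stimuli use 100 cm).
    """
    if dimension < 2:
        raise ValueError(f"dimension must be >= 2, got {dimension}")
    if side_length <= 0:
        raise ValueError(f"side_length must be positive, got {side_length}")

    n = 2**dimension
    # vertex i has coordinate k positive iff bit k of i is set
    bits = (np.arange(n)[:, None] >> np.arange(dimension)[None, :]) & 1
    vertices = (bits - 0.5) * side_length

    edges = [
        (i, i ^ (1 << k))
        for i in range(n)
        for k in range(dimension)
        if i < i ^ (1 << k)
    ]
    return WireframeObject(
        dimension=dimension,
        vertices=vertices,
        edges=np.array(sorted(edges)),
        side_length=float(side_length),
    )


def perturb_vertices(
    obj: WireframeObject,
    level: float,
    seed: int,
    space: str = "xyz",
) -> WireframeObject:
    """Displace every vertex by ``level * side_length`` in a random direction.

    Directions are uniform on the unit sphere of the perturbation space
    (isotropic, via normalised standard-normal draws), so each vertex
    moves by exactly the same amount.  For 4D objects with
    ``space="xyz"`` (default) the displacement lives in the first three
    coordinates and w is unchanged; ``space="full"`` perturbs all native
    coordinates.

    Parameters
    ----------
    obj
        Unperturbed wireframe.
    level
        Displacement as a fraction of side length.  The experiments use
        0, 0.12, 0.18 and 0.24; other non-negative values are accepted
        with a warning.
    seed
        Seed for the direction draws; the output is deterministic in it.
    """
    if level < 0:
        raise ValueError(f"irregularity level must be non-negative, got {level}")
    if level not in STANDARD_IRREGULARITY_LEVELS:
        warnings.warn(
            f"irregularity level {level} is outside the standard set "
            f"{STANDARD_IRREGULARITY_LEVELS}",
            stacklevel=2,
        )
    if space not in ("xyz", "full"):
        raise ValueError(f"space must be 'xyz' or 'full', got {space!r}")
    if level == 0:
        return replace(obj, irregularity_level=0.0, seed=seed)

    k = obj.dimension if space == "full" else min(3, obj.dimension)
    rng = np.random.default_rng(seed)
    directions = rng.standard_normal((obj.n_vertices, k))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    displacement = np.zeros_like(obj.vertices)
    displacement[:, :k] = directions * (level * obj.side_length)
    return replace(
        obj,
        vertices=obj.vertices + displacement,
        irregularity_level=float(level),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialisation


def save_obj(obj: WireframeObject, path: str | Path) -> None:
    """Write the wireframe as a Wavefront OBJ line set (``v`` and ``l``).

    Only 3D objects can be written: project 4D objects first.
    """
    if obj.dimension != 3:
        raise ValueError(
            "OBJ export supports 3D wireframes only; project 4D objects first"
        )
    lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in obj.vertices]
    lines += [f"l {a + 1} {b + 1}" for a, b in obj.edges]  # OBJ is 1-based
    Path(path).write_text("\n".join(lines) + "\n")


def save_json(obj: WireframeObject, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_dict(obj), indent=1))


def load_json(path: str | Path) -> WireframeObject:
    return _from_dict(json.loads(Path(path).read_text()))


def _to_dict(obj: WireframeObject) -> dict:
    return {
        "dimension": obj.dimension,
        "vertices": obj.vertices.tolist(),
        "edges": obj.edges.tolist(),
        "side_length": obj.side_length,
        "irregularity_level": obj.irregularity_level,
        "seed": obj.seed,
    }


def _from_dict(d: dict) -> WireframeObject:
    return WireframeObject(
        dimension=int(d["dimension"]),
        vertices=np.array(d["vertices"], dtype=float),
        edges=np.array(d["edges"], dtype=int),
        side_length=float(d["side_length"]),
        irregularity_level=float(d.get("irregularity_level", 0.0)),
        seed=d.get("seed"),
    )
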