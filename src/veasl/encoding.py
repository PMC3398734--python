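"""Encoding geometry: cycles, artery locations, transforms and the encoding matrix.

The encoding matrix ``E`` is ``N x (M + 1)`` for ``N`` encoding cycles and
``M`` arteries: entry ``(i, j)`` is the modulation value of artery ``j`` under
cycle ``i`` and the final column is all ones (the static tissue contribution).
A spatial cycle is a 1-D sinusoidal modulation across the labelling plane
defined by a centre ``(cx, cy)`` in mm, a direction ``theta`` in degrees and a
scale ``D`` in mm; the encoding phase of an artery at ``(x, y)`` is
``phi = pi * d / (2 * D)`` with ``d`` the signed distance of the artery from
the centre along the direction.

Coordinates: x increases to the subject's right, y to the anterior, in mm,
with the origin at the labelling-plane isocentre; directions are measured in
degrees from the +x axis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labelling import PHASE_CONTROL, PHASE_TAG, ModulationModel

__all__ = [
    "EncodingCycle",
    "EncodingScheme",
    "ArteryGeometry",
    "RigidTransform3",
    "AffineTransform6",
    "EncodingMatrix",
    "ClassSpec",
    "signed_distance",
    "encoding_phase",
    "build_encoding_matrix",
    "class_matrices",
    "four_artery_scheme",
]


@dataclass(frozen=True)
class EncodingCycle:
    """One encoding cycle: tag-all, control-all or a spatial modulation."""

    kind: str  # {"tag_all", "control_all", "spatial"}
    cx: float = 0.0
    cy: float = 0.0
    theta_deg: float = 0.0
    D: float = 1.0

    def __post_init__(self):
        if self.kind not in ("tag_all", "control_all", "spatial"):
            raise ValueError(f"unknown cycle kind {self.kind!r}")
        if self.kind == "spatial":
            if not self.D > 0:
                raise ValueError("spatial cycle requires scale D > 0")
            object.__setattr__(self, "theta_deg", float(self.theta_deg) % 360.0)


@dataclass(frozen=True)
class EncodingScheme:
    """An ordered list of encoding cycles."""

    cycles: tuple[EncodingCycle, ...]

    def __post_init__(self):
        object.__setattr__(self, "cycles", tuple(self.cycles))
        if len(self.cycles) < 2:
            raise ValueError("an encoding scheme needs at least 2 cycles")

    def __len__(self):
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    def to_csv(self, path):
        rows = []
        for i, c in enumerate(self.cycles, start=1):
            rows.append(
                dict(cycle=i, kind=c.kind, cx=c.cx, cy=c.cy,
                     theta_deg=c.theta_deg, D=c.D)
            )
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "EncodingScheme":
        df = pd.read_csv(path)
        cycles = [
            EncodingCycle(
                kind=str(r["kind"]), cx=float(r["cx"]), cy=float(r["cy"]),
                theta_deg=float(r["theta_deg"]), D=float(r["D"]),
            )
            for _, r in df.sort_values("cycle").iterrows()
        ]
        return cls(tuple(cycles))


def four_artery_scheme(n_cycles: int = 8) -> EncodingScheme:
    """The reference encoding scheme for four neck arteries planned at
    (+-10, +-10) mm: tag-all, control-all, two left-right encodings, two
    anterior-posterior encodings and two oblique encodings.

    The first six cycles match the in-vivo protocol; the obliques make the
    encoding matrix full rank for the four-artery geometry.
    """
    cycles = [
        EncodingCycle("tag_all"),
        EncodingCycle("control_all"),
        EncodingCycle("spatial", 0.0, 0.0, 0.0, 10.0),
        EncodingCycle("spatial", 20.0, 0.0, 0.0, 10.0),
        EncodingCycle("spatial", 0.0, 0.0, 270.0, 10.0),
        EncodingCycle("spatial", 0.0, 20.0, 270.0, 10.0),
        # Obliques centred off the artery-square diagonals (an oblique whose
        # centre lies on a diagonal cannot separate the two diagonal artery
        # pairs under an odd periodic modulation); crossed directions give a
        # well-conditioned full-rank matrix (smallest singular value ~ 1).
        EncodingCycle("spatial", 20.0, 0.0, 135.0, 4.47),
        EncodingCycle("spatial", 0.0, 20.0, 225.0, 4.47),
    ]
    if n_cycles not in (6, 8):
        raise ValueError("n_cycles must be 6 or 8")
    return EncodingScheme(tuple(cycles[:n_cycles]))


@dataclass
class ArteryGeometry:
    """Planned and current artery locations (mm) and flow speeds (cm/s)."""

    names: list[str]
    planned: np.ndarray  # (M, 2)
    current: np.ndarray | None = None  # (M, 2); defaults to planned
    speeds: np.ndarray | None = None  # (M,) cm/s; defaults to 30

    def __post_init__(self):
        self.planned = np.atleast_2d(np.asarray(self.planned, float))
        if self.current is None:
            self.current = self.planned.copy()
        self.current = np.atleast_2d(np.asarray(self.current, float))
        if self.speeds is None:
            self.speeds = np.full(len(self.planned), 30.0)
        self.speeds = np.asarray(self.speeds, float)
        M = len(self.names)
        if not (self.planned.shape == self.current.shape == (M, 2)):
            raise ValueError("planned/current locations must be (M, 2)")
        if self.speeds.shape != (M,):
            raise ValueError("speeds must be length M")
        if M < 1:
            raise ValueError("need at least one artery")
        if np.any(self.speeds <= 0):
            raise ValueError("flow speeds must be positive")

    @property
    def n_arteries(self) -> int:
        return len(self.names)

    def with_current(self, locations, speeds=None) -> "ArteryGeometry":
        return ArteryGeometry(
            names=list(self.names),
            planned=self.planned.copy(),
            current=np.asarray(locations, float),
            speeds=self.speeds.copy() if speeds is None else np.asarray(speeds, float),
        )

    def to_csv(self, path):
        pd.DataFrame(
            dict(name=self.names, x0=self.planned[:, 0], y0=self.planned[:, 1],
                 v=self.speeds)
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ArteryGeometry":
        df = pd.read_csv(path)
        return cls(
            names=[str(n) for n in df["name"]],
            planned=df[["x0", "y0"]].to_numpy(float),
            speeds=df["v"].to_numpy(float),
        )


def _centroid(points: np.ndarray) -> np.ndarray:
    return np.asarray(points, float).mean(axis=0)


@dataclass(frozen=True)
class RigidTransform3:
    """2-D 3-DOF rigid transform: rotation (degrees) about the centroid of the
    planned locations followed by a translation (mm).

    The rotation matrix is ``[[cos, sin], [-sin, cos]]`` (clockwise for
    positive angles under the package's axis convention).
    """

    theta_deg: float = 0.0
    xd: float = 0.0
    yd: float = 0.0

    def apply(self, planned: np.ndarray) -> np.ndarray:
        planned = np.atleast_2d(np.asarray(planned, float))
        c = _centroid(planned)
        th = np.deg2rad(self.theta_deg)
        R = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        return (planned - c) @ R.T + c + np.array([self.xd, self.yd])

    @property
    def params(self) -> np.ndarray:
        return np.array([self.xd, self.yd, self.theta_deg])


@dataclass(frozen=True)
class AffineTransform6:
    """General 2-D affine transform about the planned-location centroid."""

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 1.0
    xd: float = 0.0
    yd: float = 0.0

    def apply(self, planned: np.ndarray) -> np.ndarray:
        planned = np.atleast_2d(np.asarray(planned, float))
        cen = _centroid(planned)
        A = np.array([[self.a, self.b], [self.c, self.d]])
        return (planned - cen) @ A.T + cen + np.array([self.xd, self.yd])

    @classmethod
    def from_rigid(cls, t: RigidTransform3) -> "AffineTransform6":
        th = np.deg2rad(t.theta_deg)
        return cls(a=np.cos(th), b=np.sin(th), c=-np.sin(th), d=np.cos(th),
                   xd=t.xd, yd=t.yd)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.xd, self.yd])


def apply_rigid3(planned, t: RigidTransform3) -> np.ndarray:
    """Rotate planned locations about their centroid and translate."""
    return t.apply(planned)


def apply_affine6(planned, t: AffineTransform6) -> np.ndarray:
    """Apply a general 2x2 linear map about the centroid plus translation."""
    return t.apply(planned)


def signed_distance(location, cycle: EncodingCycle):
    """Signed distance (mm) of a location from a spatial cycle's centre line,
    measured along the cycle direction:
    ``d = (x - cx) cos(theta) + (y - cy) sin(theta)``.
    """
    if cycle.kind != "spatial":
        raise ValueError("signed_distance is defined for spatial cycles only")
    loc = np.asarray(location, float)
    th = np.deg2rad(cycle.theta_deg)
    return (loc[..., 0] - cycle.cx) * np.cos(th) + (loc[..., 1] - cycle.cy) * np.sin(th)


def encoding_phase(d, D):
    """Encoding phase ``phi = pi * d / (2 * D)`` (radians, unwrapped)."""
    if not np.all(np.asarray(D) > 0):
        raise ValueError("encoding scale D must be positive")
    return np.pi * np.asarray(d, float) / (2.0 * np.asarray(D, float))


@dataclass(frozen=True)
class EncodingMatrix:
    """``N x (M + 1)`` matrix of modulation values; final column all ones."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("encoding matrix must be 2-D")
        if not np.allclose(v[:, -1], 1.0):
            raise ValueError("final (static) column must be all ones")
        if np.any(np.abs(v[:, :-1]) > 1 + 1e-9):
            raise ValueError("artery modulation values must lie in [-1, 1]")

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0]

    @property
    def n_arteries(self) -> int:
        return self.values.shape[1] - 1


def build_encoding_matrix(
    scheme: EncodingScheme,
    arteries: ArteryGeometry,
    model: ModulationModel | None = None,
) -> EncodingMatrix:
    """Evaluate the modulation of every artery under every cycle.

    Spatial rows evaluate ``m(phi_ij, v_j)`` at the artery's encoding phase;
    tag-all / control-all rows evaluate the modulation at the tag / control
    phases (exactly -1 / +1 in ideal mode, speed dependent under a Bloch
    table).  The final column is the unit static column.
    """
    model = model or ModulationModel.ideal()
    M = arteries.n_arteries
    N = len(scheme)
    E = np.ones((N, M + 1))
    locs = arteries.current
    v = arteries.speeds
    for i, cyc in enumerate(scheme):
        if cyc.kind == "tag_all":
            E[i, :M] = model(np.full(M, PHASE_TAG), v)
        elif cyc.kind == "control_all":
            E[i, :M] = model(np.full(M, PHASE_CONTROL), v)
        else:
            d = signed_distance(locs, cyc)
            phi = encoding_phase(d, cyc.D)
            E[i, :M] = model(phi, v)
    return EncodingMatrix(
        values=E,
        provenance=dict(mode=model.mode, n_cycles=N, arteries=list(arteries.names)),
    )


@dataclass(frozen=True)
class ClassSpec:
    """Voxel classification: each class is a subset of arteries (plus static).

    ``selection[c]`` is the ``(M+1) x (L_c+1)`` zero/one matrix whose columns
    pick the class's artery columns and, last, the static column out of the
    full encoding matrix.
    """

    n_arteries: int
    max_per_class: int
    subsets: tuple[tuple[int, ...], ...]

    @property
    def n_classes(self) -> int:
        return len(self.subsets)

    @property
    def selection(self) -> list[np.ndarray]:
        M = self.n_arteries
        mats = []
        for sub in self.subsets:
            P = np.zeros((M + 1, len(sub) + 1))
            for col, j in enumerate(sub):
                P[j, col] = 1.0
            P[M, len(sub)] = 1.0
            mats.append(P)
        return mats

    def column_indices(self, c: int) -> np.ndarray:
        """Indices into the encoding-matrix columns selected by class c."""
        return np.array(list(self.subsets[c]) + [self.n_arteries], dtype=int)


def class_matrices(M: int, L: int, mode: str = "upto") -> ClassSpec:
    """Enumerate artery classes and their selection matrices.

    ``mode='upto'`` (default) includes every subset of size 0..L, including
    the empty static-only class; ``mode='exact'`` includes only subsets of
    size exactly L.
    """
    if not 0 <= L <= M:
        raise ValueError("require 0 <= L <= M")
    if mode not in ("upto", "exact"):
        raise ValueError(f"unknown class mode {mode!r}")
    sizes = range(0, L + 1) if mode == "upto" else [L]
    subsets = []
    for size in sizes:
        subsets.extend(itertools.combinations(range(M), size))
    return ClassSpec(n_arteries=M, max_per_class=L, subsets=tuple(subsets))
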