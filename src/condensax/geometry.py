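"""Spherocylinder geometry: single capped cylinders and linked chains.

A spherocylinder is a cylinder of core length L and radius R closed by two
hemispherical caps; its total volume is pi R^2 L + (4/3) pi R^3.  A chain
links 1-3 spherocylinders cap-to-cap: the end cap-centre of segment i is
the start point of segment i+1.  The bend angle at a joint follows the
liquid-crystal convention used throughout the package: alpha = 180 deg for
the stretched-out (collinear continuation) configuration and alpha = 0 deg
when the two segments fold back parallel to each other.
"""
from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import InvalidGeometryError, InvalidParameterError

_JOINT_TOL = 1e-6


def _as_point(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (3,):
        raise InvalidGeometryError(f"{name} must be a 3-vector, got shape {arr.shape}")
    return arr


def spherocylinder_volume(length: float, radius: float) -> float:
    """Volume of a capped cylinder: pi R^2 L + 4/3 pi R^3."""
    return np.pi * radius**2 * length + 4.0 / 3.0 * np.pi * radius**3


@dataclass(frozen=True)
class Spherocylinder:
    """A capped cylinder defined by its start cap-centre, unit axis, core length and radius."""

    start: np.ndarray
    axis: np.ndarray
    length: float
    radius: float

    def __post_init__(self) -> None:
        start = _as_point(self.start, "start")
        axis = _as_point(self.axis, "axis")
        norm = float(np.linalg.norm(axis))
        if not np.isfinite(norm) or norm < 1e-12:
            raise InvalidGeometryError("degenerate axis vector")
        if abs(norm - 1.0) > 1e-6:
            axis = axis / norm
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "axis", axis)
        if self.length <= 0:
            raise InvalidGeometryError("core length must be positive")
        if self.radius <= 0:
            raise InvalidGeometryError("radius must be positive")

    @property
    def end(self) -> np.ndarray:
        """End cap-centre (start of a linked successor segment)."""
        return self.start + self.axis * self.length

    @property
    def center(self) -> np.ndarray:
        """Centroid; caps are symmetric, so it sits at the core midpoint."""
        return self.start + self.axis * (self.length / 2.0)

    @property
    def volume(self) -> float:
        return spherocylinder_volume(self.length, self.radius)

    def translated(self, shift) -> "Spherocylinder":
        return Spherocylinder(self.start + np.asarray(shift, float), self.axis,
                              self.length, self.radius)


@dataclass(frozen=True)
class SpherocylinderChain:
    """1-3 spherocylinders linked cap-to-cap with equal radii."""

    segments: tuple[Spherocylinder, ...]

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        object.__setattr__(self, "segments", segments)
        if not 1 <= len(segments) <= 3:
            raise InvalidGeometryError("a chain holds 1-3 segments")
        radius = segments[0].radius
        for prev, nxt in zip(segments, segments[1:]):
            if abs(nxt.radius - radius) > 1e-9:
                raise InvalidGeometryError("all radii in a chain must be equal")
            if np.linalg.norm(prev.end - nxt.start) > _JOINT_TOL:
                raise InvalidGeometryError("segment joints must coincide")

    @property
    def radius(self) -> float:
        return self.segments[0].radius

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def joints(self) -> list[np.ndarray]:
        """Shared cap-centres between consecutive segments."""
        return [seg.end for seg in self.segments[:-1]]

    @property
    def angles(self) -> list[float]:
        """Inter-segment bend angles in degrees (180 = stretched out, 0 = folded back)."""
        out = []
        for prev, nxt in zip(self.segments, self.segments[1:]):
            c = float(np.clip(np.dot(prev.axis, nxt.axis), -1.0, 1.0))
            out.append(180.0 - np.degrees(np.arccos(c)))
        return out

    @property
    def volume(self) -> float:
        """Union volume: segment volumes minus one full sphere per shared joint."""
        v = sum(seg.volume for seg in self.segments)
        v -= (self.n_segments - 1) * 4.0 / 3.0 * np.pi * self.radius**3
        return v

    @property
    def reference_point(self) -> np.ndarray:
        """Volume-weighted centroid of the chain (joint spheres counted once)."""
        num = np.zeros(3)
        for seg in self.segments:
            num += seg.volume * seg.center
        v_sphere = 4.0 / 3.0 * np.pi * self.radius**3
        for joint in self.joints:
            num -= v_sphere * joint
        return num / self.volume

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.segments[-1].end - self.segments[0].start))

    def translated(self, shift) -> "SpherocylinderChain":
        return SpherocylinderChain(tuple(s.translated(shift) for s in self.segments))

    def rotated(self, rotation: Rotation, about) -> "SpherocylinderChain":
        """Rigidly rotate the whole chain about a pivot point."""
        about = np.asarray(about, dtype=float)
        segs = []
        for seg in self.segments:
            start = about + rotation.apply(seg.start - about)
            axis = rotation.apply(seg.axis)
            segs.append(Spherocylinder(start, axis, seg.length, seg.radius))
        return SpherocylinderChain(tuple(segs))


@dataclass(frozen=True)
class ModelGeometry:
    """Named preset: segment core lengths (Angstrom) and common radius."""

    name: str
    segment_lengths: tuple[float, ...]
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "segment_lengths", tuple(float(v) for v in self.segment_lengths))
        if any(length <= 0 for length in self.segment_lengths):
            raise InvalidGeometryError("segment lengths must be positive")
        if self.radius <= 0:
            raise InvalidGeometryError("radius must be positive")

    @property
    def total_length(self) -> float:
        return float(sum(self.segment_lengths))

    @property
    def aspect_ratio(self) -> float:
        """Core length over diameter (300/24 = 12.5 for model 1)."""
        return self.total_length / (2.0 * self.radius)

    @property
    def extent(self) -> float:
        """Maximal end-to-end extent including the caps."""
        return self.total_length + 2.0 * self.radius


#: The three rod approximations of the dimer: one, two or three linked segments.
MODEL_GEOMETRIES = MappingProxyType({
    "model1": ModelGeometry("model1", (300.0,), 12.0),
    "model2": ModelGeometry("model2", (155.0, 135.0), 12.0),
    "model3": ModelGeometry("model3", (155.0, 76.0, 50.0), 12.0),
})


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors drawn uniformly on the sphere, shape (n, 3)."""
    if n < 1:
        raise InvalidParameterError("need at least one direction")
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def roll_cap_extend(chain: SpherocylinderChain, new_length: float,
                    target_axis=None, rng: np.random.Generator | None = None
                    ) -> SpherocylinderChain:
    """Append a segment by rolling its cap on the previous end cap.

    The appended segment starts at the previous segment's end cap-centre
    and points along ``target_axis`` (drawn uniformly from ``rng`` when
    omitted).  Passing the previous axis itself yields the stretched-out
    continuation (bend angle 180 deg); its negation folds the chain back
    (bend angle 0 deg).
    """
    if chain.n_segments >= 3:
        raise InvalidGeometryError("chains hold at most three segments")
    if target_axis is None:
        if rng is None:
            raise InvalidParameterError("provide target_axis or rng")
        target_axis = random_unit_vectors(1, rng)[0]
    last = chain.segments[-1]
    new_seg = Spherocylinder(last.end, np.asarray(target_axis, float),
                             float(new_length), chain.radius)
    return SpherocylinderChain(chain.segments + (new_seg,))


def build_chain(geometry: ModelGeometry, start, first_axis,
                later_axes=None, rng: np.random.Generator | None = None
                ) -> SpherocylinderChain:
    """Construct a chain for a preset geometry, one segment at a time."""
    chain = SpherocylinderChain((Spherocylinder(
        np.asarray(start, float), np.asarray(first_axis, float),
        geometry.segment_lengths[0], geometry.radius),))
    for i, length in enumerate(geometry.segment_lengths[1:]):
        axis = None if later_axes is None else later_axes[i]
        chain = roll_cap_extend(chain, length, axis, rng)
    return chain


def segment_segment_distance(p1, d1, p2, d2) -> np.ndarray:
    """Minimum distance between line segments [p1, p1+d1] and [p2, p2+d2].

    All arguments broadcast over a leading batch dimension; returns the
    batch of distances.  Uses the standard clamped closest-point solution.
    """
    p1 = np.atleast_2d(np.asarray(p1, float))
    d1 = np.atleast_2d(np.asarray(d1, float))
    p2 = np.atleast_2d(np.asarray(p2, float))
    d2 = np.atleast_2d(np.asarray(d2, float))
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    # parallel segments: pick s = 0 and clamp t
    s = np.where(denom > 1e-12 * a * e + 1e-30, (b * f - c * e), 0.0)
    s = np.clip(np.divide(s, denom, out=np.zeros_like(s), where=denom > 0), 0.0, 1.0)
    t = np.divide(b * s + f, e, out=np.zeros_like(e), where=e > 0)
    t_clamped = np.clip(t, 0.0, 1.0)
    # re-optimise s for the clamped t
    s = np.clip(np.divide(b * t_clamped - c, a, out=np.zeros_like(a), where=a > 0), 0.0, 1.0)
    closest1 = p1 + s[:, None] * d1
    closest2 = p2 + t_clamped[:, None] * d2
    # one final re-clamp of t for the updated s (Ericson's algorithm)
    t2 = np.clip(np.einsum("ij,ij->i", d2, closest1 - p2) / np.where(e > 0, e, 1.0), 0.0, 1.0)
    closest2 = p2 + t2[:, None] * d2
    return np.linalg.norm(closest1 - closest2, axis=1)


def _chain_segment_arrays(chain: SpherocylinderChain):
    starts = np.array([seg.start for seg in chain.segments])
    vecs = np.array([seg.axis * seg.length for seg in chain.segments])
    return starts, vecs


def clash_check(chain_a: SpherocylinderChain, chain_b: SpherocylinderChain) -> bool:
    """True iff any core segments of the two chains approach closer than R_a + R_b."""
    sa, va = _chain_segment_arrays(chain_a)
    sb, vb = _chain_segment_arrays(chain_b)
    na, nb = len(sa), len(sb)
    ia, ib = np.repeat(np.arange(na), nb), np.tile(np.arange(nb), na)
    d = segment_segment_distance(sa[ia], va[ia], sb[ib], vb[ib])
    return bool(np.any(d < chain_a.radius + chain_b.radius))


def chain_self_clash(chain: SpherocylinderChain) -> bool:
    """Clash between non-consecutive segments of one chain.

    Consecutive segments share a joint cap by construction and are exempt.
    """
    if chain.n_segments < 3:
        return False
    sa, va = _chain_segment_arrays(chain)
    d = segment_segment_distance(sa[:1], va[:1], sa[2:3], va[2:3])
    return bool(d[0] < 2.0 * chain.radius)
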