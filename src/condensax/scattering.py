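"""Scattering amplitudes and intensities of blob and spherocylinder ensembles.

Conventions
-----------
* Lengths in Angstrom, momentum transfer q in 1/Angstrom, intensities in
  arbitrary units (a single global scale factor absorbs the contrast).
* A Gaussian blob has a volume-normalised form amplitude exp(-q^2 sigma^2 / 2)
  (unit value at q = 0); blobs carry unit weight and only the Gaussian
  window modulates them.
* A spherocylinder segment is decomposed into thin disks perpendicular to
  its axis; each disk contributes its exact transverse factor
  2 J1(q_perp r)/(q_perp r) and an axial phase, so the amplitude converges
  to the exact volume integral as the slice spacing shrinks.  One sphere
  amplitude is subtracted per chain joint so a collinear chain equals the
  single spherocylinder of the summed length.
* Orientation averaging uses a fixed, seed-controlled set of momentum
  transfer directions; the brute-force Debye sum is the exact
  orientation-averaged reference for point-like scatterers.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import j1

from .exceptions import EmptyModelError, InvalidParameterError
from .geometry import SpherocylinderChain, Spherocylinder, random_unit_vectors

__all__ = [
    "GaussianBlobEnsemble", "EnsembleModel", "OrientationSet",
    "blob_form_amplitude", "window_weight", "sphere_amplitude",
    "spherocylinder_amplitude", "chain_field", "ensemble_intensity",
    "debye_intensity", "chain_bead_decomposition",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class GaussianBlobEnsemble:
    """N Gaussian blobs of common width sigma inside a bounding sphere."""

    centers: np.ndarray
    sigma_blob: float
    container_diameter: float

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 2 or centers.shape[1] != 3 or centers.shape[0] < 1:
            raise InvalidParameterError("centers must be an (N, 3) array with N >= 1")
        if self.sigma_blob <= 0:
            raise InvalidParameterError("sigma_blob must be positive")
        if self.container_diameter <= 0:
            raise InvalidParameterError("container_diameter must be positive")
        radii = np.linalg.norm(centers, axis=1)
        if np.any(radii > self.container_diameter / 2.0 + 1e-6):
            raise InvalidParameterError("all centers must lie inside the bounding sphere")

    @property
    def n_blobs(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class EnsembleModel:
    """Many model copies (chains, or a blob ensemble) in a windowed container."""

    copies: "list[SpherocylinderChain] | GaussianBlobEnsemble"
    container_diameter: float
    window_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.container_diameter <= 0:
            raise InvalidParameterError("container_diameter must be positive")
        if self.window_sigma is not None and self.window_sigma <= 0:
            raise InvalidParameterError("window_sigma must be positive")
        if isinstance(self.copies, GaussianBlobEnsemble):
            return
        copies = list(self.copies)
        object.__setattr__(self, "copies", copies)
        if copies:
            refs = np.array([c.reference_point for c in copies])
            if np.any(np.linalg.norm(refs, axis=1) > self.container_diameter / 2.0 + 1e-6):
                raise InvalidParameterError("all copy reference points must lie inside the container")

    @property
    def n_copies(self) -> int:
        if isinstance(self.copies, GaussianBlobEnsemble):
            return self.copies.n_blobs
        return len(self.copies)


@dataclass(frozen=True)
class OrientationSet:
    """Fixed set of momentum-transfer directions used for orientation averages."""

    directions: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if dirs.ndim != 2 or dirs.shape[1] != 3 or dirs.shape[0] < 1:
            raise InvalidParameterError("directions must be an (M, 3) array with M >= 1")
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            dirs = dirs / norms[:, None]
        object.__setattr__(self, "directions", dirs)

    @classmethod
    def random(cls, m: int, seed: int) -> "OrientationSet":
        rng = np.random.default_rng(seed)
        return cls(random_unit_vectors(m, rng), seed=seed)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]


# ---------------------------------------------------------------------------
# elementary amplitudes

def blob_form_amplitude(q, sigma_blob: float):
    """Form amplitude exp(-q^2 sigma^2 / 2) of a volume-normalised Gaussian blob."""
    if sigma_blob <= 0:
        raise InvalidParameterError("sigma_blob must be positive")
    q = np.asarray(q, dtype=float)
    return np.exp(-0.5 * (q * sigma_blob) ** 2)


def window_weight(position, center_of_mass, window_sigma: float):
    """Gaussian window exp(-|r - r_cm|^2 / (2 sigma_w^2)), 1 at the centre of mass."""
    if window_sigma <= 0:
        raise InvalidParameterError("window_sigma must be positive")
    position = np.asarray(position, dtype=float)
    center = np.asarray(center_of_mass, dtype=float)
    d2 = np.sum((np.atleast_2d(position) - center) ** 2, axis=-1)
    w = np.exp(-0.5 * d2 / window_sigma**2)
    return float(w[0]) if position.ndim == 1 else w


def sphere_amplitude(q, radius: float):
    """Exact amplitude of a solid sphere, V * 3 (sin x - x cos x) / x^3, x = qR."""
    q = np.asarray(q, dtype=float)
    volume = 4.0 / 3.0 * np.pi * radius**3
    x = q * radius
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    shape = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    return volume * np.where(small, 1.0 - x**2 / 10.0, shape)


def _disk_factor(x):
    """Transverse factor 2 J1(x)/x of a uniform disk, 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x**2 / 8.0, 2.0 * j1(xs) / xs)


@lru_cache(maxsize=64)
def _cap_slices(radius: float, spacing: float):
    """Midpoint slices of one hemispherical cap: (offsets, radii, weights).

    Offsets are measured outward from the cap base plane; weights sum to
    the exact hemisphere volume (2/3) pi R^3.
    """
    n = max(2, int(np.ceil(radius / spacing)))
    d = radius / n
    off = (np.arange(n) + 0.5) * d
    r = np.sqrt(np.maximum(radius**2 - off**2, 0.0))
    w = np.pi * r**2 * d
    w *= (2.0 / 3.0 * np.pi * radius**3) / w.sum()
    return off, r, w


def _segment_field(start, axis, length, radius, q, dirs, spacing):
    """Complex amplitude of one spherocylinder for every (direction, q) pair.

    Returns an (M, Nq) array; the core cylinder is summed in closed form
    (geometric series of slice phases), cap slices are summed explicitly.
    """
    q = np.asarray(q, dtype=float)
    b = dirs @ axis                                   # cos(angle) per direction
    a0 = dirs @ start
    qpar = b[:, None] * q[None, :]
    sin_t = np.sqrt(np.maximum(1.0 - b * b, 0.0))
    qperp = sin_t[:, None] * q[None, :]

    n_core = max(1, int(np.ceil(length / spacing)))
    d_core = length / n_core
    half = 0.5 * qpar * d_core
    den = np.sin(half)
    safe = np.abs(den) > 1e-9
    ratio = np.where(safe, np.sin(n_core * half) / np.where(safe, den, 1.0), float(n_core))
    core = (np.pi * radius**2 * d_core) * _disk_factor(qperp * radius) \
        * np.exp(1j * qpar * (length / 2.0)) * ratio

    off, r_cap, w_cap = _cap_slices(radius, spacing)
    caps = np.zeros_like(core)
    for o, r, w in zip(off, r_cap, w_cap):
        fac = w * _disk_factor(qperp * r)
        caps = caps + fac * (np.exp(-1j * qpar * o) + np.exp(1j * qpar * (length + o)))

    return np.exp(1j * a0[:, None] * q[None, :]) * (core + caps)


def chain_field(chain: SpherocylinderChain, q, dirs, spacing: float | None = None):
    """(M, Nq) complex amplitude of a chain: coherent segment sum minus joint spheres."""
    if spacing is None:
        spacing = chain.radius / 2.0
    q = np.asarray(q, dtype=float)
    total = None
    for seg in chain.segments:
        field = _segment_field(seg.start, seg.axis, seg.length, seg.radius, q, dirs, spacing)
        total = field if total is None else total + field
    sph = sphere_amplitude(q, chain.radius)
    for joint in chain.joints:
        phase = np.exp(1j * (dirs @ joint)[:, None] * q[None, :])
        total = total - sph[None, :] * phase
    return total


def spherocylinder_amplitude(segment_or_chain, q_vector, spacing: float | None = None) -> complex:
    """Complex scattering amplitude of a segment or chain at one q vector."""
    obj = segment_or_chain
    if isinstance(obj, Spherocylinder):
        obj = SpherocylinderChain((obj,))
    q_vector = np.asarray(q_vector, dtype=float)
    q = float(np.linalg.norm(q_vector))
    if q == 0.0:
        return complex(obj.volume)
    direction = (q_vector / q)[None, :]
    return complex(chain_field(obj, np.array([q]), direction, spacing)[0, 0])


# ---------------------------------------------------------------------------
# ensemble intensities

def _blob_partial_sum(centers, weights, q, dirs, chunk=256):
    """P(m, q) = sum_j w_j exp(i q (n_m . r_j)), accumulated in chunks."""
    m = dirs.shape[0]
    partial = np.zeros((m, q.size), dtype=complex)
    for lo in range(0, centers.shape[0], chunk):
        block = centers[lo:lo + chunk]
        w = weights[lo:lo + chunk]
        proj = block @ dirs.T                                   # (n, M)
        phase = np.exp(1j * proj[:, :, None] * q[None, None, :])
        partial += np.einsum("j,jmq->mq", w, phase)
    return partial


def ensemble_intensity(model, q_grid, orientations: OrientationSet,
                       window_sigma: float | None = None,
                       spacing: float | None = None) -> np.ndarray:
    """Orientation-averaged intensity I(q) = <|sum_j w_j A_j(q n_m)|^2>_m.

    ``model`` may be a :class:`GaussianBlobEnsemble`, an
    :class:`EnsembleModel`, or a plain list of chains (then ``window_sigma``
    applies directly).  The Gaussian window is centred on the instantaneous
    centre of mass of the model.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or q.size == 0 or np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise InvalidParameterError("q_grid must be positive and strictly increasing")
    dirs = orientations.directions

    if isinstance(model, EnsembleModel):
        window_sigma = model.window_sigma
        model = model.copies
    if isinstance(model, GaussianBlobEnsemble):
        centers = model.centers
        if centers.shape[0] == 0:
            raise EmptyModelError("blob ensemble is empty")
        com = centers.mean(axis=0)
        weights = (window_weight(centers, com, window_sigma)
                   if window_sigma is not None else np.ones(centers.shape[0]))
        partial = _blob_partial_sum(centers, np.atleast_1d(weights), q, dirs)
        f = blob_form_amplitude(q, model.sigma_blob)
        return f**2 * np.mean(np.abs(partial) ** 2, axis=0)

    chains = list(model)
    if not chains:
        raise EmptyModelError("ensemble contains no copies")
    refs = np.array([c.reference_point for c in chains])
    com = refs.mean(axis=0)
    weights = (window_weight(refs, com, window_sigma)
               if window_sigma is not None else np.ones(len(chains)))
    weights = np.atleast_1d(weights)
    total = np.zeros((dirs.shape[0], q.size), dtype=complex)
    for w, chain in zip(weights, chains):
        total += w * chain_field(chain, q, dirs, spacing)
    return np.mean(np.abs(total) ** 2, axis=0)


def debye_intensity(points, weights, form_amplitude, q_grid,
                    pair_chunk: int = 2_000_000) -> np.ndarray:
    """Exact orientation-averaged intensity of weighted point scatterers.

    I(q) = f(q)^2 * sum_jk w_j w_k sinc(q r_jk); the j = k term is w_j^2.
    ``form_amplitude`` is a callable f(q) or a precomputed array on the grid.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    q = np.asarray(q_grid, dtype=float)
    f = np.asarray(form_amplitude(q) if callable(form_amplitude) else form_amplitude, float)
    n = points.shape[0]
    s = np.full(q.size, float(np.sum(weights**2)))
    # off-diagonal pairs, accumulated in blocks to bound memory
    block = max(1, pair_chunk // max(n, 1))
    for lo in range(0, n - 1, block):
        hi = min(lo + block, n - 1)
        diff = points[lo:hi, None, :] - points[None, lo + 1:, :]
        dist = np.linalg.norm(diff, axis=-1)
        wprod = weights[lo:hi, None] * weights[None, lo + 1:]
        # keep only j < k (upper triangle of this band)
        rows = np.arange(lo, hi)[:, None]
        cols = np.arange(lo + 1, n)[None, :]
        mask = cols > rows
        d = dist[mask]
        wp = wprod[mask]
        x = d[:, None] * q[None, :]
        s = s + 2.0 * np.sum(wp[:, None] * np.sinc(x / np.pi), axis=0)
    return f**2 * s


def chain_bead_decomposition(chain: SpherocylinderChain, spacing: float | None = None):
    """Isotropic Gaussian-bead rendering of a chain for Debye sums.

    Returns ``(points, weights, sigmas)``: slice centres along each axis,
    slice volumes as weights (the joint spheres enter as negative-weight
    beads), and a per-bead Gaussian width.  Transverse second moments are
    matched (sigma = r/2 for a disk of radius r), which is accurate for
    q r << 1 -- the dilute, low-q regime this rendering serves.
    """
    if spacing is None:
        spacing = chain.radius / 2.0
    pts, wts, sig = [], [], []
    for seg in chain.segments:
        n_core = max(1, int(np.ceil(seg.length / spacing)))
        d_core = seg.length / n_core
        s_core = (np.arange(n_core) + 0.5) * d_core
        off, r_cap, w_cap = _cap_slices(seg.radius, spacing)
        s_all = np.concatenate([-off[::-1], s_core, seg.length + off])
        r_all = np.concatenate([r_cap[::-1], np.full(n_core, seg.radius), r_cap])
        w_all = np.concatenate([w_cap[::-1], np.full(n_core, np.pi * seg.radius**2 * d_core), w_cap])
        pts.append(seg.start[None, :] + s_all[:, None] * seg.axis[None, :])
        wts.append(w_all)
        sig.append(r_all / 2.0)
    v_sphere = 4.0 / 3.0 * np.pi * chain.radius**3
    for joint in chain.joints:
        pts.append(joint[None, :])
        wts.append(np.array([-v_sphere]))
        sig.append(np.array([chain.radius / np.sqrt(5.0)]))  # matches sphere Rg
    return np.concatenate(pts), np.concatenate(wts), np.concatenate(sig)
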