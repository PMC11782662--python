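"""Real-space metrics of fitted condensate structures.

* radial distribution function g(r) with finite-volume normalisation
  against a matched uniform Monte-Carlo reference,
* local nematic order parameter S in cubic boxes,
* fractal dimension from the low-q power-law slope of I(q),
* Guinier radius of gyration for dilute profiles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidParameterError
from .profile import ScatteringProfile

__all__ = [
    "RadialDistribution", "NematicReport", "FractalFit",
    "radial_distribution", "nematic_order", "fractal_dimension", "guinier_rg",
]


@dataclass(frozen=True)
class RadialDistribution:
    """Pair-correlation estimate on shells centred at ``r_bins``."""

    r_bins: np.ndarray
    g_values: np.ndarray
    n_pairs: np.ndarray


@dataclass(frozen=True)
class NematicReport:
    """Per-box nematic order parameters for boxes above the count cutoff."""

    box_centers: np.ndarray
    s_values: np.ndarray
    counts: np.ndarray
    box_size: float
    min_count: int

    @property
    def max_s(self) -> float:
        return float(np.max(self.s_values)) if self.s_values.size else float("nan")


@dataclass(frozen=True)
class FractalFit:
    """Fractal dimension d from the slope of log I vs log q."""

    d: float
    stderr: float
    q_window: tuple[float, float]


def _pair_distance_histogram(points: np.ndarray, edges: np.ndarray,
                             block: int = 512) -> np.ndarray:
    """Histogram of all pairwise distances, computed in memory-bounded blocks."""
    counts = np.zeros(edges.size - 1)
    n = points.shape[0]
    for lo in range(0, n - 1, block):
        hi = min(lo + block, n - 1)
        diff = points[lo:hi, None, :] - points[None, lo + 1:, :]
        dist = np.linalg.norm(diff, axis=-1)
        rows = np.arange(lo, hi)[:, None]
        cols = np.arange(lo + 1, n)[None, :]
        counts += np.histogram(dist[cols > rows], bins=edges)[0]
    return counts


def radial_distribution(centers, r_max: float, dr: float,
                        container_diameter: float, n_reference: int = 10,
                        reference_seed: int = 12345) -> RadialDistribution:
    """g(r) of point centres inside a bounded sphere.

    The ideal-gas normalisation is obtained from ``n_reference`` uniform
    placements of the same number of points in the same container, which
    accounts for edge effects without analytic shell-intersection terms.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 2:
        raise InvalidParameterError("need at least two centres")
    if dr <= 0:
        raise InvalidParameterError("dr must be positive")
    if r_max > container_diameter:
        raise InvalidParameterError("r_max must not exceed the container diameter")
    edges = np.arange(0.0, r_max + dr, dr)
    observed = _pair_distance_histogram(centers, edges)

    rng = np.random.default_rng(reference_seed)
    radius = container_diameter / 2.0
    expected = np.zeros_like(observed)
    n = centers.shape[0]
    for _ in range(n_reference):
        pts = np.empty((n, 3))
        filled = 0
        while filled < n:
            cand = rng.uniform(-radius, radius, size=(n - filled, 3))
            keep = cand[np.linalg.norm(cand, axis=1) <= radius]
            pts[filled:filled + keep.shape[0]] = keep
            filled += keep.shape[0]
        expected += _pair_distance_histogram(pts, edges)
    expected /= n_reference

    g = np.divide(observed, expected, out=np.zeros_like(observed), where=expected > 0)
    r_bins = 0.5 * (edges[:-1] + edges[1:])
    return RadialDistribution(r_bins, g, observed)


def nematic_order(positions, axes, box_size: float = 400.0,
                  min_count: int = 30) -> NematicReport:
    """Local nematic order S = (3/2) e in cubic boxes.

    For each box holding at least ``min_count`` particles the order tensor
    T = <u (x) u> - I/3 is diagonalised and S is 3/2 times its largest
    eigenvalue: 0 for isotropic axes, 1 for perfect alignment.  The box
    grid is centred on the origin (the container centre); S is invariant
    under per-particle sign flips u -> -u.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if positions.shape != axes.shape:
        raise InvalidParameterError("one axis per particle is required")
    axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    if box_size <= 0:
        raise InvalidParameterError("box_size must be positive")

    # box index grid centred on the origin
    idx = np.floor(positions / box_size + 0.5).astype(int)
    box_centers, s_values, counts = [], [], []
    keys, inverse = np.unique(idx, axis=0, return_inverse=True)
    for k, key in enumerate(keys):
        members = inverse == k
        count = int(np.count_nonzero(members))
        if count < min_count:
            continue
        u = axes[members]
        tensor = (u.T @ u) / count - np.eye(3) / 3.0
        e = float(np.linalg.eigvalsh(tensor)[-1])
        box_centers.append(key * box_size)
        s_values.append(1.5 * e)
        counts.append(count)
    return NematicReport(np.array(box_centers, dtype=float).reshape(-1, 3),
                         np.array(s_values), np.array(counts, dtype=int),
                         box_size, min_count)


def fractal_dimension(profile: ScatteringProfile,
                      q_window: tuple[float, float] = (0.002, 0.02),
                      form_amplitude=None) -> FractalFit:
    """Fractal dimension d = -(slope of log I vs log q) over the window.

    A mass fractal of dimension d scatters as I(q) = f(q)^2 S(q) with
    S(q) ~ q^-d in the regime between the particle and the aggregate
    size.  When the single-particle form amplitude f(q) is known (e.g.
    the Gaussian-blob width used to render a structure), pass it as
    ``form_amplitude`` (callable or array on the profile grid) so the
    regression runs on the structure factor; otherwise the raw intensity
    is fitted.
    """
    sub = profile.restrict(*q_window)
    if len(sub) < 5:
        raise InvalidParameterError("need at least 5 points inside the fractal window")
    intensity = sub.intensity
    if form_amplitude is not None:
        f = np.asarray(form_amplitude(sub.q) if callable(form_amplitude)
                       else np.asarray(form_amplitude)[
                           (profile.q >= sub.q[0]) & (profile.q <= sub.q[-1])], float)
        if np.any(f <= 0):
            raise InvalidParameterError("form amplitude must be positive on the window")
        intensity = intensity / f**2
    if np.any(intensity <= 0):
        raise InvalidParameterError("intensities in the fractal window must be positive")
    fit = stats.linregress(np.log(sub.q), np.log(intensity))
    return FractalFit(d=-float(fit.slope), stderr=float(fit.stderr),
                      q_window=(float(sub.q[0]), float(sub.q[-1])))


def guinier_rg(profile: ScatteringProfile, qrg_limit: float = 1.3,
               max_iter: int = 50) -> float:
    """Radius of gyration from the Guinier law I(q) ~ I0 exp(-q^2 Rg^2 / 3).

    The admitted low-q range (q Rg <= ``qrg_limit``) is found by fixed-point
    iteration starting from the lowest-q points.
    """
    if np.any(profile.intensity <= 0):
        raise InvalidParameterError("Guinier analysis needs positive intensities")
    q2 = profile.q**2
    log_i = np.log(profile.intensity)

    def fit_range(mask):
        if np.count_nonzero(mask) < 3:
            raise InvalidParameterError("no admissible points for the Guinier fit")
        res = stats.linregress(q2[mask], log_i[mask])
        slope = float(res.slope)
        if slope >= 0:
            raise InvalidParameterError("non-decreasing low-q intensity; no Guinier regime")
        return float(np.sqrt(-3.0 * slope))

    mask = np.zeros_like(q2, dtype=bool)
    mask[: max(3, profile.q.size // 10)] = True
    rg = fit_range(mask)
    for _ in range(max_iter):
        new_mask = profile.q * rg <= qrg_limit
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
        rg = fit_range(mask)
    return rg
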