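"""End-to-end analysis recipes at desk scale.

These functions bundle the pipeline stages into the two benchmark
computations the package is validated on:

* :func:`fractal_recovery` -- generate a random-walk blob structure (an
  ideal chain has mass-fractal dimension 2), compute its orientation-
  averaged scattering and recover the fractal dimension from the low-q
  power-law slope of the structure factor.
* :func:`scaled_droplet_fit` -- fit model-1 spherocylinder copies to the
  noisy scattering of a confined fractal structure with the staged
  greedy reverse-Monte-Carlo procedure, then measure the local nematic
  order and box-occupancy heterogeneity of the fitted structure.

Problem sizes default to desk scale (2,000 blobs; 5,000 copies) rather
than the 50,000-100,000 copies used for beamline data; the procedure is
identical.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MODEL_GEOMETRIES
from .metrics import FractalFit, NematicReport, fractal_dimension, nematic_order
from .profile import ScatteringProfile
from .rmc import FitConfig, FitResult, fit_blobs, place_copies_from_blobs, refine_copies
from .scattering import blob_form_amplitude
from .synthetic import generate_droplet_profile, generate_random_walk_structure

__all__ = ["fractal_recovery", "scaled_droplet_fit", "DropletFitOutcome",
           "box_occupancy"]


def fractal_recovery(seed: int, n_blobs: int = 2000, step_length: float = 200.0,
                     sigma_blob: float = 40.0,
                     q_window: tuple[float, float] = (0.002, 0.02),
                     n_q: int = 25, n_orientations: int = 300) -> FractalFit:
    """Fractal dimension of a synthetic random-walk blob structure.

    The orientation-averaged intensity of Gaussian blobs on an unconfined
    random walk is computed on a log-spaced grid inside the window; the
    blob form factor is divided out and the slope of log S vs log q gives
    d (expected: 2, the ideal-chain mass-fractal dimension).
    """
    walk = generate_random_walk_structure(n_blobs, step_length, seed)
    walk = walk - walk.mean(axis=0)
    q = np.geomspace(q_window[0], q_window[1], n_q)
    profile = generate_droplet_profile(walk, q, seed, sigma_blob=sigma_blob,
                                       noise_fraction=0.0,
                                       n_orientations=n_orientations)
    return fractal_dimension(profile, q_window,
                             form_amplitude=lambda qq: blob_form_amplitude(qq, sigma_blob))


def box_occupancy(positions, box_size: float, container_diameter: float):
    """Counts of points per cubic box fully inside the container sphere."""
    positions = np.asarray(positions, dtype=float)
    idx = np.floor(positions / box_size + 0.5).astype(int)
    keys, counts = np.unique(idx, axis=0, return_counts=True)
    # include empty boxes whose volume lies inside the container
    radius = container_diameter / 2.0
    half = int(np.ceil(radius / box_size))
    grid = np.arange(-half, half + 1)
    centers = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = np.linalg.norm(centers * box_size, axis=1) + box_size * np.sqrt(3) / 2 <= radius
    centers = centers[inside]
    lookup = {tuple(k): c for k, c in zip(keys, counts)}
    return np.array([lookup.get(tuple(c), 0) for c in centers])


@dataclass
class DropletFitOutcome:
    """Everything the scaled droplet benchmark produces."""

    profile: ScatteringProfile
    blob_result: FitResult
    model_result: FitResult
    nematic: NematicReport
    occupancy: np.ndarray


def scaled_droplet_fit(seed: int, n_copies: int = 5000, n_walk: int = 2000,
                       step_length: float = 200.0,
                       container_diameter: float = 6000.0,
                       window_sigma: float = 1500.0, n_blobs: int = 500,
                       n_orientations: int = 96, blob_moves: int = 5000,
                       refine_moves: int = 4000, noise_fraction: float = 0.02,
                       box_size: float = 400.0, min_count: int = 30
                       ) -> DropletFitOutcome:
    """Greedy RMC fit of model-1 copies to a synthetic fractal droplet.

    A confined random walk provides the d = 2 target structure; its noisy
    windowed scattering is fitted first with Gaussian blobs, then model-1
    spherocylinders are placed from the blob mass distribution and
    refined clash-free.  The local nematic order of the result is
    measured in cubic boxes above the count cutoff.
    """
    walk = generate_random_walk_structure(n_walk, step_length, seed,
                                          container_diameter=0.93 * container_diameter)
    walk = walk - walk.mean(axis=0)
    radius = np.linalg.norm(walk, axis=1).max()
    limit = 0.499 * container_diameter
    if radius > limit:
        walk *= limit / radius
    q = np.geomspace(2.1 * np.pi / window_sigma, 0.03, 22)
    profile = generate_droplet_profile(walk, q, seed + 1, sigma_blob=40.0,
                                       noise_fraction=noise_fraction,
                                       window_sigma=window_sigma,
                                       container_diameter=container_diameter,
                                       n_orientations=150)
    blob_config = FitConfig(n_copies=n_blobs, sigma_blob=40.0,
                            container_diameter=container_diameter,
                            window_sigma=window_sigma, q_max=0.03,
                            n_orientations=n_orientations, translation_step=200.0,
                            max_moves=blob_moves, seed=seed + 2,
                            model_geometry="blobs")
    blob_result = fit_blobs(profile, blob_config)
    cyl_config = FitConfig(n_copies=n_copies, container_diameter=container_diameter,
                           window_sigma=window_sigma, q_max=0.03,
                           n_orientations=n_orientations, translation_step=80.0,
                           rotation_step=0.4, max_moves=refine_moves,
                           seed=seed + 3, model_geometry="model1",
                           clash_checking=True)
    initial = place_copies_from_blobs(blob_result, MODEL_GEOMETRIES["model1"], cyl_config)
    model_result = refine_copies(profile, initial, cyl_config)

    chains = model_result.final_model.copies
    positions = np.vstack([[s.center for s in c.segments] for c in chains])
    axes = np.vstack([[s.axis for s in c.segments] for c in chains])
    nematic = nematic_order(positions, axes, box_size=box_size, min_count=min_count)
    refs = np.array([c.reference_point for c in chains])
    occupancy = box_occupancy(refs, box_size, container_diameter)
    return DropletFitOutcome(profile, blob_result, model_result, nematic, occupancy)
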