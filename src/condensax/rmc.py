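"""Greedy reverse-Monte-Carlo fitting of blob and spherocylinder ensembles.

The fit minimises chi^2 between the windowed, orientation-averaged model
intensity and a measured profile.  Moves are random single-particle
translations (blobs) or chain translations/reorientations/joint pivots
(spherocylinders); a move is accepted only when chi^2 strictly decreases,
the moved particle stays inside the container and -- when clash checking
is on -- no new core overlap is created.  The orientation set is drawn
once per fit and reused for every evaluation, so the objective is
deterministic and the chi^2 trace is non-increasing by construction.

The staged refinement follows the blob -> model 1 -> model 2 -> model 3
protocol: model copies are seeded from the blob mass distribution, and
each segmented model is initialised by superimposing its first segment on
its parent's rod and appending the remaining segments clash-free at
random orientations via the rolling-cap construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .exceptions import (DegenerateWindowError, GridMismatchError,
                         InvalidParameterError, OvercrowdedPlacementError,
                         ResolutionError)
from .geometry import (MODEL_GEOMETRIES, ModelGeometry, Spherocylinder,
                       SpherocylinderChain, chain_self_clash, random_unit_vectors,
                       roll_cap_extend, segment_segment_distance)
from .profile import ScatteringProfile
from .scattering import (EnsembleModel, GaussianBlobEnsemble, OrientationSet,
                         blob_form_amplitude, chain_field, window_weight)

__all__ = [
    "FitConfig", "FitResult", "resolution_limit", "chi_squared", "fit_blobs",
    "place_copies_from_blobs", "refine_copies", "staged_pipeline",
    "GaussianBlobRMC", "SpherocylinderRMC",
]

#: slack on the q >= 2 pi / sigma_w resolution guard; the printed fit window
#: 0.002 < q with sigma_w = 3000 A sits marginally below the exact limit.
RESOLUTION_SLACK = 0.05

_MIN_WINDOW_POINTS = 5


def resolution_limit(window_sigma: float) -> float:
    """Smallest resolvable q of a windowed fit, 2 pi / sigma_w."""
    if window_sigma <= 0:
        raise InvalidParameterError("window_sigma must be positive")
    return 2.0 * np.pi / window_sigma


@dataclass(frozen=True)
class FitConfig:
    """Parameters of one reverse-Monte-Carlo stage.

    Defaults mirror the droplet analysis: 4000 blobs of width 40 A in a
    10,000 A sphere with a 3000 A window for the blob stage; the
    spherocylinder stages use a 6000 A sphere with a 1500 A window.
    """

    n_copies: int = 4000
    sigma_blob: float = 40.0
    container_diameter: float = 10_000.0
    window_sigma: float | None = 3000.0
    q_min: float | None = None
    q_max: float = 0.03
    n_orientations: int = 300
    translation_step: float = 50.0
    rotation_step: float = 0.3
    max_moves: int = 10_000
    seed: int = 0
    model_geometry: str = "blobs"
    clash_checking: bool = True
    stall_window: int | None = None
    metropolis_temperature: float | None = None
    placement_retries: int = 400
    validate_moves: bool = False

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise InvalidParameterError("n_copies must be >= 1")
        if self.translation_step <= 0 or self.rotation_step <= 0:
            raise InvalidParameterError("move step sizes must be positive")
        if self.n_orientations < 1:
            raise InvalidParameterError("n_orientations must be >= 1")
        if self.max_moves < 0:
            raise InvalidParameterError("max_moves must be >= 0")
        if self.model_geometry not in ("blobs", *MODEL_GEOMETRIES):
            raise InvalidParameterError(f"unknown model_geometry {self.model_geometry!r}")
        if self.q_min is not None and self.q_min >= self.q_max:
            raise InvalidParameterError("q_min must be smaller than q_max")

    @property
    def resolved_q_min(self) -> float:
        if self.q_min is not None:
            return self.q_min
        if self.window_sigma is not None:
            return resolution_limit(self.window_sigma)
        raise InvalidParameterError("q_min must be given when no window is used")

    def geometry(self) -> ModelGeometry:
        if self.model_geometry == "blobs":
            raise InvalidParameterError("blob stage has no chain geometry")
        return MODEL_GEOMETRIES[self.model_geometry]


@dataclass
class FitResult:
    """Outcome of one greedy stage: final structure, trace and bookkeeping."""

    final_model: "EnsembleModel | GaussianBlobEnsemble"
    chi2_trace: np.ndarray
    scale: float
    n_accepted: int
    n_rejected: int
    seed: int
    config: FitConfig
    window_center: np.ndarray
    orientations: OrientationSet

    @property
    def chi2(self) -> float:
        return float(self.chi2_trace[-1])


# ---------------------------------------------------------------------------
# objective

def chi_squared(model_intensity, experiment: ScatteringProfile,
                fit_window: tuple[float, float] | None = None):
    """(chi^2, optimal scale) of a model curve against a measured profile.

    The global scale c minimising sum_i [(c I_mod - I_exp) / sigma]^2 has the
    closed form c = sum(I_mod I_exp / sigma^2) / sum(I_mod^2 / sigma^2); unit
    weights are used when the profile carries no uncertainties.  The model
    curve must be evaluated on the experiment's q grid inside the window.
    """
    if fit_window is not None:
        experiment = experiment.restrict(*fit_window)
    i_mod = np.asarray(model_intensity, dtype=float)
    if i_mod.shape != experiment.q.shape:
        raise GridMismatchError(
            f"model ({i_mod.size} points) and experiment ({len(experiment)} points) "
            "do not share the q grid inside the fit window")
    inv_var = (1.0 / experiment.uncertainty**2
               if experiment.uncertainty is not None else np.ones_like(i_mod))
    return _chi2_scale(i_mod, experiment.intensity, inv_var)


def _chi2_scale(i_mod, i_exp, inv_var):
    denom = np.sum(i_mod**2 * inv_var)
    if denom <= 0:
        raise InvalidParameterError("model intensity vanishes on the fit window")
    c = float(np.sum(i_mod * i_exp * inv_var) / denom)
    chi2 = float(np.sum(inv_var * (c * i_mod - i_exp) ** 2))
    return chi2, c


def _fit_window(experiment: ScatteringProfile, config: FitConfig) -> ScatteringProfile:
    q_min = config.resolved_q_min
    if config.window_sigma is not None:
        limit = resolution_limit(config.window_sigma)
        if q_min < (1.0 - RESOLUTION_SLACK) * limit:
            raise ResolutionError(
                f"fit window starts at q = {q_min:.4g} below the window-function "
                f"resolution 2 pi / sigma_w = {limit:.4g} 1/A")
    try:
        sub = experiment.restrict(q_min, config.q_max)
    except InvalidParameterError as exc:
        raise DegenerateWindowError(str(exc)) from exc
    if len(sub) < _MIN_WINDOW_POINTS:
        raise DegenerateWindowError(
            f"only {len(sub)} data points inside the fit window; need >= {_MIN_WINDOW_POINTS}")
    return sub


def _accept(delta: float, config: FitConfig, rng: np.random.Generator) -> bool:
    if delta < 0:
        return True
    if config.metropolis_temperature:
        return bool(rng.random() < math.exp(-delta / config.metropolis_temperature))
    return False


def _uniform_in_sphere(n: int, diameter: float, rng: np.random.Generator) -> np.ndarray:
    radius = diameter / 2.0
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-radius, radius, size=(n - filled, 3))
        keep = cand[np.linalg.norm(cand, axis=1) <= radius]
        out[filled:filled + keep.shape[0]] = keep
        filled += keep.shape[0]
    return out


# ---------------------------------------------------------------------------
# blob stage

def fit_blobs(experiment: ScatteringProfile, config: FitConfig) -> FitResult:
    """Greedy RMC fit of Gaussian blobs to a SAXS profile."""
    if config.model_geometry != "blobs":
        raise InvalidParameterError("fit_blobs requires model_geometry='blobs'")
    sub = _fit_window(experiment, config)
    q = sub.q
    inv_var = (1.0 / sub.uncertainty**2 if sub.uncertainty is not None
               else np.ones_like(q))

    rng = np.random.default_rng(config.seed)
    dirs = random_unit_vectors(config.n_orientations, rng)
    orientations = OrientationSet(dirs, seed=config.seed)

    centers = _uniform_in_sphere(config.n_copies, config.container_diameter, rng)
    window_center = centers.mean(axis=0)
    if config.window_sigma is not None:
        weights = np.atleast_1d(window_weight(centers, window_center, config.window_sigma))
    else:
        weights = np.ones(config.n_copies)

    f2 = blob_form_amplitude(q, config.sigma_blob) ** 2
    m = dirs.shape[0]
    partial = np.zeros((m, q.size), dtype=complex)
    for lo in range(0, config.n_copies, 256):
        block = centers[lo:lo + 256]
        proj = block @ dirs.T
        phase = np.exp(1j * proj[:, :, None] * q[None, None, :])
        partial += np.einsum("j,jmq->mq", weights[lo:lo + 256], phase)

    def intensity(p):
        return f2 * np.mean(np.abs(p) ** 2, axis=0)

    chi2, scale = _chi2_scale(intensity(partial), sub.intensity, inv_var)
    trace = [chi2]
    radius = config.container_diameter / 2.0
    n_acc = n_rej = stall = 0

    for _ in range(config.max_moves):
        j = int(rng.integers(config.n_copies))
        new_center = centers[j] + rng.normal(0.0, config.translation_step, size=3)
        accepted = False
        if np.linalg.norm(new_center) <= radius:
            w_new = (window_weight(new_center, window_center, config.window_sigma)
                     if config.window_sigma is not None else 1.0)
            po = dirs @ centers[j]
            pn = dirs @ new_center
            delta = (w_new * np.exp(1j * pn[:, None] * q[None, :])
                     - weights[j] * np.exp(1j * po[:, None] * q[None, :]))
            cand = partial + delta
            chi2_new, scale_new = _chi2_scale(intensity(cand), sub.intensity, inv_var)
            if _accept(chi2_new - chi2, config, rng):
                partial = cand
                centers[j] = new_center
                weights[j] = w_new
                chi2, scale = chi2_new, scale_new
                trace.append(chi2)
                n_acc += 1
                stall = 0
                accepted = True
        if not accepted:
            n_rej += 1
            stall += 1
        if config.stall_window and stall >= config.stall_window:
            break

    ensemble = GaussianBlobEnsemble(centers, config.sigma_blob, config.container_diameter)
    return FitResult(ensemble, np.asarray(trace), scale, n_acc, n_rej,
                     config.seed, config, window_center, orientations)


# ---------------------------------------------------------------------------
# clash bookkeeping

class _CellList:
    """Uniform-grid neighbour lookup over chain reference points."""

    def __init__(self, cutoff: float):
        self.cutoff = cutoff
        self.cells: dict[tuple, set] = {}
        self.keys: dict[int, tuple] = {}

    def _key(self, point) -> tuple:
        return tuple(np.floor(np.asarray(point) / self.cutoff).astype(int))

    def add(self, idx: int, point) -> None:
        key = self._key(point)
        self.cells.setdefault(key, set()).add(idx)
        self.keys[idx] = key

    def remove(self, idx: int) -> None:
        key = self.keys.pop(idx)
        self.cells[key].discard(idx)

    def move(self, idx: int, point) -> None:
        self.remove(idx)
        self.add(idx, point)

    def neighbors(self, point, exclude: int | None = None):
        kx, ky, kz = self._key(point)
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for idx in self.cells.get((kx + dx, ky + dy, kz + dz), ()):
                        if idx != exclude:
                            out.append(idx)
        return out


def _chain_clashes(candidate: SpherocylinderChain, chains, ids) -> bool:
    """Candidate core overlaps any core among chains[ids]?"""
    if not ids:
        return False
    sa = np.array([seg.start for seg in candidate.segments])
    va = np.array([seg.axis * seg.length for seg in candidate.segments])
    sb, vb, rb = [], [], []
    for i in ids:
        for seg in chains[i].segments:
            sb.append(seg.start)
            vb.append(seg.axis * seg.length)
            rb.append(seg.radius)
    sb, vb = np.array(sb), np.array(vb)
    rb = np.array(rb)
    na, nb = sa.shape[0], sb.shape[0]
    ia = np.repeat(np.arange(na), nb)
    ib = np.tile(np.arange(nb), na)
    d = segment_segment_distance(sa[ia], va[ia], sb[ib], vb[ib])
    return bool(np.any(d < candidate.radius + rb[ib]))


def _clash_cutoff(chains) -> float:
    extent = max(sum(s.length for s in c.segments) + 2 * c.radius for c in chains)
    return extent + 2 * max(c.radius for c in chains)


def _centered_chain(geometry: ModelGeometry, position, rng,
                    chains=None, cell=None) -> SpherocylinderChain | None:
    """One random-orientation chain with its reference point at `position`.

    Returns None when the draw clashes (with itself or, when a cell list
    is given, with existing chains); the caller owns the retry budget.
    """
    axes = random_unit_vectors(len(geometry.segment_lengths), rng)
    chain = SpherocylinderChain((Spherocylinder(
        np.zeros(3), axes[0], geometry.segment_lengths[0], geometry.radius),))
    for i, length in enumerate(geometry.segment_lengths[1:]):
        chain = roll_cap_extend(chain, length, axes[i + 1])
    chain = chain.translated(np.asarray(position) - chain.reference_point)
    if chain_self_clash(chain):
        return None
    if cell is not None and _chain_clashes(chain, chains, cell.neighbors(position)):
        return None
    return chain


def place_copies_from_blobs(blob_result: FitResult, geometry: ModelGeometry,
                            config: FitConfig) -> EnsembleModel:
    """Sample chain copies from the blob-fit mass distribution.

    Reference points are drawn from the window-weighted Gaussian mixture
    defined by the fitted blobs, truncated to the (possibly smaller)
    container of ``config``; orientations are uniform; with clash checking
    on, placements are retried until clash-free within the retry budget.
    """
    blobs: GaussianBlobEnsemble = blob_result.final_model
    rng = np.random.default_rng([config.seed, 1])
    if blob_result.config.window_sigma is not None:
        mass = np.atleast_1d(window_weight(blobs.centers, blob_result.window_center,
                                           blob_result.config.window_sigma))
    else:
        mass = np.ones(blobs.n_blobs)
    probs = mass / mass.sum()
    radius = config.container_diameter / 2.0
    chains: list[SpherocylinderChain] = []
    cell = _CellList(geometry.extent + 2 * geometry.radius) if config.clash_checking else None

    for i in range(config.n_copies):
        placed = False
        for attempt in range(config.placement_retries):
            idx = rng.choice(blobs.n_blobs, p=probs)
            # widen the jitter progressively so saturated regions overflow
            # into their surroundings instead of stalling the placement
            spread = blobs.sigma_blob * (1.0 + attempt / 25.0)
            pos = blobs.centers[idx] + rng.normal(0.0, spread, size=3)
            if np.linalg.norm(pos) > radius:
                continue
            for _ in range(4):  # a few orientation draws per position
                chain = _centered_chain(geometry, pos, rng, chains, cell)
                if chain is not None:
                    break
            if chain is None:
                continue
            chains.append(chain)
            if cell is not None:
                cell.add(i, pos)
            placed = True
            break
        if not placed:
            raise OvercrowdedPlacementError(
                f"could not place copy {i} clash-free within "
                f"{config.placement_retries} retries")
    return EnsembleModel(chains, config.container_diameter, config.window_sigma)


# ---------------------------------------------------------------------------
# spherocylinder stage

def _pivot_chain(chain: SpherocylinderChain, joint_index: int, side: int,
                 rotation: Rotation) -> SpherocylinderChain:
    """Rotate the sub-chain on one side of a joint rigidly about the joint."""
    joint = chain.segments[joint_index].end
    segs = list(chain.segments)
    indices = range(joint_index + 1, len(segs)) if side == 0 else range(0, joint_index + 1)
    for i in indices:
        seg = segs[i]
        start = joint + rotation.apply(seg.start - joint)
        axis = rotation.apply(seg.axis)
        segs[i] = Spherocylinder(start, axis, seg.length, seg.radius)
    return SpherocylinderChain(tuple(segs))


def refine_copies(experiment: ScatteringProfile, initial: EnsembleModel,
                  config: FitConfig) -> FitResult:
    """Greedy RMC refinement of chain positions and orientations."""
    sub = _fit_window(experiment, config)
    q = sub.q
    inv_var = (1.0 / sub.uncertainty**2 if sub.uncertainty is not None
               else np.ones_like(q))

    chains = list(initial.copies)
    if not chains:
        raise InvalidParameterError("initial model has no copies")
    n = len(chains)
    rng = np.random.default_rng([config.seed, 2])
    dirs = random_unit_vectors(config.n_orientations, rng)
    orientations = OrientationSet(dirs, seed=config.seed)

    refs = np.array([c.reference_point for c in chains])
    window_center = refs.mean(axis=0)
    sigma_w = initial.window_sigma

    def weight_of(ref):
        return (window_weight(ref, window_center, sigma_w)
                if sigma_w is not None else 1.0)

    weights = np.array([weight_of(r) for r in refs])

    cell = None
    if config.clash_checking:
        cell = _CellList(_clash_cutoff(chains))
        for i, ref in enumerate(refs):
            cell.add(i, ref)
        for i, chain in enumerate(chains):
            if chain_self_clash(chain):
                raise InvalidParameterError(f"initial chain {i} clashes with itself")
            ids = [j for j in cell.neighbors(refs[i], exclude=i) if j > i]
            if _chain_clashes(chain, chains, ids):
                raise InvalidParameterError("initial configuration contains clashes")

    total = np.zeros((dirs.shape[0], q.size), dtype=complex)
    fields_cache_spacing = None  # chains share geometry; default spacing R/2
    for w, chain in zip(weights, chains):
        total += w * chain_field(chain, q, dirs, fields_cache_spacing)

    def intensity(t):
        return np.mean(np.abs(t) ** 2, axis=0)

    chi2, scale = _chi2_scale(intensity(total), sub.intensity, inv_var)
    trace = [chi2]
    radius = initial.container_diameter / 2.0
    n_acc = n_rej = stall = 0
    multi = chains[0].n_segments > 1

    for _ in range(config.max_moves):
        i = int(rng.integers(n))
        old = chains[i]
        kind = int(rng.integers(3 if multi else 2))
        if kind == 0:
            new = old.translated(rng.normal(0.0, config.translation_step, size=3))
        elif kind == 1:
            axis = random_unit_vectors(1, rng)[0]
            angle = rng.normal(0.0, config.rotation_step)
            new = old.rotated(Rotation.from_rotvec(axis * angle), old.reference_point)
        else:
            joint_index = int(rng.integers(old.n_segments - 1))
            side = int(rng.integers(2))
            axis = random_unit_vectors(1, rng)[0]
            angle = rng.normal(0.0, config.rotation_step)
            new = _pivot_chain(old, joint_index, side, Rotation.from_rotvec(axis * angle))

        accepted = False
        new_ref = new.reference_point
        ok = np.linalg.norm(new_ref) <= radius
        if ok and config.clash_checking:
            ok = not chain_self_clash(new) and not _chain_clashes(
                new, chains, cell.neighbors(new_ref, exclude=i))
        if ok:
            w_new = weight_of(new_ref)
            delta = (w_new * chain_field(new, q, dirs, fields_cache_spacing)
                     - weights[i] * chain_field(old, q, dirs, fields_cache_spacing))
            cand = total + delta
            chi2_new, scale_new = _chi2_scale(intensity(cand), sub.intensity, inv_var)
            if _accept(chi2_new - chi2, config, rng):
                total = cand
                chains[i] = new
                refs[i] = new_ref
                weights[i] = w_new
                if cell is not None:
                    cell.move(i, new_ref)
                chi2, scale = chi2_new, scale_new
                trace.append(chi2)
                n_acc += 1
                stall = 0
                accepted = True
                if config.validate_moves and config.clash_checking:
                    # test mode: brute-force the clash-free invariant
                    others = [j for j in range(n) if j != i]
                    assert not chain_self_clash(new)
                    assert not _chain_clashes(new, chains, others)
        if not accepted:
            n_rej += 1
            stall += 1
        if config.stall_window and stall >= config.stall_window:
            break

    model = EnsembleModel(chains, initial.container_diameter, sigma_w)
    return FitResult(model, np.asarray(trace), scale, n_acc, n_rej,
                     config.seed, config, window_center, orientations)


# ---------------------------------------------------------------------------
# staged pipeline

def _grow_stage(parent: EnsembleModel, geometry: ModelGeometry,
                config: FitConfig) -> EnsembleModel:
    """Initialise a segmented model from its parent's chains.

    The first (longest) segment is superimposed on one end of each parent
    chain; the remaining segments are appended clash-free at random
    orientations by rolling their caps on the previous segment's cap.
    """
    rng = np.random.default_rng([config.seed, 3])
    chains = list(parent.copies)
    cell = None
    if config.clash_checking:
        cell = _CellList(max(_clash_cutoff(chains), geometry.extent + 2 * geometry.radius))
        for i, chain in enumerate(chains):
            cell.add(i, chain.reference_point)

    radius = parent.container_diameter / 2.0
    for i, old in enumerate(chains):
        first_old = old.segments[0]
        candidate = None
        for _ in range(config.placement_retries):
            # the first segment is superimposed on one end of the parent's first rod
            if old.n_segments == 1 and rng.integers(2):
                start, axis = first_old.end, -first_old.axis
            else:
                start, axis = first_old.start, first_old.axis
            trial = SpherocylinderChain((Spherocylinder(
                start, axis, geometry.segment_lengths[0], geometry.radius),))
            carried = 1
            for length in geometry.segment_lengths[1:]:
                if carried < old.n_segments:
                    # inherit the parent's direction for segments it already has
                    trial = roll_cap_extend(trial, length, old.segments[carried].axis)
                else:
                    trial = roll_cap_extend(trial, length, None, rng)
                carried += 1
            if np.linalg.norm(trial.reference_point) > radius:
                continue
            if config.clash_checking:
                if chain_self_clash(trial):
                    continue
                ids = cell.neighbors(trial.reference_point, exclude=i)
                if _chain_clashes(trial, chains, ids):
                    continue
            candidate = trial
            break
        if candidate is None:
            # fall back to the fully stretched-out configuration: it occupies
            # a subset of the parent chain's own (clash-free) footprint, so it
            # is always admissible; refinement relaxes the orientation later
            ends = [(first_old.start, first_old.axis)]
            if old.n_segments == 1:
                ends.append((first_old.end, -first_old.axis))
            for start, axis in ends:
                trial = SpherocylinderChain((Spherocylinder(
                    start, axis, geometry.segment_lengths[0], geometry.radius),))
                carried = 1
                for length in geometry.segment_lengths[1:]:
                    direction = (old.segments[carried].axis if carried < old.n_segments
                                 else trial.segments[-1].axis)
                    trial = roll_cap_extend(trial, length, direction)
                    carried += 1
                if np.linalg.norm(trial.reference_point) > radius:
                    continue
                if config.clash_checking and chain_self_clash(trial):
                    continue
                candidate = trial
                break
        if candidate is None:
            # last resort (deeply folded parent): redraw every appended
            # segment at random instead of inheriting the parent's fold
            for attempt in range(config.placement_retries):
                trial = SpherocylinderChain((Spherocylinder(
                    first_old.start, first_old.axis,
                    geometry.segment_lengths[0], geometry.radius),))
                for length in geometry.segment_lengths[1:]:
                    trial = roll_cap_extend(trial, length, None, rng)
                if np.linalg.norm(trial.reference_point) > radius:
                    continue
                if config.clash_checking:
                    if chain_self_clash(trial):
                        continue
                    if _chain_clashes(trial, chains,
                                      cell.neighbors(trial.reference_point, exclude=i)):
                        continue
                candidate = trial
                break
        if candidate is None:
            raise OvercrowdedPlacementError(
                f"could not extend copy {i} clash-free within "
                f"{config.placement_retries} retries")
        chains[i] = candidate
        if cell is not None:
            cell.move(i, candidate.reference_point)
    return EnsembleModel(chains, parent.container_diameter, config.window_sigma)


def staged_pipeline(experiment: ScatteringProfile,
                    configs: Mapping[str, FitConfig]) -> dict[str, FitResult]:
    """Run blobs -> model1 -> model2 -> model3, each stage seeding the next."""
    order = [s for s in ("blobs", "model1", "model2", "model3") if s in configs]
    if not order or order[0] != "blobs":
        raise InvalidParameterError("the staged pipeline starts from a 'blobs' config")
    results: dict[str, FitResult] = {}
    results["blobs"] = fit_blobs(experiment, configs["blobs"])
    prev_model: EnsembleModel | None = None
    for stage in order[1:]:
        config = configs[stage]
        if config.model_geometry != stage:
            config = replace(config, model_geometry=stage)
        geometry = config.geometry()
        if prev_model is None:
            initial = place_copies_from_blobs(results["blobs"], geometry, config)
        else:
            initial = _grow_stage(prev_model, geometry, config)
        results[stage] = refine_copies(experiment, initial, config)
        prev_model = results[stage].final_model
    return results


# ---------------------------------------------------------------------------
# estimator facades

class GaussianBlobRMC(BaseEstimator):
    """Greedy reverse-Monte-Carlo blob fitter with a scikit-learn interface.

    ``fit`` takes a :class:`ScatteringProfile` and exposes the fitted
    ensemble and diagnostics as trailing-underscore attributes.
    """

    def __init__(self, n_blobs=4000, sigma_blob=40.0, container_diameter=10_000.0,
                 window_sigma=3000.0, q_min=None, q_max=0.03, n_orientations=300,
                 translation_step=50.0, max_moves=10_000, seed=0, stall_window=None):
        self.n_blobs = n_blobs
        self.sigma_blob = sigma_blob
        self.container_diameter = container_diameter
        self.window_sigma = window_sigma
        self.q_min = q_min
        self.q_max = q_max
        self.n_orientations = n_orientations
        self.translation_step = translation_step
        self.max_moves = max_moves
        self.seed = seed
        self.stall_window = stall_window

    def _config(self) -> FitConfig:
        return FitConfig(
            n_copies=self.n_blobs, sigma_blob=self.sigma_blob,
            container_diameter=self.container_diameter, window_sigma=self.window_sigma,
            q_min=self.q_min, q_max=self.q_max, n_orientations=self.n_orientations,
            translation_step=self.translation_step, max_moves=self.max_moves,
            seed=self.seed, model_geometry="blobs", clash_checking=False,
            stall_window=self.stall_window)

    def fit(self, X: ScatteringProfile, y=None):
        result = fit_blobs(X, self._config())
        self.result_ = result
        self.ensemble_ = result.final_model
        self.chi2_trace_ = result.chi2_trace
        self.scale_ = result.scale
        self.n_accepted_ = result.n_accepted
        self.n_rejected_ = result.n_rejected
        return self


class SpherocylinderRMC(BaseEstimator):
    """Greedy reverse-Monte-Carlo refinement of spherocylinder-chain copies."""

    def __init__(self, model_geometry="model1", n_copies=50_000,
                 container_diameter=6000.0, window_sigma=1500.0, q_min=None,
                 q_max=0.03, n_orientations=300, translation_step=50.0,
                 rotation_step=0.3, max_moves=10_000, clash_checking=True, seed=0,
                 stall_window=None):
        self.model_geometry = model_geometry
        self.n_copies = n_copies
        self.container_diameter = container_diameter
        self.window_sigma = window_sigma
        self.q_min = q_min
        self.q_max = q_max
        self.n_orientations = n_orientations
        self.translation_step = translation_step
        self.rotation_step = rotation_step
        self.max_moves = max_moves
        self.clash_checking = clash_checking
        self.seed = seed
        self.stall_window = stall_window

    def _config(self) -> FitConfig:
        return FitConfig(
            n_copies=self.n_copies, container_diameter=self.container_diameter,
            window_sigma=self.window_sigma, q_min=self.q_min, q_max=self.q_max,
            n_orientations=self.n_orientations, translation_step=self.translation_step,
            rotation_step=self.rotation_step, max_moves=self.max_moves,
            seed=self.seed, model_geometry=self.model_geometry,
            clash_checking=self.clash_checking, stall_window=self.stall_window)

    def fit(self, X: ScatteringProfile, y=None, initial: EnsembleModel | None = None,
            blob_result: FitResult | None = None):
        config = self._config()
        if initial is None:
            if blob_result is None:
                raise InvalidParameterError("provide an initial model or a blob_result")
            initial = place_copies_from_blobs(blob_result, config.geometry(), config)
        result = refine_copies(X, initial, config)
        self.result_ = result
        self.model_ = result.final_model
        self.chi2_trace_ = result.chi2_trace
        self.scale_ = result.scale
        self.n_accepted_ = result.n_accepted
        self.n_rejected_ = result.n_rejected
        return self
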