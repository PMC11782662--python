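"""Seeded generators for every input the analysis consumes.

The droplet interior is emulated by a confined 3-D random walk of blob
centres: an ideal chain has mass-fractal dimension 2, matching the
power-law decay I(q) ~ q^-2 of the measured droplet scattering.  Dilute
single-particle curves come from an exact Debye sum over a Gaussian-bead
rendering of the rod models.  Crosslink identification and targeted
transition tables are generated with known per-condition link populations
and programmed abundance fold changes, so the filtering and quantification
rules can be tested against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .geometry import (ModelGeometry, Spherocylinder, SpherocylinderChain,
                       random_unit_vectors)
from .profile import ScatteringProfile
from .scattering import (GaussianBlobEnsemble, OrientationSet,
                         chain_bead_decomposition, ensemble_intensity)

__all__ = [
    "generate_random_walk_structure", "generate_droplet_profile",
    "generate_dilute_profile", "chain_radius_of_gyration",
    "LinkPopulation", "XLTables", "generate_xl_tables",
    "default_link_populations", "DEFAULT_CONDITIONS", "HOUSEHOLDER_PEPTIDE",
]

DEFAULT_CONDITIONS = ("dilute", "phase_separated", "supernatant", "pellet")
HOUSEHOLDER_PEPTIDE = "MVLEEVQPTFDR"


# ---------------------------------------------------------------------------
# structures and scattering curves

def generate_random_walk_structure(n: int, step_length: float, seed: int,
                                   container_diameter: float | None = None
                                   ) -> np.ndarray:
    """Centres of an n-step random walk with fixed step length.

    The unconfined walk is an ideal chain (mass-fractal dimension 2,
    <R_ee^2> = n * step^2).  With ``container_diameter`` given, steps
    leaving the sphere are redrawn, confining the walk while keeping the
    local fractal statistics.
    """
    if n < 2:
        raise InvalidParameterError("need at least two particles")
    if step_length <= 0:
        raise InvalidParameterError("step_length must be positive")
    rng = np.random.default_rng(seed)
    if container_diameter is None:
        steps = random_unit_vectors(n - 1, rng) * step_length
        return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    radius = container_diameter / 2.0
    if step_length >= radius:
        raise InvalidParameterError("step_length must be smaller than the container radius")
    points = np.empty((n, 3))
    points[0] = 0.0
    for i in range(1, n):
        while True:
            cand = points[i - 1] + random_unit_vectors(1, rng)[0] * step_length
            if np.linalg.norm(cand) <= radius:
                points[i] = cand
                break
    return points


def generate_droplet_profile(structure, q_grid, seed: int,
                             sigma_blob: float = 40.0,
                             noise_fraction: float = 0.02,
                             window_sigma: float | None = None,
                             n_orientations: int = 300,
                             container_diameter: float | None = None,
                             orientation_seed: int | None = None
                             ) -> ScatteringProfile:
    """Noisy orientation-averaged scattering of a blob structure.

    The noiseless curve is the windowed ensemble intensity of Gaussian
    blobs at the structure's centres; multiplicative Gaussian noise of the
    stated relative size is applied and the per-point uncertainty is set
    to the noise level.  With ``noise_fraction = 0`` the exact curve is
    returned without uncertainties.
    """
    if noise_fraction < 0:
        raise InvalidParameterError("noise_fraction must be nonnegative")
    centers = np.atleast_2d(np.asarray(structure, dtype=float))
    if container_diameter is None:
        container_diameter = 2.0 * float(np.max(np.linalg.norm(centers, axis=1))) + 1.0
    blobs = GaussianBlobEnsemble(centers, sigma_blob, container_diameter)
    orientations = OrientationSet.random(
        n_orientations, seed if orientation_seed is None else orientation_seed)
    clean = ensemble_intensity(blobs, q_grid, orientations, window_sigma=window_sigma)
    if noise_fraction == 0:
        return ScatteringProfile(np.asarray(q_grid, float), clean)
    rng = np.random.default_rng([seed, 7])
    noisy = clean * (1.0 + noise_fraction * rng.standard_normal(clean.size))
    noisy = np.maximum(noisy, 1e-12 * clean.max())
    return ScatteringProfile(np.asarray(q_grid, float), noisy,
                             noise_fraction * clean)


def _stretched_chain(geometry: ModelGeometry) -> SpherocylinderChain:
    segs = []
    s = 0.0
    for length in geometry.segment_lengths:
        segs.append(Spherocylinder(np.array([0.0, 0.0, s]), np.array([0.0, 0.0, 1.0]),
                                   length, geometry.radius))
        s += length
    return SpherocylinderChain(tuple(segs))


def _debye_mixed(points, weights, sigmas, q):
    """Exact orientation-averaged Debye sum with per-bead Gaussian widths."""
    q = np.asarray(q, dtype=float)
    forms = np.exp(-0.5 * (q[None, :] * sigmas[:, None]) ** 2) * weights[:, None]
    diff = points[:, None, :] - points[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    out = np.empty(q.size)
    for k, qk in enumerate(q):
        sinc = np.sinc(qk * dist / np.pi)
        out[k] = forms[:, k] @ sinc @ forms[:, k]
    return out


def generate_dilute_profile(geometry: ModelGeometry, q_grid,
                            noise_fraction: float = 0.02, seed: int = 0,
                            spacing: float | None = None) -> ScatteringProfile:
    """Noisy dilute-solution form factor of a stretched chain model.

    The exact orientation average is a Debye sum over a Gaussian-bead
    rendering of the chain (accurate for q R << 1, the dilute regime of
    interest); noise is applied as in :func:`generate_droplet_profile`.
    """
    if noise_fraction < 0:
        raise InvalidParameterError("noise_fraction must be nonnegative")
    chain = _stretched_chain(geometry)
    points, weights, sigmas = chain_bead_decomposition(chain, spacing)
    q = np.asarray(q_grid, dtype=float)
    clean = _debye_mixed(points, weights, sigmas, q)
    if noise_fraction == 0:
        return ScatteringProfile(q, clean)
    rng = np.random.default_rng([seed, 11])
    noisy = clean * (1.0 + noise_fraction * rng.standard_normal(clean.size))
    noisy = np.maximum(noisy, 1e-12 * clean.max())
    return ScatteringProfile(q, noisy, noise_fraction * clean)


def chain_radius_of_gyration(geometry_or_chain, spacing: float = 1.0) -> float:
    """Radius of gyration of the solid (uniform-density) chain volume.

    Computed from a fine thin-slice decomposition: each disk contributes
    its in-plane second moment r^2/2, joint spheres are subtracted with
    the sphere second moment (3/5) R^2.
    """
    chain = (geometry_or_chain if isinstance(geometry_or_chain, SpherocylinderChain)
             else _stretched_chain(geometry_or_chain))
    pts, wts, moments = [], [], []
    for seg in chain.segments:
        radius = seg.radius
        s = np.arange(-radius, seg.length + radius, spacing) + spacing / 2.0
        s = s[s < seg.length + radius]
        overhang = np.maximum(0.0, np.maximum(-s, s - seg.length))
        r2 = np.maximum(radius**2 - overhang**2, 0.0)
        w = np.pi * r2 * spacing
        w *= seg.volume / w.sum()
        pts.append(seg.start[None, :] + s[:, None] * seg.axis[None, :])
        wts.append(w)
        moments.append(r2 / 2.0)
    v_sphere = 4.0 / 3.0 * np.pi * chain.radius**3
    for joint in chain.joints:
        pts.append(joint[None, :])
        wts.append(np.array([-v_sphere]))
        moments.append(np.array([0.6 * chain.radius**2]))
    pts = np.concatenate(pts)
    wts = np.concatenate(wts)
    moments = np.concatenate(moments)
    com = (wts[:, None] * pts).sum(axis=0) / wts.sum()
    second = np.sum(wts * (np.sum((pts - com) ** 2, axis=1) + moments)) / wts.sum()
    return float(np.sqrt(second))


# ---------------------------------------------------------------------------
# crosslink tables

@dataclass(frozen=True)
class LinkPopulation:
    """Ground-truth description of one crosslinkable species.

    ``presence`` maps condition -> per-replicate detection probability;
    ``abundance`` (optional) maps condition -> mean normalised abundance
    for the targeted-quantification table.
    """

    position_a: int
    position_b: int | None
    presence: Mapping[str, float]
    reagent: str = "dss"
    ld_score_mean: float = 30.0
    ld_score_sd: float = 4.0
    abundance: Mapping[str, float] | None = None
    zerolink: bool = False

    @property
    def peptide(self) -> str:
        if self.position_b is None:
            return f"{self.position_a}"
        a, b = sorted((self.position_a, self.position_b))
        return f"{a}-{b}"

    @property
    def link_type(self) -> str:
        if self.zerolink:
            return "zerolink"
        if self.position_b is None:
            return "monolink"
        return "selflink" if self.position_a == self.position_b else "crosslink"


@dataclass
class XLTables:
    """Synthetic identification and transition tables with their ground truth."""

    identifications: pd.DataFrame
    transitions: pd.DataFrame
    truth: pd.DataFrame


def generate_xl_tables(populations: Sequence[LinkPopulation],
                       conditions: Sequence[str] = DEFAULT_CONDITIONS,
                       n_replicates: int = 3, seed: int = 0,
                       noise_cv: float = 0.05,
                       householder_area: float = 1.0e6) -> XLTables:
    """Identification and targeted transition tables with known composition.

    Identification rows carry residue positions, link type, reagent,
    ld.Score, deltaS (PDH), FDR, condition and replicate.  Transition rows
    carry 5 heavy + 5 light transition areas per targeted peptide per
    replicate plus one householder-peptide row used for normalisation.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    for pop in populations:
        if not pop.presence:
            raise InvalidParameterError(f"population {pop.peptide}: empty presence map")
        if pop.zerolink and pop.reagent != "pdh":
            raise InvalidParameterError(
                f"population {pop.peptide}: zerolinks arise only with PDH")
        if any(not 0 <= p <= 1 for p in pop.presence.values()):
            raise InvalidParameterError(
                f"population {pop.peptide}: presence probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)

    id_rows = []
    for condition in conditions:
        for replicate in range(1, n_replicates + 1):
            for pop in populations:
                if rng.random() >= pop.presence.get(condition, 0.0):
                    continue
                id_rows.append({
                    "position_a": pop.position_a,
                    "position_b": pop.position_b if pop.position_b is not None else np.nan,
                    "link_type": pop.link_type,
                    "reagent": pop.reagent,
                    "ld_score": rng.normal(pop.ld_score_mean, pop.ld_score_sd),
                    "delta_s": rng.uniform(0.91, 0.995) if pop.reagent == "pdh" else np.nan,
                    "fdr": rng.uniform(0.0, 0.04),
                    "condition": condition,
                    "replicate": replicate,
                    "spectra_count": int(1 + rng.poisson(2.0)),
                })
    identifications = pd.DataFrame(id_rows)

    tr_rows = []
    targeted = [p for p in populations if p.abundance is not None]
    # fixed per-peptide transition split, drawn once
    splits = {p.peptide: rng.dirichlet(np.full(5, 8.0)) for p in targeted}
    for condition in conditions:
        for replicate in range(1, n_replicates + 1):
            hh_area = householder_area * rng.lognormal(0.0, 0.05)
            tr_rows.append({"peptide": HOUSEHOLDER_PEPTIDE, "condition": condition,
                            "replicate": replicate, "channel": "householder",
                            "transition": 1, "area": hh_area})
            for pop in targeted:
                mean = pop.abundance.get(condition)
                if mean is None:
                    raise InvalidParameterError(
                        f"population {pop.peptide}: no abundance for condition {condition}")
                total = mean * hh_area * rng.lognormal(0.0, noise_cv)
                for channel, share in (("heavy", 0.5), ("light", 0.5)):
                    for t in range(5):
                        tr_rows.append({
                            "peptide": pop.peptide, "condition": condition,
                            "replicate": replicate, "channel": channel,
                            "transition": t + 1,
                            "area": total * share * splits[pop.peptide][t],
                        })
    transitions = pd.DataFrame(tr_rows)

    truth_rows = []
    for pop in populations:
        row = {"peptide": pop.peptide, "position_a": pop.position_a,
               "position_b": pop.position_b, "link_type": pop.link_type,
               "reagent": pop.reagent, "ld_score_mean": pop.ld_score_mean}
        for condition in conditions:
            row[f"presence_{condition}"] = pop.presence.get(condition, 0.0)
            if pop.abundance is not None:
                row[f"abundance_{condition}"] = pop.abundance.get(condition, np.nan)
        truth_rows.append(row)
    return XLTables(identifications, transitions, pd.DataFrame(truth_rows))


def default_link_populations() -> list[LinkPopulation]:
    """A condensation-experiment-like population: shared, condition-specific
    and sub-threshold species over four conditions.

    Includes pellet-only crosslinks, coiled-coil selflinks enriched in the
    condensed conditions, monolinks depleted there, and a PDH set covering
    the C-terminal region; targeted abundances program a 2-fold (or larger)
    enrichment of the pellet-specific links.
    """
    everywhere = {c: 0.9 for c in DEFAULT_CONDITIONS}
    pellet_only = {"pellet": 0.95}
    pops: list[LinkPopulation] = []

    # pellet-specific crosslinks with programmed 2x pellet enrichment
    for a, b in [(211, 346), (211, 359), (216, 245), (79, 338), (245, 346)]:
        pops.append(LinkPopulation(a, b, pellet_only, abundance={
            "dilute": 1.0, "phase_separated": 2.0, "supernatant": 1.0, "pellet": 2.0}))
    # crosslinks shared by all conditions
    for a, b in [(23, 374), (81, 150), (5, 81), (150, 207), (189, 220),
                 (220, 245), (95, 245), (120, 311), (23, 95), (150, 189)]:
        pops.append(LinkPopulation(a, b, everywhere))
    # coiled-coil selflinks, more present in the condensed conditions
    for a in (207, 311, 338, 374):
        pops.append(LinkPopulation(a, a, {
            "dilute": 0.5, "phase_separated": 0.9, "supernatant": 0.5, "pellet": 0.9}))
    # monolinks, depleted on condensation
    for a in (15, 95, 120, 224, 300, 410):
        pops.append(LinkPopulation(a, None, {
            "dilute": 0.9, "phase_separated": 0.6, "supernatant": 0.9, "pellet": 0.6}))
    # sub-threshold identifications that the score filter must remove
    for a, b in [(30, 260), (101, 330)]:
        pops.append(LinkPopulation(a, b, everywhere, ld_score_mean=14.0, ld_score_sd=2.0))
    # sporadic single-replicate species removed by the consistency rule
    pops.append(LinkPopulation(60, 300, {c: 0.25 for c in DEFAULT_CONDITIONS}))
    # PDH crosslinks covering the acidic C-terminal region
    for a, b in [(240, 395), (395, 420), (405, 432), (374, 440)]:
        pops.append(LinkPopulation(a, b, {"dilute": 0.9, "phase_separated": 0.9},
                                   reagent="pdh", ld_score_mean=32.0))
    return pops
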