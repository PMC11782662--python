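"""1-D SAXS profiles and their plain-text interchange format.

A profile is a measured or simulated scattering curve I(q) on a strictly
increasing, positive momentum-transfer grid q (1/Angstrom), with optional
positive per-point uncertainties in the same (arbitrary) units as the
intensity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScatteringProfile:
    """One-dimensional scattering curve on a q grid.

    Parameters
    ----------
    q : array of float
        Momentum-transfer values in 1/Angstrom, strictly increasing, > 0.
    intensity : array of float
        Nonnegative intensities (arbitrary units), same length as ``q``.
    uncertainty : array of float, optional
        Positive 1-sigma uncertainties, same length and units as ``intensity``.
    """

    q: np.ndarray
    intensity: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", intensity)
        if q.ndim != 1 or q.size == 0:
            raise InvalidParameterError("q must be a non-empty 1-D array")
        if np.any(q <= 0):
            raise InvalidParameterError("q values must be strictly positive")
        if np.any(np.diff(q) <= 0):
            raise InvalidParameterError("q values must be strictly increasing")
        if intensity.shape != q.shape:
            raise InvalidParameterError("intensity and q must have the same length")
        if np.any(intensity < 0):
            raise InvalidParameterError("intensities must be nonnegative")
        if self.uncertainty is not None:
            unc = np.asarray(self.uncertainty, dtype=float)
            object.__setattr__(self, "uncertainty", unc)
            if unc.shape != q.shape:
                raise InvalidParameterError("uncertainty and q must have the same length")
            if np.any(unc <= 0):
                raise InvalidParameterError("uncertainties must be strictly positive")

    def __len__(self) -> int:
        return self.q.size

    def restrict(self, q_min: float, q_max: float) -> "ScatteringProfile":
        """Return the sub-profile with q_min <= q <= q_max."""
        mask = (self.q >= q_min) & (self.q <= q_max)
        if not np.any(mask):
            raise InvalidParameterError(
                f"no data points in the window [{q_min}, {q_max}]"
            )
        unc = self.uncertainty[mask] if self.uncertainty is not None else None
        return ScatteringProfile(self.q[mask], self.intensity[mask], unc)


def read_saxs_profile(path) -> ScatteringProfile:
    """Read a 2- or 3-column text profile (q, I[, sigma]).

    Columns may be separated by whitespace or commas; lines starting with
    '#' are comments.  Rows with non-positive q are dropped with a logged
    warning; non-numeric content raises :class:`ParseError` naming the line.
    """
    rows = []
    n_dropped = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            try:
                values = [float(tok) for tok in tokens]
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric content on line {lineno}") from exc
            if len(values) not in (2, 3):
                raise ParseError(
                    f"{path}: expected 2 or 3 columns on line {lineno}, got {len(values)}"
                )
            if values[0] <= 0:
                n_dropped += 1
                continue
            rows.append(values)
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with non-positive q", path, n_dropped)
    if not rows:
        raise ParseError(f"{path}: no usable data rows")
    n_cols = min(len(r) for r in rows)
    data = np.array([r[:n_cols] for r in rows], dtype=float)
    unc = data[:, 2] if n_cols == 3 else None
    return ScatteringProfile(data[:, 0], data[:, 1], unc)


def write_saxs_profile(profile: ScatteringProfile, path) -> None:
    """Write a profile as 3-column (or 2-column) text, 6+ significant digits."""
    cols = [profile.q, profile.intensity]
    header = "q(1/A) I(a.u.)"
    if profile.uncertainty is not None:
        cols.append(profile.uncertainty)
        header += " sigma(a.u.)"
    np.savetxt(path, np.column_stack(cols), fmt="%.8e", header=header)
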