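"""Structure file output: pseudo-atom PDB and the XYZ-with-axis table.

The XYZ table is the lossless interchange format consumed by the metrics
stage: one row per segment with the segment midpoint, unit axis, core
length, radius, segment index and chain id.  The PDB output (via gemmi)
is a visualisation aid with one pseudo-atom per blob or per chain
reference point; PDB fixed columns cannot hold coordinates beyond
9999 Angstrom, so PDB coordinates are written in nanometres (noted in a
REMARK).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .geometry import Spherocylinder, SpherocylinderChain
from .scattering import EnsembleModel, GaussianBlobEnsemble

__all__ = ["write_structure", "read_xyz_table", "chains_from_xyz", "blobs_from_xyz"]

_XYZ_COLUMNS = ["chain_id", "segment", "x", "y", "z",
                "axis_x", "axis_y", "axis_z", "length", "radius"]


def _points_of(model):
    if isinstance(model, GaussianBlobEnsemble):
        return model.centers
    if isinstance(model, EnsembleModel):
        if isinstance(model.copies, GaussianBlobEnsemble):
            return model.copies.centers
        return np.array([c.reference_point for c in model.copies])
    raise InvalidParameterError(f"cannot write structure of type {type(model).__name__}")


def _chains_of(model):
    if isinstance(model, EnsembleModel) and not isinstance(model.copies, GaussianBlobEnsemble):
        return model.copies
    return None


def write_structure(model, path, format: str = "xyz") -> None:
    """Write a blob ensemble or chain model as 'pdb' or 'xyz' (table)."""
    if format == "pdb":
        _write_pdb(model, path)
    elif format == "xyz":
        _write_xyz(model, path)
    else:
        raise InvalidParameterError(f"unknown structure format {format!r}")


def _write_pdb(model, path) -> None:
    import gemmi

    structure = gemmi.Structure()
    structure.name = "condensax pseudo-atom model"
    model_g = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, point in enumerate(_points_of(model)):
        residue = gemmi.Residue()
        residue.name = "BLB"
        residue.seqid = gemmi.SeqId(i % 9999 + 1, " ")
        atom = gemmi.Atom()
        atom.name = "C"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*(np.asarray(point) / 10.0))  # nm, see module docstring
        residue.add_atom(atom)
        chain.add_residue(residue)
    model_g.add_chain(chain)
    structure.add_model(model_g)
    structure.raw_remarks = ["REMARK   3 PSEUDO-ATOM MODEL, COORDINATES IN NANOMETRES"]
    structure.write_pdb(str(path))


def _write_xyz(model, path) -> None:
    chains = _chains_of(model)
    rows = []
    if chains is None:
        for i, point in enumerate(_points_of(model)):
            sigma = model.sigma_blob if isinstance(model, GaussianBlobEnsemble) \
                else model.copies.sigma_blob
            rows.append([i, 0, *point, 0.0, 0.0, 0.0, 0.0, sigma])
    else:
        for i, ch in enumerate(chains):
            for j, seg in enumerate(ch.segments):
                rows.append([i, j, *seg.center, *seg.axis, seg.length, seg.radius])
    frame = pd.DataFrame(rows, columns=_XYZ_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.10g")


def read_xyz_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_XYZ_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidParameterError(f"XYZ table misses columns {sorted(missing)}")
    return frame


def chains_from_xyz(frame: pd.DataFrame) -> list[SpherocylinderChain]:
    """Rebuild chains from an XYZ-with-axis table."""
    chains = []
    for _, grp in frame.groupby("chain_id", sort=True):
        segs = []
        for row in grp.sort_values("segment").itertuples():
            mid = np.array([row.x, row.y, row.z])
            axis = np.array([row.axis_x, row.axis_y, row.axis_z])
            start = mid - axis * row.length / 2.0
            segs.append(Spherocylinder(start, axis, row.length, row.radius))
        chains.append(SpherocylinderChain(tuple(segs)))
    return chains


def blobs_from_xyz(frame: pd.DataFrame, container_diameter: float) -> GaussianBlobEnsemble:
    """Rebuild a blob ensemble from a table written for blobs."""
    centers = frame[["x", "y", "z"]].to_numpy()
    sigma = float(frame["radius"].iloc[0])
    return GaussianBlobEnsemble(centers, sigma, container_diameter)
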