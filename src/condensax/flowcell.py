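"""Droplet-statistics arithmetic for flow-cell SAXS measurements.

A sample flowing through the illuminated volume is continuously renewed;
these helpers quantify how many droplets contribute to an averaged
measurement, which justifies treating the data as an orientational and
configurational ensemble average.
"""
from __future__ import annotations

from .exceptions import InvalidParameterError


def sample_renewals(flow_velocity_mm_s: float, beam_extent_um: float,
                    exposure_s: float = 1.0) -> float:
    """Number of times the illuminated volume is renewed during one exposure.

    With a 7.5 mm/s flow through a 12 um beam footprint the sample is
    renewed 625 times per one-second exposure.
    """
    if flow_velocity_mm_s <= 0 or beam_extent_um <= 0 or exposure_s <= 0:
        raise InvalidParameterError("velocity, beam extent and exposure must be positive")
    return flow_velocity_mm_s * 1000.0 / beam_extent_um * exposure_s


def droplets_per_measurement(droplets_in_beam: float, renewals_per_exposure: float,
                             n_exposures: int) -> float:
    """Total droplets contributing to an averaged measurement.

    ~40 droplets in the beam at any instant, renewed 625 times per
    exposure, over 40 averaged exposures gives ~1e6 droplets.
    """
    if droplets_in_beam <= 0 or renewals_per_exposure <= 0 or n_exposures <= 0:
        raise InvalidParameterError("all factors must be positive")
    return droplets_in_beam * renewals_per_exposure * n_exposures
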