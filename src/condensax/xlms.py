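"""Post-identification crosslinking-MS analysis.

Operates on identification tables (one row per identified crosslinked
peptide per condition and replicate) and targeted transition-intensity
tables.  Implements link-type classification, the qualitative quality /
consistency filters, domain mapping on the 440-residue reference
sequence, householder-peptide normalisation, differential abundance
analysis and conformo-specific link selection.

Link types: a *crosslink* joins two different residues, a *monolink* is a
single reagent-modified residue, a *selflink* joins two positionally
identical residues (necessarily inter-molecular in a homodimer) and a
*zerolink* joins directly bonded residues without a linker (PDH only).

All printed thresholds are strict inequalities: ld.Score > 20 (DSS),
ld.Score > 25 with deltaS > 0.9 and FDR < 0.05 (PDH), log2 fold change > 1
for enrichment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SEQUENCE_LENGTH", "DomainMap", "default_domain_map", "classify_link",
    "peptide_key", "filter_qualitative_dss", "filter_qualitative_pdh",
    "assign_domains", "aggregate_domain_counts", "normalize_quant",
    "differential_analysis", "conformo_specific", "summarize_counts",
]

SEQUENCE_LENGTH = 440

LINK_TYPES = ("crosslink", "monolink", "selflink", "zerolink")


@dataclass(frozen=True)
class DomainMap:
    """Named residue intervals (1-based, inclusive) on the reference sequence.

    ``regions`` are the non-overlapping top-level intervals used for
    aggregation; ``subregions`` carry finer annotation (linker L2, zinc
    finger, tail, coiled-coil segments) and are informational.
    """

    regions: Mapping[str, tuple[int, int]]
    subregions: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", MappingProxyType(dict(self.regions)))
        object.__setattr__(self, "subregions", MappingProxyType(dict(self.subregions)))
        spans = sorted(self.regions.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise InvalidParameterError("top-level regions must not overlap")
        for a, b in list(self.regions.values()) + list(self.subregions.values()):
            if not (1 <= a <= b <= SEQUENCE_LENGTH):
                raise InvalidParameterError("intervals must lie within the sequence")

    def region_of(self, position: int) -> str:
        _check_position(position)
        for name, (a, b) in self.regions.items():
            if a <= position <= b:
                return name
        raise InvalidParameterError(f"position {position} is not covered by any region")


def default_domain_map() -> DomainMap:
    """Domain boundaries of the reference protein (CLIP-170 family +TIP dimer)."""
    return DomainMap(
        regions={
            "CAP-Gly": (1, 80),
            "L1": (81, 188),
            "coiled coil": (189, 389),
            "C-terminal": (390, 440),
        },
        subregions={
            "L2": (390, 419),
            "zinc finger": (420, 431),
            "tail": (432, 440),
            "coiled-coil A": (189, 297),
            "coiled-coil B": (302, 357),
            "coiled-coil C": (363, 389),
        },
    )


def _check_position(position: int) -> None:
    if not (1 <= int(position) <= SEQUENCE_LENGTH):
        raise InvalidParameterError(
            f"residue position {position} outside 1..{SEQUENCE_LENGTH}")


def classify_link(position_a: int, position_b: int | None,
                  reagent: str = "dss", zerolink: bool = False) -> str:
    """Link type from the residue positions (symmetric in a and b)."""
    _check_position(position_a)
    if position_b is None or (isinstance(position_b, float) and np.isnan(position_b)):
        return "monolink"
    _check_position(position_b)
    if zerolink:
        if reagent != "pdh":
            raise InvalidParameterError("zerolinks arise only with the PDH reagent")
        return "zerolink"
    return "selflink" if int(position_a) == int(position_b) else "crosslink"


def peptide_key(position_a, position_b, link_type: str, reagent: str) -> str:
    """Order-normalised uniqueness key of a crosslinked peptide."""
    if position_b is None or (isinstance(position_b, float) and np.isnan(position_b)):
        return f"{int(position_a)}|{link_type}|{reagent}"
    a, b = sorted((int(position_a), int(position_b)))
    return f"{a}-{b}|{link_type}|{reagent}"


def _with_keys(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["peptide"] = [
        peptide_key(r.position_a, r.position_b, r.link_type, r.reagent)
        for r in records.itertuples()
    ]
    return out


def filter_qualitative_dss(records: pd.DataFrame, min_score: float = 20.0,
                           min_replicates: int = 2) -> pd.DataFrame:
    """Quality and consistency filter for DSS identifications.

    Keeps an observation iff its ld.Score exceeds ``min_score`` (strict)
    and the same unique peptide passes that score in at least
    ``min_replicates`` distinct replicates of the same condition.  The
    stricter reading of the consistency rule is used: every contributing
    observation must itself pass the score threshold.
    """
    if records.empty:
        return records.copy()
    recs = _with_keys(records[records["reagent"] == "dss"])
    good = recs[recs["ld_score"] > min_score]
    if good.empty:
        return good.drop(columns="peptide")
    reps = good.groupby(["condition", "peptide"])["replicate"].nunique()
    keep = reps[reps >= min_replicates].index
    mask = pd.MultiIndex.from_frame(good[["condition", "peptide"]]).isin(keep)
    return good[mask].drop(columns="peptide")


def filter_qualitative_pdh(records: pd.DataFrame, min_score: float = 25.0,
                           min_delta_s: float = 0.9,
                           max_fdr: float = 0.05) -> pd.DataFrame:
    """Quality filter for PDH identifications (no replicate requirement).

    All three thresholds are applied conjunctively and strictly; records
    missing deltaS or FDR are rejected with a logged warning.
    """
    if records.empty:
        return records.copy()
    recs = records[records["reagent"] == "pdh"]
    missing = recs["delta_s"].isna() | recs["fdr"].isna()
    if missing.any():
        logger.warning("rejecting %d PDH record(s) missing deltaS or FDR",
                       int(missing.sum()))
    recs = recs[~missing]
    return recs[(recs["ld_score"] > min_score)
                & (recs["delta_s"] > min_delta_s)
                & (recs["fdr"] < max_fdr)]


def assign_domains(records: pd.DataFrame,
                   domain_map: DomainMap | None = None) -> pd.DataFrame:
    """Map each record's positions to top-level regions.

    Adds ``region_a`` / ``region_b`` columns and an order-normalised
    ``region_pair`` label (monolinks get their single region).
    """
    if domain_map is None:
        domain_map = default_domain_map()
    out = records.copy()
    region_a, region_b, pair = [], [], []
    for r in records.itertuples():
        ra = domain_map.region_of(int(r.position_a))
        if r.position_b is None or (isinstance(r.position_b, float) and np.isnan(r.position_b)):
            rb = None
            pair.append(ra)
        else:
            rb = domain_map.region_of(int(r.position_b))
            pair.append(" / ".join(sorted((ra, rb))))
        region_a.append(ra)
        region_b.append(rb)
    out["region_a"] = region_a
    out["region_b"] = region_b
    out["region_pair"] = pair
    return out


def aggregate_domain_counts(records: pd.DataFrame,
                            domain_map: DomainMap | None = None) -> pd.DataFrame:
    """Sum identified spectra per region pair and link category."""
    annotated = assign_domains(records, domain_map)
    agg = (annotated.groupby(["region_pair", "link_type"])["spectra_count"]
           .sum().reset_index(name="n_spectra"))
    return agg.sort_values(["region_pair", "link_type"]).reset_index(drop=True)


def normalize_quant(transitions: pd.DataFrame,
                    householder: str = "MVLEEVQPTFDR",
                    n_transitions: int = 5) -> pd.DataFrame:
    """Normalised abundances from a targeted transition-intensity table.

    The abundance of a crosslinked peptide in one replicate is the sum of
    its 10 common transition areas (5 heavy + 5 light) divided by the
    householder (non-crosslinked reference) peptide area of the same
    replicate.  A missing householder raises an error naming the
    replicate; fewer than 5 transitions per form is an error.
    """
    required = {"peptide", "condition", "replicate", "channel", "transition", "area"}
    if not required.issubset(transitions.columns):
        raise InvalidParameterError(
            f"transition table misses columns {sorted(required - set(transitions.columns))}")
    hh = transitions[transitions["peptide"] == householder]
    hh_area = hh.groupby(["condition", "replicate"])["area"].sum()
    rows = []
    peptides = transitions[transitions["peptide"] != householder]
    for (pep, condition, replicate), grp in peptides.groupby(
            ["peptide", "condition", "replicate"]):
        if (condition, replicate) not in hh_area.index:
            raise InvalidParameterError(
                f"householder peptide missing in condition {condition!r} "
                f"replicate {replicate}")
        for channel in ("heavy", "light"):
            n = int((grp["channel"] == channel).sum())
            if n < n_transitions:
                raise InvalidParameterError(
                    f"peptide {pep} ({condition}, replicate {replicate}): "
                    f"{n} {channel} transitions, need {n_transitions}")
        total = grp[grp["channel"].isin(["heavy", "light"])]["area"].sum()
        rows.append({"peptide": pep, "condition": condition, "replicate": replicate,
                     "abundance": total / hh_area.loc[(condition, replicate)]})
    return pd.DataFrame(rows)


def differential_analysis(abundances: pd.DataFrame, condition_a: str,
                          condition_b: str, welch: bool = False,
                          fdr_correct: bool = False) -> pd.DataFrame:
    """Per-peptide log2 fold change A/B with a two-sided unpaired t-test.

    ``enriched`` flags log2FC > 1 (strict).  The pooled-variance Student
    test is the default; ``welch`` switches to unequal variances.
    Peptides with fewer than two replicates in either condition, or a
    non-positive mean, are skipped with a warning.  ``fdr_correct``
    optionally adds Benjamini-Hochberg adjusted p-values.
    """
    rows = []
    for pep, grp in abundances.groupby("peptide"):
        a = grp.loc[grp["condition"] == condition_a, "abundance"].to_numpy()
        b = grp.loc[grp["condition"] == condition_b, "abundance"].to_numpy()
        if a.size < 2 or b.size < 2:
            logger.warning("peptide %s: fewer than 2 replicates per condition; skipped", pep)
            continue
        if a.mean() <= 0 or b.mean() <= 0:
            logger.warning("peptide %s: non-positive mean abundance; skipped", pep)
            continue
        log2fc = float(np.log2(a.mean() / b.mean()))
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.isclose(a.mean(), b.mean()):
            p_value = 1.0
        else:
            p_value = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
        rows.append({"peptide": pep, "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                     "log2fc": log2fc, "p_value": p_value, "enriched": log2fc > 1.0})
    out = pd.DataFrame(rows)
    if fdr_correct and not out.empty:
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


def _peptide_sets(filtered_by_condition) -> dict[str, set]:
    if isinstance(filtered_by_condition, pd.DataFrame):
        recs = _with_keys(filtered_by_condition)
        return {cond: set(grp["peptide"]) for cond, grp in recs.groupby("condition")}
    return {cond: set(peps) for cond, peps in filtered_by_condition.items()}


def conformo_specific(filtered_by_condition) -> pd.DataFrame:
    """Peptides present in exactly one condition's filtered set.

    Accepts either a filtered record table (grouped by its ``condition``
    column) or a mapping condition -> peptide keys.  Such
    condition-unique ("conformo-specific") links report on the
    conformational state that produced them.
    """
    sets = _peptide_sets(filtered_by_condition)
    rows = []
    for condition, peps in sets.items():
        others = set().union(*(s for c, s in sets.items() if c != condition)) \
            if len(sets) > 1 else set()
        for pep in sorted(peps - others):
            rows.append({"peptide": pep, "condition": condition})
    return pd.DataFrame(rows, columns=["peptide", "condition"])


def summarize_counts(records: pd.DataFrame, condition: str | None = None) -> dict:
    """Unique-peptide counts per link category (plus their sum).

    ``total`` always equals the sum of the four categories.
    """
    counts = {t: 0 for t in LINK_TYPES}
    if not records.empty:
        recs = records if condition is None else records[records["condition"] == condition]
        if not recs.empty:
            keyed = _with_keys(recs)
            uniques = keyed.drop_duplicates("peptide")
            for link_type, grp in uniques.groupby("link_type"):
                counts[link_type] = int(len(grp))
    counts["total"] = sum(counts[t] for t in LINK_TYPES)
    return counts
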