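"""Descriptive fermentation summaries and treatment-level aggregation.

VFA molar profile and the acetate:propionate ratios, substrate
disappearance over the 48 h bag incubation, efficiency of microbial protein
synthesis (EMPS, g microbial N per kg OM fermented), and mean/SEM
aggregation over vessels (the experimental unit; repeated days within a
vessel are averaged first).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .records import NORMALIZED_VFA, VesselDayRecord


@dataclass
class VfaProfile:
    """Molar shares (mol/100 mol) and the classical ratios."""

    molar_percentages: dict[str, float]
    a_to_p: float | None
    ab_to_p: float | None


def vfa_profile(concentrations: Mapping[str, float]) -> VfaProfile:
    """Molar profile from individual VFA concentrations (mM).

    Shares are percentages of the molar sum over the normalized acids
    (formate, when present, is expressed on the same basis but excluded
    from the normalizing sum, matching how such profiles are reported).
    Scale-invariant: multiplying all concentrations by k changes nothing.
    """
    for product, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"concentration for {product} must be >= 0, got {conc}")
    denom = sum(v for p, v in concentrations.items() if p in NORMALIZED_VFA)
    if denom <= 0:
        raise ValueError("all-zero VFA concentrations: profile undefined")
    shares = {p: 100.0 * v / denom for p, v in concentrations.items()}
    acetate = shares.get("acetate", 0.0)
    butyrate = shares.get("butyrate", 0.0)
    propionate = shares.get("propionate", 0.0)
    if propionate > 0:
        a_to_p: float | None = acetate / propionate
        ab_to_p: float | None = (acetate + butyrate) / propionate
    else:
        a_to_p = ab_to_p = None
    return VfaProfile(shares, a_to_p, ab_to_p)


def substrate_disappearance(mass_in: float, mass_residue: float) -> float:
    """Apparent disappearance (%) of a substrate component over incubation."""
    if mass_in <= 0:
        raise ValueError(f"mass_in must be > 0 g, got {mass_in}")
    if mass_residue < 0:
        raise ValueError(f"mass_residue must be >= 0 g, got {mass_residue}")
    if mass_residue > mass_in:
        warnings.warn(
            f"residue ({mass_residue} g) exceeds input ({mass_in} g); "
            "reporting negative disappearance", UserWarning, stacklevel=2)
    return 100.0 * (mass_in - mass_residue) / mass_in


def emps(microbial_n: float, om_fermented: float) -> float:
    """Efficiency of microbial protein synthesis, g microbial N/kg OM fermented.

    mg N/d divided by g OM/d is numerically g N per kg OM.
    """
    if microbial_n < 0:
        raise ValueError(f"microbial N must be >= 0 mg/d, got {microbial_n}")
    if om_fermented <= 0:
        raise ValueError(f"OM fermented must be > 0 g/d, got {om_fermented}")
    return microbial_n / om_fermented


def aggregate_by_treatment(frame: pd.DataFrame, value: str, *,
                           treatment: str = "treatment",
                           unit: str = "vessel") -> pd.DataFrame:
    """Mean and SEM of ``value`` per treatment, over experimental units.

    Repeated measures (days) within a unit are averaged first; SEM = sd/sqrt(n)
    over unit means. A treatment with a single unit gets SEM = NaN (flagged,
    not silently zero); an empty frame raises.
    """
    if frame.empty:
        raise ValueError("no data to aggregate")
    for col in (treatment, unit, value):
        if col not in frame.columns:
            raise KeyError(f"column {col!r} not in frame")
    unit_means = (frame.dropna(subset=[value])
                  .groupby([treatment, unit], sort=True)[value].mean())
    if unit_means.empty:
        raise ValueError(f"no non-missing values for {value!r}")
    grouped = unit_means.groupby(level=0)
    out = pd.DataFrame({
        "mean": grouped.mean(),
        "sem": grouped.apply(lambda s: s.std(ddof=1) / math.sqrt(len(s))
                             if len(s) > 1 else float("nan")),
        "n_units": grouped.size(),
    })
    out.index.name = treatment
    return out


def records_summary(records: Iterable[VesselDayRecord]) -> pd.DataFrame:
    """Per-record descriptive quantities (profile ratios, disappearance, EMPS).

    One row per vessel-day with whatever can be computed from the available
    measurements; missing inputs give missing outputs.
    """
    rows = []
    for r in records:
        row: dict[str, object] = {"vessel": r.vessel_id,
                                  "treatment": r.treatment, "day": r.day}
        if r.vfa_total is not None and r.vfa_profile:
            shares = r.vfa_profile
            p = shares.get("propionate", 0.0)
            if p > 0:
                row["a_to_p"] = shares.get("acetate", 0.0) / p
                row["ab_to_p"] = (shares.get("acetate", 0.0)
                                  + shares.get("butyrate", 0.0)) / p
        if r.substrate_in is not None and r.residue is not None:
            row["dm_disappearance"] = substrate_disappearance(
                r.substrate_in, r.residue)
        if r.microbial_n is not None and r.om_fermented:
            row["emps"] = emps(r.microbial_n, r.om_fermented)
        rows.append(row)
    return pd.DataFrame(rows)
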