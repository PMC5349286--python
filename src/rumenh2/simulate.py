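"""Synthetic vessel x day measurement records with known ground truth.

Emulates the measurement structure of a semi-continuous fermenter
(RUSITEC) experiment: T treatments x V vessels x D days, every analyte
generated as

    value(vessel, day) = treatment mean + vessel effect + day effect + residual

with independent zero-mean normal effects (vessel effect constant within a
vessel, day effect shared by all vessels of a treatment on a day) and
left-truncation at zero. VFA molar shares and gas percentages are noised on
the share scale and renormalized to the profile's own total so simulated
records remain valid compositions.

Default treatment profiles are the printed means of the reference
experiment; default dispersions are backed out of its printed SEM column
(n = 4 vessels), split 50 % vessel / 25 % day / 25 % residual variance —
the source reports no variance partition, so the split is a configurable
package choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import fixtures
from .records import GASES, NORMALIZED_VFA, VFA_PRODUCTS, VesselDayRecord

#: Analytes carried by a treatment profile, in record-construction order.
ANALYTES: tuple[str, ...] = (
    ("vfa_total",) + VFA_PRODUCTS
    + ("ethanol", "n_propanol", "ammonium", "nitrate", "nitrite",
       "gas_total", "ch4_pct", "h2_pct", "co2_pct", "n2o_pct",
       "dissolved_h2", "substrate_in", "residue", "microbial_n",
       "om_fermented")
)

_GAS_KEYS = tuple(f"{g}_pct" for g in GASES)


@dataclass(frozen=True)
class TreatmentProfile:
    """True mean of every analyte for one treatment."""

    label: str
    means: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.means) - set(ANALYTES)
        if unknown:
            raise KeyError(f"unknown analyte(s) {sorted(unknown)}")
        for analyte, mean in self.means.items():
            if mean < 0:
                raise ValueError(f"{self.label}: mean {analyte} must be >= 0")

    def record(self, vessel_id: str | None = None, day: int = 0) -> VesselDayRecord:
        """The noise-free vessel-day record at this profile's means."""
        m = self.means
        return VesselDayRecord(
            vessel_id=vessel_id or f"{self.label}-truth",
            treatment=self.label,
            day=day,
            vfa_total=m.get("vfa_total"),
            vfa_profile={p: m[p] for p in VFA_PRODUCTS if p in m},
            alcohols={a: m[a] for a in ("ethanol", "n_propanol") if a in m},
            ammonium=m.get("ammonium"),
            nitrate=m.get("nitrate"),
            nitrite=m.get("nitrite"),
            gas_total=m.get("gas_total"),
            gas_fractions={g: m[f"{g}_pct"] for g in GASES if f"{g}_pct" in m},
            dissolved_h2=m.get("dissolved_h2"),
            substrate_in=m.get("substrate_in"),
            residue=m.get("residue"),
            microbial_n=m.get("microbial_n"),
            om_fermented=m.get("om_fermented"),
        )


def perturb_profile(profile: TreatmentProfile,
                    overrides: dict[str, float]) -> TreatmentProfile:
    """A new profile with some analyte means replaced; the original is untouched."""
    unknown = set(overrides) - set(ANALYTES)
    if unknown:
        raise KeyError(f"unknown analyte(s) {sorted(unknown)}")
    return replace(profile, means={**profile.means, **overrides})


def default_profiles() -> list[TreatmentProfile]:
    """The four reference-experiment treatments at their printed means."""
    out = []
    for trt in fixtures.TREATMENTS:
        rec = fixtures.mean_record(trt)
        means = {
            "vfa_total": rec.vfa_total,
            **rec.vfa_profile,
            **rec.alcohols,
            "ammonium": rec.ammonium, "nitrate": rec.nitrate,
            "nitrite": rec.nitrite, "gas_total": rec.gas_total,
            **{f"{g}_pct": v for g, v in rec.gas_fractions.items()},
            "dissolved_h2": rec.dissolved_h2,
            "substrate_in": rec.substrate_in, "residue": rec.residue,
            "microbial_n": rec.microbial_n, "om_fermented": rec.om_fermented,
        }
        out.append(TreatmentProfile(trt, means))
    return out


@dataclass(frozen=True)
class VarianceModel:
    """Per-analyte standard deviations of the three noise components."""

    vessel_sd: dict[str, float] = field(default_factory=dict)
    day_sd: dict[str, float] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("vessel_sd", "day_sd", "residual_sd"):
            for analyte, sd in getattr(self, name).items():
                if analyte not in ANALYTES:
                    raise KeyError(f"{name}: unknown analyte {analyte!r}")
                if sd < 0:
                    raise ValueError(f"{name}[{analyte}] must be >= 0, got {sd}")

    def sds(self, analyte: str) -> tuple[float, float, float]:
        return (self.vessel_sd.get(analyte, 0.0),
                self.day_sd.get(analyte, 0.0),
                self.residual_sd.get(analyte, 0.0))

    def true_sem(self, analyte: str, n_vessels: int, n_days: int) -> float:
        """Model-implied SEM of a treatment mean (vessels x days averaged)."""
        v, d, r = self.sds(analyte)
        return math.sqrt(v * v / n_vessels + d * d / n_days
                         + r * r / (n_vessels * n_days))

    @classmethod
    def from_sem(cls, sems: dict[str, float], n_vessels: int = 4,
                 split: tuple[float, float, float] = (0.5, 0.25, 0.25),
                 ) -> "VarianceModel":
        """Back a variance model out of printed SEMs.

        A printed SEM over ``n_vessels`` implies a vessel-mean SD of
        SEM * sqrt(n_vessels); that variance is split across the three
        components by ``split`` (fractions summing to 1). The day and
        residual shares are interpreted as single-draw SDs, so a vessel
        mean over many days has slightly less spread than the implied SD —
        adequate for a generator meant to emulate, not to fit.
        """
        if abs(sum(split) - 1.0) > 1e-9:
            raise ValueError(f"split must sum to 1, got {split}")
        vessel, day, resid = ({}, {}, {})
        for analyte, sem in sems.items():
            var = (sem * math.sqrt(n_vessels)) ** 2
            vessel[analyte] = math.sqrt(split[0] * var)
            day[analyte] = math.sqrt(split[1] * var)
            resid[analyte] = math.sqrt(split[2] * var)
        return cls(vessel, day, resid)


def default_variance_model(n_vessels: int = 4) -> VarianceModel:
    """Dispersion backed out of the reference experiment's SEM columns."""
    t3, t4, t5 = (fixtures.fixture(t) for t in ("T3", "T4", "T5"))
    sems: dict[str, float] = {
        "vfa_total": t4.sem("vfa_total"),
        **{p: t4.sem(p) for p in VFA_PRODUCTS},
        "ethanol": t4.sem("ethanol"), "n_propanol": t4.sem("n_propanol"),
        "ammonium": t4.sem("ammonium"), "nitrate": t4.sem("nitrate"),
        "nitrite": t4.sem("nitrite"),
        "gas_total": t3.sem("gas_total"),
        "ch4_pct": t3.sem("ch4_pct"), "h2_pct": t3.sem("h2_pct"),
        "co2_pct": t3.sem("co2_pct"), "n2o_pct": t3.sem("n2o_pct"),
        "dissolved_h2": t3.sem("dissolved_h2"),
        # residue/OM fermented spread propagated from disappearance SEMs on
        # a 10 g DM (≈9 g OM) substrate: d(residue) = 10 g x d(DM%)/100.
        "residue": fixtures.SUBSTRATE_DM_G * t3.sem("dm_disappearance") / 100.0,
        "om_fermented": 0.9 * fixtures.SUBSTRATE_DM_G
        * t3.sem("om_disappearance") / 100.0,
        "microbial_n": t5.sem("microbial_n_total"),
    }
    return VarianceModel.from_sem(sems, n_vessels=n_vessels)


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated experiment."""

    treatments: tuple[TreatmentProfile, ...]
    variance: VarianceModel = field(default_factory=VarianceModel)
    n_vessels: int = 4
    days: tuple[int, ...] = tuple(range(8, 14))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        if not self.days:
            raise ValueError("days must be nonempty")
        if not self.treatments:
            raise ValueError("treatments must be nonempty")


def default_config(seed: int = 0, n_vessels: int = 4,
                   days: tuple[int, ...] = tuple(range(8, 14))) -> SimConfig:
    return SimConfig(treatments=tuple(default_profiles()),
                     variance=default_variance_model(n_vessels),
                     n_vessels=n_vessels, days=days, seed=seed)


def balance_recovery_study(n_replicates: int = 1000, seed: int = 0,
                           n_vessels: int = 4,
                           days: tuple[int, ...] = tuple(range(8, 14)),
                           scenario: str = "SC1") -> dict:
    """Monte-Carlo check that the pipeline recovers the generator's truth.

    For each replicate a fresh experiment is simulated at the default
    profiles/dispersions, the full pipeline (flux table -> ledger) runs per
    vessel-day, days are averaged within vessel and vessels within
    treatment. Returns the ground-truth [2H] balance per treatment, the
    (n_replicates x n_treatments) matrix of estimates, the empirical
    sampling SD of the estimator per treatment, and the fraction of
    replicates whose estimate lies within 3 of those SDs of truth.
    """
    from .stoichiometry import build_flux_table, ledger  # local: avoid cycle

    cfg0 = default_config(seed=seed, n_vessels=n_vessels, days=days)
    treatments = [p.label for p in cfg0.treatments]
    truth = {}
    for profile in cfg0.treatments:
        led = ledger(build_flux_table(profile.record()), scenario)
        truth[profile.label] = led.balance

    estimates = np.empty((n_replicates, len(treatments)))
    for rep in range(n_replicates):
        cfg = default_config(seed=(seed + rep) % (2**31 - 1),
                             n_vessels=n_vessels, days=days)
        records, _ = simulate_experiment(cfg)
        sums: dict[tuple[str, str], list[float]] = {}
        for record in records:
            bal = ledger(build_flux_table(record), scenario).balance
            sums.setdefault((record.treatment, record.vessel_id), []).append(bal)
        for ti, trt in enumerate(treatments):
            vessel_means = [float(np.mean(v)) for (t, _), v in sums.items()
                            if t == trt]
            estimates[rep, ti] = float(np.mean(vessel_means))

    truth_vec = np.array([truth[t] for t in treatments])
    sampling_sd = estimates.std(axis=0, ddof=1)
    inside = np.abs(estimates - truth_vec) <= 3.0 * sampling_sd
    coverage = inside.mean(axis=0)
    return {
        "treatments": treatments,
        "truth": truth,
        "estimates": estimates,
        "sampling_sd": dict(zip(treatments, sampling_sd)),
        "coverage": dict(zip(treatments, coverage)),
    }


def _renormalize(values: np.ndarray, keys: tuple[str, ...],
                 subset: tuple[str, ...], target: float) -> None:
    """Scale the ``subset`` rows of ``values`` so each column sums to ``target``."""
    idx = [keys.index(k) for k in subset if k in keys]
    if not idx or target <= 0:
        return
    total = values[idx, ...].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total > 0, target / total, 1.0)
    values[idx, ...] *= scale


def simulate_experiment(config: SimConfig,
                        ) -> tuple[list[VesselDayRecord], dict[str, VesselDayRecord]]:
    """Generate one synthetic experiment.

    Returns the simulated records (one per vessel-day, vessel ids
    ``<treatment>-v<i>``) and the ground truth: a noise-free record per
    treatment at the profile means. Same config (including seed) gives
    bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    records: list[VesselDayRecord] = []
    truth: dict[str, VesselDayRecord] = {}
    n_v, days = config.n_vessels, config.days
    n_d = len(days)
    for profile in config.treatments:
        truth[profile.label] = profile.record()
        keys = tuple(k for k in ANALYTES if k in profile.means)
        n_a = len(keys)
        means = np.array([profile.means[k] for k in keys])[:, None, None]
        v_sd, d_sd, r_sd = (np.array([getattr(config.variance, n).get(k, 0.0)
                                      for k in keys])[:, None, None]
                            for n in ("vessel_sd", "day_sd", "residual_sd"))
        vessel_eff = rng.standard_normal((n_a, n_v, 1)) * v_sd
        day_eff = rng.standard_normal((n_a, 1, n_d)) * d_sd
        resid = rng.standard_normal((n_a, n_v, n_d)) * r_sd
        values = np.maximum(means + vessel_eff + day_eff + resid, 0.0)
        # keep compositions valid: renormalize shares to the profile's own totals
        profile_sum = sum(profile.means.get(p, 0.0) for p in NORMALIZED_VFA)
        gas_sum = sum(profile.means.get(k, 0.0) for k in _GAS_KEYS)
        _renormalize(values, keys, NORMALIZED_VFA, profile_sum)
        _renormalize(values, keys, _GAS_KEYS, gas_sum)
        # a single dominant gas can inherit the whole (printed) sum, which
        # may exceed 100 by rounding; cap at the valid percentage range
        gas_idx = [keys.index(k) for k in _GAS_KEYS if k in keys]
        values[gas_idx, ...] = np.minimum(values[gas_idx, ...], 100.0)
        for vi in range(n_v):
            for di, day in enumerate(days):
                sample = dict(zip(keys, values[:, vi, di]))
                noisy = TreatmentProfile(profile.label, sample)
                rec = noisy.record(vessel_id=f"{profile.label}-v{vi + 1}", day=day)
                records.append(rec)
    return records, truth
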