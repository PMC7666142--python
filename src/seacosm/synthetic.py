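"""Synthetic seasonal microcosm experiments with known ground truth.

Emulates a seasonal manipulation-experiment campaign: at each season,
surface seawater is split across six treatments (whole water, 1-µm
predator-reduced, 1:4 dilution with 0.2-µm filtrate, 1:4 dilution with
30-kDa virus-free filtrate; whole water and predator-reduced also run in
continuous dark) in triplicate bottles, and group-specific cell densities
are sampled a few times over 36-48 h.

Each group in each treatment grows exponentially at the net rate implied by
its generating mortality partition and the treatment's pressure-retention
factors (the forward model of :mod:`seacosm.model_core`), optionally with a
lag phase and a plateau; observed densities get multiplicative lognormal
noise (default) or Poisson counting noise.  The generating parameters are
returned alongside the tidy abundance table so estimator recovery can be
tested exactly.

Initial community composition and total cell density are seeded from the
packaged in-situ tables (group fractions of total DAPI counts per season,
total prokaryotic abundance per season); default rate parameters are chosen
within the span of growth rates published for the same coastal observatory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fixtures import load_fixture
from .model_core import (
    DEFAULT_DILUTION,
    MortalityPartition,
    TreatmentCode,
    predict_net_rates,
)
from .rates import ABUNDANCE_COLUMNS

__all__ = [
    "GroupSpec",
    "NoiseSpec",
    "ExperimentDesign",
    "SimulationTruth",
    "GROUP_PARENTS",
    "SEASONS",
    "true_net_rate",
    "expected_abundance",
    "make_experiment",
    "simulate_campaign",
    "default_season_specs",
    "default_season_design",
    "check_nesting",
]

SEASONS = ("winter", "spring", "summer", "fall")

#: Taxonomic nesting of the probe-defined groups.  ALT and NOR5 are
#: gammaproteobacterial subgroups; the proteobacterial groups and
#: Bacteroidetes nest within Eubacteria; everything is within total
#: prokaryotes (PRK, the DAPI count).  AAP is a functional (not
#: phylogenetic) category counted against the total.
GROUP_PARENTS: dict[str, str | None] = {
    "PRK": None,
    "EUB": "PRK",
    "ROSEO": "EUB",
    "SAR11": "EUB",
    "GAMMA": "EUB",
    "ALT": "GAMMA",
    "NOR5": "GAMMA",
    "CFB": "EUB",
    "AAP": "PRK",
}

# Baseline (mu, m_g, r_c, m_v) in day^-1 per group, before seasonal
# modulation.  Chosen so that control net rates sit near the low end and
# dilution/virus-reduced rates near the high end of the growth-rate ranges
# published for this site: slow oligotrophs (SAR11) vs fast opportunists
# (Alteromonadaceae and Gammaproteobacteria generally).
_BASE_RATES: dict[str, tuple[float, float, float, float]] = {
    "PRK": (0.80, 0.35, 0.30, 0.08),
    "EUB": (0.80, 0.35, 0.30, 0.08),
    "ROSEO": (1.00, 0.40, 0.40, 0.08),
    "SAR11": (0.55, 0.25, 0.18, 0.06),
    "GAMMA": (2.00, 0.80, 0.90, 0.10),
    "ALT": (3.00, 1.10, 1.60, 0.12),
    "NOR5": (1.00, 0.40, 0.35, 0.08),
    "CFB": (0.90, 0.40, 0.30, 0.08),
    "AAP": (1.20, 0.60, 0.40, 0.10),
}

# Seasonal multipliers on (m_g, r_c, m_v): grazing strongest in winter,
# resource limitation strongest in summer, viral pressure elevated in fall
# (and somewhat in spring).
_SEASON_LOSS_SCALE: dict[str, tuple[float, float, float]] = {
    "winter": (1.4, 0.6, 0.8),
    "spring": (1.0, 1.0, 1.2),
    "summer": (0.9, 1.3, 0.9),
    "fall": (1.0, 1.0, 1.4),
}
_SEASON_MU_SCALE: dict[str, float] = {
    "winter": 1.0,
    "spring": 0.9,
    "summer": 1.1,
    "fall": 0.9,
}

# Light stimulation of gross growth for groups with photoheterotrophic
# members (proteorhodopsin-bearing SAR11 and Bacteroidetes, aerobic
# anoxygenic phototrophs and allied Rhodobacteraceae / NOR5).
_LIGHT_MODIFIERS: dict[str, float] = {
    "SAR11": 1.10,
    "CFB": 1.05,
    "ROSEO": 1.05,
    "NOR5": 1.05,
    "AAP": 1.15,
}

_SEASON_DURATION_H: dict[str, int] = {
    "winter": 36,
    "spring": 48,
    "summer": 36,
    "fall": 48,
}


@dataclass(frozen=True)
class GroupSpec:
    """Generating parameters for one bacterioplankton group.

    ``initial_fraction`` is the group's share of total DAPI counts at t=0;
    ``mu`` and the loss terms are the ambient (undiluted, lit) partition;
    ``light_modifier`` multiplies ``mu`` under light incubation.
    """

    name: str
    initial_fraction: float
    mu: float
    m_g: float
    r_c: float
    m_v: float
    light_modifier: float = 1.0
    parent: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.initial_fraction <= 1.0):
            raise ValueError(
                f"{self.name}: initial_fraction must be in [0, 1]; "
                f"got {self.initial_fraction}"
            )
        if self.light_modifier <= 0:
            raise ValueError(f"{self.name}: light_modifier must be > 0")

    def partition(
        self,
        dilution: float = DEFAULT_DILUTION,
        experiment: str | None = None,
        *,
        light: bool = False,
    ) -> MortalityPartition:
        """Generating partition; with ``light=True`` the gross growth rate
        carries the light modifier, matching what the light-incubated
        treatment system identifies."""
        return MortalityPartition(
            mu=self.mu * (self.light_modifier if light else 1.0),
            m_g=self.m_g,
            r_c=self.r_c,
            m_v=self.m_v,
            dilution=dilution,
            group=self.name,
            experiment=experiment,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model for simulated counts.

    ``lognormal``: multiplicative mean-1 lognormal with coefficient of
    variation ``cv`` (default 10%), a generic model of microscopy counting
    scatter.  ``poisson``: cell counts per filter are Poisson with mean
    expected_density / ``cells_per_count`` (one counted cell represents
    ``cells_per_count`` cells mL^-1), rescaled back to a density.
    ``none``: exact expected densities.
    """

    kind: str = "lognormal"
    cv: float = 0.10
    cells_per_count: float = 1000.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "lognormal", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0 or self.cells_per_count <= 0:
            raise ValueError("cv must be >= 0 and cells_per_count > 0")

    def draw(self, expected: float, rng: np.random.Generator) -> float:
        if self.kind == "none" or (self.kind == "lognormal" and self.cv == 0):
            return expected
        if self.kind == "lognormal":
            sigma = np.sqrt(np.log1p(self.cv**2))
            return expected * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        counts = rng.poisson(expected / self.cells_per_count)
        return counts * self.cells_per_count


_DEFAULT_TREATMENTS = (
    TreatmentCode.CT_L,
    TreatmentCode.CT_D,
    TreatmentCode.PR_L,
    TreatmentCode.PR_D,
    TreatmentCode.DI_L,
    TreatmentCode.VR_L,
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of one seasonal incubation experiment.

    Dark incubations exist only for the control and predator-reduced
    manipulations, matching the six-treatment design.  AAP, counted by a
    separate microscopy protocol, is sampled at only the first and last
    time point and only in the CT/PR treatments.
    """

    season: str
    seed: int
    total_dapi_t0: float = 1.0e6
    duration_h: float = 48.0
    sample_times_h: tuple[float, ...] | None = None
    treatments: tuple[TreatmentCode, ...] = _DEFAULT_TREATMENTS
    replicates: int = 3
    dilution: float = DEFAULT_DILUTION
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    lag_h: float = 0.0
    plateau_h: float | None = None
    aap_time_points: int = 2

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.total_dapi_t0 <= 0:
            raise ValueError("total_dapi_t0 must be > 0")
        times = self.times()
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValueError("sample times must start at 0 and be strictly increasing")
        if times[-1] > self.duration_h:
            raise ValueError(
                f"sample time {times[-1]} h outside incubation duration "
                f"{self.duration_h} h"
            )

    def times(self) -> np.ndarray:
        if self.sample_times_h is not None:
            return np.asarray(self.sample_times_h, dtype=float)
        return np.linspace(0.0, self.duration_h, 4)


@dataclass
class SimulationTruth:
    """Generating parameters retained for estimator-recovery tests.

    ``partitions`` holds, per group, the partition identified by the four
    light-incubated treatments (gross growth rate including the group's
    light modifier) — the quantity the downstream solver can recover.
    """

    season: str
    dilution: float
    partitions: dict[str, MortalityPartition]
    net_rates: dict[tuple[str, str], float]  # (group, treatment code) -> k day^-1
    initial_abundance: dict[str, float]  # group -> N0 cells mL^-1 (undiluted)

    def to_json(self) -> str:
        payload = {
            "season": self.season,
            "dilution": self.dilution,
            "partitions": {
                g: {"mu": p.mu, "m_g": p.m_g, "r_c": p.r_c, "m_v": p.m_v}
                for g, p in self.partitions.items()
            },
            "net_rates": {
                f"{g}|{t}": k for (g, t), k in sorted(self.net_rates.items())
            },
            "initial_abundance": self.initial_abundance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def true_net_rate(
    spec: GroupSpec,
    treatment: TreatmentCode,
    dilution: float = DEFAULT_DILUTION,
) -> float:
    """Net growth rate (day^-1) of a group under one treatment.

    The treatment retains a fraction of each ambient pressure; light
    incubation multiplies the gross growth rate by the group's light
    modifier.  With all pressure factors at 1 and no light effect this is
    the control net rate of the group's generating partition.
    """
    f = treatment.factors(dilution)
    mu = spec.mu * (spec.light_modifier if treatment.light else 1.0)
    return mu - (f.grazer * spec.m_g + f.resource * spec.r_c + f.virus * spec.m_v)


def expected_abundance(
    n0: float,
    k_per_day: float,
    t_h: float,
    lag_h: float = 0.0,
    plateau_h: float | None = None,
) -> float:
    """Deterministic trajectory: optional flat lag, exponential, optional plateau."""
    t_eff = min(t_h, plateau_h) if plateau_h is not None else t_h
    t_growth = max(0.0, t_eff - lag_h)
    return n0 * np.exp(k_per_day * t_growth / 24.0)


def check_nesting(specs: list[GroupSpec], *, strict: bool = False) -> list[str]:
    """Check that child initial fractions fit within their parents.

    Probe-derived community compositions routinely violate strict nesting
    by small margins (probe coverage and specificity are imperfect), so by
    default violations are returned as messages; with ``strict=True`` the
    first violation raises.
    """
    by_name = {s.name: s for s in specs}
    children: dict[str, list[GroupSpec]] = {}
    for s in specs:
        parent = s.parent
        if parent is not None and parent in by_name:
            # AAP is a functional category overlapping the phylogenetic
            # groups; its fraction is not budgeted against the parent.
            if s.name == "AAP":
                continue
            children.setdefault(parent, []).append(s)
    messages = []
    for parent, kids in children.items():
        total = sum(k.initial_fraction for k in kids)
        if total > by_name[parent].initial_fraction + 1e-12:
            msg = (
                f"children of {parent} sum to {total:.4f} > parent fraction "
                f"{by_name[parent].initial_fraction:.4f} "
                f"({', '.join(k.name for k in kids)})"
            )
            if strict:
                raise ValueError(msg)
            messages.append(msg)
    return messages


def make_experiment(
    design: ExperimentDesign,
    groups: list[GroupSpec],
    *,
    strict_nesting: bool = False,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate one seasonal experiment.

    For each group, treatment and replicate bottle, the expected density is
    ``N0 * f_treatment * exp(k_true * t / 24)`` with ``t`` in hours, where
    ``N0`` is the group's share of the total initial DAPI count and
    ``f_treatment`` accounts for the 1:4 dilution of starting cells in the
    DI and VR treatments; the observation is the expected density passed
    through the design's noise model.  The same seed always produces the
    same table.

    Returns the tidy abundance table and the :class:`SimulationTruth`
    holding every generating partition and net rate.
    """
    check_nesting(groups, strict=strict_nesting)
    rng = np.random.default_rng(design.seed)
    times = design.times()
    aap_times = (
        np.array([times[0], times[-1]]) if len(times) >= 2 else times
    )

    partitions: dict[str, MortalityPartition] = {}
    net_rates: dict[tuple[str, str], float] = {}
    initial: dict[str, float] = {}
    records: list[tuple] = []
    for spec in groups:
        partitions[spec.name] = spec.partition(
            design.dilution, design.season, light=True
        )
        n0 = spec.initial_fraction * design.total_dapi_t0
        initial[spec.name] = n0
        is_aap = spec.name == "AAP"
        for treatment in design.treatments:
            if is_aap and treatment.base not in ("CT", "PR"):
                continue
            k_true = true_net_rate(spec, treatment, design.dilution)
            net_rates[(spec.name, treatment.value)] = k_true
            group_times = aap_times if is_aap else times
            start = n0 * (
                design.dilution if treatment.base in ("DI", "VR") else 1.0
            )
            for rep in range(1, design.replicates + 1):
                for t in group_times:
                    expected = expected_abundance(
                        start, k_true, float(t), design.lag_h, design.plateau_h
                    )
                    observed = design.noise.draw(expected, rng)
                    records.append(
                        (
                            design.season,
                            treatment.value,
                            rep,
                            spec.name,
                            float(t),
                            float(observed),
                        )
                    )
    table = pd.DataFrame(records, columns=list(ABUNDANCE_COLUMNS))
    truth = SimulationTruth(
        season=design.season,
        dilution=design.dilution,
        partitions=partitions,
        net_rates=net_rates,
        initial_abundance=initial,
    )
    return table, truth


def simulate_campaign(
    seed: int,
    seasons: tuple[str, ...] = SEASONS,
    noise: NoiseSpec | None = None,
    **design_overrides,
) -> tuple[pd.DataFrame, dict[str, SimulationTruth]]:
    """Simulate a full multi-season campaign with the default designs.

    Each season gets a sub-seed derived deterministically from ``seed``.
    Returns the concatenated abundance table and per-season truths.
    """
    tables = []
    truths: dict[str, SimulationTruth] = {}
    child = np.random.SeedSequence(seed).spawn(len(seasons))
    for season, ss in zip(seasons, child):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        design = default_season_design(season, seed=sub_seed, noise=noise)
        if design_overrides:
            design = replace(design, **design_overrides)
        table, truth = make_experiment(design, default_season_specs(season))
        tables.append(table)
        truths[season] = truth
    return pd.concat(tables, ignore_index=True), truths


def default_season_specs(season: str) -> list[GroupSpec]:
    """Fixture-backed group specs for one season.

    Initial fractions come from the packaged in-situ composition table
    (percent of DAPI counts for that season); rate parameters are the
    package defaults modulated by season (grazing heavier in winter,
    resource limitation heavier in summer, viral losses heavier in fall).
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    table2 = load_fixture("table2")
    fractions = (
        table2[table2["season"] == season].set_index("group")["percent"] / 100.0
    )
    g_scale, r_scale, v_scale = _SEASON_LOSS_SCALE[season]
    mu_scale = _SEASON_MU_SCALE[season]
    specs = []
    for name, (mu, m_g, r_c, m_v) in _BASE_RATES.items():
        frac = 1.0 if name == "PRK" else float(fractions[name])
        specs.append(
            GroupSpec(
                name=name,
                initial_fraction=frac,
                mu=mu * mu_scale,
                m_g=m_g * g_scale,
                r_c=r_c * r_scale,
                m_v=m_v * v_scale,
                light_modifier=_LIGHT_MODIFIERS.get(name, 1.0),
                parent=GROUP_PARENTS[name],
            )
        )
    return specs


def default_season_design(
    season: str, seed: int, noise: NoiseSpec | None = None
) -> ExperimentDesign:
    """Default incubation design for one season.

    Total initial DAPI density comes from the packaged initial-parameters
    table; incubations last 36 h (winter, summer) or 48 h (spring, fall)
    with four evenly spaced samplings.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    table1 = load_fixture("table1")
    total = float(table1.loc["prokaryotic_abundance_cells_ml", season])
    return ExperimentDesign(
        season=season,
        seed=seed,
        total_dapi_t0=total,
        duration_h=float(_SEASON_DURATION_H[season]),
        noise=noise if noise is not None else NoiseSpec(),
    )
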