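"""Linear rate budget for seawater manipulation treatments.

A microcosm experiment exposes the same seawater community to a set of
treatments that selectively remove mortality pressures: whole water (CT),
predator-reduced 1-µm filtrate (PR), 1:4 dilution with 0.2-µm filtrate (DI)
and 1:4 dilution with 30-kDa virus-free filtrate (VR).  Treating losses as
additive per-capita rates, the net growth rate ``k`` measured in each
treatment is a linear combination of the gross growth rate ``mu`` and three
loss terms — grazing mortality ``m_g``, a resource-limitation constraint
``r_c`` and viral mortality ``m_v`` — scaled by the dilution factor ``D``::

    k_CT = mu - (m_g + r_c + m_v)
    k_PR = mu - (r_c + m_v)
    k_DI = mu - (D*m_g + D*r_c + m_v)
    k_VR = mu - D*(m_g + r_c + m_v)

The system is linear and, for D != 1, has the unique closed-form inverse
implemented by :func:`solve_partition`.  All rates are per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "TreatmentCode",
    "PressureFactors",
    "NetRateSet",
    "MortalityPartition",
    "RatioKind",
    "ResponseRatio",
    "DEFAULT_DILUTION",
    "DEFAULT_RATIO_EPSILON",
    "predict_net_rates",
    "solve_partition",
    "response_ratio",
    "bootstrap_partition",
]

#: Fraction of whole seawater retained in the diluted treatments (1:4 dilution).
DEFAULT_DILUTION = 0.25

#: Denominator threshold (day^-1) below which a response ratio is undefined.
DEFAULT_RATIO_EPSILON = 1e-6


@dataclass(frozen=True)
class PressureFactors:
    """Fraction of each ambient pressure retained by a treatment."""

    grazer: float
    resource: float
    virus: float


class TreatmentCode(str, Enum):
    """The six experimental treatments; ``_L``/``_D`` = light/dark incubation."""

    CT_L = "CT_L"
    CT_D = "CT_D"
    PR_L = "PR_L"
    PR_D = "PR_D"
    DI_L = "DI_L"
    VR_L = "VR_L"

    @property
    def base(self) -> str:
        """Manipulation class without the light flag: CT, PR, DI or VR."""
        return self.value.split("_")[0]

    @property
    def light(self) -> bool:
        return self.value.endswith("_L")

    def factors(self, dilution: float = DEFAULT_DILUTION) -> PressureFactors:
        """Pressure-retention fractions for this treatment.

        CT retains everything; PR removes grazers; DI scales the
        encounter-dependent grazing and resource-competition pressures by the
        dilution factor but leaves viruses untouched (0.2-µm filtrate passes
        viruses); VR scales all three pressures by the dilution factor.
        """
        _check_dilution(dilution)
        base = self.base
        if base == "CT":
            return PressureFactors(1.0, 1.0, 1.0)
        if base == "PR":
            return PressureFactors(0.0, 1.0, 1.0)
        if base == "DI":
            return PressureFactors(dilution, dilution, 1.0)
        return PressureFactors(dilution, dilution, dilution)  # VR

    @property
    def starting_fraction(self) -> float:
        """Fraction of ambient cells present at t=0 (dilution of starting cells)."""
        return DEFAULT_DILUTION if self.base in ("DI", "VR") else 1.0


def _check_dilution(dilution: float) -> None:
    if not (0.0 < dilution < 1.0):
        raise ValueError(
            "dilution factor must lie strictly in (0, 1) — at D = 1 the "
            f"four-treatment system is singular; got {dilution!r}"
        )


def _check_finite(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite; got {value!r}")


@dataclass(frozen=True)
class NetRateSet:
    """Replicate-aggregated net growth rates (day^-1) for the four light treatments."""

    k_ct: float
    k_pr: float
    k_di: float
    k_vr: float
    dilution: float = DEFAULT_DILUTION
    group: str | None = None
    experiment: str | None = None
    sd_ct: float = 0.0
    sd_pr: float = 0.0
    sd_di: float = 0.0
    sd_vr: float = 0.0

    def __post_init__(self) -> None:
        _check_dilution(self.dilution)
        _check_finite(k_ct=self.k_ct, k_pr=self.k_pr, k_di=self.k_di, k_vr=self.k_vr)
        for name in ("sd_ct", "sd_pr", "sd_di", "sd_vr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.k_ct, self.k_pr, self.k_di, self.k_vr])


@dataclass(frozen=True)
class MortalityPartition:
    """Gross growth and loss components (day^-1) solved from a :class:`NetRateSet`.

    Negative components are physically questionable but arise routinely from
    measurement noise (e.g. VR/DI ratios below 1 imply negative viral
    mortality); they are reported as computed and listed in
    ``negative_components`` rather than truncated, unless truncation was
    requested at solve time.
    """

    mu: float
    m_g: float
    r_c: float
    m_v: float
    dilution: float = DEFAULT_DILUTION
    group: str | None = None
    experiment: str | None = None
    negative_components: tuple[str, ...] = field(default=())
    truncated: bool = False

    def __post_init__(self) -> None:
        _check_dilution(self.dilution)
        _check_finite(mu=self.mu, m_g=self.m_g, r_c=self.r_c, m_v=self.m_v)

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.m_g, self.r_c, self.m_v])


def predict_net_rates(partition: MortalityPartition) -> NetRateSet:
    """Forward model: treatment net rates implied by a mortality partition.

    This is the generating model of the synthetic experiments and the
    verification oracle for :func:`solve_partition`.
    """
    mu, m_g, r_c, m_v = partition.mu, partition.m_g, partition.r_c, partition.m_v
    d = partition.dilution
    return NetRateSet(
        k_ct=mu - (m_g + r_c + m_v),
        k_pr=mu - (r_c + m_v),
        k_di=mu - (d * m_g + d * r_c + m_v),
        k_vr=mu - d * (m_g + r_c + m_v),
        dilution=d,
        group=partition.group,
        experiment=partition.experiment,
    )


def solve_partition(
    rates: NetRateSet, *, truncate_negative: bool = False
) -> MortalityPartition:
    """Closed-form inversion of the four treatment equations.

    ``m_g = k_PR - k_CT`` (removing grazers adds back exactly the grazing
    loss), ``m_v = (k_VR - k_DI) / (1 - D)``, ``r_c = (k_DI - k_PR + D*m_g)
    / (1 - D)`` and ``mu = k_PR + r_c + m_v``.  The solution is exact: the
    round trip through :func:`predict_net_rates` reproduces the input rates
    to floating-point precision.

    Parameters
    ----------
    rates
        Net growth rates from the four light-incubated treatments.
    truncate_negative
        If True, clamp negative loss components (and a negative ``mu``) to
        zero after solving.  The components remain listed in
        ``negative_components`` either way.
    """
    d = rates.dilution
    m_g = rates.k_pr - rates.k_ct
    m_v = (rates.k_vr - rates.k_di) / (1.0 - d)
    r_c = (rates.k_di - rates.k_pr + d * m_g) / (1.0 - d)
    mu = rates.k_pr + r_c + m_v

    components = {"mu": mu, "m_g": m_g, "r_c": r_c, "m_v": m_v}
    negative = tuple(name for name, value in components.items() if value < 0)
    if truncate_negative:
        components = {k: max(v, 0.0) for k, v in components.items()}
    return MortalityPartition(
        mu=components["mu"],
        m_g=components["m_g"],
        r_c=components["r_c"],
        m_v=components["m_v"],
        dilution=d,
        group=rates.group,
        experiment=rates.experiment,
        negative_components=negative,
        truncated=truncate_negative,
    )


class RatioKind(str, Enum):
    """Which pressure a treatment-pair ratio isolates."""

    GRAZING = "grazing"  # PR / CT
    RESOURCES = "resources"  # DI / PR
    VIRUSES = "viruses"  # VR / DI
    LIGHT = "light"  # L / D (same manipulation, light vs dark)


#: Numerator / denominator treatment bases for each non-light ratio kind.
RATIO_PAIRS: dict[RatioKind, tuple[str, str]] = {
    RatioKind.GRAZING: ("PR", "CT"),
    RatioKind.RESOURCES: ("DI", "PR"),
    RatioKind.VIRUSES: ("VR", "DI"),
}


@dataclass(frozen=True)
class ResponseRatio:
    """Ratio of net growth rates between two treatments.

    A value above 1 indicates release from the corresponding pressure; the
    value is missing (None) when the denominator rate is at or below
    ``epsilon``, in which case ``reason`` records why.  The rate difference
    numerator − denominator is always available as a fallback effect size.
    """

    kind: RatioKind
    numerator: float
    denominator: float
    value: float | None
    difference: float
    epsilon: float = DEFAULT_RATIO_EPSILON
    reason: str | None = None
    group: str | None = None
    experiment: str | None = None


def response_ratio(
    k_num: float,
    k_den: float,
    kind: RatioKind | str,
    epsilon: float = DEFAULT_RATIO_EPSILON,
    *,
    group: str | None = None,
    experiment: str | None = None,
) -> ResponseRatio:
    """Pressure response ratio between two treatment net growth rates.

    PR/CT measures grazing release, DI/PR resource release, VR/DI viral
    release, and L/D the effect of light exposure.  Degenerate denominators
    (≤ epsilon) give a missing value rather than an error.
    """
    kind = RatioKind(kind)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    _check_finite(k_num=k_num, k_den=k_den)
    difference = k_num - k_den
    if k_den > epsilon:
        value: float | None = k_num / k_den
        reason = None
    else:
        value = None
        reason = f"denominator {k_den:.6g} day^-1 <= epsilon {epsilon:.6g}"
    return ResponseRatio(
        kind=kind,
        numerator=k_num,
        denominator=k_den,
        value=value,
        difference=difference,
        epsilon=epsilon,
        reason=reason,
        group=group,
        experiment=experiment,
    )


def bootstrap_partition(
    replicate_rates: dict[str, np.ndarray],
    dilution: float = DEFAULT_DILUTION,
    n_boot: int = 999,
    seed: int | np.random.Generator = 0,
    *,
    group: str | None = None,
    experiment: str | None = None,
) -> dict[str, dict[str, float]]:
    """Propagate replicate-bottle scatter into the partition by bootstrap.

    The point partition is computed on replicate-mean rates; uncertainty is
    obtained by resampling replicate bottles with replacement within each
    treatment, re-averaging and re-solving, ``n_boot`` times.

    Parameters
    ----------
    replicate_rates
        Mapping of treatment base (``"CT"``, ``"PR"``, ``"DI"``, ``"VR"``)
        to the array of per-replicate net rates (day^-1).
    n_boot
        Number of bootstrap draws (default 999).
    seed
        Integer seed or a Generator; results are reproducible for a fixed seed.

    Returns
    -------
    dict
        Per component (``mu``, ``m_g``, ``r_c``, ``m_v``): the point
        estimate, bootstrap standard deviation, and 2.5/97.5 percentiles.
    """
    required = ("CT", "PR", "DI", "VR")
    missing = [t for t in required if t not in replicate_rates]
    if missing:
        raise ValueError(f"replicate rates missing for treatments: {missing}")
    arrays = {t: np.asarray(replicate_rates[t], dtype=float) for t in required}
    for t, arr in arrays.items():
        if arr.size < 1 or not np.all(np.isfinite(arr)):
            raise ValueError(f"treatment {t}: need >= 1 finite replicate rate")

    rng = np.random.default_rng(seed)
    point = solve_partition(
        NetRateSet(
            k_ct=arrays["CT"].mean(),
            k_pr=arrays["PR"].mean(),
            k_di=arrays["DI"].mean(),
            k_vr=arrays["VR"].mean(),
            dilution=dilution,
            group=group,
            experiment=experiment,
        )
    )
    draws = np.empty((n_boot, 4))
    for b in range(n_boot):
        means = {
            t: rng.choice(arr, size=arr.size, replace=True).mean()
            for t, arr in arrays.items()
        }
        p = solve_partition(
            NetRateSet(
                k_ct=means["CT"],
                k_pr=means["PR"],
                k_di=means["DI"],
                k_vr=means["VR"],
                dilution=dilution,
            )
        )
        draws[b] = p.as_array()

    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    sd = draws.std(axis=0, ddof=1)
    names = ("mu", "m_g", "r_c", "m_v")
    point_values = point.as_array()
    return {
        name: {
            "estimate": float(point_values[i]),
            "sd": float(sd[i]),
            "ci_low": float(lo[i]),
            "ci_high": float(hi[i]),
        }
        for i, name in enumerate(names)
    }
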