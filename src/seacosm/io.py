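"""Readers, writers, configuration and the end-to-end pipeline.

The pipeline ties the stages together: simulate (or ingest) a tidy
abundance table, estimate net growth rates per replicate, partition the
light-treatment rates into gross growth and loss components, compute the
four pressure response ratios, and run the summary statistics.  Every
intermediate is written as a comma-separated, UTF-8, dot-decimal CSV that
re-validates through its own reader, alongside a machine-readable warnings
table and a run log (seed, configuration hash, package versions) sufficient
to reproduce the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform

from . import __version__
from .fixtures import load_fixture
from .model_core import (
    DEFAULT_DILUTION,
    DEFAULT_RATIO_EPSILON,
    NetRateSet,
    RatioKind,
    RATIO_PAIRS,
    response_ratio,
    solve_partition,
)
from .rates import ABUNDANCE_COLUMNS, estimate_rates, validate_abundance_table
from .stats import anova_tukey, permanova, range_summary, ward_cluster
from .synthetic import SEASONS, NoiseSpec, simulate_campaign

__all__ = [
    "PipelineConfig",
    "read_abundance_csv",
    "write_abundance_csv",
    "load_fixture",
    "partition_table",
    "ratio_table",
    "run_pipeline",
]


def read_abundance_csv(path) -> pd.DataFrame:
    """Read and validate a tidy abundance CSV.

    Expects the six canonical columns (comma-separated, dot decimal);
    errors report the offending file line numbers.  Decimal-comma or
    semicolon-separated exports are detected and rejected with a dialect
    hint rather than silently misparsed.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"cells_per_ml": str, "time_h": str})
    if len(table.columns) == 1 and ";" in table.columns[0]:
        raise ValueError(
            f"{path}: single semicolon-joined column — this looks like a "
            "semicolon-separated/decimal-comma dialect; expected "
            "comma-separated with dot decimals"
        )
    missing = [c for c in ABUNDANCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    def lines(idx) -> list[int]:
        return [int(i) + 2 for i in idx]  # +1 header, +1 zero-base

    for col in ("time_h", "cells_per_ml"):
        raw = table[col].astype(str)
        values = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[values.isna()]
        if len(bad):
            hint = ""
            if raw.loc[bad].str.contains(",").any():
                hint = " (values contain ',' — decimal-comma dialect? use dot decimals)"
            raise ValueError(
                f"{path}: non-numeric {col} at lines {lines(bad[:5])}{hint}"
            )
        table[col] = values
    if (table["time_h"] < 0).any():
        bad = table.index[table["time_h"] < 0]
        raise ValueError(f"{path}: negative time_h at lines {lines(bad[:5])}")
    if (table["cells_per_ml"] < 0).any():
        bad = table.index[table["cells_per_ml"] < 0]
        raise ValueError(f"{path}: negative cells_per_ml at lines {lines(bad[:5])}")
    keys = ["season", "treatment", "replicate", "group", "time_h"]
    dup = table.duplicated(subset=keys, keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (season, treatment, replicate, group, time_h) "
            f"keys at lines {lines(table.index[dup][:6])}"
        )
    return table


def write_abundance_csv(table: pd.DataFrame, path) -> None:
    """Write a validated tidy abundance table as canonical CSV."""
    validate_abundance_table(table.copy())
    table.loc[:, list(ABUNDANCE_COLUMNS)].to_csv(path, index=False)


def partition_table(
    aggregated: pd.DataFrame,
    dilution: float = DEFAULT_DILUTION,
    *,
    truncate_negative: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Solve the mortality partition for every (season, group).

    Uses the replicate-mean net rates of the four light-incubated
    treatments (CT_L, PR_L, DI_L, VR_L); dark treatments never enter the
    partition.  Groups missing any of the four treatments are skipped with
    a warning record.  Returns the partition table and the warning records.
    """
    needed = {"CT_L", "PR_L", "DI_L", "VR_L"}
    rows: list[dict] = []
    warnings: list[dict] = []
    for (season, group), sub in aggregated.groupby(["season", "group"], sort=True):
        have = dict(zip(sub["treatment"], sub["k_mean"]))
        if not needed.issubset(have):
            warnings.append(
                {
                    "stage": "partition",
                    "season": season,
                    "group": group,
                    "message": f"missing light treatments {sorted(needed - set(have))}; "
                    "partition skipped",
                }
            )
            continue
        rates = NetRateSet(
            k_ct=have["CT_L"],
            k_pr=have["PR_L"],
            k_di=have["DI_L"],
            k_vr=have["VR_L"],
            dilution=dilution,
            group=group,
            experiment=season,
        )
        part = solve_partition(rates, truncate_negative=truncate_negative)
        if part.negative_components:
            warnings.append(
                {
                    "stage": "partition",
                    "season": season,
                    "group": group,
                    "message": "negative components "
                    + ",".join(part.negative_components)
                    + (" (truncated to 0)" if truncate_negative else ""),
                }
            )
        rows.append(
            {
                "season": season,
                "group": group,
                "mu": part.mu,
                "m_g": part.m_g,
                "r_c": part.r_c,
                "m_v": part.m_v,
                "dilution": dilution,
                "negative_components": ";".join(part.negative_components),
                "truncated": truncate_negative,
            }
        )
    return pd.DataFrame(rows), warnings


_LIGHT_PAIRS = (("CT_L", "CT_D"), ("PR_L", "PR_D"))


def ratio_table(
    aggregated: pd.DataFrame, epsilon: float = DEFAULT_RATIO_EPSILON
) -> tuple[pd.DataFrame, list[dict]]:
    """All pressure response ratios per (season, group).

    PR_L/CT_L (grazing), DI_L/PR_L (resources), VR_L/DI_L (viruses) and the
    light/dark pairs CT_L/CT_D and PR_L/PR_D.  Ratios with a degenerate
    denominator get a missing value and a warning record; the rate
    difference is reported regardless.
    """
    rows: list[dict] = []
    warnings: list[dict] = []
    for (season, group), sub in aggregated.groupby(["season", "group"], sort=True):
        have = dict(zip(sub["treatment"], sub["k_mean"]))

        def emit(kind: RatioKind, num_code: str, den_code: str) -> None:
            if num_code not in have or den_code not in have:
                return
            rr = response_ratio(
                have[num_code],
                have[den_code],
                kind,
                epsilon,
                group=group,
                experiment=season,
            )
            if rr.value is None:
                warnings.append(
                    {
                        "stage": "ratios",
                        "season": season,
                        "group": group,
                        "message": f"{kind.value} ratio {num_code}/{den_code} skipped: {rr.reason}",
                    }
                )
            rows.append(
                {
                    "season": season,
                    "group": group,
                    "kind": kind.value,
                    "numerator_treatment": num_code,
                    "denominator_treatment": den_code,
                    "k_numerator": rr.numerator,
                    "k_denominator": rr.denominator,
                    "ratio": rr.value if rr.value is not None else np.nan,
                    "difference": rr.difference,
                }
            )

        for kind, (num_base, den_base) in RATIO_PAIRS.items():
            emit(kind, f"{num_base}_L", f"{den_base}_L")
        for num_code, den_code in _LIGHT_PAIRS:
            emit(RatioKind.LIGHT, num_code, den_code)
    return pd.DataFrame(rows), warnings


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    output_dir: str = "seacosm_out"
    seed: int = 1
    mode: str = "simulate"  # or "ingest"
    input_csv: str | None = None
    seasons: tuple[str, ...] = SEASONS
    dilution: float = DEFAULT_DILUTION
    regression_mode: str = "full"
    min_points: int = 3
    ratio_epsilon: float = DEFAULT_RATIO_EPSILON
    truncate_negative: bool = False
    noise_kind: str = "lognormal"
    noise_cv: float = 0.10
    permanova_permutations: int = 999

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest" and not self.input_csv:
            raise ValueError("ingest mode requires input_csv")
        if not (0.0 < self.dilution < 1.0):
            raise ValueError(
                "dilution factor must lie strictly in (0, 1) — at D = 1 the "
                f"four-treatment system is singular; got {self.dilution!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seasons" in raw:
            raw["seasons"] = tuple(raw["seasons"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seasons"] = list(d["seasons"])
        return d

    def digest(self) -> str:
        """Hash of the run semantics; the output location does not affect it."""
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Paths and in-memory results of one pipeline run."""

    output_dir: Path
    abundance: pd.DataFrame
    rates_replicate: pd.DataFrame
    rates_aggregated: pd.DataFrame
    partitions: pd.DataFrame
    ratios: pd.DataFrame
    warnings: pd.DataFrame
    summary: dict


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run simulate/ingest → estimate → partition → ratios → stats.

    Writes all intermediate CSVs, a warnings table, a Newick-style
    dendrogram of final community profiles, and ``run_log.json`` into the
    configured output directory.  Identical configuration and seed produce
    identical report bytes.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[dict] = []

    if config.mode == "simulate":
        noise = NoiseSpec(kind=config.noise_kind, cv=config.noise_cv)
        abundance, truths = simulate_campaign(
            config.seed, seasons=config.seasons, noise=noise,
            dilution=config.dilution,
        )
        for season, truth in truths.items():
            (out / f"truth_{season}.json").write_text(truth.to_json())
    else:
        abundance = read_abundance_csv(config.input_csv)
    write_abundance_csv(abundance, out / "abundance.csv")

    est = estimate_rates(
        abundance, mode=config.regression_mode, min_points=config.min_points
    )
    est.per_replicate.to_csv(out / "rates_replicate.csv", index=False)
    est.aggregated.to_csv(out / "rates_aggregated.csv", index=False)
    for rec in est.issues.to_dict("records"):
        warnings.append(
            {
                "stage": "estimate",
                "season": rec["season"],
                "group": rec["group"],
                "message": f"{rec['treatment']}/{rec['replicate']}: {rec['issue']}",
            }
        )

    partitions, part_warnings = partition_table(
        est.aggregated, config.dilution, truncate_negative=config.truncate_negative
    )
    warnings.extend(part_warnings)
    partitions.to_csv(out / "partitions.csv", index=False)

    ratios, ratio_warnings = ratio_table(est.aggregated, config.ratio_epsilon)
    warnings.extend(ratio_warnings)
    ratios.to_csv(out / "ratios.csv", index=False)

    # --- summary statistics -------------------------------------------------
    summary: dict = {}

    # Per-group rate ranges across seasons (all treatments pooled).
    if len(est.aggregated):
        ranges = (
            est.aggregated.groupby(["group", "season"])["k_mean"]
            .agg(k_min="min", k_max="max")
            .reset_index()
        )
        overall = range_summary(ranges)
        overall.to_csv(out / "range_summary.csv", index=False)
        summary["range_summary_rows"] = len(overall)

    # ANOVA of gross growth rate across seasons, as in seasonal-comparison
    # analyses (needs >= 2 seasons with >= 2 groups each).
    if len(partitions) and partitions["season"].nunique() >= 2:
        counts = partitions.groupby("season").size()
        if (counts >= 2).all():
            res = anova_tukey(
                partitions["mu"].to_numpy(), partitions["season"].to_numpy()
            )
            summary["anova_mu_seasons"] = {
                "f": res.f_statistic,
                "p": res.p_value,
            }
            res.tukey.to_csv(out / "tukey_mu_seasons.csv", index=False)

    # Community profiles (relative abundance per group) at the final time
    # point of each season × treatment, replicate-averaged: Ward clustering
    # on Bray-Curtis dissimilarities plus PERMANOVA by treatment.
    profiles = _community_profiles(abundance)
    if len(profiles) >= 4:
        labels = [f"{s}|{t}" for s, t in profiles.index]
        clustering = ward_cluster(
            profiles.to_numpy(), labels=labels, distance="bray-curtis"
        )
        (out / "dendrogram.txt").write_text(clustering.to_newick() + "\n")
        treatment_labels = np.array([t for _, t in profiles.index])
        uniq, counts = np.unique(treatment_labels, return_counts=True)
        if uniq.size >= 2 and (counts >= 2).all():
            dm = squareform(pdist(profiles.to_numpy(), metric="braycurtis"))
            perm = permanova(
                dm,
                treatment_labels,
                n_perm=config.permanova_permutations,
                seed=config.seed,
            )
            summary["permanova_treatments"] = {
                "pseudo_f": perm.pseudo_f,
                "p": perm.p_value,
                "n_permutations": perm.n_permutations,
            }

    warnings_df = pd.DataFrame(
        warnings, columns=["stage", "season", "group", "message"]
    )
    warnings_df.to_csv(out / "warnings.csv", index=False)

    log = {
        "seed": config.seed,
        "config": {
            k: v for k, v in config.to_dict().items() if k != "output_dir"
        },
        "config_hash": config.digest(),
        "versions": {
            "seacosm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "summary": summary,
        "n_warnings": len(warnings_df),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    return ReportBundle(
        output_dir=out,
        abundance=abundance,
        rates_replicate=est.per_replicate,
        rates_aggregated=est.aggregated,
        partitions=partitions,
        ratios=ratios,
        warnings=warnings_df,
        summary=summary,
    )


def _community_profiles(abundance: pd.DataFrame) -> pd.DataFrame:
    """Relative group composition per (season, treatment) at the final sampling.

    Replicates are averaged; the total-count group (PRK) and the separately
    protocolled AAP category are excluded from the composition.
    """
    sub = abundance[~abundance["group"].isin(["PRK", "AAP"])]
    if not len(sub):
        return pd.DataFrame()
    last = sub.loc[
        sub.groupby(["season", "treatment", "replicate", "group"])["time_h"].idxmax()
    ]
    mean = (
        last.groupby(["season", "treatment", "group"])["cells_per_ml"]
        .mean()
        .unstack("group")
        .dropna(axis=1)
    )
    totals = mean.sum(axis=1)
    return mean.div(totals, axis=0)
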