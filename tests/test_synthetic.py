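"""Synthetic microcosm generator: forward rates, trajectories, fixtures, determinism."""

import io as _io

import numpy as np
import pytest

from seacosm import (
    ExperimentDesign,
    GroupSpec,
    NoiseSpec,
    TreatmentCode,
    estimate_rates,
    make_experiment,
    partition_table,
    true_net_rate,
)
from seacosm.synthetic import (
    SEASONS,
    check_nesting,
    default_season_design,
    default_season_specs,
    expected_abundance,
)


def spec_with(mu, m_g=0.0, r_c=0.0, m_v=0.0, modifier=1.0, name="X", fraction=0.1):
    return GroupSpec(
        name=name,
        initial_fraction=fraction,
        mu=mu,
        m_g=m_g,
        r_c=r_c,
        m_v=m_v,
        light_modifier=modifier,
    )


class TestTrueNetRate:
    def test_control_matches_budget_arithmetic(self):
        spec = spec_with(1.1, 0.4, 8 / 15, 1 / 15)
        assert true_net_rate(spec, TreatmentCode.CT_L, 0.25) == pytest.approx(0.1)

    def test_zero_losses_return_mu(self):
        spec = spec_with(0.7)
        for code in TreatmentCode:
            assert true_net_rate(spec, code) == pytest.approx(0.7)

    def test_light_modifier_sets_light_dark_ratio(self):
        spec = spec_with(1.0, modifier=1.2)
        k_light = true_net_rate(spec, TreatmentCode.PR_L)
        k_dark = true_net_rate(spec, TreatmentCode.PR_D)
        assert (k_light, k_dark) == pytest.approx((1.2, 1.0))
        assert k_light / k_dark == pytest.approx(1.2)


class TestTrajectories:
    def test_closed_form_growth(self):
        assert expected_abundance(4e5, 0.5, 24.0) == pytest.approx(4e5 * np.e**0.5)

    def test_dilution_of_starting_cells(self):
        design = ExperimentDesign(
            season="spring", seed=0, total_dapi_t0=1e6, noise=NoiseSpec(kind="none")
        )
        table, _ = make_experiment(design, [spec_with(0.5, name="SAR11", fraction=1.0)])
        di_t0 = table[
            (table.treatment == "DI_L") & (table.time_h == 0.0)
        ]["cells_per_ml"]
        assert np.allclose(di_t0, 2.5e5)
        ct_t0 = table[
            (table.treatment == "CT_L") & (table.time_h == 0.0)
        ]["cells_per_ml"]
        assert np.allclose(ct_t0, 1e6)

    def test_lag_and_plateau(self):
        assert expected_abundance(1e5, 2.4, 6.0, lag_h=12.0) == pytest.approx(1e5)
        grown = expected_abundance(1e5, 2.4, 36.0, lag_h=12.0)
        assert grown == pytest.approx(1e5 * np.exp(2.4 * 24.0 / 24.0))
        plateaued = expected_abundance(1e5, 2.4, 48.0, lag_h=12.0, plateau_h=36.0)
        assert plateaued == pytest.approx(grown)

    def test_out_of_range_sample_times_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ExperimentDesign(
                season="spring", seed=0, duration_h=36.0, sample_times_h=(0.0, 48.0)
            )


class TestDeterminism:
    def test_same_seed_byte_identical_csv(self):
        design = ExperimentDesign(season="fall", seed=123, total_dapi_t0=1e6)
        groups = [spec_with(0.6, 0.2, 0.1, 0.05, name="EUB", fraction=0.7)]
        buffers = []
        for _ in range(2):
            table, _ = make_experiment(design, groups)
            buf = _io.StringIO()
            table.to_csv(buf, index=False)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]

    def test_different_seeds_differ(self):
        groups = [spec_with(0.6, 0.2, 0.1, 0.05, name="EUB", fraction=0.7)]
        t1, _ = make_experiment(
            ExperimentDesign(season="fall", seed=1, total_dapi_t0=1e6), groups
        )
        t2, _ = make_experiment(
            ExperimentDesign(season="fall", seed=2, total_dapi_t0=1e6), groups
        )
        assert not np.allclose(t1["cells_per_ml"], t2["cells_per_ml"])


class TestDesignStructure:
    def test_aap_sampled_twice_in_ct_pr_only(self):
        design = default_season_design("winter", seed=0, noise=NoiseSpec(kind="none"))
        table, _ = make_experiment(design, default_season_specs("winter"))
        aap = table[table.group == "AAP"]
        assert set(aap.treatment.unique()) == {"CT_L", "CT_D", "PR_L", "PR_D"}
        assert aap.groupby(["treatment", "replicate"]).size().eq(2).all()

    def test_dark_treatments_only_for_ct_and_pr(self):
        design = default_season_design("summer", seed=0)
        dark = [t for t in design.treatments if not t.light]
        assert {t.base for t in dark} == {"CT", "PR"}

    def test_truth_json_round_trips(self):
        import json

        design = default_season_design("spring", seed=5, noise=NoiseSpec(kind="none"))
        _, truth = make_experiment(design, default_season_specs("spring"))
        payload = json.loads(truth.to_json())
        assert payload["season"] == "spring"
        assert payload["partitions"]["SAR11"]["m_g"] == pytest.approx(0.25)


class TestDefaultSpecs:
    def test_fixture_backed_fractions_and_totals(self):
        winter = {s.name: s for s in default_season_specs("winter")}
        assert winter["SAR11"].initial_fraction == pytest.approx(0.435)
        fall = {s.name: s for s in default_season_specs("fall")}
        assert fall["ALT"].initial_fraction == pytest.approx(0.043)
        design = default_season_design("summer", seed=0)
        assert design.total_dapi_t0 == pytest.approx(7.28e5)

    def test_unknown_season_rejected(self):
        with pytest.raises(ValueError, match="unknown season"):
            default_season_specs("monsoon")

    def test_rates_within_published_site_ranges(self):
        # gross growth stays below the site's historical maximum (5.9/day)
        # and net control rates stay above a mild negative bound
        for season in SEASONS:
            for s in default_season_specs(season):
                assert 0.0 < s.mu <= 5.9
                k_ct = true_net_rate(s, TreatmentCode.CT_L)
                assert k_ct > -0.5


class TestNesting:
    def test_probe_fractions_flagged_softly(self):
        # published winter composition overshoots the gamma budget
        messages = check_nesting(default_season_specs("winter"))
        assert any("GAMMA" in m for m in messages)
        with pytest.raises(ValueError, match="GAMMA"):
            check_nesting(default_season_specs("winter"), strict=True)

    def test_nesting_conserved_with_homogeneous_family(self):
        """With compliant fractions and family-homogeneous rates, the sum of
        child abundances never exceeds the parent at any sampled time."""
        common = dict(mu=1.0, m_g=0.3, r_c=0.2, m_v=0.05)
        groups = [
            GroupSpec(name="GAMMA", initial_fraction=0.10, parent="EUB", **common),
            GroupSpec(name="ALT", initial_fraction=0.04, parent="GAMMA", **common),
            GroupSpec(name="NOR5", initial_fraction=0.03, parent="GAMMA", **common),
        ]
        assert check_nesting(groups) == []
        design = ExperimentDesign(
            season="spring", seed=9, total_dapi_t0=1e6, noise=NoiseSpec(kind="none")
        )
        table, _ = make_experiment(design, groups)
        wide = table.pivot_table(
            index=["treatment", "replicate", "time_h"],
            columns="group",
            values="cells_per_ml",
        )
        assert ((wide["ALT"] + wide["NOR5"]) <= wide["GAMMA"] * (1 + 1e-12)).all()


class TestRecovery:
    def test_noiseless_single_season_recovery(self):
        design = default_season_design("spring", seed=21, noise=NoiseSpec(kind="none"))
        specs = default_season_specs("spring")
        table, truth = make_experiment(design, specs)
        est = estimate_rates(table)
        for _, row in est.aggregated.iterrows():
            k_true = truth.net_rates[(row["group"], row["treatment"])]
            assert row["k_mean"] == pytest.approx(k_true, abs=1e-9)
            assert row["k_sd"] == pytest.approx(0.0, abs=1e-9)
        parts, _ = partition_table(est.aggregated, design.dilution)
        for _, row in parts.iterrows():
            tp = truth.partitions[row["group"]]
            assert np.allclose(
                [row["mu"], row["m_g"], row["r_c"], row["m_v"]],
                tp.as_array(),
                atol=1e-9,
            )

    def test_poisson_noise_mode_runs(self):
        design = ExperimentDesign(
            season="spring",
            seed=4,
            total_dapi_t0=1e6,
            noise=NoiseSpec(kind="poisson", cells_per_count=500.0),
        )
        table, _ = make_experiment(design, [spec_with(0.8, name="EUB", fraction=0.7)])
        assert (table["cells_per_ml"] % 500.0 == 0).all()
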