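"""Tests of moment matching, DSA tornado and PSA/CEAC machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from sincea.sensitivity import (
    PointMass,
    build_parameter_registry,
    moment_match,
    run_dsa,
    run_psa,
)


class TestMomentMatch:
    def test_gamma_method_of_moments(self):
        dist = moment_match(100.0, 0.25, "gamma")
        # shape = (mean/sd)^2 = 16, scale = sd^2/mean = 6.25
        assert dist.kwds["a"] == pytest.approx(16.0)
        assert dist.kwds["scale"] == pytest.approx(6.25)
        assert dist.mean() == pytest.approx(100.0)
        assert dist.std() == pytest.approx(25.0)

    def test_beta_moments_and_degenerate(self):
        dist = moment_match(0.5, 0.2, "beta")
        assert dist.mean() == pytest.approx(0.5)
        assert dist.std() == pytest.approx(0.1)
        assert isinstance(moment_match(0.5, 0.0, "beta"), PointMass)

    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            moment_match(1.5, 0.25, "beta")

    def test_lognormal_ci_inversion_roundtrip(self):
        dist = moment_match(0.67, 0.25, "lognormal", ci=(0.5, 0.9))
        mu = math.log(math.sqrt(0.5 * 0.9))
        sigma = (math.log(0.9) - math.log(0.5)) / (2 * 1.959964)
        assert math.log(dist.kwds["scale"]) == pytest.approx(mu)
        assert dist.kwds["s"] == pytest.approx(sigma)
        # recompute the 95% CI from (mu, sigma)
        lo = math.exp(mu - 1.959964 * sigma)
        hi = math.exp(mu + 1.959964 * sigma)
        assert lo == pytest.approx(0.5, rel=1e-6)
        assert hi == pytest.approx(0.9, rel=1e-6)


class TestRegistry:
    def test_covers_expected_categories(self, workbook):
        registry = build_parameter_registry(workbook)
        cats = {p.category for p in registry}
        assert {"discount", "sd_utility", "pd_utility", "lump_cost",
                "drug_price", "ae_cost", "ae_disutility", "pfs_hr",
                "os_hr"} <= cats
        for p in registry:
            assert p.low <= p.base <= p.high

    def test_hr_bounds_are_the_confidence_intervals(self, workbook):
        registry = build_parameter_registry(workbook)
        arm = workbook.arms[1]
        row = next(p for p in registry if p.name == f"OS HR [{arm.name}]")
        assert (row.low, row.high) == arm.hr_os_ci

    def test_discount_rate_spans_zero_to_eight_percent(self, workbook):
        row = next(p for p in build_parameter_registry(workbook)
                   if p.category == "discount")
        assert (row.low, row.high) == (0.0, 0.08)
        assert row.dist is None  # held fixed in the PSA


class TestRunDsa:
    def test_base_column_invariant_and_sorted(self, workbook, reference_fits):
        df = run_dsa(workbook, reference_fits, workbook.arms[1].name)
        assert df["base_icer"].nunique() == 1
        spreads = df["spread"].dropna().to_numpy()
        assert np.all(np.diff(spreads) <= 1e-9)

    def test_zero_width_parameter_has_zero_spread_and_ranks_last(self, workbook, reference_fits):
        from sincea.sensitivity import Parameter

        registry = build_parameter_registry(workbook)
        frozen = Parameter("frozen input", "lump_cost", 1.0, 1.0, 1.0,
                           lambda w, v: None, None)
        df = run_dsa(workbook, reference_fits, workbook.arms[1].name,
                     registry=registry + [frozen])
        row = df[df["parameter"] == "frozen input"].iloc[0]
        assert row["spread"] == 0.0
        assert df["parameter"].iloc[-1] in ("frozen input",) or np.isnan(
            df["spread"].iloc[-1]
        )


class TestRunPsa:
    def test_degenerate_distributions_reproduce_base_case(self, workbook, reference_fits):
        from sincea.cea import evaluate_workbook
        from sincea.sensitivity import Parameter

        registry = [
            Parameter(p.name, p.category, p.base, p.low, p.high, p.setter,
                      PointMass(p.base) if p.dist is not None else None)
            for p in build_parameter_registry(workbook)
        ]
        psa = run_psa(workbook, reference_fits, n_draws=20, seed=0,
                      wtp_step=50_000.0, registry=registry)
        base = evaluate_workbook(workbook, reference_fits)
        for arm, res in base.items():
            sub = psa.draws[psa.draws["arm"] == arm]
            assert np.allclose(sub["cost"], res.cost)
            assert np.allclose(sub["qaly"], res.qaly)
        # degenerate draws -> CEAC is a 0/1 step function per strategy
        assert set(np.round(psa.ceac["probability"], 12)) <= {0.0, 1.0}

    def test_cheapest_strategy_wins_at_zero_wtp_under_degenerate_costs(
        self, workbook, reference_fits
    ):
        from sincea.sensitivity import Parameter

        registry = [
            Parameter(p.name, p.category, p.base, p.low, p.high, p.setter,
                      PointMass(p.base) if p.dist is not None else None)
            for p in build_parameter_registry(workbook)
        ]
        psa = run_psa(workbook, reference_fits, n_draws=5, seed=0,
                      wtp_step=200_000.0, registry=registry)
        at_zero = psa.ceac[psa.ceac["wtp"] == 0.0].set_index("strategy")["probability"]
        assert at_zero[workbook.reference.name] == 1.0  # chemotherapy is cheapest

    def test_ceac_probabilities_sum_to_one(self, workbook, reference_fits):
        psa = run_psa(workbook, reference_fits, n_draws=100, seed=2,
                      wtp_step=10_000.0)
        sums = psa.ceac.groupby("wtp")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_reproducible_under_fixed_seed(self, workbook, reference_fits):
        a = run_psa(workbook, reference_fits, n_draws=30, seed=9, wtp_step=100_000.0)
        b = run_psa(workbook, reference_fits, n_draws=30, seed=9, wtp_step=100_000.0)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.ceac, b.ceac)

    def test_small_dispersion_means_converge_to_base_case(self, workbook, reference_fits):
        """With nearly degenerate distributions the PSA means sit within
        Monte-Carlo error of the base case (mean preservation)."""
        from sincea.cea import evaluate_workbook

        registry = build_parameter_registry(workbook, dispersion=0.02)
        for p in registry:  # HRs default to CI-derived spread; narrow them too
            if p.category in ("pfs_hr", "os_hr"):
                p.dist = moment_match(p.base, 0.02, "lognormal")
        psa = run_psa(workbook, reference_fits, n_draws=200, seed=4,
                      wtp_step=100_000.0, registry=registry)
        base = evaluate_workbook(workbook, reference_fits)
        for arm, res in base.items():
            sub = psa.draws[psa.draws["arm"] == arm]
            assert sub["cost"].mean() == pytest.approx(res.cost, rel=0.02)
            assert sub["qaly"].mean() == pytest.approx(res.qaly, rel=0.02)
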