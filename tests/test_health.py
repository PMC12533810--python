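"""County exposure aggregation, health impact function, and IRR identities."""

import numpy as np
import pandas as pd
import pytest

from smokewave import (
    CountyCrosswalk,
    CountyProfile,
    HealthImpactFunction,
    SyntheticConfig,
    aggregate_irr,
    county_burdens,
    county_exposure,
    delta_events,
    ensemble_average,
    episode_mean,
    irr,
    make_counties,
    make_ensemble,
    run_endpoints,
)

HIF = HealthImpactFunction("asthma_ed_visits", beta=6.7e-3, beta_se=5e-4)
PROF = CountyProfile("X", population=1e5, baseline_rate=2.2e-5)


def _xwalk(rows):
    return CountyCrosswalk(pd.DataFrame(rows, columns=["county_id", "row", "col", "weight"]))


class TestCrosswalk:
    def test_weights_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _xwalk([("A", 0, 0, 0.5), ("A", 0, 1, 0.4)])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _xwalk([("A", 0, 0, 1.5), ("A", 0, 1, -0.5)])

    def test_cells_outside_grid_rejected(self, make_field):
        xw = _xwalk([("A", 5, 99, 1.0)])
        scenario = episode_mean(make_field(np.full((3, 6, 8), 10.0)), ["2023-06-06"])
        with pytest.raises(ValueError, match="outside the grid"):
            county_exposure(scenario, scenario, xw)


class TestCountyExposure:
    def test_identical_fields_give_zero(self, make_field, days):
        f = episode_mean(make_field(np.full((3, 6, 8), 30.0)), days)
        xw = _xwalk([("A", 0, 0, 0.5), ("A", 0, 1, 0.5)])
        assert county_exposure(f, f, xw)["A"] == 0.0

    def test_single_cell_county(self, make_field, days):
        scen = np.full((3, 6, 8), 10.0)
        scen[:, 2, 3] = 90.0
        ctrl = np.full((3, 6, 8), 10.0)
        xw = _xwalk([("A", 2, 3, 1.0)])
        dx = county_exposure(
            episode_mean(make_field(scen), days),
            episode_mean(make_field(ctrl), days),
            xw,
        )
        assert dx["A"] == pytest.approx(80.0)

    def test_matches_weighted_sum_oracle(self, make_field, days):
        rng = np.random.default_rng(17)
        scen = rng.uniform(0, 150, (3, 6, 8))
        ctrl = rng.uniform(0, 20, (3, 6, 8))
        cells = [(r, c) for r in range(6) for c in range(8)]
        rng.shuffle(cells)
        raw_w = rng.uniform(0.1, 1.0, 10)
        rows = []
        for county, chunk in (("A", cells[:10]), ("B", cells[10:20])):
            w = rng.uniform(0.1, 1.0, len(chunk))
            w = w / w.sum()
            rows += [(county, r, c, wi) for (r, c), wi in zip(chunk, w)]
        xw = _xwalk(rows)
        sm = episode_mean(make_field(scen), days)
        cm = episode_mean(make_field(ctrl), days)
        got = county_exposure(sm, cm, xw)
        diff = sm.values[0] - cm.values[0]
        for county in ("A", "B"):
            expected = sum(
                wi * diff[r, c] for (cid, r, c, wi) in rows if cid == county
            )
            assert got[county] == pytest.approx(expected, rel=1e-12)


class TestDeltaEvents:
    def test_zero_exposure_change(self):
        dy, var = delta_events(HIF, PROF, 0.0, n_days=3)
        assert dy == 0.0 and var == 0.0

    def test_small_signal_linearization(self):
        # for beta*dx < 0.01 the log-linear response is linear within 1%
        dx = 0.01 / HIF.beta * 0.99
        dy, _ = delta_events(HIF, PROF, dx, n_days=3)
        linear = PROF.baseline_rate * PROF.population * HIF.beta * dx * 3
        assert dy / linear == pytest.approx(1.0, abs=0.01)

    def test_closed_form_against_high_precision_oracle(self):
        # frozen from sympy with 25-digit arithmetic:
        # y0=2.2e-5/day, Pop=1e5, beta=6.7e-3, dx=100, n_days=3, se=5e-4
        dy, var = delta_events(HIF, PROF, 100.0, n_days=3)
        assert dy == pytest.approx(3.222723386608819, rel=1e-12)
        assert var == pytest.approx(0.028514993308397500, rel=1e-12)

    def test_bounded_by_baseline_events(self):
        dy, _ = delta_events(HIF, PROF, 1e6, n_days=3)
        assert dy <= PROF.baseline_rate * PROF.population * 3 + 1e-12

    def test_delta_method_agrees_with_monte_carlo(self):
        # beta_se * dx < 0.05 regime
        rng = np.random.default_rng(99)
        dx = 80.0
        assert HIF.beta_se * dx < 0.05
        _, var_delta = delta_events(HIF, PROF, dx, n_days=3)
        _, var_mc = delta_events(HIF, PROF, dx, n_days=3, method="mc",
                                 n_draws=200_000, rng=rng)
        assert var_mc == pytest.approx(var_delta, rel=0.05)

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError, match="population"):
            CountyProfile("bad", population=-1.0, baseline_rate=1e-5)


class TestIrr:
    def test_zero_delta_gives_unit_irr(self):
        point, lo, hi = irr(0.0, 0.0, 100.0)
        assert point == lo == hi == 1.0

    def test_hand_arithmetic_example(self):
        # sum(dY)=40, sum(base)=100, sum(var)=25 -> 1.40, [1.302, 1.498]
        point, lo, hi = irr(40.0, 25.0, 100.0)
        assert point == pytest.approx(1.40)
        assert lo == pytest.approx(1.302, abs=5e-4)
        assert hi == pytest.approx(1.498, abs=5e-4)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            irr(10.0, 1.0, 0.0)

    def test_partition_invariance(self):
        rng = np.random.default_rng(4)
        dys = rng.uniform(0, 30, 12)
        vars_ = rng.uniform(0, 5, 12)
        bases = rng.uniform(50, 500, 12)
        whole = irr(dys.sum(), vars_.sum(), bases.sum())
        halves = irr(
            dys[:6].sum() + dys[6:].sum(),
            vars_[:6].sum() + vars_[6:].sum(),
            bases[:6].sum() + bases[6:].sum(),
        )
        assert whole == pytest.approx(halves, rel=1e-14)

    def test_strictly_increasing_in_exposure(self):
        prof = CountyProfile("X", 1e5, 2.2e-5)
        points = []
        for dx in (0.0, 10.0, 50.0, 100.0, 200.0):
            dy, var = delta_events(HIF, prof, dx, 3)
            points.append(irr(dy, var, prof.baseline_rate * prof.population * 3)[0])
        assert all(b > a for a, b in zip(points, points[1:]))
        assert points[0] == 1.0


class TestRunEndpoints:
    @pytest.fixture()
    def pipeline_inputs(self, small_cfg):
        ens, controls = make_ensemble(small_cfg)
        profiles, xwalk = make_counties(small_cfg)
        return small_cfg, ens, controls, profiles, xwalk

    def test_identical_endpoints_identical_tables(self, pipeline_inputs):
        cfg, ens, controls, profiles, xwalk = pipeline_inputs
        h1 = HealthImpactFunction("a", 5e-3, 5e-4)
        h2 = HealthImpactFunction("b", 5e-3, 5e-4)
        res = run_endpoints(ens, controls, xwalk, profiles, [h1, h2], cfg.days)
        for scen in res["a"]:
            pd.testing.assert_frame_equal(res["a"][scen], res["b"][scen])

    def test_scenario_cardinality(self, pipeline_inputs):
        cfg, ens, controls, profiles, xwalk = pipeline_inputs
        res = run_endpoints(ens, controls, xwalk, profiles, [HIF], cfg.days)
        tables = res[HIF.endpoint]
        assert len(tables) == 5  # four members plus the average case
        assert "CMAQ-Average" in tables

    def test_plume_core_counties_outrank_background_in_every_member(
        self, pipeline_inputs
    ):
        cfg, ens, controls, profiles, xwalk = pipeline_inputs
        res = run_endpoints(ens, controls, xwalk, profiles, [HIF], cfg.days)
        # oracle: recompute exposure per county and rank
        for scen, table in res[HIF.endpoint].items():
            t = table.set_index("county_id")
            core = t["delta_x"].idxmax()
            background = t["delta_x"].idxmin()
            assert t.loc[core, "irr"] > t.loc[background, "irr"]

    def test_ranking_matches_oracle_recomputation(self, pipeline_inputs):
        cfg, ens, controls, profiles, xwalk = pipeline_inputs
        res = run_endpoints(ens, controls, xwalk, profiles, [HIF], cfg.days)
        table = res[HIF.endpoint]["CMAQ-Average"]
        avg_mean = episode_mean(ensemble_average(ens), cfg.days)
        ctrl_mean = episode_mean(controls[0], cfg.days)
        expo = county_exposure(avg_mean, ctrl_mean, xwalk)
        oracle = county_burdens(HIF, profiles, expo, cfg.n_days)
        got_rank = table.sort_values("irr", ascending=False)["county_id"].tolist()
        oracle_rank = oracle.sort_values("irr", ascending=False)["county_id"].tolist()
        assert got_rank == oracle_rank

    def test_irr_ranking_invariant_under_population_scaling(self, pipeline_inputs):
        cfg, ens, controls, profiles, xwalk = pipeline_inputs
        scaled = [
            CountyProfile(p.county_id, p.population * 10.0, p.baseline_rate, p.region_id)
            for p in profiles
        ]
        r1 = run_endpoints(ens, controls, xwalk, profiles, [HIF], cfg.days)
        r2 = run_endpoints(ens, controls, xwalk, scaled, [HIF], cfg.days)
        t1 = r1[HIF.endpoint]["CMAQ-Average"].sort_values("irr")["county_id"].tolist()
        t2 = r2[HIF.endpoint]["CMAQ-Average"].sort_values("irr")["county_id"].tolist()
        assert t1 == t2


def test_aggregate_irr_groups_sum_exactly():
    burdens = pd.DataFrame(
        {
            "county_id": ["A", "B", "C"],
            "delta_x": [10.0, 20.0, 5.0],
            "delta_events": [4.0, 6.0, 2.0],
            "variance": [1.0, 2.0, 0.5],
            "baseline_events": [50.0, 30.0, 20.0],
            "irr": [np.nan] * 3,
            "ci_low": [np.nan] * 3,
            "ci_high": [np.nan] * 3,
        }
    )
    whole = aggregate_irr(burdens)
    assert whole.loc[0, "irr"] == pytest.approx(12.0 / 100.0 + 1.0)
    split = aggregate_irr(burdens, by=pd.Series({"A": "r1", "B": "r1", "C": "r2"}))
    r1 = split.set_index("region_id").loc["r1"]
    assert r1["irr"] == pytest.approx(10.0 / 80.0 + 1.0)
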