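"""Sweep campaign, percentage contributions, tEV:nEV ratios, fold changes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evkinetics import (
    CellPopulation,
    IsolationYields,
    ScenarioGrid,
    TumorSpec,
    default_tumor_spec,
    fold_change,
    percentage_contribution,
    run_grid,
    steady_state_count,
    tev_nev_ratio,
    tumor_to_population,
)


class TestPercentageContribution:
    def test_zero_tumor(self):
        assert percentage_contribution(0.0, 1e10) == 0.0

    def test_symmetry_at_equal_pools(self):
        assert percentage_contribution(5e9, 5e9) == pytest.approx(50.0)

    def test_realistic_magnitude(self):
        # 6e9 tumor EVs against a 1e13 normal pool -> ~0.06%
        assert percentage_contribution(6e9, 1e13) == pytest.approx(0.06, rel=1e-3)

    def test_denominator_variants_close_at_small_share(self):
        total = percentage_contribution(6e9, 1e13, denominator="total")
        normal = percentage_contribution(6e9, 1e13, denominator="normal")
        assert normal > total
        assert normal / total == pytest.approx(1.0, rel=1e-3)

    def test_zero_pool_rejected(self):
        with pytest.raises(ValueError):
            percentage_contribution(1.0, 0.0)

    @given(
        st.floats(min_value=1.0, max_value=1e12),
        st.floats(min_value=1.0, max_value=1e15),
        st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_scale_invariant(self, tumor, pool, scale):
        base = percentage_contribution(tumor, pool)
        assert percentage_contribution(tumor * 1.5, pool) > base
        assert percentage_contribution(tumor, pool * 1.5) < base
        assert percentage_contribution(tumor * scale, pool * scale) == pytest.approx(
            base, rel=1e-9
        )


class TestTevNevRatio:
    def test_symmetric_populations(self, tumor_1cm):
        assert tev_nev_ratio(tumor_1cm, [tumor_1cm]) == pytest.approx(1.0)

    def test_yield_linearity(self, tumor_1cm, calibrated_panel):
        full = tev_nev_ratio(tumor_1cm, calibrated_panel)
        half = tev_nev_ratio(
            tumor_1cm, calibrated_panel, IsolationYields(yield_tumor=0.5)
        )
        assert half == pytest.approx(full / 2)

    def test_published_pool_sizes_give_1e_minus_6(self, baseline_rates):
        """1e4 tumor EVs against 1e10 total per ml -> fraction 1e-6 (0.0001%)."""
        total = baseline_rates.total
        tumor = CellPopulation("tumor", 1.0, 1e4 * total, baseline_rates)
        normal = CellPopulation("normal", 1.0, 1e10 * total, baseline_rates)
        assert tev_nev_ratio(tumor, [normal]) == pytest.approx(1e-6, rel=1e-9)

    def test_empty_normals_rejected(self, tumor_1cm):
        with pytest.raises(ValueError):
            tev_nev_ratio(tumor_1cm, [])


class TestFoldChange:
    def test_identity(self):
        assert fold_change(3.7, 3.7) == 1.0

    def test_elimination_tenth_is_near_tenfold(self, baseline_rates):
        base = tumor_to_population(default_tumor_spec(1.0), baseline_rates)
        slow = tumor_to_population(
            TumorSpec(diameter=1.0, elimination_multiplier=0.1), baseline_rates
        )
        fold = fold_change(steady_state_count(base), steady_state_count(slow))
        # (E+U)/(0.1E+U) with printed constants
        assert fold == pytest.approx(9.851, rel=1e-3)

    def test_uptake_multipliers_weak_effect(self, baseline_rates):
        """Uptake is ~600x smaller than elimination, so even 10x barely moves N*."""
        base = tumor_to_population(default_tumor_spec(1.0), baseline_rates)
        up10 = tumor_to_population(
            TumorSpec(diameter=1.0, uptake_multiplier=10.0), baseline_rates
        )
        up100 = tumor_to_population(
            TumorSpec(diameter=1.0, uptake_multiplier=100.0), baseline_rates
        )
        # (E+U)/(E+10U) and (E+U)/(E+100U) with printed constants
        assert fold_change(steady_state_count(base), steady_state_count(up10)) == pytest.approx(
            0.0991667 / 0.1006670, rel=1e-6
        )
        assert fold_change(steady_state_count(base), steady_state_count(up100)) == pytest.approx(
            0.0991667 / 0.1156700, rel=1e-6
        )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestScenarioGrid:
    def test_default_grid_size(self):
        grid = ScenarioGrid()
        assert len(list(grid.scenarios())) == 27

    def test_ordering_diameter_outer(self):
        grid = ScenarioGrid(
            tumor_diameters=[0.5, 2.0],
            uptake_multipliers=[1.0, 10.0],
            elimination_multipliers=[1.0],
        )
        assert list(grid.scenarios()) == [
            (0.5, 1.0, 1.0),
            (0.5, 10.0, 1.0),
            (2.0, 1.0, 1.0),
            (2.0, 10.0, 1.0),
        ]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tumor_diameters": []},
            {"uptake_multipliers": []},
            {"elimination_multipliers": [0.0]},
            {"horizon_min": 0},
        ],
    )
    def test_invalid_grid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioGrid(**kwargs)


@pytest.fixture(scope="module")
def grid_result(baseline_rates, calibrated_panel):
    grid = ScenarioGrid(blood_panel=calibrated_panel)
    return run_grid(grid, baseline_rates, default_tumor_spec())


class TestRunGrid:
    def test_all_default_scenarios_succeed(self, grid_result):
        assert len(grid_result.scenarios) == 27
        assert not any(r.failed for r in grid_result.scenarios)

    def test_diameter_fold_at_default_rates(self, grid_result):
        by_scenario = {
            r.scenario: r.summary.steady_state_count for r in grid_result.scenarios
        }
        fold = by_scenario[(2.0, 1.0, 1.0)] / by_scenario[(0.5, 1.0, 1.0)]
        assert fold == pytest.approx(64.0, rel=1e-9)
        assert fold >= 10.0

    def test_contribution_increases_with_diameter(self, grid_result):
        for u in (1.0, 10.0, 100.0):
            for e in (1.0, 0.1, 0.01):
                pcts = [
                    r.contribution.percent_contribution
                    for r in grid_result.scenarios
                    if r.scenario[1] == u and r.scenario[2] == e
                ]
                assert pcts == sorted(pcts)
                assert pcts[0] < pcts[1] < pcts[2]

    def test_determinism(self, grid_result, baseline_rates, calibrated_panel):
        again = run_grid(
            ScenarioGrid(blood_panel=calibrated_panel), baseline_rates, default_tumor_spec()
        )
        a, b = grid_result.to_frame(), again.to_frame()
        assert a.equals(b)

    def test_unstable_scenario_recorded_not_dropped(self, baseline_rates, calibrated_panel):
        grid = ScenarioGrid(
            elimination_multipliers=[1.0, 11.0],  # 11 x 0.099 > 1/min: unstable
            uptake_multipliers=[1.0],
            tumor_diameters=[1.0],
            blood_panel=calibrated_panel,
        )
        result = run_grid(grid, baseline_rates, default_tumor_spec())
        assert len(result.scenarios) == 2
        failed = [r for r in result.scenarios if r.failed]
        assert len(failed) == 1 and failed[0].scenario == (1.0, 1.0, 11.0)

    def test_tidy_frame_columns(self, grid_result):
        frame = grid_result.to_frame()
        assert len(frame) == 27
        for col in (
            "diameter_cm",
            "uptake_multiplier",
            "elimination_multiplier",
            "steady_state_count",
            "time_to_steady_state_min",
            "percent_contribution",
        ):
            assert col in frame.columns

    def test_plots_render(self, grid_result, tmp_path):
        from evkinetics.scenarios import plot_summary_bars, plot_trajectories

        plot_trajectories(grid_result, tmp_path / "lines.png")
        plot_summary_bars(grid_result, tmp_path / "bars.png")
        assert (tmp_path / "lines.png").stat().st_size > 0
        assert (tmp_path / "bars.png").stat().st_size > 0
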