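"""Target sweep, phase classification, functional roles, type chi-squared."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boombust.analysis import (
    PhaseAssignment,
    annual_counts,
    annual_prioritisation,
    classify_years,
    functional_classification,
    marginal_increase,
    pearson_chisq,
    phase_mean_irsc,
    sweep_targets,
    type_irreplaceability,
    type_phase_table,
)
from boombust.datamodel import CovariateSeries, PlanningUnitTable, RunConfig, ValidationError
from boombust.solver import IrreplaceabilityResult, ProblemInstance, classify_irsc, exact_minset


def _cov(flows, start_year=2000):
    years = np.arange(start_year, start_year + len(flows))
    return CovariateSeries(pd.DataFrame({"year": years, "flow_total": flows}))


def _irsc_result(values: dict) -> IrreplaceabilityResult:
    frame = pd.DataFrame(
        {
            "pu_id": list(values),
            "irsc": list(values.values()),
            "irsc_class": [classify_irsc(v) for v in values.values()],
        }
    )
    return IrreplaceabilityResult(frame=frame, n_solutions=100)


class TestMarginalIncrease:
    def test_published_wetland_count_series(self):
        counts = [4, 6, 8, 11, 16, 20, 27, 34, 56, 225]
        increases = marginal_increase(counts)
        assert increases[-2:] == [65, 302]

    @pytest.mark.parametrize(
        "counts, expected",
        [([10, 10], [0]), ([34, 56], [65]), ([4, 6], [50])],
    )
    def test_rounding_to_integer_percent(self, counts, expected):
        assert marginal_increase(counts) == expected

    def test_zero_denominator_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = marginal_increase([0, 5, 10])
        assert np.isnan(out[0]) and out[1] == 100


class TestPhaseClassification:
    def test_octile_flows_split_into_quartiles(self):
        phases = classify_years(_cov([1, 2, 3, 4, 5, 6, 7, 8]))
        # type-7 quantiles: q25 = 2.75, q75 = 6.25, strict inequalities
        assert phases.cutpoints == (2.75, 6.25)
        assert phases.frame.loc[phases.frame["flow"].isin([1, 2]), "phase"].tolist() == ["dry"] * 2
        assert phases.frame.loc[phases.frame["flow"].isin([7, 8]), "phase"].tolist() == ["wet"] * 2
        assert (phases.frame["phase"] == "normal").sum() == 4

    def test_constant_flow_all_normal(self):
        phases = classify_years(_cov([5.0] * 6))
        assert set(phases.frame["phase"]) == {"normal"}

    @given(st.permutations(list(range(1, 9))))
    @settings(max_examples=30, deadline=None)
    def test_year_order_does_not_change_labels(self, flows):
        years = np.arange(2000, 2008)
        cov = CovariateSeries(pd.DataFrame({"year": years, "flow_total": flows}))
        phases = classify_years(cov)
        by_flow = phases.frame.set_index("flow")["phase"]
        assert by_flow[1] == "dry" and by_flow[8] == "wet"

    def test_too_few_years_rejected(self):
        with pytest.raises(ValidationError, match="4 years"):
            classify_years(_cov([1, 2, 3]))

    def test_missing_flow_rejected(self):
        cov = _cov([1, 2, 3, 4])
        with pytest.raises(ValidationError, match="missing flow"):
            cov.flow_for_years([2000, 2050])


class TestFunctionalClassification:
    PHASES = PhaseAssignment(
        frame=pd.DataFrame(
            {"year": [1, 2, 3, 4], "flow": [1.0, 2.0, 9.0, 10.0],
             "phase": ["dry", "dry", "wet", "wet"]}
        ),
        cutpoints=(1.5, 8.5),
    )

    def test_published_wet_dry_pairs(self):
        # mean IrSc pairs reported for named wetlands: (wet, dry)
        annual = {
            1: _irsc_result({"coolmunda": 1.0, "cuttaburra": 0.47, "lowbidgee": 0.94}),
            2: _irsc_result({"coolmunda": 1.0, "cuttaburra": 0.47, "lowbidgee": 0.94}),
            3: _irsc_result({"coolmunda": 0.47, "cuttaburra": 1.0, "lowbidgee": 1.0}),
            4: _irsc_result({"coolmunda": 0.47, "cuttaburra": 1.0, "lowbidgee": 1.0}),
        }
        roles = functional_classification(annual, self.PHASES)
        by_id = roles.frame.set_index("pu_id")["role"]
        assert by_id["coolmunda"] == "refuge"       # 0.47 wet / 1.00 dry
        assert by_id["cuttaburra"] == "breeding"    # 1.00 wet / 0.47 dry
        assert by_id["lowbidgee"] == "both"         # 1.00 wet / 0.94 dry

    def test_roles_partition_pus(self):
        rng = np.random.default_rng(0)
        annual = {
            y: _irsc_result({f"pu{i}": rng.uniform() for i in range(20)})
            for y in (1, 2, 3, 4)
        }
        roles = functional_classification(annual, self.PHASES)
        assert len(roles.frame) == 20
        assert roles.frame["role"].isin(["refuge", "breeding", "both", "neither"]).all()
        assert roles.frame["pu_id"].is_unique

    def test_threshold_boundary_inclusive(self):
        annual = {y: _irsc_result({"x": 0.6 if y <= 2 else 0.59}) for y in (1, 2, 3, 4)}
        roles = functional_classification(annual, self.PHASES)
        assert roles.frame.loc[0, "role"] == "refuge"

    def test_missing_phase_rejected(self):
        phases = PhaseAssignment(
            frame=pd.DataFrame({"year": [1, 2], "flow": [1.0, 2.0], "phase": ["dry", "dry"]}),
            cutpoints=(0.5, 5.0),
        )
        annual = {y: _irsc_result({"x": 1.0}) for y in (1, 2)}
        with pytest.raises(ValidationError, match="wet"):
            functional_classification(annual, phases)


class TestPhaseFixturePipeline:
    def test_dry_and_wet_years_select_different_pu_sets(self, phase_scenario):
        pus, tensor = phase_scenario
        dry = ProblemInstance.from_tensor(tensor, pus, "0.8", year=2001)
        wet = ProblemInstance.from_tensor(tensor, pus, "0.8", year=2002)
        assert exact_minset(dry)[1] == [frozenset({"A", "B"})]
        assert exact_minset(wet)[1] == [frozenset({"B", "C"})]

    def test_roles_recovered_from_annual_prioritisation(self, phase_scenario, fast_config):
        pus, tensor = phase_scenario
        annual = annual_prioritisation(tensor, pus, fast_config)
        phases = PhaseAssignment(
            frame=pd.DataFrame(
                {"year": [2001, 2002], "flow": [1.0, 10.0], "phase": ["dry", "wet"]}
            ),
            cutpoints=(2.0, 8.0),
        )
        roles = functional_classification(annual, phases)
        by_id = roles.frame.set_index("pu_id")["role"]
        assert by_id.to_dict() == {
            "A": "refuge", "B": "both", "C": "breeding", "D": "neither"
        }

    def test_identical_years_get_identical_irsc(self, fixture_scenario, fast_config):
        pus, tensor = fixture_scenario
        twice = tensor.frame.assign(year=2000)
        other = tensor.frame.assign(year=2001)
        both = pd.concat([twice, other], ignore_index=True)
        from boombust.datamodel import AbundanceTensor
        doubled = AbundanceTensor(both)
        annual = annual_prioritisation(doubled, pus, fast_config)
        assert annual[2000].frame.equals(annual[2001].frame)

    def test_all_zero_year_yields_empty_solution(self, fixture_scenario, fast_config):
        pus, tensor = fixture_scenario
        frame = pd.concat(
            [tensor.frame, pd.DataFrame(
                {"species_id": ["s1"], "pu_id": ["A"], "year": [2001], "count": [0]}
            )],
            ignore_index=True,
        )
        from boombust.datamodel import AbundanceTensor
        with_empty = AbundanceTensor(frame)
        annual = annual_prioritisation(with_empty, pus, fast_config)
        counts = annual_counts(annual, 0.6)
        assert counts[2001] == 0
        assert (annual[2001].irsc() == 0).all()


class TestSweep:
    def test_fixture_counts_across_targets(self, fixture_scenario, fast_config):
        pus, tensor = fixture_scenario
        result = sweep_targets(tensor, pus, fast_config, targets=("0.1", "0.8", "1"))
        assert result.counts == [1, 3, 4]
        assert result.frame["pct_increase"].tolist()[1:] == [200, 33]

    def test_exact_optimum_size_monotone_over_target_grid(self, fixture_scenario):
        pus, tensor = fixture_scenario
        sizes = []
        for k in range(1, 11):
            from fractions import Fraction
            inst = ProblemInstance.from_tensor(tensor, pus, Fraction(k, 10))
            sizes.append(exact_minset(inst)[0].size)
        assert sizes == sorted(sizes)
        assert sizes[0] == 1 and sizes[-1] == 4


class TestTypeIrreplaceability:
    def test_area_correction_example(self):
        pus = PlanningUnitTable(pd.DataFrame(
            {"pu_id": ["a", "b"], "wetland_type": ["lacustrine", "palustrine"],
             "area": [1.0, 4.0]}
        ))
        irsc = pd.Series({"a": 1.0, "b": 1.0})
        props = type_irreplaceability(irsc, pus)
        assert props["lacustrine"] == pytest.approx(0.8)
        assert props["palustrine"] == pytest.approx(0.2)

    def test_single_type_gets_everything(self):
        pus = PlanningUnitTable(pd.DataFrame(
            {"pu_id": ["a", "b"], "wetland_type": ["riverine", "riverine"],
             "area": [1.0, 2.0]}
        ))
        props = type_irreplaceability(pd.Series({"a": 0.5, "b": 0.25}), pus)
        assert props["riverine"] == pytest.approx(1.0)

    def test_all_zero_scores_flagged_undefined(self):
        pus = PlanningUnitTable(pd.DataFrame(
            {"pu_id": ["a", "b"], "wetland_type": ["riverine", "lacustrine"],
             "area": [1.0, 2.0]}
        ))
        with pytest.warns(UserWarning, match="undefined"):
            props = type_irreplaceability(pd.Series({"a": 0.0, "b": 0.0}), pus)
        assert props.isna().all()

    def test_zero_area_with_score_rejected(self):
        pus = PlanningUnitTable(pd.DataFrame(
            {"pu_id": ["a", "b"], "wetland_type": ["riverine", "lacustrine"],
             "area": [0.0, 2.0]}
        ))
        with pytest.raises(ValidationError, match="zero area"):
            type_irreplaceability(pd.Series({"a": 0.5, "b": 0.1}), pus)

    def test_proportions_sum_to_one_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(4, 12)
            pus = PlanningUnitTable(pd.DataFrame(
                {
                    "pu_id": [f"p{i}" for i in range(n)],
                    "wetland_type": rng.choice(
                        ["estuarine", "lacustrine", "palustrine", "riverine"], size=n
                    ),
                    "area": rng.uniform(0.5, 10, size=n),
                }
            ))
            irsc = pd.Series(rng.uniform(0.05, 1, size=n), index=pus.pu_ids)
            assert type_irreplaceability(irsc, pus).sum() == pytest.approx(1.0, abs=1e-12)


class TestChiSquared:
    def test_uniform_table_statistic_zero(self):
        stat, df, p = pearson_chisq(np.full((3, 2), 7.0))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 2 and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        stat, df, p = pearson_chisq([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, abs=1e-9)   # 4 * 25 / 15
        assert df == 1

    def test_four_by_two_degrees_of_freedom(self):
        stat, df, _ = pearson_chisq(np.arange(1, 9).reshape(4, 2))
        assert df == 3

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            pearson_chisq([[0, 0], [1, 2]])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.uniform(0.5, 30, size=(rng.integers(2, 5), rng.integers(2, 4)))
        stat, df, _ = pearson_chisq(table)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        oracle = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle, abs=1e-10)

    def test_type_phase_table_feeds_chisq(self, phase_scenario):
        pus, _ = phase_scenario
        dry = pd.Series([1.0, 1.0, 0.1, 0.2], index=pus.pu_ids)
        wet = pd.Series([0.1, 1.0, 1.0, 0.1], index=pus.pu_ids)
        table = type_phase_table(dry, wet, pus)
        assert table.shape == (4, 2)
        # column totals rescale to each phase's summed IrSc
        assert table["dry"].sum() == pytest.approx(2.3)
        assert table["wet"].sum() == pytest.approx(2.2)
        stat, df, p = pearson_chisq(table.to_numpy())
        assert df == 3
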