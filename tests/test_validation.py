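"""Measured-flux matching, uncentered correlation, correlation ranges."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fluxinfer.boolexpr import parse
from fluxinfer.expression import eflux_bounds, reaction_expression
from fluxinfer.fixtures import (
    ToySpec,
    make_toy_model,
    oracle_correlation_range,
)
from fluxinfer.methods import FluxDistribution, solve_eflux2
from fluxinfer.template import build_template
from fluxinfer.validation import (
    MeasuredFluxSet,
    MeasuredRecord,
    ValidationError,
    correlation_range,
    expression_flux_correlation,
    match_predicted_to_measured,
    normalize_to_measured,
    read_measured_table,
    summarize_conditions,
    uncentered_pearson,
)


def _flux(values):
    return FluxDistribution(
        fluxes=pd.Series(values), method="test", objective_value=0.0,
        status="optimal", solver="",
    )


def _measured(rows):
    return MeasuredFluxSet(
        records=[MeasuredRecord(m, parse(expr), v) for m, expr, v in rows]
    )


class TestMatching:
    def test_series_takes_minimum(self):
        res = match_predicted_to_measured(
            _flux({"r1": 3.0, "r2": 2.5}), _measured([("m", "r1 and r2", 2.0),
                                                      ("g", "r1", 3.0)])
        )
        assert res.predicted[0] == 2.5

    def test_parallel_sums(self):
        res = match_predicted_to_measured(
            _flux({"r1": 1.0, "r2": 2.0}), _measured([("m", "r1 or r2", 3.0),
                                                      ("g", "r1", 1.0)])
        )
        assert res.predicted[0] == 3.0

    def test_nested_rule(self):
        res = match_predicted_to_measured(
            _flux({"r1": 3.0, "r2": 2.0, "r3": 0.5}),
            _measured([("m", "(r1 and r2) or r3", 2.5), ("g", "r1", 3.0)]),
        )
        assert res.predicted[0] == 2.5

    def test_missing_reaction_fails_loudly(self):
        with pytest.raises(ValidationError, match="nope"):
            match_predicted_to_measured(
                _flux({"r1": 1.0, "r2": 1.0}),
                _measured([("bad", "r1 and nope", 1.0), ("g", "r2", 1.0)]),
            )

    def test_order_independent_correlation(self, composite_dc):
        template, _, bounds, measured = composite_dc
        flux = solve_eflux2(template, bounds)
        fwd = match_predicted_to_measured(flux, measured)
        rev = match_predicted_to_measured(
            flux, MeasuredFluxSet(records=list(reversed(measured.records)))
        )
        assert fwd.correlation == pytest.approx(rev.correlation, abs=1e-12)


class TestUncenteredPearson:
    @pytest.mark.parametrize(
        "x, y, r",
        [
            ((1, 2, 2), (1, 2, 2), 1.0),
            ((1, 0), (0, 1), 0.0),
            ((3, 4), (4, 3), 0.96),       # (12+12)/(5*5)
            ((1, 1), (-1, -1), -1.0),
        ],
    )
    def test_known_values(self, x, y, r):
        assert uncentered_pearson(x, y) == pytest.approx(r)

    def test_zero_vector_undefined(self):
        with pytest.raises(ValidationError, match="zero"):
            uncentered_pearson((0.0, 0.0), (1.0, 2.0))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="mismatch"):
            uncentered_pearson((1.0,), (1.0, 2.0))

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.floats(0.1, 10),
        st.floats(0.1, 10),
        st.sampled_from([-1.0, 1.0]),
        st.sampled_from([-1.0, 1.0]),
    )
    def test_scale_invariance_with_sign(self, xs, a, b, sa, sb):
        x = np.asarray(xs)
        y = x + 1.0  # correlated but distinct, nonzero
        r0 = uncentered_pearson(x + 2.0, y)
        r1 = uncentered_pearson(sa * a * (x + 2.0), sb * b * y)
        assert r1 == pytest.approx(sa * sb * r0, abs=1e-9)


class TestExpressionFluxCorrelation:
    def test_proportional_expression_gives_unity(self, composite_dc):
        template, rxnexp, _, _ = composite_dc
        measured = _measured([
            ("a", "RT1", -float(rxnexp.get("RT1"))),  # sign dropped via |.|
            ("b", "RU1", float(rxnexp.get("RU1"))),
            ("c", "RREV", float(rxnexp.get("RREV"))),
        ])
        r, excluded = expression_flux_correlation(rxnexp, measured)
        assert r == pytest.approx(1.0)
        assert excluded == 0

    def test_unavailable_records_excluded(self, composite_dc):
        template, rxnexp, _, _ = composite_dc
        measured = _measured([
            ("a", "RT1", 3.0),
            ("b", "RU1", 2.0),
            ("c", "EX_w", 1.0),  # no GPR -> no expression
        ])
        r, excluded = expression_flux_correlation(rxnexp, measured)
        assert excluded == 1

    def test_hand_computed_value(self, composite_dc):
        _, rxnexp, _, _ = composite_dc
        # g(RT1)=6, g(RU1 or RU2)=8; measured |v| = (3, 4)
        measured = _measured([("a", "RT1", 3.0), ("b", "RU1 or RU2", -4.0)])
        r, _ = expression_flux_correlation(rxnexp, measured)
        assert r == pytest.approx((6 * 3 + 8 * 4) / (10 * 5))


class TestNormalizeToMeasured:
    def test_rescales_to_measured_norm(self):
        res = match_predicted_to_measured(
            _flux({"r1": 2.0, "r2": 0.0}),
            _measured([("a", "r1", 3.0), ("b", "r2", 4.0)]),
        )
        assert np.allclose(normalize_to_measured(res), [5.0, 0.0])

    def test_correlation_unchanged(self, composite_dc):
        template, _, bounds, measured = composite_dc
        flux = solve_eflux2(template, bounds)
        res = match_predicted_to_measured(flux, measured)
        scaled = normalize_to_measured(res)
        assert uncentered_pearson(scaled, res.measured) == pytest.approx(
            res.correlation
        )


class TestCorrelationRange:
    def test_determined_network_gives_point_range(self, chain):
        model, profile, measured = chain
        template = build_template(model, "DC", carbon_source="EX_A")
        bounds = eflux_bounds(template, reaction_expression(template, profile))
        lo, hi = correlation_range(template, measured,
                                   lb=bounds.lower, ub=bounds.upper)
        assert lo == pytest.approx(hi, abs=1e-6)

    def test_matches_grid_oracle_on_branch(self, branch_dc):
        """The 1-DOF E-Flux face: extremes agree with dense enumeration."""
        template, _, bounds, measured = branch_dc
        lo, hi = correlation_range(template, measured,
                                   lb=bounds.lower, ub=bounds.upper)
        olo, ohi = oracle_correlation_range(
            template, bounds.lower, bounds.upper, template.objective, measured
        )
        assert lo == pytest.approx(olo, abs=1e-4)
        assert hi == pytest.approx(ohi, abs=1e-4)

    def test_matches_grid_oracle_with_and_mapping(self, composite_dc):
        template, _, bounds, measured = composite_dc
        lo, hi = correlation_range(template, measured,
                                   lb=bounds.lower, ub=bounds.upper)
        olo, ohi = oracle_correlation_range(
            template, bounds.lower, bounds.upper, template.objective, measured
        )
        assert lo == pytest.approx(olo, abs=1e-4)
        assert hi == pytest.approx(ohi, abs=1e-4)

    @pytest.mark.parametrize("fixture", ["branch_dc", "composite_dc"])
    def test_contains_eflux2_correlation(self, fixture, request):
        template, _, bounds, measured = request.getfixturevalue(fixture)
        lo, hi = correlation_range(template, measured,
                                   lb=bounds.lower, ub=bounds.upper)
        flux = solve_eflux2(template, bounds)
        c = match_predicted_to_measured(flux, measured).correlation
        assert lo - 1e-6 <= c <= hi + 1e-6


def test_read_measured_table(tmp_path):
    p = tmp_path / "measured.csv"
    p.write_text(
        "measured_id,mapping,value\nm1,r1 and r2,2.5\nm2,r3,-1.0\n"
    )
    ms = read_measured_table(p)
    assert len(ms) == 2
    assert ms.records[0].mapping == parse("r1 and r2")
    assert ms.values().tolist() == [2.5, -1.0]
    bad = tmp_path / "bad.csv"
    bad.write_text("a,b\n1,2\n")
    with pytest.raises(ValidationError, match="columns"):
        read_measured_table(bad)


def test_summarize_conditions():
    out = summarize_conditions([0.8, 0.9, 1.0])
    assert out["mean"] == pytest.approx(0.9)
    assert out["sd"] == pytest.approx(0.1)
    assert out["n"] == 3
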