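"""Concentration index: trapezoid oracle, bounds, symmetry, transfers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tcm_equity as te
from tcm_equity.exceptions import (
    ContractError,
    InsufficientDataError,
    UndefinedIndexError,
)


def trapezoid_ci(weight_shares, resource_shares):
    """Independent oracle: 1 minus twice the area under the concentration
    curve, integrated trapezoid by trapezoid in cumulative-share space."""
    x = np.concatenate([[0.0], np.cumsum(weight_shares)])
    y = np.concatenate([[0.0], np.cumsum(resource_shares)])
    area = sum(
        (x[i] - x[i - 1]) * (y[i] + y[i - 1]) / 2.0 for i in range(1, len(x))
    )
    return 1.0 - 2.0 * area


def shares(weights, resources):
    return te.ShareSeries(
        units=tuple(f"u{i}" for i in range(len(weights))),
        weight_shares=tuple(weights),
        resource_shares=tuple(resources),
    )


positive_vectors = st.integers(min_value=2, max_value=12).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(0.01, 100), min_size=n, max_size=n),
        st.lists(st.floats(0.01, 100), min_size=n, max_size=n),
    )
)


class TestConcentrationIndex:
    def test_two_unit_worked_example(self):
        # poor unit holds 30% of the resource with 50% of the population
        s = shares((0.5, 0.5), (0.3, 0.7))
        assert te.concentration_index(s) == pytest.approx(0.2, abs=1e-12)
        assert te.concentration_index(s) == pytest.approx(
            trapezoid_ci((0.5, 0.5), (0.3, 0.7)), abs=1e-12
        )

    def test_rank_reversal_negates(self):
        forward = te.concentration_index(shares((0.5, 0.5), (0.3, 0.7)))
        reverse = te.concentration_index(shares((0.5, 0.5), (0.7, 0.3)))
        assert reverse == pytest.approx(-forward, abs=1e-12)

    @given(positive_vectors)
    def test_matches_oracle_and_bounded(self, vecs):
        w, y = np.asarray(vecs[0]), np.asarray(vecs[1])
        w, y = w / w.sum(), y / y.sum()
        ci = te.concentration_index(shares(w, y))
        assert ci == pytest.approx(trapezoid_ci(w, y), abs=1e-9)
        assert -1.0 <= ci <= 1.0

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=10))
    def test_zero_when_resource_tracks_weight(self, raw):
        w = np.asarray(raw)
        w = w / w.sum()
        assert te.concentration_index(shares(w, w)) == pytest.approx(0, abs=1e-12)

    @given(positive_vectors, st.data())
    def test_transfer_to_richer_unit_never_decreases_ci(self, vecs, data):
        w, y = np.asarray(vecs[0]), np.asarray(vecs[1])
        w, y = w / w.sum(), y / y.sum()
        n = len(w)
        i = data.draw(st.integers(0, n - 2), label="poorer unit")
        j = data.draw(st.integers(i + 1, n - 1), label="richer unit")
        amount = data.draw(st.floats(0, float(y[i])), label="transfer")
        y2 = y.copy()
        y2[i] -= amount
        y2[j] += amount
        before = te.concentration_index(shares(w, y))
        after = te.concentration_index(shares(w, y2))
        assert after >= before - 1e-9

    def test_reversed_rank_values_violate_contract(self):
        s = te.ShareSeries(
            units=("a", "b"),
            weight_shares=(0.5, 0.5),
            resource_shares=(0.3, 0.7),
            rank_values=(2.0, 1.0),
        )
        with pytest.raises(ContractError, match="ascending"):
            te.concentration_index(s)

    def test_share_sums_validated(self):
        with pytest.raises(ContractError):
            shares((0.5, 0.4), (0.3, 0.7))


class TestRanking:
    def test_orders_by_per_capita_gdp_with_alphabetical_ties(self):
        def rec(name, gdp):
            return te.ProvinceYearRecord(
                province=name, region="Eastern", year=2016,
                population=100.0, area_km2=10.0, gdp=gdp,
                resources=dict.fromkeys(te.INDICATORS, 1),
            )

        ordered = te.rank_by_gdp_per_capita(
            [rec("Beijing", 200), rec("Tianjin", 100), rec("Hebei", 300)]
        )
        assert [r.province for r in ordered] == ["Tianjin", "Beijing", "Hebei"]
        tied = te.rank_by_gdp_per_capita([rec("Tianjin", 100), rec("Beijing", 100)])
        assert [r.province for r in tied] == ["Beijing", "Tianjin"]

    def test_matches_argsort_oracle(self, noisy_panel):
        year_records = [r for r in noisy_panel if r.year == 2016]
        ordered = te.rank_by_gdp_per_capita(year_records)
        keys = [(r.gdp / r.population, r.province) for r in year_records]
        expected = [year_records[i].province for i in np.lexsort(
            ([k[1] for k in keys], [k[0] for k in keys]))]
        assert [r.province for r in ordered] == expected

    def test_single_unit_insufficient(self, noisy_panel):
        with pytest.raises(InsufficientDataError):
            te.rank_by_gdp_per_capita(noisy_panel[:1])


class TestShareSeriesConstruction:
    def test_scale_invariance_of_ci(self, noisy_panel):
        year_records = [r for r in noisy_panel if r.year == 2018]
        base = te.concentration_index(te.share_series(year_records, "beds"))
        scaled_records = [
            te.ProvinceYearRecord(
                province=r.province, region=r.region, year=r.year,
                population=r.population, area_km2=r.area_km2, gdp=r.gdp,
                resources={k: 7 * v for k, v in r.resources.items()},
            )
            for r in year_records
        ]
        scaled = te.concentration_index(te.share_series(scaled_records, "beds"))
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_region_unit_mode_uses_four_units(self, noisy_panel):
        year_records = [r for r in noisy_panel if r.year == 2016]
        s = te.share_series(year_records, "beds", unit="region")
        assert len(s.units) == 4
        assert set(s.units) == set(te.REGION_ORDER)

    def test_zero_total_resource_undefined(self):
        records = [
            te.ProvinceYearRecord(
                province=p, region="Northeast", year=2016,
                population=10.0, area_km2=1.0, gdp=float(g),
                resources=dict.fromkeys(te.INDICATORS, 0),
            )
            for p, g in (("Jilin", 5), ("Liaoning", 9))
        ]
        with pytest.raises(UndefinedIndexError):
            te.share_series(records, "beds")
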