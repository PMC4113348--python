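"""Census I/O and tabulation into sufficient statistics."""

import numpy as np
import pandas as pd
import pytest

import orchidemog as od
from orchidemog.census import CensusParseError, CensusValidationError
from orchidemog.stages import ADULT_FATES, SEEDLING_FATES

from conftest import single_pop_params


def test_roundtrip_is_byte_identical(tiny_census_df, tmp_path):
    census = od.CensusTable(tiny_census_df)
    path = tmp_path / "census.csv"
    od.write_census(census, path)
    reread = od.read_census(path)
    assert len(reread) == 3
    path2 = tmp_path / "census2.csv"
    od.write_census(reread, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_dead_individuals_stay_dead(tiny_census_df):
    df = tiny_census_df.copy()
    df.loc[1, "stage"] = "D"  # dead at month 1, alive ("J") at month 2
    with pytest.raises(CensusValidationError, match="after dying"):
        od.CensusTable(df)


def test_parse_errors_carry_line_numbers(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("population,stream,month,individual,stage\n1,1,0,i1,S\n1,1,1,i1,XX\n")
    with pytest.raises(CensusParseError, match=":3"):
        od.read_census(p)
    p.write_text("wrong,header\n")
    with pytest.raises(CensusParseError, match="header"):
        od.read_census(p)


def test_duplicate_records_rejected(tiny_census_df):
    df = pd.concat([tiny_census_df, tiny_census_df.iloc[[0]]])
    with pytest.raises(CensusValidationError, match="duplicate"):
        od.CensusTable(df)


def _mk(records):
    return od.CensusTable(pd.DataFrame(
        records, columns=["population", "stream", "month", "individual", "stage"]
    ))


def test_single_adult_transition_counted_once():
    census = _mk([(1, 1, 0, "x", "A0"), (1, 1, 1, "x", "A1")])
    counts = od.tabulate_adult_transitions(census)
    i_a1 = ADULT_FATES.index("A1")
    assert counts.adult1[0, 0, 0, i_a1] == 1
    assert counts.adult1.sum() == 1
    assert counts.adult_missing == 0


def test_gap_transition_goes_to_gap_stratum_not_monthly():
    census = _mk([(1, 1, 3, "x", "A1"), (1, 1, 5, "x", "A2")])
    counts = od.tabulate_adult_transitions(census)
    assert counts.adult1.sum() == 0
    assert set(counts.adult_gaps) == {(0, 3, 2)}
    assert counts.adult_gaps[(0, 3, 2)][1, 2] == 1  # from A1 to A2


def test_disappearing_adult_is_missing_not_dead():
    census = _mk([(1, 1, 0, "x", "A0"), (1, 1, 1, "y", "A1"),
                  (1, 1, 0, "y", "A1")])
    counts = od.tabulate_adult_transitions(census)
    # x vanishes after month 0: right-censored; y's A1->A1 is counted
    assert counts.adult_missing == 1
    assert counts.adult1.sum() == 1


def test_adult_regression_to_young_rejected():
    census = _mk([(1, 1, 0, "x", "A0"), (1, 1, 1, "x", "J")])
    with pytest.raises(CensusValidationError, match="regressed"):
        od.tabulate_adult_transitions(census)


def test_young_13month_fates_and_recruits():
    records = [
        (1, 1, 0, "s1", "S"), (1, 1, 13, "s1", "A1"),   # S -> A1
        (1, 1, 0, "j1", "J"), (1, 1, 13, "j1", "J"),    # J -> J
        (1, 1, 13, "new", "J"),                          # new juvenile recruit
    ]
    census = _mk(records)
    counts = od.tabulate_young_transitions(census)
    assert counts.young_s[0, SEEDLING_FATES.index("A1")] == 1
    assert counts.young_j[0, 0] == 1
    assert counts.recruits == [(0, 0, 1, 0.0)]


def test_seedling_to_large_adult_excluded_with_tally():
    census = _mk([(1, 1, 0, "s1", "S"), (1, 1, 13, "s1", "A2")])
    counts = od.tabulate_young_transitions(census)
    assert counts.young_excluded == 1
    assert counts.young_s.sum() == 0


def test_short_census_raises():
    census = _mk([(1, 1, 0, "s1", "S"), (1, 1, 5, "s1", "S")])
    with pytest.raises(ValueError, match="span"):
        od.tabulate_young_transitions(census)


def test_fate_counts_sum_to_at_risk(study_counts):
    # every monthly stratum: fates partition the individuals at risk
    at_risk = study_counts.adult1.sum(axis=-1)
    assert (at_risk >= 0).all()
    tidy = study_counts.to_tidy()
    assert tidy["count"].sum() == (
        study_counts.adult1.sum()
        + sum(int(np.asarray(v).sum()) for v in study_counts.adult_gaps.values())
        + study_counts.young_s.sum() + study_counts.young_j.sum()
    )


def test_tabulated_frequencies_match_generating_rates():
    """Empirical monthly adult fates converge to (1-m)(1-r), ... at large n."""
    params = single_pop_params(n_months=15, m=0.05, r=0.4, s=0.3)
    initial = np.array([[0, 0, 300, 300, 300]])
    cfg = od.SimConfig(true_params=params, initial=initial, n_months=15, seed=5)
    counts = od.tabulate_adult_transitions(od.simulate_census(cfg))
    n = counts.adult1.sum(axis=(0, 1, 2))  # pooled over stages (rates identical)
    total = n.sum()
    assert total > 5000
    expected = od.adult_fate_probs(0.05, 0.4, 0.3)
    freq = n / total
    se = np.sqrt(expected * (1 - expected) / total)
    assert np.all(np.abs(freq - expected) < 3 * se + 1e-12)
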