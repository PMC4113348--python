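"""Census tables and their reduction to sufficient statistics.

The raw input is a long-format table of individual stage observations,
one row per (individual, month).  The hierarchical model never sees the
table itself: it consumes :class:`TransitionCounts`, the multinomial
counts of monthly adult fates (stratified by population, month and
starting stage), the 13-month fates of seedlings and juveniles, and the
per-interval recruit counts with their reproductive-adult exposure.

Survey gaps are first-class: a transition spanning ``g > 1`` months is
tabulated in its own stratum keyed by the gap length, and the likelihood
evaluates it with the ``g``-step product of monthly transition kernels.
Individuals that disappear while alive and never reappear are tallied as
missing, not dead.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stages import (
    ADULT_FATES,
    ADULT_INDEX,
    ADULT_STAGES,
    ALL_STAGES,
    JUVENILE_FATES,
    SEEDLING_FATES,
    is_adult,
    is_young,
)

__all__ = [
    "CensusTable",
    "TransitionCounts",
    "read_census",
    "write_census",
    "tabulate_adult_transitions",
    "tabulate_young_transitions",
    "tabulate",
]

CENSUS_COLUMNS = ("population", "stream", "month", "individual", "stage")

# weight of a large reproductive adult relative to a small one when
# accumulating fruit-production exposure (see params.RHO)
from .params import RHO


class CensusValidationError(ValueError):
    pass


class CensusParseError(ValueError):
    pass


@dataclass
class CensusTable:
    """Validated long-format census: one row per (individual, month)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self._validate()

    # -- properties --------------------------------------------------------
    @property
    def populations(self) -> np.ndarray:
        return np.sort(self.df["population"].unique())

    @property
    def n_populations(self) -> int:
        return int(self.df["population"].max())

    @property
    def stream_map(self) -> dict[int, int]:
        """population id (1-based) -> stream id (1 or 2), constant in time."""
        pairs = self.df[["population", "stream"]].drop_duplicates()
        return dict(zip(pairs["population"].astype(int), pairs["stream"].astype(int)))

    @property
    def max_month(self) -> int:
        return int(self.df["month"].max())

    def survey_months(self, population: int) -> np.ndarray:
        sub = self.df[self.df["population"] == population]
        return np.sort(sub["month"].unique())

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        df = self.df
        missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
        if missing:
            raise CensusValidationError(f"census missing columns {missing}")
        bad = ~df["stage"].isin(ALL_STAGES)
        if bad.any():
            raise CensusValidationError(
                f"unknown stage codes: {sorted(df.loc[bad, 'stage'].unique())}"
            )
        if (df["month"] < 0).any():
            raise CensusValidationError("month_index must be >= 0")
        dup = df.duplicated(subset=["individual", "month"])
        if dup.any():
            row = df[dup].iloc[0]
            raise CensusValidationError(
                f"duplicate record for individual {row['individual']!r} "
                f"at month {row['month']}"
            )
        # a population lives in exactly one stream
        streams = df.groupby("population")["stream"].nunique()
        if (streams > 1).any():
            k = int(streams[streams > 1].index[0])
            raise CensusValidationError(f"population {k} mapped to several streams")
        if not df["stream"].isin([1, 2]).all():
            raise CensusValidationError("stream ids must be 1 or 2")
        # death is absorbing: no live record after a D record
        sub = df[["individual", "month", "stage"]].sort_values(["individual", "month"])
        dead_at = sub[sub["stage"] == "D"].groupby("individual")["month"].min()
        if len(dead_at):
            live = sub[sub["stage"] != "D"]
            merged = live.merge(dead_at.rename("death_month"), on="individual")
            resurrected = merged[merged["month"] > merged["death_month"]]
            if len(resurrected):
                row = resurrected.iloc[0]
                raise CensusValidationError(
                    f"individual {row['individual']!r} recorded alive at month "
                    f"{row['month']} after dying at month {row['death_month']}"
                )

    def __len__(self) -> int:
        return len(self.df)


def read_census(path) -> CensusTable:
    """Read and validate a census CSV (columns population,stream,month,individual,stage)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CensusParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != list(CENSUS_COLUMNS):
            raise CensusParseError(
                f"{path}: header must be {','.join(CENSUS_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise CensusParseError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            pop_s, stream_s, month_s, indiv, stage = (v.strip() for v in row)
            try:
                pop, stream, month = int(pop_s), int(stream_s), int(month_s)
            except ValueError as exc:
                raise CensusParseError(f"{path}:{lineno}: {exc}") from None
            if stage not in ALL_STAGES:
                raise CensusParseError(
                    f"{path}:{lineno}: unknown stage code {stage!r}"
                )
            rows.append((pop, stream, month, indiv, stage))
    df = pd.DataFrame(rows, columns=CENSUS_COLUMNS)
    return CensusTable(df)


def write_census(census: CensusTable, path=None) -> str | None:
    """Write a census in canonical form (sorted by population, individual, month)."""
    df = census.df.sort_values(["population", "individual", "month"], kind="mergesort")
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    text = buf.getvalue()
    if path is None:
        return text
    with open(path, "w", newline="") as fh:
        fh.write(text)
    return None


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class TransitionCounts:
    """Multinomial/Poisson sufficient statistics of a census.

    ``adult1[k, j, i, fate]`` are one-month adult fate counts (0-based
    population ``k``, transition month ``j``, starting adult stage ``i`` in
    (A0, A1, A2), fate in (A0, A1, A2, D)).  ``adult_gaps`` holds strata
    whose transitions span ``g > 1`` months, keyed by ``(k, j, g)``.
    ``young_s[k]`` / ``young_j[k]`` are 13-month seedling / juvenile fate
    counts over :data:`SEEDLING_FATES` / :data:`JUVENILE_FATES`.
    ``recruits`` holds one row per (population, interval):
    ``(k, n_new_seedlings, n_new_juveniles, exposure)`` where exposure is
    the interval's accumulated small-adult-equivalent months.
    """

    n_populations: int
    n_transition_months: int
    stream_map: np.ndarray  # (K,), entries 0/1
    adult1: np.ndarray = None  # type: ignore[assignment]
    adult_gaps: dict = field(default_factory=dict)
    young_s: np.ndarray = None  # type: ignore[assignment]
    young_j: np.ndarray = None  # type: ignore[assignment]
    recruits: list = field(default_factory=list)
    adult_missing: int = 0
    young_missing: int = 0
    young_excluded: int = 0
    lag: int = 13

    def __post_init__(self) -> None:
        K, M = self.n_populations, self.n_transition_months
        if self.adult1 is None:
            self.adult1 = np.zeros((K, M, 3, 4), dtype=np.int64)
        if self.young_s is None:
            self.young_s = np.zeros((K, 5), dtype=np.int64)
        if self.young_j is None:
            self.young_j = np.zeros((K, 5), dtype=np.int64)
        self.stream_map = np.asarray(self.stream_map, dtype=int)

    @classmethod
    def empty(cls, n_populations: int, n_transition_months: int,
              stream_map=None) -> "TransitionCounts":
        if stream_map is None:
            stream_map = np.zeros(n_populations, dtype=int)
        return cls(n_populations, n_transition_months, stream_map)

    def validate(self) -> None:
        if (self.adult1 < 0).any() or (self.young_s < 0).any() or (self.young_j < 0).any():
            raise ValueError("negative counts")
        for (k, j, g), arr in self.adult_gaps.items():
            if g < 2 or (np.asarray(arr) < 0).any():
                raise ValueError(f"invalid gap stratum ({k}, {j}, {g})")
        for k, n_s, n_j, x in self.recruits:
            if n_s < 0 or n_j < 0 or x < 0:
                raise ValueError("invalid recruit row")

    def merge(self, other: "TransitionCounts") -> "TransitionCounts":
        """Combine adult and young statistics tabulated separately."""
        if (self.n_populations != other.n_populations
                or self.n_transition_months != other.n_transition_months):
            raise ValueError("cannot merge counts with different dimensions")
        out = TransitionCounts(
            self.n_populations, self.n_transition_months, self.stream_map,
            adult1=self.adult1 + other.adult1,
            young_s=self.young_s + other.young_s,
            young_j=self.young_j + other.young_j,
            adult_gaps={**self.adult_gaps},
            recruits=self.recruits + other.recruits,
            adult_missing=self.adult_missing + other.adult_missing,
            young_missing=self.young_missing + other.young_missing,
            young_excluded=self.young_excluded + other.young_excluded,
            lag=other.lag,
        )
        for key, arr in other.adult_gaps.items():
            out.adult_gaps[key] = out.adult_gaps.get(key, 0) + np.asarray(arr)
        return out

    # -- tidy export -------------------------------------------------------
    def to_tidy(self) -> pd.DataFrame:
        """Counts as a tidy frame: population, month, gap, from, to, count."""
        rows = []
        K, M = self.n_populations, self.n_transition_months
        for k in range(K):
            for j in range(M):
                for i, frm in enumerate(ADULT_STAGES):
                    for c, to in enumerate(ADULT_FATES):
                        n = int(self.adult1[k, j, i, c])
                        if n:
                            rows.append((k + 1, j, 1, frm, to, n))
        for (k, j, g), arr in sorted(self.adult_gaps.items()):
            for i, frm in enumerate(ADULT_STAGES):
                for c, to in enumerate(ADULT_FATES):
                    n = int(arr[i, c])
                    if n:
                        rows.append((k + 1, j, g, frm, to, n))
        for k in range(K):
            for c, to in enumerate(SEEDLING_FATES):
                n = int(self.young_s[k, c])
                if n:
                    rows.append((k + 1, -1, self.lag, "S", to, n))
            for c, to in enumerate(JUVENILE_FATES):
                n = int(self.young_j[k, c])
                if n:
                    rows.append((k + 1, -1, self.lag, "J", to, n))
        return pd.DataFrame(
            rows, columns=["population", "month", "gap", "from", "to", "count"]
        )


def _stream_array(census: CensusTable) -> tuple[int, np.ndarray]:
    K = census.n_populations
    smap = np.zeros(K, dtype=int)
    for pop, stream in census.stream_map.items():
        smap[pop - 1] = stream - 1
    return K, smap


def tabulate_adult_transitions(census: CensusTable) -> TransitionCounts:
    """Count monthly adult fates; gap-g transitions go to their own strata."""
    K, smap = _stream_array(census)
    M = census.max_month
    counts = TransitionCounts.empty(K, M, smap)
    last_survey = {int(pop): int(census.survey_months(pop)[-1])
                   for pop in census.populations}
    df = census.df.sort_values(["individual", "month"], kind="mergesort")
    months = df["month"].to_numpy()
    stage = df["stage"].to_numpy()
    pops = df["population"].to_numpy()
    indiv = df["individual"].to_numpy()
    fate_index = {c: i for i, c in enumerate(ADULT_FATES)}
    for start in range(len(df) - 1):
        if indiv[start] != indiv[start + 1]:
            # final record of an individual: an adult vanishing while the
            # study continues is observed-missing (right-censored, not dead);
            # one observed at the last survey is simply end-of-study
            if is_adult(stage[start]) and months[start] < last_survey[int(pops[start])]:
                counts.adult_missing += 1
            continue
        frm = stage[start]
        if not is_adult(frm):
            continue
        g = int(months[start + 1] - months[start])
        to = stage[start + 1]
        if is_young(to):
            raise CensusValidationError(
                f"individual {indiv[start]!r} regressed from {frm} to {to} "
                f"at month {months[start + 1]}"
            )
        k = int(pops[start]) - 1
        i, c = ADULT_INDEX[frm], fate_index[to]
        if g == 1:
            counts.adult1[k, int(months[start]), i, c] += 1
        else:
            key = (k, int(months[start]), g)
            if key not in counts.adult_gaps:
                counts.adult_gaps[key] = np.zeros((3, 4), dtype=np.int64)
            counts.adult_gaps[key][i, c] += 1
    # the final row is always some individual's terminal record
    if (len(df) and is_adult(stage[-1])
            and months[-1] < last_survey[int(pops[-1])]):
        counts.adult_missing += 1
    return counts


def _young_intervals(survey: np.ndarray, lag: int) -> list[tuple[int, int]]:
    """Non-overlapping ~lag-month intervals anchored on surveyed months."""
    intervals = []
    t0 = int(survey[0])
    while True:
        later = survey[survey >= t0 + lag]
        if len(later) == 0:
            break
        t1 = int(later[0])
        intervals.append((t0, t1))
        t0 = t1
    return intervals


def tabulate_young_transitions(census: CensusTable, lag: int = 13) -> TransitionCounts:
    """13-month seedling/juvenile fates, recruit counts and adult exposure."""
    if census.max_month < lag:
        raise ValueError(
            f"census spans {census.max_month} months; need at least lag={lag}"
        )
    K, smap = _stream_array(census)
    counts = TransitionCounts.empty(K, census.max_month, smap)
    counts.lag = lag
    s_fate = {c: i for i, c in enumerate(SEEDLING_FATES)}
    j_fate = {c: i for i, c in enumerate(JUVENILE_FATES)}
    df = census.df
    first_seen = df.groupby("individual")["month"].min()
    for pop in census.populations:
        k = int(pop) - 1
        sub = df[df["population"] == pop]
        survey = np.sort(sub["month"].unique())
        by_month = {int(t): g.set_index("individual")["stage"]
                    for t, g in sub.groupby("month")}
        death_month = (
            sub[sub["stage"] == "D"].groupby("individual")["month"].min().to_dict()
        )
        for t0, t1 in _young_intervals(survey, lag):
            window = survey[(survey >= t0) & (survey < t1)]
            # fruit-production exposure: A1-equivalent months on survey dates,
            # scaled to the nominal interval length
            x_obs = 0.0
            for t in window:
                roster = by_month[int(t)]
                x_obs += (roster == "A1").sum() + RHO * (roster == "A2").sum()
            exposure = x_obs * lag / len(window) if len(window) else 0.0
            start_roster = by_month[t0]
            end_roster = by_month.get(t1, pd.Series(dtype=object))
            n_s = n_j = 0
            for ind, st in start_roster.items():
                if not is_young(st):
                    continue
                if ind in end_roster.index:
                    fate = end_roster[ind]
                elif ind in death_month and t0 < death_month[ind] <= t1:
                    fate = "D"
                else:
                    counts.young_missing += 1
                    continue
                if st == "S":
                    if fate == "A2":
                        # seedlings lack the time to reach A2 in 13 months;
                        # excluded with a tally rather than crashing
                        counts.young_excluded += 1
                        continue
                    counts.young_s[k, s_fate[fate]] += 1
                else:
                    if fate == "S":
                        raise CensusValidationError(
                            f"individual {ind!r} regressed from J to S"
                        )
                    counts.young_j[k, j_fate[fate]] += 1
            # recruits: first-ever appearance inside the interval as S or J
            appearing = sub[(sub["month"] > t0) & (sub["month"] <= t1)]
            for ind, grp in appearing.groupby("individual"):
                if first_seen[ind] <= t0 or first_seen[ind] > t1:
                    continue
                st = grp.sort_values("month")["stage"].iloc[0]
                if st == "S":
                    n_s += 1
                elif st == "J":
                    n_j += 1
            counts.recruits.append((k, n_s, n_j, float(exposure)))
    return counts


def tabulate(census: CensusTable, lag: int = 13) -> TransitionCounts:
    """Full sufficient statistics: adult + young + recruit parts."""
    return tabulate_adult_transitions(census).merge(
        tabulate_young_transitions(census, lag=lag)
    )
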