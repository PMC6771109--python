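"""Indirect age standardisation and period-method survival table assembly.

Expected incidence counts apply national age-specific rates to each area's
population (internal standardisation, so the national ratio is exactly 1).
Survival tables accrue person-time within a fixed calendar window, split by
follow-up year since diagnosis, and attach expected other-cause deaths from
background mortality rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceData",
    "SurvivalTable",
    "expected_cases",
    "AGE_GROUPS",
    "age_group",
    "build_strata",
    "stratum_levels",
    "period_person_time",
    "attach_expected_deaths",
]


@dataclass
class IncidenceData:
    """Per-area observed and expected case counts for one indicator."""

    area_ids: list
    y: np.ndarray
    E: np.ndarray
    sex: str = "persons"
    cancer: str = "all"
    excluded_areas: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.E = np.asarray(self.E, dtype=float)
        if len(self.area_ids) != len(self.y) or len(self.y) != len(self.E):
            raise ValueError("area_ids, y and E must have equal length")
        if np.any(self.y < 0):
            raise ValueError("observed counts must be non-negative")
        if np.any(self.E <= 0):
            raise ValueError(
                "expected counts must be strictly positive for modelled areas"
            )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"area": self.area_ids, "observed": self.y, "expected": self.E})


def _pivot(df: pd.DataFrame, age_bands) -> pd.DataFrame:
    g = df.groupby(["area", "age_band"], observed=True)["count"].sum().unstack(fill_value=0)
    if age_bands is not None:
        g = g.reindex(columns=list(age_bands), fill_value=0)
    return g


def expected_cases(
    cases, population, *, area_ids=None, age_bands=None, sex="persons", cancer="all"
) -> IncidenceData:
    """Expected counts by indirect standardisation with internal national rates.

    ``cases`` and ``population`` are either area x age matrices (rows in the
    order of ``area_ids``) or long data frames with columns
    ``area, age_band, count``.  National age-specific rates are
    r_a = sum_i y_ia / sum_i n_ia and E_i = sum_a n_ia r_a, which makes
    sum(E) equal sum(y) exactly.  Areas with E = 0 are dropped and reported
    on ``excluded_areas``.
    """
    if isinstance(cases, pd.DataFrame):
        cmat = _pivot(cases, age_bands)
        pmat = _pivot(population, age_bands)
        pmat = pmat.reindex(index=cmat.index.union(pmat.index), fill_value=0)
        cmat = cmat.reindex(index=pmat.index, columns=pmat.columns, fill_value=0)
        ids = list(pmat.index)
        y_ia = cmat.to_numpy(dtype=float)
        n_ia = pmat.to_numpy(dtype=float)
    else:
        y_ia = np.atleast_2d(np.asarray(cases, dtype=float))
        n_ia = np.atleast_2d(np.asarray(population, dtype=float))
        if y_ia.shape != n_ia.shape:
            raise ValueError("case and population matrices must share a shape")
        ids = list(area_ids) if area_ids is not None else [f"A{i}" for i in range(len(y_ia))]
    if np.any(n_ia < 0):
        raise ValueError("populations must be non-negative")
    nat_cases = y_ia.sum(axis=0)
    nat_pop = n_ia.sum(axis=0)
    bad = (nat_pop == 0) & (nat_cases > 0)
    if np.any(bad):
        raise ValueError(
            f"age band(s) {np.flatnonzero(bad).tolist()} have cases but zero national population"
        )
    rates = np.divide(nat_cases, nat_pop, out=np.zeros_like(nat_cases), where=nat_pop > 0)
    E = n_ia @ rates
    y = y_ia.sum(axis=1)
    keep = E > 0
    excluded = [ids[i] for i in np.flatnonzero(~keep)]
    return IncidenceData(
        [ids[i] for i in np.flatnonzero(keep)],
        y[keep],
        E[keep],
        sex=sex,
        cancer=cancer,
        excluded_areas=excluded,
    )


# broad age groups chosen for roughly equal case numbers; the printed upper
# boundary of the third group overlaps the fourth, resolved closed-left
AGE_GROUPS = ((15, 54), (55, 64), (65, 74), (75, 89))


def age_group(age) -> int:
    """Index of the broad survival age group for an age at diagnosis."""
    age = float(age)
    if not 15 <= age <= 89:
        raise ValueError(f"age {age} outside the modelled range [15, 89]")
    for k, (lo, hi) in enumerate(AGE_GROUPS):
        if age < hi + 1:
            return k
    return len(AGE_GROUPS) - 1  # pragma: no cover


def stratum_levels(persons_model: bool = False, sites: Sequence | None = None) -> list[str]:
    """Ordered stratum labels: broad age groups, crossed with sex for the
    all-persons model and with site for aggregate cancer groupings."""
    levels = [f"age{lo}-{hi}" for lo, hi in AGE_GROUPS]
    if persons_model:
        levels = [f"{a}|{s}" for a in levels for s in ("M", "F")]
    if sites:
        levels = [f"{a}|{site}" for a in levels for site in sites]
    return levels


def build_strata(
    age_at_diagnosis,
    sex: str | None = None,
    cancer_site: str | None = None,
    persons_model: bool = False,
    sites: Sequence | None = None,
) -> str:
    """Stratum label for one patient under the chosen model layout."""
    label = "age{}-{}".format(*AGE_GROUPS[age_group(age_at_diagnosis)])
    if persons_model:
        if sex not in ("M", "F"):
            raise ValueError("the all-persons model requires sex 'M' or 'F'")
        label = f"{label}|{sex}"
    if sites:
        if cancer_site not in sites:
            raise ValueError(f"unknown cancer site {cancer_site!r}")
        label = f"{label}|{cancer_site}"
    return label


class SurvivalTable:
    """Cells (area x stratum x follow-up year) of deaths, person-time and
    expected other-cause deaths, plus optional calendar-year slices used to
    attach background mortality."""

    MAX_FOLLOWUP = 5

    def __init__(self, cells: pd.DataFrame, strata: list | None = None, slices=None):
        required = {"area", "stratum", "followup_year", "deaths", "person_time", "expected_deaths"}
        missing = required - set(cells.columns)
        if missing:
            raise ValueError(f"cells missing columns: {sorted(missing)}")
        t = cells["followup_year"]
        if ((t < 1) | (t > self.MAX_FOLLOWUP)).any():
            raise ValueError("follow-up years must lie in 1..5")
        if (cells["deaths"] < 0).any() or (cells["person_time"] < 0).any():
            raise ValueError("negative deaths or person-time")
        zero_pt = cells["person_time"] == 0
        if (cells.loc[zero_pt, "deaths"] != 0).any():
            raise ValueError("cells with zero person-time cannot contain deaths")
        self.cells = cells.reset_index(drop=True)
        self.strata = strata if strata is not None else sorted(cells["stratum"].unique())
        self.slices = slices

    @property
    def area_ids(self) -> list:
        return list(dict.fromkeys(self.cells["area"]))

    def design(self, area_ids: Sequence | None = None):
        """(i_idx, k_idx, t_idx, d, y, dstar) arrays for the sampler."""
        ids = list(area_ids) if area_ids is not None else self.area_ids
        amap = {a: i for i, a in enumerate(ids)}
        kmap = {s: k for k, s in enumerate(self.strata)}
        c = self.cells
        return (
            c["area"].map(amap).to_numpy(dtype=int),
            c["stratum"].map(kmap).to_numpy(dtype=int),
            c["followup_year"].to_numpy(dtype=int) - 1,
            c["deaths"].to_numpy(dtype=float),
            c["person_time"].to_numpy(dtype=float),
            c["expected_deaths"].to_numpy(dtype=float),
        )

    def indicator_matrix(self) -> np.ndarray:
        """Rows x strata one-hot matrix; mutually exclusive and exhaustive."""
        kmap = {s: k for k, s in enumerate(self.strata)}
        X = np.zeros((len(self.cells), len(self.strata)))
        X[np.arange(len(self.cells)), self.cells["stratum"].map(kmap)] = 1.0
        return X


def _yearly_slices(lo: float, hi: float):
    """Split [lo, hi) into (calendar_year, duration) pieces."""
    out = []
    t = lo
    while t < hi:
        nxt = min(hi, float(np.floor(t) + 1.0))
        out.append((int(np.floor(t)), nxt - t))
        t = nxt
    return out


def period_person_time(
    patients: pd.DataFrame,
    window=(2006.0, 2015.0),
    *,
    area_ids: Sequence | None = None,
    strata: Sequence | None = None,
    min_diagnosis: float = 2001.0,
) -> SurvivalTable:
    """Period-method person-time: each patient contributes to follow-up year t
    only the overlap of (diag + t - 1, diag + t] with the calendar window,
    truncated at death or censoring.

    ``patients`` columns: area, stratum, diag_time, end_time, event (1 =
    death).  Dates are continuous years; the window is half-open
    [start, end).  Deaths are counted in the cell where the death falls
    inside the window.
    """
    w0, w1 = float(window[0]), float(window[1])
    if not w1 > w0:
        raise ValueError("empty period window")
    diag = patients["diag_time"].to_numpy(dtype=float)
    end = patients["end_time"].to_numpy(dtype=float)
    event = patients["event"].to_numpy()
    if np.any(end < diag):
        raise ValueError("death or censoring before diagnosis")
    if np.any(diag < min_diagnosis):
        raise ValueError(f"diagnoses before {min_diagnosis} are outside the eligible cohort")

    ids = list(area_ids) if area_ids is not None else sorted(patients["area"].unique())
    strat = list(strata) if strata is not None else sorted(patients["stratum"].unique())
    cell_pt: dict[tuple, float] = {}
    cell_deaths: dict[tuple, int] = {}
    slice_pt: dict[tuple, float] = {}
    areas = patients["area"].to_numpy()
    strata_col = patients["stratum"].to_numpy()
    for p in range(len(patients)):
        for t in range(1, SurvivalTable.MAX_FOLLOWUP + 1):
            start = diag[p] + t - 1
            stop = min(diag[p] + t, end[p])
            lo = max(start, w0)
            hi = min(stop, w1)
            key = (areas[p], strata_col[p], t)
            if hi > lo:
                cell_pt[key] = cell_pt.get(key, 0.0) + (hi - lo)
                for year, dur in _yearly_slices(lo, hi):
                    skey = key + (year,)
                    slice_pt[skey] = slice_pt.get(skey, 0.0) + dur
            if (
                event[p]
                and start < end[p] <= diag[p] + t
                and w0 <= end[p] < w1
            ):
                cell_deaths[key] = cell_deaths.get(key, 0) + 1

    rows = []
    for a in ids:
        for s in strat:
            for t in range(1, SurvivalTable.MAX_FOLLOWUP + 1):
                key = (a, s, t)
                rows.append(
                    (a, s, t, cell_deaths.get(key, 0), cell_pt.get(key, 0.0), 0.0)
                )
    cells = pd.DataFrame(
        rows,
        columns=["area", "stratum", "followup_year", "deaths", "person_time", "expected_deaths"],
    )
    slices = pd.DataFrame(
        [(a, s, t, yr, pt) for (a, s, t, yr), pt in slice_pt.items()],
        columns=["area", "stratum", "followup_year", "cal_year", "person_time"],
    )
    return SurvivalTable(cells, strata=strat, slices=slices)


def _rate_lookup(rates) -> Callable[[str, int], float]:
    if np.isscalar(rates):
        return lambda stratum, year: float(rates)
    if callable(rates):
        return rates
    if isinstance(rates, Mapping):
        def look(stratum, year):
            for key in ((stratum, year), stratum, year):
                if key in rates:
                    return float(rates[key])
            raise KeyError(f"no background rate for stratum={stratum!r}, year={year}")
        return look
    raise TypeError("rates must be a scalar, mapping or callable")


def attach_expected_deaths(table: SurvivalTable, rates) -> SurvivalTable:
    """Fill d* for each cell as the sum of rate x time over its calendar-year
    person-time slices.

    ``rates`` may be a scalar, a mapping keyed by stratum, year or
    (stratum, year), or a callable ``(stratum, year) -> rate``.
    """
    if table.slices is None:
        raise ValueError("table has no person-time slices; build it with period_person_time")
    look = _rate_lookup(rates)
    dstar: dict[tuple, float] = {}
    for row in table.slices.itertuples(index=False):
        key = (row.area, row.stratum, row.followup_year)
        dstar[key] = dstar.get(key, 0.0) + look(row.stratum, row.cal_year) * row.person_time
    cells = table.cells.copy()
    cells["expected_deaths"] = [
        dstar.get((r.area, r.stratum, r.followup_year), 0.0)
        for r in cells.itertuples(index=False)
    ]
    return SurvivalTable(cells, strata=table.strata, slices=table.slices)
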