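"""Synthetic registry inputs with known ground truth.

The real inputs (cancer registry case records, official population tables,
death registrations) are restricted, so every downstream stage is exercised
on data generated here: a lattice geography with a few islands,
age-structured populations, Poisson counts driven by a known spatial field,
and a period-method survival cohort with known excess hazards and known
background mortality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .spatial_structure import AreaGraph, repair_islands

__all__ = [
    "SyntheticConfig",
    "ExclusionFixture",
    "AreaRecord",
    "generate_lattice_geography",
    "simulate_leroux_field",
    "simulate_incidence_counts",
    "simulate_survival_cohort",
    "generate_exclusion_fixture",
    "generate_population_table",
    "generate_case_table",
    "write_synthetic_inputs",
    "DEFAULT_AGE_BANDS",
]

# 5-year bands to 85+, the resolution official population tables come in
DEFAULT_AGE_BANDS = tuple(
    [f"{a}-{a + 4}" for a in range(0, 85, 5)] + ["85+"]
)


def _default_rates() -> dict[str, float]:
    # cases per person-year, rising steeply with age
    return {
        band: 2e-5 * (1.45 ** k) for k, band in enumerate(DEFAULT_AGE_BANDS)
    }


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic registry; defaults run full MCMC in minutes."""

    grid_rows: int = 20
    grid_cols: int = 20
    n_islands: int = 2
    rho_true: float = 0.8
    sigma2_true: float = 0.2
    beta0_true: float = 0.0
    age_bands: tuple = DEFAULT_AGE_BANDS
    baseline_rates: dict = field(default_factory=_default_rates)
    pop_range: tuple = (500, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_islands < 0:
            raise ValueError("n_islands must be >= 0")
        if not 0.0 <= self.rho_true <= 1.0:
            raise ValueError("rho_true must lie in [0, 1]")
        if self.sigma2_true <= 0:
            raise ValueError("sigma2_true must be positive")
        if any(r <= 0 for r in self.baseline_rates.values()):
            raise ValueError("all baseline rates must be positive")
        if self.pop_range[0] < 5:
            raise ValueError("minimum population must be >= 5 residents")

    @property
    def n_areas(self) -> int:
        return self.grid_rows * self.grid_cols + self.n_islands


@dataclass
class AreaRecord:
    area_id: str
    flag: str | None = None


@dataclass
class ExclusionFixture:
    """A registry of area records carrying mutually exclusive exclusion flags."""

    records: list[AreaRecord]

    @property
    def total(self) -> int:
        return len(self.records)

    def flag_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            if rec.flag is not None:
                counts[rec.flag] = counts.get(rec.flag, 0) + 1
        return counts


EXCLUSION_FLAGS = ("no_population", "no_location", "under_5_residents", "remote_island")


def generate_exclusion_fixture(total: int, flag_counts: dict) -> ExclusionFixture:
    """Registry of ``total`` records with exactly the requested flags.

    Flags are mutually exclusive per record; their counts must not exceed
    ``total``.
    """
    n_flagged = sum(flag_counts.values())
    if any(v < 0 for v in flag_counts.values()):
        raise ValueError("flag counts must be non-negative")
    if n_flagged > total:
        raise ValueError(f"flag counts sum to {n_flagged} > total {total}")
    records = []
    i = 0
    for flag, count in flag_counts.items():
        for _ in range(count):
            records.append(AreaRecord(f"A{i:04d}", flag))
            i += 1
    while i < total:
        records.append(AreaRecord(f"A{i:04d}", None))
        i += 1
    return ExclusionFixture(records)


def generate_lattice_geography(config: SyntheticConfig) -> AreaGraph:
    """Rook-adjacency lattice plus isolated island nodes.

    Centroids sit on the integer grid; islands are offset to the right of
    the lattice so the nearest mainland area is well defined.
    """
    rows, cols = config.grid_rows, config.grid_cols
    n_lat = rows * cols
    ids = [f"G{r:03d}_{c:03d}" for r in range(rows) for c in range(cols)]
    ids += [f"ISL{k}" for k in range(config.n_islands)]
    n = len(ids)
    W = np.zeros((n, n))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                W[i, i + 1] = W[i + 1, i] = 1.0
            if r + 1 < rows:
                W[i, i + cols] = W[i + cols, i] = 1.0
    cents = np.zeros((n, 2))
    for r in range(rows):
        for c in range(cols):
            cents[r * cols + c] = (c, r)
    for k in range(config.n_islands):
        cents[n_lat + k] = (cols + 2.0 + 3.0 * k, rows / 2.0 + k)
    return AreaGraph(ids, W, cents)


def simulate_leroux_field(
    graph: AreaGraph, rho: float, sigma2: float, seed
) -> np.ndarray:
    """One exact draw of the zero-mean field with precision [rho(D-W)+(1-rho)I]/sigma2.

    Sampling is by Cholesky of the precision matrix: with Q = L L', solving
    L' x = z for z ~ N(0, I) gives x ~ N(0, Q^{-1}) exactly.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if rho == 1.0:
        raise ValueError(
            "rho = 1 makes the joint precision rank-deficient (D - W is singular); "
            "use rho < 1"
        )
    rng = np.random.default_rng(seed)
    W = graph.W
    D = np.diag(graph.neighbour_counts)
    Q = (rho * (D - W) + (1.0 - rho) * np.eye(graph.n_areas)) / sigma2
    try:
        L = np.linalg.cholesky(Q)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rho<1 keeps Q PD
        raise ValueError("precision matrix is not positive definite") from exc
    z = rng.standard_normal(graph.n_areas)
    return sla.solve_triangular(L.T, z, lower=False)


def simulate_leroux_draws(
    graph: AreaGraph, rho: float, sigma2: float, n_draws: int, seed
) -> np.ndarray:
    """Matrix of independent field draws (n_draws x n_areas); moment tests."""
    if rho == 1.0:
        raise ValueError("rho = 1 makes the joint precision rank-deficient")
    rng = np.random.default_rng(seed)
    W = graph.W
    D = np.diag(graph.neighbour_counts)
    Q = (rho * (D - W) + (1.0 - rho) * np.eye(graph.n_areas)) / sigma2
    L = np.linalg.cholesky(Q)
    z = rng.standard_normal((graph.n_areas, n_draws))
    return sla.solve_triangular(L.T, z, lower=False).T


def simulate_incidence_counts(E, beta0: float, S, seed) -> np.ndarray:
    """Poisson counts y_i ~ Poisson(E_i * exp(beta0 + S_i))."""
    E = np.asarray(E, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected counts must be strictly positive")
    rng = np.random.default_rng(seed)
    return rng.poisson(E * np.exp(beta0 + S))


def generate_population_table(config: SyntheticConfig, graph: AreaGraph) -> pd.DataFrame:
    """Area x sex x age-band resident counts, uniform totals in pop_range."""
    rng = np.random.default_rng(config.seed)
    bands = list(config.age_bands)
    # fixed age pyramid shared across areas, mildly declining with age
    weights = np.linspace(1.5, 0.5, len(bands))
    weights /= weights.sum()
    rows = []
    for aid in graph.area_ids:
        for sex in ("M", "F"):
            total = rng.integers(config.pop_range[0], config.pop_range[1] + 1)
            counts = rng.multinomial(total, weights)
            for band, cnt in zip(bands, counts):
                rows.append((aid, sex, band, int(cnt)))
    return pd.DataFrame(rows, columns=["area", "sex", "age_band", "count"])


def generate_case_table(
    config: SyntheticConfig,
    population: pd.DataFrame,
    S: np.ndarray,
    graph: AreaGraph,
    years: float = 5.0,
) -> pd.DataFrame:
    """Case counts per area x sex x age band from the known spatial field.

    Counts are Poisson with mean n * rate * years * exp(beta0 + S_i), so the
    standardisation + model chain can recover the generating field.
    """
    rng = np.random.default_rng(config.seed + 1)
    idx = {a: i for i, a in enumerate(graph.area_ids)}
    pop = population.copy()
    lam = (
        pop["count"].to_numpy(float)
        * pop["age_band"].map(config.baseline_rates).to_numpy(float)
        * years
        * np.exp(config.beta0_true + S[[idx[a] for a in pop["area"]]])
    )
    pop["count"] = rng.poisson(lam)
    return pop.rename(columns={"count": "count"})


@dataclass
class StrataDesign:
    """Stratum labels and the true generating coefficients of the cohort."""

    labels: tuple = ("age15-54", "age55-64", "age65-74", "age75-89")
    alpha_true: tuple = (-2.0, -2.5, -3.0, -3.3, -3.5)  # log excess hazard per year
    beta_true: tuple | None = None  # per-stratum shift; zeros if None
    patients_per_area: int = 40

    def __post_init__(self) -> None:
        if len(self.alpha_true) != 5:
            raise ValueError("five follow-up-year intercepts required")
        if self.beta_true is None:
            self.beta_true = tuple(0.0 for _ in self.labels)
        if len(self.beta_true) != len(self.labels):
            raise ValueError("one beta per stratum required")


def simulate_survival_cohort(
    graph: AreaGraph,
    strata_design: StrataDesign,
    S_true,
    background_rates,
    period_window=(2006.0, 2015.0),
    seed=0,
):
    """Period-method survival table with known excess-hazard truth.

    Patients are diagnosed uniformly over [window_start - 5, window_end) and
    followed while alive; person-time accrues only inside the period window.
    Cell deaths are drawn Poisson with mean d* + y * exp(alpha_t + beta_k + S_i)
    where d* = background_rate * y.  Returns ``(table, truth)``.
    """
    from .standardisation import SurvivalTable, period_person_time

    w0, w1 = float(period_window[0]), float(period_window[1])
    if not w1 > w0:
        raise ValueError("period window must be a non-empty year range")
    rates = np.asarray(
        [background_rates] * len(strata_design.labels)
        if np.isscalar(background_rates)
        else background_rates,
        dtype=float,
    )
    if np.any(rates <= 0):
        raise ValueError("background rates must be positive")
    rng = np.random.default_rng(seed)
    S_true = np.asarray(S_true, dtype=float)

    rows = []
    for aid in graph.area_ids:
        for k, lab in enumerate(strata_design.labels):
            diag = rng.uniform(w0 - 5.0, w1, size=strata_design.patients_per_area)
            for d in diag:
                rows.append((aid, lab, d, w1, 0))
    patients = pd.DataFrame(
        rows, columns=["area", "stratum", "diag_time", "end_time", "event"]
    )
    table = period_person_time(
        patients,
        window=(w0, w1),
        area_ids=list(graph.area_ids),
        strata=list(strata_design.labels),
    )
    cells = table.cells
    k_idx = cells["stratum"].map(
        {lab: k for k, lab in enumerate(strata_design.labels)}
    ).to_numpy()
    i_idx = cells["area"].map(
        {a: i for i, a in enumerate(graph.area_ids)}
    ).to_numpy()
    t_idx = cells["followup_year"].to_numpy() - 1
    y = cells["person_time"].to_numpy(float)
    dstar = rates[k_idx] * y
    lp = (
        np.asarray(strata_design.alpha_true)[t_idx]
        + np.asarray(strata_design.beta_true)[k_idx]
        + S_true[i_idx]
    )
    mu = dstar + y * np.exp(lp)
    deaths = rng.poisson(mu)
    cells = cells.assign(deaths=deaths, expected_deaths=dstar)
    truth = {
        "alpha": list(strata_design.alpha_true),
        "beta": list(strata_design.beta_true),
        "S": S_true.tolist(),
        "background_rates": rates.tolist(),
    }
    return SurvivalTable(cells, strata=list(strata_design.labels)), truth


def write_synthetic_inputs(config: SyntheticConfig, out_dir) -> dict:
    """Generate the full synthetic registry and write it as plain-text files.

    Produces areas.csv, edges.csv, population.csv, cases.csv, survival.csv
    and truth.json; returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = generate_lattice_geography(config)
    repaired = repair_islands(graph)
    S = simulate_leroux_field(
        repaired, config.rho_true, config.sigma2_true, seed=config.seed + 10
    )
    pop = generate_population_table(config, graph)
    cases = generate_case_table(config, pop, S, graph)
    design = StrataDesign()
    table, truth = simulate_survival_cohort(
        repaired, design, S, background_rates=0.02, seed=config.seed + 20
    )

    areas = pd.DataFrame(
        {
            "id": graph.area_ids,
            "centroid_x": graph.centroids[:, 0],
            "centroid_y": graph.centroids[:, 1],
            "flag": "",
        }
    )
    paths = {
        "areas": out / "areas.csv",
        "edges": out / "edges.csv",
        "population": out / "population.csv",
        "cases": out / "cases.csv",
        "survival": out / "survival.csv",
        "truth": out / "truth.json",
    }
    areas.to_csv(paths["areas"], index=False)
    graph.write_edges_csv(paths["edges"])
    pop.to_csv(paths["population"], index=False)
    cases.to_csv(paths["cases"], index=False)
    table.cells.to_csv(paths["survival"], index=False)
    truth_all = {
        "rho": config.rho_true,
        "sigma2": config.sigma2_true,
        "beta0": config.beta0_true,
        "S": S.tolist(),
        **truth,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_all, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
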