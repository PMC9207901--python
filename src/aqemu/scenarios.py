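"""Full-factorial scenario scans, sensitivity curves and target attainment.

The scan lattice covers the five sector scalings at 8 levels
{0.0, 0.2, ..., 1.4} — 8⁵ = 32,768 configurations. A populated grid holds
the national and regional population-weighted exposures (and optionally
the national mortality burden) per scenario; attainment reports enumerate
the scenarios whose scoped exposure meets a concentration target and
summarize the mean per-sector emission reduction over that set.

``evaluate_grid`` accepts either a fitted :class:`~aqemu.emulation.EmulatorSet`
or the synthetic :class:`~aqemu.synthetic.SurrogateSimulator` itself as the
field evaluator — the latter is the brute-force oracle path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import health
from .emulation import EmulatorSet
from .evaluation import TuningFactors, apply_tuning
from .metrics import population_weighted
from .synthetic import SECTORS, SurrogateSimulator, SyntheticDomain, simulate_many

#: The concentration targets scanned against, on each pollutant's scale.
PM_TARGETS = {"NAQT": 35.0, "WHO-IT2": 25.0, "WHO-IT3": 15.0, "WHO-AQG": 5.0}
O3_TARGETS = {"NAQT": 80.0, "WHO": 50.0, "counterfactual": 35.7}


@dataclass
class ScenarioGrid:
    """The scan lattice plus, once evaluated, per-scenario outputs."""

    levels: np.ndarray
    X: np.ndarray  # (n_scenarios, 5)
    table: pd.DataFrame | None = None

    @property
    def n_scenarios(self) -> int:
        return self.X.shape[0]


def build_grid(lower: float = 0.0, upper: float = 1.5, step: float = 0.2,
               n_sectors: int = len(SECTORS)) -> ScenarioGrid:
    """Cartesian product of equally spaced scaling levels per sector.

    Defaults give levels {0.0, 0.2, ..., 1.4} (``upper`` exclusive) and
    8⁵ = 32,768 scenarios; the all-ones baseline is not itself a lattice
    point and is evaluated separately where needed.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    levels = np.arange(lower, upper - 1e-12, step)
    if levels.size < 2:
        raise ValueError("grid must have at least 2 levels per sector")
    X = np.array(list(itertools.product(levels, repeat=n_sectors)), dtype=float)
    return ScenarioGrid(levels=levels, X=X)


def _predict_fields(evaluator, X: np.ndarray, pollutant: str) -> np.ndarray:
    """(n_cells, n_scenarios) concentration matrix from either evaluator."""
    if isinstance(evaluator, SurrogateSimulator):
        pm, o3 = simulate_many(evaluator, X)
        return pm if pollutant == "PM2.5" else o3
    if isinstance(evaluator, EmulatorSet):
        return evaluator.predict_matrix(X, pollutant)
    raise TypeError("evaluator must be an EmulatorSet or SurrogateSimulator")


def evaluate_grid(
    evaluator,
    grid: ScenarioGrid,
    tuning: dict[str, TuningFactors] | None,
    domain: SyntheticDomain,
    pollutants=("PM2.5", "O3"),
    gemm: pd.DataFrame | None = None,
    o3_params: health.O3RiskParams | None = None,
    rates: pd.DataFrame | None = None,
    compute_burden: bool = False,
) -> ScenarioGrid:
    """Populate the grid with tuned population-weighted exposures.

    Adds one exposure column per (pollutant, scope) where the scopes are
    national, each region, and the bay-area subset; with
    ``compute_burden=True`` also the national mortality per pollutant
    (central estimate).
    """
    table = pd.DataFrame(grid.X, columns=list(SECTORS))
    for pollutant in pollutants:
        conc = _predict_fields(evaluator, grid.X, pollutant)
        if tuning and pollutant in tuning:
            conc = conc * tuning[pollutant].factor_for_cells(domain)[:, None]
        pop = domain.population
        table[f"exposure_{pollutant}_national"] = np.average(conc, weights=pop, axis=0)
        for r in np.unique(domain.region_id):
            mask = domain.region_id == r
            table[f"exposure_{pollutant}_region{r}"] = np.average(
                conc[mask], weights=pop[mask], axis=0
            )
        if domain.gba.any():
            table[f"exposure_{pollutant}_gba"] = np.average(
                conc[domain.gba], weights=pop[domain.gba], axis=0
            )
        if compute_burden:
            if gemm is None and pollutant == "PM2.5":
                raise ValueError("burden computation needs GEMM parameters")
            table[f"mort_{pollutant}_national"] = _national_mort(
                conc, pollutant, domain, gemm, o3_params, rates
            )
    return ScenarioGrid(levels=grid.levels, X=grid.X, table=table)


def _national_mort(conc, pollutant, domain, gemm, o3_params, rates) -> np.ndarray:
    """Vectorized national mortality per scenario (central variant)."""
    from .synthetic import AGE_BRACKETS

    out = np.zeros(conc.shape[1])
    if pollutant == "PM2.5":
        z = health.excess_exposure(conc, health.PM_COUNTERFACTUAL)
        rate = health._rate_lookup(rates, "NCD+LRI", "central")
        for j, age in enumerate(AGE_BRACKETS):
            prm = gemm.loc[age]
            rr = health.gemm_rr(z, prm["theta"], prm["alpha"], prm["mu"], prm["nu"])
            pop_a = domain.population * domain.age_fraction[:, j]
            out += (pop_a[:, None] * (1.0 - 1.0 / rr)).sum(axis=0) * rate["I_MORT"][j]
    else:
        o3p = o3_params or health.O3RiskParams()
        z = health.excess_exposure(conc, o3p.cf)
        rate = health._rate_lookup(rates, "COPD", "central")
        frac = 1.0 - np.exp(-z * np.log(o3p.hr) / o3p.per_ppb)
        for j in range(len(AGE_BRACKETS)):
            pop_a = domain.population * domain.age_fraction[:, j]
            out += (pop_a[:, None] * frac).sum(axis=0) * rate["I_MORT"][j]
    return out


def sector_curve(
    evaluator,
    sector: str,
    levels,
    tuning,
    domain: SyntheticDomain,
    gemm=None,
    o3_params=None,
    rates=None,
    others_at: float = 1.0,
) -> pd.DataFrame:
    """Single-sector sensitivity: sweep one sector, others at baseline.

    Returns exposure, national MORT and DALY rate per level, absolute and
    relative to the all-baseline scenario.
    """
    if sector not in SECTORS:
        raise ValueError(f"unknown sector {sector!r}")
    k = SECTORS.index(sector)
    levels = np.asarray(levels, dtype=float)
    X = np.full((levels.size + 1, len(SECTORS)), others_at)
    X[:-1, k] = levels  # last row = baseline reference
    rows = []
    hia = gemm is not None and rates is not None
    o3p = o3_params or health.O3RiskParams()
    cols: dict[str, np.ndarray] = {}
    for pollutant in ("PM2.5", "O3"):
        conc = _predict_fields(evaluator, X, pollutant)
        if tuning and pollutant in tuning:
            conc = conc * tuning[pollutant].factor_for_cells(domain)[:, None]
        cols[pollutant] = conc
    for i, level in enumerate(levels):
        row = {"sector": sector, "scaling": float(level)}
        for pollutant in ("PM2.5", "O3"):
            conc, base = cols[pollutant][:, i], cols[pollutant][:, -1]
            exp_i = population_weighted(conc, domain.population)
            exp_b = population_weighted(base, domain.population)
            row[f"exposure_{pollutant}"] = exp_i
            row[f"rel_exposure_{pollutant}"] = exp_i / exp_b - 1.0
            if hia:
                bi = health.assess_burden(
                    domain,
                    conc if pollutant == "PM2.5" else None,
                    conc if pollutant == "O3" else None,
                    gemm, o3p, rates,
                )
                bb = health.assess_burden(
                    domain,
                    base if pollutant == "PM2.5" else None,
                    base if pollutant == "O3" else None,
                    gemm, o3p, rates,
                )
                for measure in ("MORT", "DALYs"):
                    vi = bi[(bi.level == "national") & (bi.measure == measure)]["value"].iloc[0]
                    vb = bb[(bb.level == "national") & (bb.measure == measure)]["value"].iloc[0]
                    row[f"{measure}_{pollutant}"] = vi
                    row[f"rel_{measure}_{pollutant}"] = vi / vb - 1.0 if vb > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def pair_surface(
    evaluator,
    sector_a: str,
    sector_b: str,
    levels,
    tuning,
    domain: SyntheticDomain,
    pollutant: str = "PM2.5",
    others_at: float = 1.0,
) -> pd.DataFrame:
    """Two-sector exposure surface with the other sectors at baseline."""
    if sector_a == sector_b:
        raise ValueError("sectors must be distinct")
    for s in (sector_a, sector_b):
        if s not in SECTORS:
            raise ValueError(f"unknown sector {s!r}")
    levels = np.asarray(levels, dtype=float)
    ka, kb = SECTORS.index(sector_a), SECTORS.index(sector_b)
    pairs = list(itertools.product(levels, levels))
    X = np.full((len(pairs), len(SECTORS)), others_at)
    X[:, ka] = [a for a, _ in pairs]
    X[:, kb] = [b for _, b in pairs]
    conc = _predict_fields(evaluator, X, pollutant)
    if tuning and pollutant in tuning:
        conc = conc * tuning[pollutant].factor_for_cells(domain)[:, None]
    exposure = np.average(conc, weights=domain.population, axis=0)
    return pd.DataFrame(
        {
            sector_a: X[:, ka],
            sector_b: X[:, kb],
            f"exposure_{pollutant}": exposure,
        }
    )


@dataclass
class AttainmentReport:
    """Scenarios whose scoped exposure meets a concentration target."""

    target_name: str
    threshold: float
    pollutant: str
    scope: str
    count: int
    n_scenarios: int
    attaining_index: np.ndarray
    mean_reduction_pct: dict[str, float]

    def summary(self) -> str:
        red = ", ".join(
            f"{s} {self.mean_reduction_pct[s]:.0f}%" for s in SECTORS
        )
        return (
            f"{self.count} of {self.n_scenarios} configurations meet "
            f"{self.target_name} ({self.threshold:g} {self.pollutant}, "
            f"{self.scope}); mean emission reductions: {red}"
        )


def attainment(
    grid: ScenarioGrid,
    threshold: float,
    pollutant: str = "PM2.5",
    scope: str = "national",
    target_name: str = "target",
) -> AttainmentReport:
    """Enumerate the attaining subset and its mean per-sector reductions.

    The mean reduction for sector k is the arithmetic mean of
    (1 − scaling_k)·100% over the attaining scenarios; an empty subset is
    reported with NaN reductions.
    """
    if grid.table is None:
        raise ValueError("grid must be populated by evaluate_grid first")
    col = f"exposure_{pollutant}_{scope}"
    if col not in grid.table:
        raise KeyError(f"unknown scope column {col!r}")
    mask = grid.table[col].to_numpy() <= threshold
    idx = np.flatnonzero(mask)
    if idx.size:
        reductions = {
            s: float((1.0 - grid.X[idx, k]).mean() * 100.0)
            for k, s in enumerate(SECTORS)
        }
    else:
        reductions = {s: float("nan") for s in SECTORS}
    return AttainmentReport(
        target_name=target_name,
        threshold=threshold,
        pollutant=pollutant,
        scope=scope,
        count=int(idx.size),
        n_scenarios=grid.n_scenarios,
        attaining_index=idx,
        mean_reduction_pct=reductions,
    )
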