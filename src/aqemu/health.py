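"""Health impact assessment: exposure–response, attributable burden, 95UI.

For PM2.5 the relative risk follows the GEMM (Global Exposure Mortality
Model) for non-accidental mortality (NCD+LRI):

    z  = max(0, PM2.5 − cf),          cf = 2.4 μg m⁻³
    RR = exp( θ·ln(1 + z/α) / (1 + exp((μ − z)/ν)) )        (per age bracket)
    PAF = P · (1 − 1/RR)

For O3 (6mDM8h) a log-linear hazard per 10 ppb for COPD:

    z  = max(0, O3 − cf),             cf = 35.7 ppb
    PAF = P · (1 − exp(−z·ln(HR)/10)),   HR = 1.06 (95UI 1.02–1.10)

Burden measures are products with baseline rates: MORT = PAF·I_MORT,
YLL = PAF·I_YLL, YLD = PAF·I_YLD, DALYs = YLL + YLD; rates are per
100,000 people. 95% uncertainty intervals are propagated by evaluating the
whole pipeline at the all-lower / central / all-upper parameter tuples
(each stage is monotone in each parameter, so the output triple is
ordered).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .metrics import population_weighted
from .synthetic import AGE_BRACKETS, SyntheticDomain

PM_COUNTERFACTUAL = 2.4   # μg m⁻³
O3_COUNTERFACTUAL = 35.7  # ppb

MEASURES = ("MORT", "YLL", "YLD", "DALYs")
VARIANTS = ("lower", "central", "upper")


@dataclass
class O3RiskParams:
    """COPD mortality hazard per 10 ppb of 6mDM8h ozone."""

    hr: float = 1.06
    hr_lower: float = 1.02
    hr_upper: float = 1.10
    cf: float = O3_COUNTERFACTUAL
    per_ppb: float = 10.0

    def __post_init__(self):
        if not self.hr_lower <= self.hr <= self.hr_upper:
            raise ValueError("hazard ratio triple must be ordered")

    def hr_variant(self, variant: str) -> float:
        return {"lower": self.hr_lower, "central": self.hr, "upper": self.hr_upper}[variant]


def load_gemm_params(path=None) -> pd.DataFrame:
    """Age-bracket GEMM parameter table (θ with 95UI, α, μ, ν).

    The packaged default is a synthetic fixture (see
    ``data/gemm_params_synthetic.csv``); a study would substitute the
    published cohort-derived table in the same layout.
    """
    if path is None:
        with resources.files("aqemu.data").joinpath(
            "gemm_params_synthetic.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"age", "theta", "theta_lower", "theta_upper", "alpha", "mu", "nu"}
    if not required.issubset(df.columns):
        raise ValueError(f"GEMM table must contain {sorted(required)}")
    if not ((df["theta_lower"] <= df["theta"]) & (df["theta"] <= df["theta_upper"])).all():
        raise ValueError("θ triples must be ordered")
    if (df["alpha"] <= 0).any() or (df["nu"] <= 0).any():
        raise ValueError("α and ν must be positive")
    return df.set_index("age")


def excess_exposure(conc, cf: float):
    """Exposure above the no-excess-risk counterfactual: max(0, conc − cf)."""
    c = np.asarray(conc, dtype=float)
    if (c < 0).any():
        raise ValueError("concentration must be non-negative")
    out = np.maximum(0.0, c - cf)
    return float(out) if out.ndim == 0 else out


def gemm_rr(z, theta: float, alpha: float, mu: float, nu: float):
    """GEMM relative risk; 1 at z = 0, increasing in z for θ > 0."""
    zz = np.asarray(z, dtype=float)
    if (zz < 0).any():
        raise ValueError("excess exposure must be non-negative")
    if alpha <= 0 or nu <= 0:
        raise ValueError("α and ν must be positive")
    out = np.exp(theta * np.log1p(zz / alpha) / (1.0 + np.exp((mu - zz) / nu)))
    return float(out) if out.ndim == 0 else out


def paf_pm(rr, population):
    """Attributable persons P·(1 − 1/RR)."""
    r = np.asarray(rr, dtype=float)
    p = np.asarray(population, dtype=float)
    if (r < 1).any():
        raise ValueError("RR must be >= 1")
    if (p < 0).any():
        raise ValueError("population must be non-negative")
    out = p * (1.0 - 1.0 / r)
    return float(out) if out.ndim == 0 else out


def paf_o3(z, params: O3RiskParams, population, variant: str = "central"):
    """Attributable persons P·(1 − exp(−z·ln(HR)/10))."""
    zz = np.asarray(z, dtype=float)
    p = np.asarray(population, dtype=float)
    hr = params.hr_variant(variant)
    if hr <= 0:
        raise ValueError("HR must be positive")
    out = p * (1.0 - np.exp(-zz * np.log(hr) / params.per_ppb))
    return float(out) if out.ndim == 0 else out


def burden(paf, i_mort, i_yll, i_yld):
    """(MORT, YLL, YLD) = PAF × (I_MORT, I_YLL, I_YLD)."""
    paf = np.asarray(paf, dtype=float)
    if (paf < 0).any():
        raise ValueError("PAF must be non-negative")
    return paf * i_mort, paf * i_yll, paf * i_yld


def dalys(yll, yld):
    """Disability-adjusted life years: YLL + YLD."""
    yll = np.asarray(yll, dtype=float)
    yld = np.asarray(yld, dtype=float)
    if (yll < 0).any() or (yld < 0).any():
        raise ValueError("YLL and YLD must be non-negative")
    out = yll + yld
    return float(out) if out.ndim == 0 else out


def rates_per_100k(burden_value, population):
    """Burden per 100,000 people."""
    p = np.asarray(population, dtype=float)
    if (p <= 0).any():
        raise ValueError("population must be positive")
    out = np.asarray(burden_value, dtype=float) / p * 1e5
    return float(out) if out.ndim == 0 else out


def _rate_lookup(rates: pd.DataFrame, cause: str, variant: str) -> dict[str, np.ndarray]:
    sub = rates[rates["cause"] == cause]
    out = {}
    for measure in ("I_MORT", "I_YLL", "I_YLD"):
        tab = sub[sub["measure"] == measure].set_index("age")[variant]
        out[measure] = tab.reindex(list(AGE_BRACKETS)).to_numpy()
    return out


def _cell_burden_pm(
    pm_values: np.ndarray,
    domain: SyntheticDomain,
    gemm: pd.DataFrame,
    rates: pd.DataFrame,
    variant: str,
) -> dict[str, np.ndarray]:
    """Per-cell PM2.5 burden summed over adult age brackets."""
    z = excess_exposure(pm_values, PM_COUNTERFACTUAL)
    rate = _rate_lookup(rates, "NCD+LRI", variant)
    theta_col = {"lower": "theta_lower", "central": "theta", "upper": "theta_upper"}[variant]
    mort = np.zeros(domain.n_cells)
    yll = np.zeros(domain.n_cells)
    yld = np.zeros(domain.n_cells)
    for j, age in enumerate(AGE_BRACKETS):
        prm = gemm.loc[age]
        rr = gemm_rr(z, prm[theta_col], prm["alpha"], prm["mu"], prm["nu"])
        paf = paf_pm(rr, domain.population * domain.age_fraction[:, j])
        m, l, d = burden(paf, rate["I_MORT"][j], rate["I_YLL"][j], rate["I_YLD"][j])
        mort += m
        yll += l
        yld += d
    return {"MORT": mort, "YLL": yll, "YLD": yld, "DALYs": yll + yld}


def _cell_burden_o3(
    o3_values: np.ndarray,
    domain: SyntheticDomain,
    o3_params: O3RiskParams,
    rates: pd.DataFrame,
    variant: str,
) -> dict[str, np.ndarray]:
    """Per-cell O3/COPD burden summed over adult age brackets."""
    z = excess_exposure(o3_values, o3_params.cf)
    rate = _rate_lookup(rates, "COPD", variant)
    mort = np.zeros(domain.n_cells)
    yll = np.zeros(domain.n_cells)
    yld = np.zeros(domain.n_cells)
    for j in range(len(AGE_BRACKETS)):
        paf = paf_o3(z, o3_params, domain.population * domain.age_fraction[:, j], variant)
        m, l, d = burden(paf, rate["I_MORT"][j], rate["I_YLL"][j], rate["I_YLD"][j])
        mort += m
        yll += l
        yld += d
    return {"MORT": mort, "YLL": yll, "YLD": yld, "DALYs": yll + yld}


def _aggregation_units(domain: SyntheticDomain):
    units = [("national", "all", np.ones(domain.n_cells, dtype=bool))]
    for r in np.unique(domain.region_id):
        units.append(("region", int(r), domain.region_id == r))
    if domain.gba.any():
        units.append(("gba", "GBA", domain.gba))
    return units


def assess_burden(
    domain: SyntheticDomain,
    pm_values: np.ndarray | None,
    o3_values: np.ndarray | None,
    gemm: pd.DataFrame,
    o3_params: O3RiskParams,
    rates: pd.DataFrame,
    variant: str = "central",
) -> pd.DataFrame:
    """Burden per pollutant aggregated nationally, by region and for the
    reporting-only bay-area subset (the latter is also inside its region,
    so it never enters national sums twice).

    Returns a tidy frame: level, unit, pollutant, measure, value,
    population, rate_per_100k.
    """
    per_cell: dict[str, dict[str, np.ndarray]] = {}
    if pm_values is not None:
        per_cell["PM2.5"] = _cell_burden_pm(pm_values, domain, gemm, rates, variant)
    if o3_values is not None:
        per_cell["O3"] = _cell_burden_o3(o3_values, domain, o3_params, rates, variant)

    rows = []
    for level, unit, mask in _aggregation_units(domain):
        pop = float(domain.population[mask].sum())
        for pollutant, cb in per_cell.items():
            for measure in MEASURES:
                val = float(cb[measure][mask].sum())
                rows.append(
                    {
                        "level": level,
                        "unit": unit,
                        "pollutant": pollutant,
                        "measure": measure,
                        "value": val,
                        "population": pop,
                        "rate_per_100k": rates_per_100k(val, pop),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class BurdenResult:
    """Burden with 95UI: tidy frame with lower/central/upper columns."""

    data: pd.DataFrame

    def __post_init__(self):
        bad = (self.data["lower"] > self.data["central"]) | (
            self.data["central"] > self.data["upper"]
        )
        if bad.any():
            raise ValueError("burden intervals must be ordered lower<=central<=upper")

    def national(self, pollutant: str, measure: str) -> tuple[float, float, float]:
        row = self.data[
            (self.data["level"] == "national")
            & (self.data["pollutant"] == pollutant)
            & (self.data["measure"] == measure)
        ].iloc[0]
        return float(row["lower"]), float(row["central"]), float(row["upper"])


def propagate_ui(
    domain: SyntheticDomain,
    pm_values: np.ndarray | None,
    o3_values: np.ndarray | None,
    gemm: pd.DataFrame,
    o3_params: O3RiskParams,
    rates: pd.DataFrame,
) -> BurdenResult:
    """95UI by bound evaluation: run the full pipeline at the all-lower,
    central and all-upper parameter tuples (θ, HR, baseline rates)."""
    frames = {}
    for variant in VARIANTS:
        df = assess_burden(domain, pm_values, o3_values, gemm, o3_params, rates, variant)
        frames[variant] = df.set_index(["level", "unit", "pollutant", "measure"])
    out = frames["central"][["population"]].copy()
    for variant in VARIANTS:
        out[variant] = frames[variant]["value"]
        out[f"rate_{variant}"] = frames[variant]["rate_per_100k"]
    return BurdenResult(data=out.reset_index())


def total_burden(pm: pd.DataFrame, o3: pd.DataFrame) -> pd.DataFrame:
    """Combine the two pollutants' burden tables measure-wise.

    Inputs are tidy frames with (level, unit, measure, value) rows at the
    same aggregation levels; the output adds each pollutant's share of the
    combined total.
    """
    key = ["level", "unit", "measure"]
    a = pm.set_index(key)["value"]
    b = o3.set_index(key)["value"]
    if not a.index.equals(b.index):
        raise ValueError("burden tables must cover identical aggregation levels")
    tot = (a + b).rename("value").reset_index()
    tot["share_pm"] = (a / (a + b)).to_numpy()
    tot["share_o3"] = (b / (a + b)).to_numpy()
    return tot
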