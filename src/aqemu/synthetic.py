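"""Synthetic study domain and surrogate air-quality simulator.

Everything the downstream pipeline consumes — a gridded domain with an
administrative hierarchy and population, a cheap surrogate for the chemical
transport model, a monitoring network, and baseline health rates — is
generated here with the statistical structure the analysis assumes:

* annual-mean PM2.5 responds near-linearly (and monotonically) to scalings
  of the five anthropogenic emission sectors, with configurable national
  population-weighted sector shares;
* 6mDM8h O3 responds nonlinearly, and in "VOC-limited" cells reducing a
  NOx-heavy sector (ENE, TRA or AGR) *increases* O3 (titration);
* site observations equal truth times a regional bias plus noise.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed sector order used everywhere: residential, industry, land
#: transport, agriculture, power generation.
SECTORS: tuple[str, ...] = ("RES", "IND", "TRA", "AGR", "ENE")

#: Adult age brackets (5-year steps from 25, open-ended 80+).
AGE_BRACKETS: tuple[str, ...] = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

#: National template of adult age fractions (sums to ~0.72 of the
#: population; the remainder is under-25 and carries no risk).
_AGE_TEMPLATE = np.array(
    [0.085, 0.082, 0.078, 0.072, 0.068, 0.064,
     0.058, 0.050, 0.042, 0.032, 0.022, 0.018]
)

N_REGIONS = 6

# NOx-heavy sectors whose reduction can raise O3 in VOC-limited cells.
NOX_SECTORS = ("ENE", "TRA", "AGR")


@dataclass
class SyntheticDomain:
    """A flat grid of cells with admin labels, population and age structure.

    Every prefecture belongs to exactly one province and every province to
    one region; a subset of one province is flagged as the reporting-only
    bay-area ("GBA"-like) grouping.
    """

    cell_id: np.ndarray
    prefecture_id: np.ndarray
    province_id: np.ndarray
    region_id: np.ndarray
    population: np.ndarray
    age_fraction: np.ndarray  # (n_cells, n_brackets)
    gba: np.ndarray  # boolean reporting-only subset
    seed: int

    @property
    def n_cells(self) -> int:
        return self.cell_id.size

    @property
    def adult_population(self) -> np.ndarray:
        """Persons per (cell, age bracket)."""
        return self.population[:, None] * self.age_fraction

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "prefecture_id": self.prefecture_id,
                "province_id": self.province_id,
                "region_id": self.region_id,
                "population": self.population,
                "gba": self.gba,
            }
        )
        for j, b in enumerate(AGE_BRACKETS):
            df[f"frac_{b}"] = self.age_fraction[:, j]
        return df


def make_domain(n_cells: int, n_prefectures: int, seed: int) -> SyntheticDomain:
    """Build a synthetic domain with a consistent admin hierarchy.

    Population is log-normal across cells; age fractions are the national
    template with mild per-cell perturbation (always summing to < 1, the
    remainder being the unexposed under-25 population). Every prefecture is
    non-empty by construction.
    """
    if n_cells < 1 or n_prefectures < 1:
        raise ValueError("n_cells and n_prefectures must be positive")
    if n_cells < n_prefectures:
        raise ValueError("need n_cells >= n_prefectures")
    rng = np.random.default_rng(seed)

    # each prefecture gets one guaranteed cell, remainder assigned at random
    prefecture_id = np.concatenate(
        [
            np.arange(n_prefectures),
            rng.integers(0, n_prefectures, size=n_cells - n_prefectures),
        ]
    )

    n_provinces = max(1, -(-n_prefectures // 3))
    province_of_pref = np.arange(n_prefectures) % n_provinces
    province_id = province_of_pref[prefecture_id]

    n_regions = min(N_REGIONS, n_provinces)
    region_of_prov = np.arange(n_provinces) % n_regions
    region_id = region_of_prov[province_id]

    population = rng.lognormal(mean=np.log(5.0e5), sigma=1.0, size=n_cells)

    jitter = rng.lognormal(0.0, 0.05, size=(n_cells, len(AGE_BRACKETS)))
    age_fraction = _AGE_TEMPLATE[None, :] * jitter
    # keep the adult total strictly below 1 per cell
    total = age_fraction.sum(axis=1)
    over = total >= 0.95
    if over.any():
        age_fraction[over] *= (0.95 / total[over])[:, None]

    # bay-area reporting subset: first province of the last region (if any)
    gba_prov = int(np.flatnonzero(region_of_prov == n_regions - 1)[0])
    gba = province_id == gba_prov

    return SyntheticDomain(
        cell_id=np.arange(n_cells),
        prefecture_id=prefecture_id,
        province_id=province_id,
        region_id=region_id,
        population=population,
        age_fraction=age_fraction,
        gba=gba,
        seed=seed,
    )


@dataclass
class SurrogateSimulator:
    """Closed-form stand-in for the chemical transport model.

    PM2.5 per cell: ``pm_base + sum_k pm_coeff[:, k] * s_k ** pm_exponent``
    — non-decreasing in every sector scaling; at the all-ones baseline the
    sector contributions are exactly ``pm_coeff``, so the configured
    national population-weighted shares are reproduced.

    O3 per cell: background plus a per-sector quadratic
    ``a*s + q*s**2`` and one signed IND×TRA interaction. In VOC-limited
    cells the NOx-heavy sector terms are decreasing on [0, 1], so reducing
    those emissions raises O3.
    """

    domain: SyntheticDomain
    pm_base: np.ndarray
    pm_coeff: np.ndarray      # (n_cells, 5)
    pm_exponent: np.ndarray   # (n_cells, 5), ~1
    o3_background: np.ndarray
    o3_lin: np.ndarray        # (n_cells, 5)
    o3_quad: np.ndarray       # (n_cells, 5)
    o3_interaction: np.ndarray  # (n_cells,) coefficient on s_IND*s_TRA
    voc_limited: np.ndarray   # boolean per cell
    noise_sd: float = 0.0
    seed: int = 0


def make_simulator(
    domain: SyntheticDomain,
    sector_shares=(0.21, 0.28, 0.04, 0.03, 0.02),
    other_share: float = 0.42,
    seed: int = 0,
    pm_nonlinearity: float = 1.0,
    voc_limited_fraction: float = 0.2,
    noise_sd: float = 0.0,
    mean_pm: float = 47.0,
    mean_o3: float = 37.0,
) -> SurrogateSimulator:
    """Construct a surrogate whose baseline national population-weighted
    PM2.5 sector shares match ``sector_shares`` exactly.

    ``sector_shares`` follows the fixed :data:`SECTORS` order
    (RES, IND, TRA, AGR, ENE); the default reproduces national
    contributions of 21% residential, 28% industry, 4% transport,
    3% agriculture, 2% power generation, 42% other sources.

    ``pm_nonlinearity`` scales the spread of the per-cell power exponents
    around 1 (0 gives an exactly linear PM response); ``other_share`` is the
    non-scanned-source share left in the additive base term.
    """
    shares = np.asarray(sector_shares, dtype=float)
    if shares.size != len(SECTORS):
        raise ValueError("need one share per sector")
    if not np.isclose(shares.sum() + other_share, 1.0, atol=1e-8):
        raise ValueError("sector shares plus other_share must sum to 1")
    rng = np.random.default_rng(seed)
    n = domain.n_cells

    # per-cell total baseline concentration, log-normal around mean_pm
    total_conc = mean_pm * rng.lognormal(0.0, 0.35, size=n)
    total_conc *= mean_pm / np.average(total_conc, weights=domain.population)

    # raw per-cell shares: jittered targets, then column-rescaled so the
    # national population-weighted shares hit the targets exactly
    w = domain.population * total_conc
    w = w / w.sum()
    frac = shares[None, :] * rng.lognormal(0.0, 0.25, size=(n, len(SECTORS)))
    realized = w @ frac
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(shares[None, :] > 0, frac * shares[None, :] / realized[None, :], 0.0)
    frac_other = 1.0 - frac.sum(axis=1)
    if (frac_other <= 0).any():
        # extreme jitter pathologies only; re-balance proportionally
        bad = frac_other <= 0
        frac[bad] *= (1.0 - other_share) / frac[bad].sum(axis=1, keepdims=True)
        frac_other = 1.0 - frac.sum(axis=1)

    pm_base = total_conc * frac_other
    pm_coeff = total_conc[:, None] * frac
    pm_exponent = 1.0 + pm_nonlinearity * rng.uniform(-0.08, 0.08, size=(n, len(SECTORS)))

    # --- ozone ---
    o3_background = mean_o3 * rng.lognormal(0.0, 0.05, size=n)
    voc_limited = rng.random(n) < voc_limited_fraction
    if 0 < voc_limited_fraction and not voc_limited.any():
        voc_limited[rng.integers(0, n)] = True

    o3_lin = np.zeros((n, len(SECTORS)))
    o3_quad = np.zeros((n, len(SECTORS)))
    u = rng.lognormal(0.0, 0.2, size=(n, len(SECTORS)))
    for k, name in enumerate(SECTORS):
        if name == "IND":
            o3_lin[:, k] = 2.5 * u[:, k]
            o3_quad[:, k] = 0.5 * u[:, k]
        elif name == "RES":
            o3_lin[:, k] = 0.8 * u[:, k]
            o3_quad[:, k] = 0.1 * u[:, k]
        else:  # NOx-heavy: titration in VOC-limited cells
            scale = {"TRA": 1.0, "AGR": 0.6, "ENE": 0.8}[name]
            nox_up = scale * u[:, k] * 0.9
            nox_dn = scale * u[:, k]
            o3_lin[:, k] = np.where(voc_limited, -1.2 * nox_dn, nox_up)
            o3_quad[:, k] = np.where(voc_limited, 0.25 * nox_dn, -0.15 * nox_up)
    o3_interaction = rng.normal(0.0, 0.15, size=n)

    return SurrogateSimulator(
        domain=domain,
        pm_base=pm_base,
        pm_coeff=pm_coeff,
        pm_exponent=pm_exponent,
        o3_background=o3_background,
        o3_lin=o3_lin,
        o3_quad=o3_quad,
        o3_interaction=o3_interaction,
        voc_limited=voc_limited,
        noise_sd=float(noise_sd),
        seed=seed,
    )


def _check_scalings(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(SECTORS):
        raise ValueError(f"scenarios must have {len(SECTORS)} sector scalings")
    if (X < 0).any() or (X > 1.5).any():
        raise ValueError("sector scalings must lie in [0, 1.5]")
    return X


def simulate_many(sim: SurrogateSimulator, scenarios) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the surrogate on a batch of scenarios.

    Returns ``(pm, o3)`` arrays of shape (n_cells, n_scenarios).
    """
    X = _check_scalings(scenarios)
    # PM: (cells, sectors) coeffs against (scen, sectors) scalings
    s_pow = X[None, :, :] ** sim.pm_exponent[:, None, :]  # (cells, scen, 5)
    pm = sim.pm_base[:, None] + np.einsum("ck,csk->cs", sim.pm_coeff, s_pow)
    o3 = (
        sim.o3_background[:, None]
        + sim.o3_lin @ X.T
        + sim.o3_quad @ (X.T**2)
        + sim.o3_interaction[:, None]
        * (X[:, SECTORS.index("IND")] * X[:, SECTORS.index("TRA")])[None, :]
    )
    if sim.noise_sd > 0:
        # reproducible per-scenario noise keyed off the scenario bytes
        for j in range(X.shape[0]):
            key = np.frombuffer(np.ascontiguousarray(X[j]).tobytes(), dtype=np.uint8)
            nrng = np.random.default_rng([sim.seed, *key.tolist()])
            pm[:, j] += nrng.normal(0.0, sim.noise_sd, size=pm.shape[0])
            o3[:, j] += nrng.normal(0.0, sim.noise_sd, size=o3.shape[0])
    return pm, o3


def simulate(sim: SurrogateSimulator, scenario) -> tuple[np.ndarray, np.ndarray]:
    """Annual-mean PM2.5 (μg m⁻³) and 6mDM8h O3 (ppb) per cell for one
    scenario of five sector scalings in [0, 1.5]."""
    pm, o3 = simulate_many(sim, np.atleast_2d(scenario))
    return pm[:, 0], o3[:, 0]


def make_observations(
    sim: SurrogateSimulator,
    domain: SyntheticDomain,
    bias_by_admin: dict[int, float] | None = None,
    noise_sd: float = 0.0,
    coverage: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic monitoring network: observed = truth × province bias + noise.

    ``bias_by_admin`` maps province_id to a multiplicative bias (default 1
    everywhere). ``coverage`` is the fraction of cells hosting a site; with
    coverage < 1 some prefectures may have no sites, exercising the
    province-level tuning fallback downstream.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    bias_by_admin = bias_by_admin or {}
    rng = np.random.default_rng(seed)
    n_sites = max(1, int(round(coverage * domain.n_cells)))
    site_cells = rng.choice(domain.n_cells, size=n_sites, replace=False)
    site_cells.sort()

    pm_true, o3_true = simulate(sim, np.ones(len(SECTORS)))
    rows = []
    for pollutant, truth in (("PM2.5", pm_true), ("O3", o3_true)):
        for s, c in enumerate(site_cells):
            prov = int(domain.province_id[c])
            bias = float(bias_by_admin.get(prov, 1.0))
            value = truth[c] * bias + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "site_id": f"{pollutant}-{s:04d}",
                    "cell_id": int(c),
                    "prefecture_id": int(domain.prefecture_id[c]),
                    "province_id": prov,
                    "pollutant": pollutant,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def make_baseline_rates(seed: int = 0) -> pd.DataFrame:
    """Cause- and age-specific baseline MORT/YLL/YLD rates with 95UI.

    Synthetic fixture emulating national burden-of-disease style rate
    tables: non-accidental (NCD+LRI, used for PM2.5) and COPD (used for O3)
    rates per person per year, increasing with age, with ordered
    lower ≤ central ≤ upper triples.
    """
    rng = np.random.default_rng(seed)
    n_age = len(AGE_BRACKETS)
    # mortality ramps geometrically with age
    mort_young, mort_old = 8e-4, 9e-2
    ramp = mort_young * (mort_old / mort_young) ** (np.arange(n_age) / (n_age - 1))
    ramp = ramp * rng.lognormal(0.0, 0.03, size=n_age)
    ramp = np.maximum.accumulate(ramp)  # keep monotone in age
    life_left = np.linspace(48.0, 8.0, n_age)  # years of life lost per death
    yld_years = np.linspace(6.0, 2.0, n_age)

    rows = []
    for cause, scale in (("NCD+LRI", 1.0), ("COPD", 0.08)):
        for j, age in enumerate(AGE_BRACKETS):
            central = {
                "I_MORT": scale * ramp[j],
                "I_YLL": scale * ramp[j] * life_left[j],
                "I_YLD": scale * ramp[j] * yld_years[j],
            }
            for measure, c in central.items():
                lo = c * rng.uniform(0.82, 0.92)
                hi = c * rng.uniform(1.08, 1.18)
                rows.append(
                    {
                        "cause": cause,
                        "age": age,
                        "measure": measure,
                        "lower": lo,
                        "central": c,
                        "upper": hi,
                    }
                )
    return pd.DataFrame(rows)


def national_sector_shares(sim: SurrogateSimulator) -> np.ndarray:
    """Realized national population-weighted PM2.5 sector shares at the
    all-ones baseline (fraction of the baseline exposure removed when the
    sector is zeroed)."""
    pop = sim.domain.population
    base_pm, _ = simulate(sim, np.ones(len(SECTORS)))
    base = np.average(base_pm, weights=pop)
    shares = np.empty(len(SECTORS))
    for k in range(len(SECTORS)):
        s = np.ones(len(SECTORS))
        s[k] = 0.0
        pm_k, _ = simulate(sim, s)
        shares[k] = (base - np.average(pm_k, weights=pop)) / base
    return shares
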