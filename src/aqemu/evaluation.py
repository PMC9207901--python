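"""Model evaluation metrics and observation-matching tuning.

NMBF and NMAEF are the symmetric, factor-interpretable bias/error metrics:
with model values M and observations O,

    NMBF  = ΣM/ΣO − 1        if mean(M) ≥ mean(O),  else  1 − ΣO/ΣM
    NMAEF = Σ|M−O| / ΣO      if mean(M) ≥ mean(O),  else  Σ|M−O| / ΣM

so NMBF = −0.5 means the model underestimates observations by 50% on
average and NMAEF = 0.5 means a gross error of half the mean observation.

Tuning scales modelled fields per administrative unit so unit means match
observed means — by prefecture where sites exist, falling back to the
province, defaulting to 1 where a province has no sites at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SyntheticDomain

logger = logging.getLogger(__name__)


def _paired(model, obs) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(model, dtype=float)
    o = np.asarray(obs, dtype=float)
    if m.shape != o.shape or m.size < 1:
        raise ValueError("model and observations must be equal-length, non-empty")
    return m, o


def nmbf(model, obs) -> float:
    """Normalized mean bias factor (piecewise-symmetric)."""
    m, o = _paired(model, obs)
    if m.mean() >= o.mean():
        if o.sum() <= 0:
            raise ZeroDivisionError("observation sum must be positive")
        return float(m.sum() / o.sum() - 1.0)
    if m.sum() <= 0:
        raise ZeroDivisionError("model sum must be positive")
    return float(1.0 - o.sum() / m.sum())


def nmaef(model, obs) -> float:
    """Normalized mean absolute error factor (piecewise-symmetric)."""
    m, o = _paired(model, obs)
    denom = o.sum() if m.mean() >= o.mean() else m.sum()
    if denom <= 0:
        raise ZeroDivisionError("normalizing sum must be positive")
    return float(np.abs(m - o).sum() / denom)


def r2_rmse(pred, truth) -> tuple[float, float]:
    """Coefficient of determination and root mean squared error."""
    p, t = _paired(pred, truth)
    if p.size < 2:
        raise ValueError("need at least two pairs")
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R² undefined for constant truth")
    ss_res = float(((p - t) ** 2).sum())
    return 1.0 - ss_res / ss_tot, float(np.sqrt(((p - t) ** 2).mean()))


@dataclass
class TuningFactors:
    """Per-admin-unit multiplicative scale factors for one pollutant."""

    pollutant: str
    prefecture: dict[int, float] = field(default_factory=dict)
    province: dict[int, float] = field(default_factory=dict)

    def factor_for_cells(self, domain: SyntheticDomain) -> np.ndarray:
        out = np.ones(domain.n_cells)
        for i in range(domain.n_cells):
            pref = int(domain.prefecture_id[i])
            if pref in self.prefecture:
                out[i] = self.prefecture[pref]
            else:
                out[i] = self.province.get(int(domain.province_id[i]), 1.0)
        return out

    def provenance_for_cells(self, domain: SyntheticDomain) -> np.ndarray:
        tags = np.empty(domain.n_cells, dtype=object)
        for i in range(domain.n_cells):
            if int(domain.prefecture_id[i]) in self.prefecture:
                tags[i] = "prefecture"
            elif int(domain.province_id[i]) in self.province:
                tags[i] = "province"
            else:
                tags[i] = "default"
        return tags

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"admin_level": "prefecture", "admin_id": k, "pollutant": self.pollutant,
             "factor": v}
            for k, v in sorted(self.prefecture.items())
        ] + [
            {"admin_level": "province", "admin_id": k, "pollutant": self.pollutant,
             "factor": v}
            for k, v in sorted(self.province.items())
        ]
        return pd.DataFrame(rows)


def fit_tuning(
    model_field: np.ndarray,
    observations: pd.DataFrame,
    domain: SyntheticDomain,
    pollutant: str,
) -> TuningFactors:
    """Mean-ratio tuning factors: mean(observed)/mean(modelled) per
    prefecture with sites; province-level for cells whose prefecture has
    none; factor 1 (with a logged warning) for unobserved provinces."""
    obs = observations[observations["pollutant"] == pollutant]
    factors = TuningFactors(pollutant=pollutant)
    for level, key in (("prefecture", "prefecture_id"), ("province", "province_id")):
        for unit, grp in obs.groupby(key):
            model_mean = model_field[grp["cell_id"].to_numpy()].mean()
            if model_mean <= 0:
                raise ValueError(
                    f"non-positive model mean in observed {level} {unit}"
                )
            getattr(factors, level)[int(unit)] = float(grp["value"].mean() / model_mean)
    missing = set(np.unique(domain.province_id)) - set(factors.province)
    if missing:
        logger.warning(
            "provinces %s have no observations for %s; factor defaults to 1",
            sorted(missing), pollutant,
        )
    return factors


def apply_tuning(
    field_values: np.ndarray, factors: TuningFactors, domain: SyntheticDomain
) -> np.ndarray:
    """Cell values scaled by their admin unit's tuning factor."""
    return np.asarray(field_values, dtype=float) * factors.factor_for_cells(domain)
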