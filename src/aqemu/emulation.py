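"""Per-cell Gaussian-process emulators of the simulator.

One emulator per (grid cell, pollutant) maps the five sector scaling
factors to the annual metric. Each emulator is a Yeo–Johnson power
transform of the inputs followed by a GP with an anisotropic Matern 5/2
kernel plus a small fitted noise term; hyperparameters are chosen by
marginal-likelihood maximization with a fixed number of seeded restarts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.preprocessing import PowerTransformer

from .evaluation import r2_rmse
from .synthetic import SECTORS

logger = logging.getLogger(__name__)

N_DIMS = len(SECTORS)


@dataclass
class GPConfig:
    """Fitting choices for one cell emulator."""

    n_restarts: int = 5
    nu: float = 2.5
    length_scale_bounds: tuple[float, float] = (1e-1, 1e3)
    signal_bounds: tuple[float, float] = (1e-6, 1e6)
    noise_bounds: tuple[float, float] = (1e-10, 1e-2)
    noise_init: float = 1e-8
    transform_inputs: bool = True
    normalize_y: bool = True


@dataclass
class CellEmulator:
    cell_id: int
    pollutant: str
    transformer: PowerTransformer | None
    gp: GaussianProcessRegressor
    X_train: np.ndarray
    y_train: np.ndarray

    @property
    def noise_scale(self) -> float:
        white = self.gp.kernel_.k2
        return float(np.sqrt(white.noise_level))


def _make_kernel(config: GPConfig):
    return ConstantKernel(1.0, config.signal_bounds) * Matern(
        length_scale=np.ones(N_DIMS),
        length_scale_bounds=config.length_scale_bounds,
        nu=config.nu,
    ) + WhiteKernel(config.noise_init, config.noise_bounds)


def fit_cell(
    X,
    y,
    config: GPConfig | None = None,
    seed: int = 0,
    cell_id: int = 0,
    pollutant: str = "PM2.5",
) -> CellEmulator:
    """Fit one cell's emulator on the training design.

    The input transform is fitted on the training inputs only; the GP's
    hyperparameters come from ``config.n_restarts`` seeded restarts of the
    marginal-likelihood optimizer, so refitting with the same seed is
    deterministic.
    """
    config = config or GPConfig()
    X = np.asarray(getattr(X, "X", X), dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] < 5:
        raise ValueError("need a 2-D design with >= 5 rows matching y")
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    if np.unique(X, axis=0).shape[0] != X.shape[0]:
        raise ValueError("degenerate design: duplicate rows")

    transformer = None
    Xt = X
    if config.transform_inputs:
        transformer = PowerTransformer(method="yeo-johnson", standardize=True)
        Xt = transformer.fit_transform(X)

    gp = GaussianProcessRegressor(
        kernel=_make_kernel(config),
        n_restarts_optimizer=config.n_restarts,
        normalize_y=config.normalize_y,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # hyperparameters pinned at a bound are expected (near-linear
        # targets push length-scales high and noise to the floor)
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(Xt, y)
    return CellEmulator(
        cell_id=cell_id,
        pollutant=pollutant,
        transformer=transformer,
        gp=gp,
        X_train=X,
        y_train=y,
    )


def predict(emulator: CellEmulator, scenarios, return_std: bool = True):
    """Posterior mean (and sd) at new scenarios within the training box."""
    X = np.atleast_2d(np.asarray(getattr(scenarios, "X", scenarios), dtype=float))
    if (X < 0).any() or (X > 1.5).any():
        raise ValueError("scenario outside the [0, 1.5] training box")
    Xt = emulator.transformer.transform(X) if emulator.transformer else X
    if return_std:
        mean, sd = emulator.gp.predict(Xt, return_std=True)
        return mean, sd
    return emulator.gp.predict(Xt)


@dataclass
class EmulatorSet:
    """One fitted emulator per (cell, pollutant), plus fit diagnostics."""

    emulators: dict[tuple[int, str], CellEmulator] = field(default_factory=dict)
    train_X: np.ndarray | None = None
    config: GPConfig = field(default_factory=GPConfig)
    seed: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.emulators)

    def pollutants(self) -> list[str]:
        return sorted({p for _, p in self.emulators})

    def cells(self, pollutant: str) -> list[int]:
        return sorted(c for c, p in self.emulators if p == pollutant)

    def predict_matrix(self, scenarios, pollutant: str) -> np.ndarray:
        """Posterior means, shape (n_cells, n_scenarios), cells in id order."""
        cells = self.cells(pollutant)
        X = np.atleast_2d(np.asarray(getattr(scenarios, "X", scenarios), dtype=float))
        out = np.empty((len(cells), X.shape[0]))
        for i, c in enumerate(cells):
            out[i] = predict(self.emulators[(c, pollutant)], X, return_std=False)
        return out


def _cell_seed(seed: int, cell_id: int, pollutant: str) -> int:
    # order-independent per-cell seed
    return (seed * 1_000_003 + cell_id * 2 + (pollutant == "O3")) % (2**31 - 1)


def fit_all(
    train_X,
    train_fields: dict[str, np.ndarray],
    config: GPConfig | None = None,
    seed: int = 0,
) -> EmulatorSet:
    """Fit every (cell, pollutant) emulator independently.

    ``train_fields`` maps pollutant → array of shape (n_runs, n_cells).
    Per-cell fits use seeds derived from (seed, cell, pollutant), so the
    result is independent of iteration order. Cells with non-finite
    targets are skipped with a logged error.
    """
    config = config or GPConfig()
    X = np.asarray(getattr(train_X, "X", train_X), dtype=float)
    emuset = EmulatorSet(train_X=X, config=config, seed=seed)
    for pollutant, Y in train_fields.items():
        Y = np.asarray(Y, dtype=float)
        if Y.shape[0] != X.shape[0]:
            raise ValueError("training fields must have one row per run")
        for c in range(Y.shape[1]):
            y = Y[:, c]
            if not np.isfinite(y).all():
                logger.error("cell %d %s has non-finite targets; skipped", c, pollutant)
                emuset.skipped.append((c, pollutant))
                continue
            emuset.emulators[(c, pollutant)] = fit_cell(
                X, y, config, seed=_cell_seed(seed, c, pollutant),
                cell_id=c, pollutant=pollutant,
            )
    return emuset


def evaluate_set(
    emuset: EmulatorSet, test_X, test_fields: dict[str, np.ndarray]
) -> dict[str, dict]:
    """Pooled and per-cell R²/RMSE on held-out runs.

    Pooling flattens all (cell, test-run) prediction/truth pairs per
    pollutant. Any test row identical to a training row is rejected
    (train/test hygiene).
    """
    X = np.atleast_2d(np.asarray(getattr(test_X, "X", test_X), dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty test design")
    if emuset.train_X is not None:
        for row in X:
            if np.any(np.all(np.isclose(emuset.train_X, row, atol=1e-12), axis=1)):
                raise ValueError("test design contains a training row")
    results: dict[str, dict] = {}
    for pollutant, Y in test_fields.items():
        Y = np.asarray(Y, dtype=float)
        pred = emuset.predict_matrix(X, pollutant)  # (cells, runs)
        truth = Y.T
        r2, rmse = r2_rmse(pred.ravel(), truth.ravel())
        per_cell = []
        for i in range(pred.shape[0]):
            err = pred[i] - truth[i]
            per_cell.append(
                {"cell_id": i, "rmse": float(np.sqrt((err**2).mean()))}
            )
        results[pollutant] = {"r2": r2, "rmse": rmse, "per_cell": per_cell}
    return results


# ---------------------------------------------------------------------------
# persistence: JSON index + per-cell parameter records (text only)

def save_set(emuset: EmulatorSet, directory) -> None:
    """Persist an EmulatorSet as JSON records.

    Stores the fitted kernel hyperparameters, transformer state and
    training data; reloading rebuilds each GP with the optimizer disabled,
    reproducing bit-identical predictions.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = emuset.config
    index = {
        "seed": emuset.seed,
        "train_X": emuset.train_X.tolist() if emuset.train_X is not None else None,
        "skipped": [list(k) for k in emuset.skipped],
        "config": {
            "n_restarts": cfg.n_restarts,
            "nu": cfg.nu,
            "length_scale_bounds": list(cfg.length_scale_bounds),
            "signal_bounds": list(cfg.signal_bounds),
            "noise_bounds": list(cfg.noise_bounds),
            "noise_init": cfg.noise_init,
            "transform_inputs": cfg.transform_inputs,
            "normalize_y": cfg.normalize_y,
        },
        "emulators": [],
    }
    for (c, pollutant), emu in sorted(emuset.emulators.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        rec = {
            "cell_id": c,
            "pollutant": pollutant,
            "theta": emu.gp.kernel_.theta.tolist(),
            "X_train": emu.X_train.tolist(),
            "y_train": emu.y_train.tolist(),
        }
        if emu.transformer is not None:
            rec["transform"] = {
                "lambdas": emu.transformer.lambdas_.tolist(),
                "mean": emu.transformer._scaler.mean_.tolist(),
                "scale": emu.transformer._scaler.scale_.tolist(),
            }
        index["emulators"].append(rec)
    (directory / "emulator_set.json").write_text(json.dumps(index))


def load_set(directory) -> EmulatorSet:
    """Rebuild a persisted EmulatorSet; predictions are bit-identical."""
    directory = Path(directory)
    index = json.loads((directory / "emulator_set.json").read_text())
    c = index["config"]
    config = GPConfig(
        n_restarts=c["n_restarts"],
        nu=c["nu"],
        length_scale_bounds=tuple(c["length_scale_bounds"]),
        signal_bounds=tuple(c["signal_bounds"]),
        noise_bounds=tuple(c["noise_bounds"]),
        noise_init=c["noise_init"],
        transform_inputs=c["transform_inputs"],
        normalize_y=c["normalize_y"],
    )
    emuset = EmulatorSet(
        train_X=np.asarray(index["train_X"]) if index["train_X"] is not None else None,
        config=config,
        seed=index["seed"],
        skipped=[tuple(k) for k in index["skipped"]],
    )
    for rec in index["emulators"]:
        X = np.asarray(rec["X_train"], dtype=float)
        y = np.asarray(rec["y_train"], dtype=float)
        transformer = None
        Xt = X
        if "transform" in rec:
            transformer = PowerTransformer(method="yeo-johnson", standardize=True)
            # restore fitted state without refitting
            transformer.lambdas_ = np.asarray(rec["transform"]["lambdas"])
            from sklearn.preprocessing import StandardScaler

            scaler = StandardScaler()
            scaler.mean_ = np.asarray(rec["transform"]["mean"])
            scaler.scale_ = np.asarray(rec["transform"]["scale"])
            scaler.var_ = scaler.scale_**2
            scaler.n_features_in_ = X.shape[1]
            scaler.n_samples_seen_ = X.shape[0]
            transformer._scaler = scaler
            transformer.n_features_in_ = X.shape[1]
            Xt = transformer.transform(X)
        kernel = _make_kernel(config)
        kernel.theta = np.asarray(rec["theta"], dtype=float)
        gp = GaussianProcessRegressor(
            kernel=kernel, optimizer=None, normalize_y=config.normalize_y
        )
        gp.fit(Xt, y)
        emuset.emulators[(rec["cell_id"], rec["pollutant"])] = CellEmulator(
            cell_id=rec["cell_id"],
            pollutant=rec["pollutant"],
            transformer=transformer,
            gp=gp,
            X_train=X,
            y_train=y,
        )
    return emuset
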