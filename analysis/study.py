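"""Shared configuration of the desk-scale study driven by the numbered
analysis scripts: one place for the seeds, sizes and file locations, plus
constructors that rebuild each deterministic artifact on demand.

The emulator set is the only expensive artifact; script 03 persists it
under results/emulators and later scripts reload it from there.
"""

from pathlib import Path

import numpy as np

from aqemu import design, emulation, evaluation, synthetic

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
EMULATOR_DIR = RESULTS / "emulators"

SEED = 42
N_CELLS = 100
N_PREFECTURES = 10
N_TRAIN, N_TEST = 50, 5

#: province bias factors and site noise used for the monitoring network
OBS_BIAS = {0: 1.30, 2: 0.85}
OBS_NOISE_SD = 0.5
OBS_COVERAGE = 0.6


def make_domain():
    return synthetic.make_domain(N_CELLS, N_PREFECTURES, seed=SEED)


def make_simulator(domain):
    return synthetic.make_simulator(domain, seed=SEED + 1)


def make_designs():
    return design.train_test_designs(
        n_train=N_TRAIN, n_test=N_TEST, seeds=(SEED + 2, SEED + 3)
    )


def make_observations(sim, domain):
    return synthetic.make_observations(
        sim, domain, bias_by_admin=OBS_BIAS, noise_sd=OBS_NOISE_SD,
        coverage=OBS_COVERAGE, seed=SEED + 6,
    )


def load_emulators() -> emulation.EmulatorSet:
    if not (EMULATOR_DIR / "emulator_set.json").exists():
        raise SystemExit("no persisted emulators; run 03_fit_emulators.py first")
    return emulation.load_set(EMULATOR_DIR)


def fit_tuning_factors(sim, domain):
    obs = make_observations(sim, domain)
    pm_base, o3_base = synthetic.simulate(sim, np.ones(5))
    return {
        "PM2.5": evaluation.fit_tuning(pm_base, obs, domain, "PM2.5"),
        "O3": evaluation.fit_tuning(o3_base, obs, domain, "O3"),
    }
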