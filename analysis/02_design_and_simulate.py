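"""Build the 50-run training and 5-run test maximin Latin hypercube
designs over the five sector scalings (0–150%), run the surrogate
simulator on both, and write designs and gridded fields."""

import numpy as np
import pandas as pd

import study
from aqemu import synthetic
from aqemu.design import _min_distance

study.RESULTS.mkdir(exist_ok=True)

domain = study.make_domain()
sim = study.make_simulator(domain)
train, test = study.make_designs()

for d, name in ((train, "train"), (test, "test")):
    d.to_frame().to_csv(study.RESULTS / f"design_{name}.csv", index=False)
    pm, o3 = synthetic.simulate_many(sim, d.X)
    for tag, field in (("pm25", pm), ("o3", o3)):
        out = pd.DataFrame(field, columns=[f"run{j}" for j in range(d.n_runs)])
        out.insert(0, "cell_id", domain.cell_id)
        out.to_csv(study.RESULTS / f"fields_{tag}_{name}.csv", index=False)
    print(f"{name}: {d.n_runs} runs, min pairwise design distance "
          f"{_min_distance(d.X):.3f}")

pm_b, o3_b = synthetic.simulate(sim, np.ones(5))
print(f"baseline national exposure: "
      f"PM2.5 {np.average(pm_b, weights=domain.population):.1f} ug/m3, "
      f"O3 {np.average(o3_b, weights=domain.population):.1f} ppb")
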