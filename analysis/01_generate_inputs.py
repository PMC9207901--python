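"""Generate the synthetic study inputs and write them for inspection:
the gridded domain (population, admin hierarchy, age structure), the
surrogate simulator's realized national sector shares, the monitoring
network, and the baseline health-rate table."""

import numpy as np
import pandas as pd

import study
from aqemu import synthetic

study.RESULTS.mkdir(exist_ok=True)

domain = study.make_domain()
sim = study.make_simulator(domain)
obs = study.make_observations(sim, domain)
rates = synthetic.make_baseline_rates(seed=study.SEED + 5)

domain.to_frame().to_csv(study.RESULTS / "domain.csv", index=False)
obs.to_csv(study.RESULTS / "observations.csv", index=False)
rates.to_csv(study.RESULTS / "baseline_rates.csv", index=False)

shares = synthetic.national_sector_shares(sim)
pd.DataFrame(
    {"sector": synthetic.SECTORS, "national_pw_share": shares}
).to_csv(study.RESULTS / "sector_shares.csv", index=False)

print(f"domain: {domain.n_cells} cells, "
      f"{np.unique(domain.prefecture_id).size} prefectures, "
      f"{np.unique(domain.province_id).size} provinces, "
      f"{np.unique(domain.region_id).size} regions "
      f"({int(domain.gba.sum())} bay-area cells)")
print(f"population: {domain.population.sum()/1e6:.1f} M persons")
print("national population-weighted PM2.5 sector shares at baseline:")
for s, v in zip(synthetic.SECTORS, shares):
    print(f"  {s}: {100*v:.1f}%")
print(f"monitoring network: {obs.site_id.nunique()} site records, "
      f"{obs.prefecture_id.nunique()} of {np.unique(domain.prefecture_id).size} "
      f"prefectures observed")
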