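"""Regenerate the bundled synthetic life table.

Annual all-cause mortality rates with a Gompertz-Makeham shape plus an
infant-mortality bump, ages 0-100.  This is a synthetic stand-in for national
life tables, not real data; swap in a real table via the config.
"""
import numpy as np
import pandas as pd

ages = np.arange(0, 101)
makeham = 2.0e-4
gompertz = 2.5e-5 * np.exp(0.085 * ages)
infant = 3.0e-3 * np.exp(-ages / 1.5)
rates = np.round(makeham + gompertz + infant, 6)

df = pd.DataFrame({"age": ages, "annual_rate": rates})
df.to_csv("src/sojourn/data/synthetic_life_table.csv", index=False)
print(df.iloc[[0, 1, 55, 80, 100]])
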