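"""Balance diagnostics and subgroup AUROC reporting.

Standardized mean differences (SMDs) quantify how demographically similar
two candidate chart-review samples are; subgroup AUROCs show how a learned
phenotype performs within demographic strata of the test data.
"""

import numpy as np
import pandas as pd

from coversample import (
    auroc,
    balance_table,
    fit_cp,
    smd,
    smd_multilevel,
    subgroup_auroc,
)

# -- SMDs on published-style proportions -----------------------------------
print("binary SMD, 47% vs 43% male:", round(smd(0.47, 0.43), 3))
age_a = [0.02, 0.11, 0.38, 0.49]  # children / young / middle / older
age_b = [0.03, 0.24, 0.38, 0.35]
print("multi-level SMD, age bands:", round(smd_multilevel(age_a, age_b), 3))

# -- balance table between two simulated samples ---------------------------
rng = np.random.default_rng(0)
demo = pd.DataFrame({
    "sex": rng.choice(["f", "m"], 400),
    "age_band": rng.choice(["child", "young", "middle", "older"], 400, p=[0.05, 0.15, 0.4, 0.4]),
})
tab = balance_table(demo, np.arange(0, 100), np.arange(100, 200))
print("\n", tab.round(3).to_string(index=False))

# -- subgroup AUROC with a not-evaluable stratum ---------------------------
x = rng.normal(size=300)
y = (x + rng.normal(size=300) > 0).astype(int)
groups = np.where(np.arange(300) < 290, "majority", "tiny")
y[groups == "tiny"] = 0  # a stratum with controls only -> reported as NaN
model = fit_cp(x[:, None], y)
scores = model.predict_proba(x[:, None])
print("\noverall AUROC:", round(auroc(scores, y), 3))
print(subgroup_auroc(scores, y, groups, n_boot=200).round(3).to_string(index=False))
# One SMD is reported per variable (binary or Mahalanobis multi-level form);
# strata whose labels are single-class get NaN AUROC rather than an error.
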