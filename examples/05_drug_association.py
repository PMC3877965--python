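"""Risk score as a predictive biomarker: association with drug response.

89 simulated cell lines get integer risk scores and a drug-sensitivity
readout (activity area: growth inhibition integrated over concentrations;
higher = more sensitive).  One drug genuinely tracks the score, one does
not, and one is mostly missing and is excluded by the >50%-missing rule.
"""

import numpy as np
import pandas as pd

from pathsurv import associate_drugs, generate_drug_response

rng = np.random.default_rng(3)
cells = [f"cell_{i:03d}" for i in range(89)]
scores = pd.Series(rng.integers(0, 17, 89), index=cells, name="risk_score")

drugs = pd.DataFrame(index=cells)
drugs["egfr_inhibitor"] = generate_drug_response(scores, slope=0.25, noise_sd=1.0, seed=4)
drugs["inert_compound"] = pd.Series(rng.normal(size=89), index=cells)
sparse = pd.Series(np.nan, index=cells)
sparse.iloc[:30] = rng.normal(size=30)
drugs["mostly_missing"] = sparse

table = associate_drugs(scores, drugs)
print(table.to_string(index=False))
print("\np_lm: OLS slope test; p_kw: Kruskal-Wallis over score tertiles;")
print("p_wx: Wilcoxon rank-sum, High vs Low tertile. The responsive drug is")
print("significant in all three; the sparse drug is excluded, not tested.")
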