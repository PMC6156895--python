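"""Pedigree kinship and the mixed-model EWAS fit.

Builds kinship coefficients from a small two-generation pedigree, then
fits one probe twice — with the kinship random effect and with plain
OLS — on data where the probe has a real polygenic component, so the
two models weight related samples differently.
"""

import numpy as np
import pandas as pd

from globalp import kinship_from_pedigree, fit_probe_lmm, fit_probe_ols
from globalp.io import SampleTable

# 30 families: two founders and two full sibs each
rows = []
for f in range(30):
    rows += [(f"fa{f}", "", ""), (f"mo{f}", "", ""),
             (f"s1_{f}", f"fa{f}", f"mo{f}"), (f"s2_{f}", f"fa{f}", f"mo{f}")]
ped = pd.DataFrame(rows, columns=["id", "father", "mother"])
kin = kinship_from_pedigree(ped)
ids = list(kin.sample_ids)
print(f"kinship: phi(founder, founder) = {kin.phi[0, 0]}, "
      f"phi(parent, child) = {kin.phi[ids.index('fa0'), ids.index('s1_0')]}, "
      f"phi(sib, sib) = {kin.phi[ids.index('s1_0'), ids.index('s2_0')]}")

# a probe whose M-value is half polygenic, half independent noise
rng = np.random.default_rng(3)
n = len(ids)
A = kin.relationship
g = np.linalg.cholesky(A + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
y = rng.standard_normal(n)                      # null phenotype
m = 0.8 * g + 0.8 * rng.standard_normal(n)

samples = SampleTable(pd.DataFrame({"phenotype": y}, index=pd.Index(ids)),
                      phenotype="phenotype")
lmm = fit_probe_lmm(m, samples, kin)
ols = fit_probe_ols(m, samples)
print(f"LMM: beta = {lmm.beta_hat:.4f}, se = {lmm.se:.4f}, p = {lmm.p_value:.3f},"
      f" variance ratio sg2/se2 = {np.exp(lmm.log_delta):.2f}")
print(f"OLS: beta = {ols.beta_hat:.4f}, se = {ols.se:.4f}, p = {ols.p_value:.3f}")
print("\nBoth estimates are near 0 (the phenotype is null).  The mixed model")
print("detects the family variance (ratio well above 0) and computes the fit")
print("under the correct within-family covariance, which OLS ignores.")
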