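"""The region statistic on paper-and-pencil cases.

Shows the quadratic form z' Sigma^-1 z and its chi-square reference on
inputs small enough to verify by hand, plus the BH step-up correction.
"""

import numpy as np

from globalp import region_chi2, bh_fdr

# one probe: the region test reduces to the squared z / two-sided normal test
stat, df, p = region_chi2([1.96], np.eye(1))
print(f"m=1, z=1.96      -> chi2 = {stat:.4f}, df = {df}, p = {p:.4f} (normal two-sided)")

# two positively correlated probes, both z = 1: correlation discounts the
# evidence -- the statistic is (z1^2 - 2 rho z1 z2 + z2^2)/(1 - rho^2) = 4/3
stat, df, p = region_chi2([1.0, 1.0], [[1.0, 0.5], [0.5, 1.0]])
print(f"m=2, z=(1,1), rho=0.5 -> chi2 = {stat:.4f} (= 4/3), p = {p:.4f} "
      f"(= exp(-2/3) = {np.exp(-2/3):.4f})")

# independent probes: the statistic is the plain sum of squared z-scores
z = np.array([1.0, -2.0, 0.5])
stat, df, p = region_chi2(z, np.eye(3))
print(f"m=3, Sigma=I      -> chi2 = {stat:.4f} (= sum z^2 = {float(z @ z):.4f}), "
      f"df = {df}, p = {p:.4f}")

# BH step-up across overlapping region tests
pvals = [0.005, 0.011, 0.02, 0.74]
print(f"\nBH q-values for p = {pvals}: {np.round(bh_fdr(pvals), 4)}")
print("Each q is the smallest FDR level at which that region would be called.")
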