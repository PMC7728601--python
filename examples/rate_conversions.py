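"""Rate and time conversions: mutation rate, LTR insertion ages and
coalescent output scaling."""

import numpy as np

from malus.rates import ltr_insertion_age, mutation_rate, scale_demography

# per-year substitution rate from interspecific distance and split time
mu = mutation_rate(D=0.014, T=1.8e6)
print(f"mutation rate: {mu:.1e} substitutions/site/year "
      "(D = 0.014 between the two wild species, T = 1.8 Ma)")

# a retrotransposon whose twin LTRs have diverged 0.78% inserted ~1 Ma ago
age = ltr_insertion_age(d=0.0078, mu=mu)
print(f"LTR-RT insertion age at 0.78% twin-LTR divergence: {age:,.0f} years")

# rescale coalescent (PSMC-style) output into years and individuals
times = np.array([0.01, 0.05, 0.2, 0.8, 2.0])
lambdas = np.array([1.0, 0.6, 0.3, 0.8, 1.2])
dem = scale_demography(theta0=0.002, times=times, lambdas=lambdas,
                       mu=mu, s=100.0, g=7.5)
print(f"baseline Ne (N0): {dem.N0:,.0f} individuals")
for yr, ne in zip(dem.years, dem.Ne):
    print(f"  {yr:12,.0f} years ago: Ne = {ne:,.0f}")
# The Ne trajectory is the demographic history in natural units; dips mark
# population bottlenecks (e.g. glacial periods).
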