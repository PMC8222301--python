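"""The abundance control: does biomass explain the release counts?

Couples a synthetic SA (surface-integrated backscatter) series to 30-min
event counts so that abundance explains ~12% of the count variance, then
recovers that figure with the log-log GLS-AR(1) fit.
"""

from scon import (
    AbundanceCouplingParams,
    ClusterParams,
    DielIntensityParams,
    aggregate_counts,
    fit_gls_ar1,
    gen_abundance_series,
    gen_clustered,
)

days = 18
events = gen_clustered(DielIntensityParams(),
                       ClusterParams(branching_ratio=0.5, kernel_decay_s=10.0),
                       seed=3, days=days)
counts = aggregate_counts(events, (0, days * 86_400))
series = gen_abundance_series(counts, AbundanceCouplingParams(target_r2=0.12),
                              seed=21)

fit = fit_gls_ar1(series)
print(f"rows used: {fit.n_used} (dropped {fit.n_dropped} zero/NaN intervals)")
print(f"slope = {fit.slope:.3f}, AR(1) phi = {fit.phi:.2f}")
print(f"F(1, {fit.df[1]}) = {fit.f_stat:.2f}, p = {fit.p_value:.2e}")
print(f"variance explained = {fit.var_explained:.3f}")
# A significant slope with small variance explained mirrors the control
# logic: abundance covaries with release counts but explains far too
# little of their variation to account for the observed clustering.
# Single-series estimates scatter around the 0.12 coupling target
# (ensemble sd ~ 0.04 at this length); only the ensemble mean pins it.
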