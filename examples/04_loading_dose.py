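"""Coverage-based loading doses across published ICU ceftazidime models.

LD = Vd * TC * exp(kappa * omega_V): the dose that fills the volume of
distribution to the 60 mg/L target immediately, inflated by the Vd
variability so a chosen fraction of patients (80% here) is covered.
"""

from ceftazpk import LoadingDoseSpec, kappa_for_coverage, literature_ld_table, loading_dose

kappa = kappa_for_coverage(0.80)
print(f"80% coverage quantile: kappa = {kappa:.2f}")

spec = LoadingDoseSpec(Vd=88.0, TC=60.0, kappa=round(kappa, 2), omega_V=0.57)
print(f"current model: LD = {loading_dose(spec) / 1000:.1f} g")

table, median = literature_ld_table(coverage=0.80)
print(table.to_string(index=False))
print(f"median loading dose across models: {median:.1f} g")
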