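"""Run the NMR bucket preprocessing chain on synthetic spectra.

Simulates Lorentzian-peak urine spectra where the 3.16 ppm peak is twice as
high in one class, then applies the full chain — 0.04-ppm binning over
0.16-9.00 ppm, urea/water region deletion, integral normalization to 100,
pareto scaling, 10-quantile discretization — and shows that the planted
bucket is the one the chi2 selector finds.
"""

from rulemine import PreprocessConfig, chi2_select, preprocess_spectra
from rulemine.synth import SyntheticSpec, generate_spectra

spec = SyntheticSpec(seed=3)
table, target, truth = generate_spectra(spec)
print(f"raw spectra: {len(table.subjects)} subjects x {table.n_buckets} samples")
print(f"discriminating peaks planted at {truth['discriminating_ppm']} ppm")

config = PreprocessConfig()  # overlap_rule="overlap" keeps 183 buckets
dataset = preprocess_spectra(table, target, config)
print(f"discretized: {dataset.n_subjects} subjects x {len(dataset.variables)} buckets, "
      f"10 quantile bins each")

selected = chi2_select(dataset)
print(f"chi2 + Bonferroni selects: {selected}")
# 'bucket 3.16' is the 0.04-ppm bucket holding the planted 2:1 peak; its
# selection shows the class signal survives normalization, scaling and
# discretization end to end.
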