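"""The full pipeline in one call: screen, fit, classify, allometry, report.

Equivalent to `morphmix simulate` + `morphmix analyze` on the command line.
"""

import json

from morphmix import (AnalysisConfig, GeneratorConfig, generate_population,
                      run_analysis, validate_report)

table = generate_population(GeneratorConfig(seed=1, n_males=500, n_females=189))
report = run_analysis(table, AnalysisConfig(seed=1))
doc = report.to_dict()

assert validate_report(doc) == [], "report must match the shipped schema"

male_kde = doc["descriptive"]["male"]["kde_patella"]
female_kde = doc["descriptive"]["female"]["kde_patella"]
print(f"male trait KDE modes:   {male_kde['mode_count']} (bimodal = dimorphic)")
print(f"female trait KDE modes: {female_kde['mode_count']}")
print(f"variance ratio male:    {doc['descriptive']['male']['variance_comparison']['ratio']}")
print(f"variance ratio female:  {doc['descriptive']['female']['variance_comparison']['ratio']}")
print(f"preferred model:        {doc['model_comparison']['preferred']}")
print(f"classification counts:  {doc['classification']['counts']}")
print(json.dumps({g: f["slope"] for g, f in doc["allometry"]["fits"].items()},
                 indent=2))
# A bimodal male trait with a mean-standardized variance ratio far above 1
# and a mixture preferred by AIC make the case for discrete male dimorphism.
# Note: the default generation mode draws male patella from the mixture
# independently of prosoma, so the male SMA "slopes" here are sd ratios, not
# real lines — run 03_allometry_sma.py (allometric mode) for line recovery.
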