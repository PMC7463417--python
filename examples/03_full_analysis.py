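"""Run the complete response-prediction analysis on a synthetic cohort.

Covers the full chain: feature extraction for both readers, Fisher exact
CR-rate contingency tests, two-step feature selection (Mann-Whitney filter,
then lowest-p per category), ROC analysis with Youden cutoffs, the combined
logistic prediction probability with Hosmer-Lemeshow calibration, the
MTV-vs-volume consistency checks, and interobserver ICC. The final summary
is the machine twin of a clinical radiomics report: each ROC row carries
the cutoff in feature units and the sensitivity/specificity/accuracy the
cutoff achieves, and the combined model's AUC is typically the highest.
"""

from pettex.pipeline import analyze_cohort, format_report
from pettex.synthetic_cohort import CohortConfig, generate_cohort

records = generate_cohort(CohortConfig(seed=1))
report = analyze_cohort(records)
print(format_report(report))
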