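"""Draw a synthetic SCLC-like cohort and inspect its ground truth.

The generator emulates the five inputs the pipeline consumes: a somatic
mutation table, clinical survival records, a log-scale expression matrix,
a drug-response table, and the causal gene set whose burden drives the
planted survival effect.
"""

import numpy as np

from pathburden import SynthConfig, generate_cohort

cohort = generate_cohort(SynthConfig(seed=1))
truth = cohort.truth

print(f"cohort size:        {len(cohort.roster)} samples")
print(f"mutation records:   {len(cohort.mutations)}")
print(f"causal set:         {truth.causal_set_name} "
      f"({len(truth.causal_set)} genes)")
print(f"burden threshold:   {truth.groups.threshold:.0f} (cohort median)")
print(f"group sizes:        {truth.groups.n_high} mut-high / "
      f"{truth.groups.n_low} mut-low")
print(f"true group HR:      {np.exp(truth.beta):.3f}")
print(f"censoring realized: {1 - cohort.clinical.data['event'].mean():.2f}")

# Samples strictly above the median pathway burden form the mut-high group;
# their hazard is multiplied by exp(beta) < 1, so they live longer.
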