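"""Generate a registry-like synthetic trauma cohort and inspect its shape.

The generator draws ICD-10-like injury codes from a skewed
rank-frequency law and produces 30-day death from the multiplicative
independent-survival model (the patient's survival probability is the
product of per-code survivals); 24-hour death is a thinning of 30-day
death, so it is always nested.
"""

import numpy as np

from iciss import generate_cohort, titco_like_spec, write_cohort

spec = titco_like_spec(seed=1, n_patients=16_000)
cohort = generate_cohort(spec)

d30 = [r.died_30d for r in cohort if r.died_30d is not None]
d24 = [r.died_24h for r in cohort if r.died_24h is not None]
male = [r.sex == "male" for r in cohort if r.sex is not None]
n_codes = [len(r.injuries) for r in cohort]

print(f"patients:            {len(cohort)}")
print(f"30-day mortality:    {100 * np.mean(d30):.1f}%   (emulation target ~21.6%)")
print(f"24-hour mortality:   {100 * np.mean(d24):.1f}%    (emulation target ~6.4%)")
print(f"male:                {100 * np.mean(male):.1f}%   (emulation target ~77%)")
print(f"injury codes/patient: mean {np.mean(n_codes):.2f}, max {max(n_codes)}")

write_cohort(cohort, "scratch_cohort.csv")
print("cohort written to scratch_cohort.csv "
      "(one row per patient, injuries ';'-packed)")
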