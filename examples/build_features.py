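"""Build the 29-slot behavioral feature vector for one simulated patient.

Each slot is a named behavioral or physiological summary over the diary
window (voiding rhythm, nocturia, fluid composition, adherence, scale
scores).  NaN marks a slot whose construction is undefined on the available
data — e.g. the PFMT adherence decay rate needs at least 10 days of training
records.
"""

import math

from cbis.features import FEATURE_SCHEMA, build_feature_vector
from cbis.preprocessing import run_qc
from cbis.simulator import SimConfig, generate_cohort

diary = generate_cohort(SimConfig(n_patients=1, days=7, seed=3))[0]
clean, report, _, _ = run_qc(diary)
fv = build_feature_vector(clean, report)

print(f"patient {fv.patient_id}, window {fv.window_start} (+{fv.span_days}d)\n")
category = None
for name, cat in FEATURE_SCHEMA:
    if cat != category:
        category = cat
        print(f"[{cat}]")
    v = fv[name]
    print(f"  {name:32s} {'undefined' if math.isnan(v) else f'{v:.2f}'}")

# Ratio features are percentages (nocturnal polyuria ratio = nocturnal
# volume / 24h volume x 100); frequencies are fractions in [0, 1]; interval
# features are minutes.
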