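"""Turn raw clinical variables into binary deficits with a codebook.

Each codebook row names a deficit, the raw variable it comes from, and the
dichotomization rule (inclusive threshold, code match, or pass-through).
Missing raw values propagate to missing deficits.
"""

import numpy as np
import pandas as pd

from frailty_ga import Codebook, CodebookEntry, apply_codebook

raw = pd.DataFrame({
    "mmse": [29, 26, 27, np.nan],
    "walk_speed": [1.3, 0.6, 0.8, 1.1],
    "heart_failure": [0, 1, 0, 0],
})

codebook = Codebook([
    CodebookEntry("low_cognition", "mmse", "threshold_le", 27, "cognition"),
    CodebookEntry("slow_gait", "walk_speed", "threshold_le", 0.8, "function"),
    CodebookEntry("heart_failure", "heart_failure", "already_binary",
                  domain_tag="disease"),
])

deficits = apply_codebook(raw, codebook)
print(deficits)
print()
print("1 = rule fired (deficit present), 0 = absent, NaN = raw value missing;")
print("thresholds are inclusive, so MMSE of exactly 27 counts as a deficit.")
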