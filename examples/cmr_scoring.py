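"""Composite cardiometabolic risk scores for a small fasting panel.

The score sums within-sample z-scores of reciprocal HDL, LDL, fasting
glucose and mean arterial pressure; higher means worse.  Because the
standardisation is within-sample, the score has no clinical cut-point
and the high/low classes come from a median split.
"""

import pandas as pd

from bioage import cmr_score

panel = pd.DataFrame(
    {
        "glucose": [4.8, 5.1, 5.6, 5.0, 5.3],  # mmol/L
        "hdl": [1.7, 1.4, 1.0, 1.5, 1.2],      # mmol/L
        "ldl": [1.8, 2.2, 3.0, 2.0, 2.6],      # mmol/L
        "sbp1": [108, 115, 126, 111, 119],     # mmHg
        "sbp2": [110, 113, 128, 113, 121],
        "dbp1": [62, 66, 74, 63, 70],
        "dbp2": [60, 68, 72, 65, 68],
    }
)
out = cmr_score(panel)
print(out[["map", "z_inv_hdl", "z_ldl", "z_glucose", "z_map", "cmr", "risk_class"]].round(2))
print("Child 2 (low HDL, high LDL/BP) carries the highest composite risk.")
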