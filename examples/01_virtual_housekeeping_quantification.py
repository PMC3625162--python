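"""Quantify a small Ct table with the virtual-housekeeping (card-median) stack.

Builds a toy two-card Ct table, applies the 35-cycle cut-off, aligns the card
medians, and converts ΔΔCt (centered on the per-assay mean) to relative
quantities.  The printed geometric means show the normalization guarantee:
each assay's present RQ values multiply out to 1.
"""

import numpy as np
import pandas as pd

import zygoct as z

values = pd.DataFrame(
    {
        "S1": {"Anxa8": 24.1, "Fbn1": 27.0, "Mfap5": 22.4, "Rgs16": 36.2},
        "S2": {"Anxa8": 25.3, "Fbn1": 26.1, "Mfap5": 23.0, "Rgs16": 33.9},
        "S3": {"Anxa8": 23.8, "Fbn1": 28.2, "Mfap5": 21.9, "Rgs16": 34.8},
        "S4": {"Anxa8": 24.9, "Fbn1": 26.8, "Mfap5": 22.1, "Rgs16": 35.6},
    }
)
cards = pd.Series({"S1": "cardA", "S2": "cardA", "S3": "cardB", "S4": "cardB"})
ct = z.CtMatrix(values, cards)

trimmed = z.apply_ct_cutoff(ct, 35.0)
print(f"non-detects after 35-Ct cut-off: {(~trimmed.detect_mask).to_numpy().sum()}"
      " (late Rgs16 reactions discarded)")

corrected, factors = z.card_median_correction(trimmed)
print(f"shared card median (virtual housekeeping Ct): {factors.target:.3f}")
print("per-card additive corrections (cycles):")
print(factors.offsets.to_string())

rq = z.delta_delta_ct(z.delta_ct(corrected))
print("\nrelative quantities (RQ = 2^-ΔΔCt; >1 = above the assay's own mean):")
print(rq.rq.round(3).to_string())

gm = np.exp2(np.log2(rq.rq).mean(axis=1, skipna=True))
print("\nper-assay geometric mean of present RQ (1 by construction):")
print(gm.round(9).to_string())
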