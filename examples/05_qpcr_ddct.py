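"""Relative qPCR quantification with the 2^-ddCt method (U6-normalised).

dCt = Ct(target) - Ct(U6) per sample; ddCt = mean dCt(group) - mean
dCt(calibrator); fold = 2^-ddCt, so the water calibrator is 1 by definition.
"""

import pandas as pd

from mirforge.diffexpr import ddct

rows = []
for sample, group, mir_ct, u6_ct in [
    ("w1", "H2O", 25.1, 20.0), ("w2", "H2O", 24.9, 19.9),
    ("n1", "NaCl", 23.2, 20.1), ("n2", "NaCl", 23.0, 19.8),
    ("c1", "Na2CO3", 26.9, 20.0), ("c2", "Na2CO3", 27.1, 20.2),
]:
    rows.append({"sample": sample, "group": group, "target": "zma-miR001-5p", "ct": mir_ct})
    rows.append({"sample": sample, "group": group, "target": "U6", "ct": u6_ct})

folds = ddct(pd.DataFrame(rows), reference="U6", calibrator="H2O")
print(folds.round(3))
# NaCl Ct drops ~2 cycles below water after U6 normalisation -> ~4x up;
# Na2CO3 rises ~2 cycles -> ~0.25x (down).
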