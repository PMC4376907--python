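"""Pick the number of clusters with Evanno's ΔK.

Takes replicate log-likelihoods from an external clustering tool (here a
synthetic table with a clear knee at K = 2) and computes the Evanno table:
L'(K), |L''(K)| and ΔK = |L''(K)| / sd(L(K)). The K with the largest ΔK is
the supported cluster count.
"""

import pandas as pd

from gbskit import delta_k

rows = []
for k, mean_l in ((1, -500.0), (2, -300.0), (3, -290.0), (4, -288.0)):
    for rep, offset in enumerate((-2.0, 0.0, 2.0)):  # sd(L(K)) = 2
        rows.append((k, rep + 1, mean_l + offset))
table = pd.DataFrame(rows, columns=["K", "replicate", "logL"])

best, full = delta_k(table)
print(full.to_string(index=False))
print(f"\nbest K = {best}")
print("ΔK peaks where the likelihood gain collapses — the knee of L(K).")
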