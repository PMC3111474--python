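"""Motif scanning and the sequence evidence for a regulatory state.

Builds a sharp 8-bp PSSM, plants two copies of its consensus in a random
500 bp promoter window, scans both strands, and shows how the scan's
sufficient statistics (N_b background bases, N_m motifs, log R) convert
into the log-likelihood difference favouring 'this gene is a target'.
"""

import numpy as np

from tnevo import SequenceModelParams, build_pssm, scan_window, seq_loglik_difference
from tnevo.motif import select_best_window

rng = np.random.default_rng(0)
probs = np.full((8, 4), 0.1 / 3)
for i, b in enumerate("ACGTACGT"):
    probs[i, "ACGT".index(b)] = 0.9
pssm = build_pssm(probs)
params = SequenceModelParams(q=0.01, threshold=0.8)

background = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
window = background[:120] + pssm.consensus() + background[128:300] + pssm.consensus() + background[308:]

scan = scan_window(window, pssm, params)
print(f"Called motifs: {scan.n_motifs} at", [(h.start, h.strand) for h in scan.hits])
print(f"Background bases N_b = {scan.n_background}, summed hit score log R = {scan.log_r:.2f}")

diff = seq_loglik_difference(scan, params)
print(f"log P(S|target) - log P(S|non-target) = {diff:.2f}")
print("  (positive: the window's motif content outweighs the q-penalty on motif states)")

# a 5 kb region: the best 500 bp sliding window represents the whole region
rng2 = np.random.default_rng(1)
region = "".join("ACGT"[i] for i in rng2.integers(0, 4, size=5000))
region = region[:3210] + pssm.consensus() + region[3218:]
best = select_best_window(region, pssm, params, window_size=500, step=250)
hit_starts = [h.start for h in best.hits]
print(f"\nBest window of the 5 kb region: [{best.start}, {best.end}) "
      f"with {best.n_motifs} hit(s) at {hit_starts} -- the planted site is at 3210")
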