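"""4DTv divergence between simulated homologous CDS pairs.

Simulates pairs at two known transversion distances (mimicking a recent
speciation and an old duplication), corrects with the HKY transversion
component, and reads the modes of the pooled distribution.
"""

import numpy as np

import phyloconv as pc

records = []
for d_true, n_pairs, seed0 in ((0.08, 60, 100), (0.90, 60, 500)):
    for i in range(n_pairs):
        pair = pc.simulate_codon_pair(
            d_true, np.full(4, 0.25), n_codons=800, seed=seed0 + i
        )
        records.append(pc.pairwise_4dtv(pair))

finite = [r for r in records if r.corrected_defined]
summ = pc.summarize_4dtv(finite, bin_width=0.05)
mean_lo = np.mean([r.corrected_4dtv for r in finite if r.corrected_4dtv < 0.5])
mean_hi = np.mean([r.corrected_4dtv for r in finite if r.corrected_4dtv >= 0.5])
print(f"{len(finite)}/{len(records)} pairs with a defined correction")
print(f"mean corrected 4DTv, young component: {mean_lo:.3f} (true 0.08)")
print(f"mean corrected 4DTv, old component:   {mean_hi:.3f} (true 0.90)")
print(f"histogram modes (bin width 0.05): {[round(m, 3) for m in summ['modes']]}")
print(
    "Peaks in the corrected 4DTv distribution date divergence events: a\n"
    "low-4DTv peak reflects a recent split, a high one an ancient\n"
    "duplication such as a whole-genome duplication."
)
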