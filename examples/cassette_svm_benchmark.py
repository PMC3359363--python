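"""Leave-one-extein-out ranking of native cassettes with the linear SVM.

Builds a family of synthetic exteins whose native insertion-site cassettes
share a two-residue motif (G at -1, P at +2).  For each held-out extein a
class-weighted linear SVM (positive errors x3) is trained on the other
exteins' native cassettes plus 3 freshly sampled decoys each, and the
native site is ranked against the held-out extein's decoy sites (1 = above
every decoy).  The label-shuffled control trains on mislabelled sites and
should rank at chance.
"""

import numpy as np

from inteinsite import planted_motif_benchmark

seeds = range(5)
planted = [planted_motif_benchmark(seed=s) for s in seeds]
shuffled = [planted_motif_benchmark(seed=s, shuffled=True) for s in seeds]

print("mean native rank per seed (15 exteins, 12 candidate sites each):")
for s, (p, q) in enumerate(zip(planted, shuffled)):
    print(f"  seed {s}: planted motif {p:.3f}   label-shuffled {q:.3f}")
print(f"\noverall: planted {np.mean(planted):.3f}, shuffled {np.mean(shuffled):.3f}")
print("a rank near 1 means the model puts the native cassette above nearly")
print("every decoy; the shuffled control near 0.5 confirms the signal is the")
print("cassette motif, not an artefact of the protocol.")
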