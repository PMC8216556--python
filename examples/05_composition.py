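"""Amino-acid composition comparison between protein sets.

Compares the per-protein percent composition of two sequence sets with a
two-sample t-test per residue — the analysis used to ask whether proteins
upregulated at high temperature favor particular residues (e.g. charged
ones).  Here one set is artificially enriched in glutamate.
"""

import numpy as np

from thermoglyco.composition import aa_composition, compare_composition

rng = np.random.default_rng(4)
aas = list("ACDFGHIKLMNPQRSTVWY")  # E excluded from the baseline alphabet
baseline = ["".join(rng.choice(aas, size=300)) for _ in range(25)]
glu_rich = []
for _ in range(25):
    s = list(rng.choice(aas, size=300))
    for i in rng.choice(300, size=25, replace=False):
        s[i] = "E"
    glu_rich.append("".join(s))

prof = aa_composition(glu_rich)
print(f"profile of the Glu-rich set: mean percents sum to "
      f"{prof['mean_percent'].sum():.1f}")

cmp = compare_composition(glu_rich, baseline).sort_values("p_value")
print(f"\n{'residue':<8} {'set A %':>8} {'set B %':>8} {'diff':>7} {'p':>10}")
for aa, row in cmp.head(5).iterrows():
    print(f"{aa:<8} {row['mean_a']:>8.2f} {row['mean_b']:>8.2f} "
          f"{row['difference']:>7.2f} {row['p_value']:>10.2e}")
print("\nGlutamate tops the list: its planted ~8% excess is recovered with")
print("a vanishing p-value; unperturbed residues sit near p = 1.")
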