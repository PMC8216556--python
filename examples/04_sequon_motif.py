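"""N-X-S/T sequon detection and the +/-10 occupancy-frequency matrix.

Scans a sequence for glycosylation sequons (X may not be proline;
overlapping sequons all count), then builds the 21-position occupancy
matrix over all synthetic glycosites and prints the residue frequencies at
the +1/+2 positions and the glycoprotein site-count distribution.
"""

import thermoglyco as tg
from thermoglyco.sequon import extract_window
from thermoglyco.simulate import SimulationConfig, generate

demo = "NVTQNPSLNGS"
hits = tg.find_sequons(demo)
print(f"sequons in {demo!r}: "
      + ", ".join(f"{s.triplet}@{s.position}" for s in hits))
print("(position 5 is skipped: its X residue is proline)\n")

ds = generate(SimulationConfig(seed=8, n_proteins=300, n_glycoproteins=150,
                               n_categories=5))
windows = [extract_window(ds.proteome[s.accession], s.position) for s in ds.sites]
mat = tg.occupancy_matrix(windows)
print(f"{len(windows)} glycosite windows; occupancy at key positions:")
print(f"  S at +2: {mat.at['S', 2]:.2f}   T at +2: {mat.at['T', 2]:.2f} "
      "(every site sits in N-X-S/T, so these sum to 1)")
print(f"  P at +1: {mat.at['P', 1]:.2f} (proline is forbidden at X)\n")

dist = tg.site_count_distribution(ds.sites)
print("fraction of glycoproteins by number of sites:")
for b, f in dist.items():
    print(f"  {b:>2} site(s): {f:.2f}")
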