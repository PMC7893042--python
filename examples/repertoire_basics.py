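"""Build a clonotype table from rearrangement records and summarise it.

Generates an oligoclonal repertoire (a few massively expanded clones over a
diverse tail), then prints the frequency spectrum head, the repertoire mass
carried by clones expanded above 1%, and the frequency histogram.
"""

from tcrshare import (fraction_above, frequency_histogram, frequency_spectrum,
                      generate_repertoire)

rep, truth = generate_repertoire(n_clones=200, distribution=("geometric", 0.9),
                                 n_reads=20_000, seed=7, sample_id="Treg_PB")

print(f"repertoire {rep.sample_id}: {rep.n_clonotypes} clonotypes from "
      f"{rep.total_count} in-frame sequences")

print("\ntop 5 clonotypes (frequency spectrum):")
for key, freq in frequency_spectrum(rep)[:5]:
    print(f"  {key[:18]}...  {freq:.4f}")

mass = fraction_above(rep, 0.01)
print(f"\nmass of clonotypes expanded above 1%: {mass:.3f}")
print("-> the fraction of the repertoire carried by expanded clones; values "
      "near 0.8 indicate strong oligoclonal dominance.")

histogram = frequency_histogram(rep)
print(f"\nfrequency histogram has {len(histogram)} distinct frequency groups; "
      f"largest group: {histogram[-1][1]} clonotypes at frequency "
      f"{histogram[-1][0]:.5f}")
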