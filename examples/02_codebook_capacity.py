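"""Virtual-channel encoding: codes, theoretical ratios and capacity.

Two detection spectral channels with up to three repeats of the same DFP
sequence give nine virtual codes per imaging round; a single-channel ladder
of 1-10 repeats spans theoretical ratios 0.1 to 1.0.
"""

from nanoladder import (
    ChannelConfig,
    assign_codebook,
    capacity,
    enumerate_codes,
    theoretical_ratio,
)
from nanoladder.simulate import DEFAULT_GENE_PANEL

nineplex = ChannelConfig(n_detection_channels=2, n_levels=3)
print(f"codes per round: {capacity(nineplex, 1)}")
print(f"two imaging rounds: {capacity(nineplex, 2)} transcripts")

codebook = assign_codebook(list(DEFAULT_GENE_PANEL), nineplex)
print("\ngene -> (De1, De2) repeat levels -> theoretical De/Re ratios")
for gene, code in codebook.assignments.items():
    ratios = theoretical_ratio(code, nineplex)
    print(f"  {gene:6s} {code.levels}  ->  ({ratios[0]:.3f}, {ratios[1]:.3f})")

ladder = ChannelConfig(n_detection_channels=1, n_levels=10)
print("\nsingle-channel 1-10 DFP ladder (max-normalized):")
for code in enumerate_codes(ladder):
    print(f"  barcode {code.levels[0]:2d}: ratio {theoretical_ratio(code, ladder)[0]:.1f}")
print("The smallest barcode's expected ratio is 0.1 — one DFP against a 10-DFP maximum.")
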