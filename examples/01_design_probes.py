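"""Design circular DNAzyme probes for a target RNA and its negative controls.

Builds a random 300-nt target, finds purine-pyrimidine cleavage junctions,
designs the matched circular probe, emits the SNV / MM12 / core-deleted
controls, and screens specificity against the controls' substrates.
"""

import numpy as np

from nanoladder import (
    TargetTranscript,
    design_circular_dnazyme,
    emit_padlock_linker,
    find_cleavage_sites,
    make_control_variant,
    probe_sheet,
    rank_cleavage_sites,
    screen_specificity,
)

rng = np.random.default_rng(42)
target = TargetTranscript("THBS1_fragment", "".join(rng.choice(list("ACGU"), 300)))

sites = rank_cleavage_sites(find_cleavage_sites(target, arm_len=20))
best = next(s for s in sites if s.flank_ok)
print(f"{len(sites)} R-Y junctions; designing at position {best.position} ({best.dinucleotide})")

probe = design_circular_dnazyme(target, best)
print(probe_sheet([probe]).to_string(index=False))

padlock, linker = emit_padlock_linker(probe)
print(f"\npadlock ({len(padlock)} nt) circularizes with linker {linker}")

# negative-control substrates: mutations land inside the 40-nt recognition
# region the arms cover (SNV in its middle, MM12 spread across it)
region = (best.position + 1 - 20, best.position + 1 + 20)
snv_rna = make_control_variant(target, "SNV", seed=1, region=region)
mm12_rna = make_control_variant(target, "MM12", seed=1, region=region)
report = screen_specificity(probe, [target, snv_rna, mm12_rna])
print("\nSpecificity screen (cleavage requires a mismatch-free junction window):")
print(report.to_string(index=False))
print(
    "\nOnly the matched substrate stays cleavage-competent: central mismatches "
    "abolish DNAzyme activity, which is what makes the probe SNV-discriminating."
)
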