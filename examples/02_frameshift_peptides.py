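"""From a coding sequence to its M1/M2 frameshift peptides.

Plants a 10-base A-run in a random in-frame CDS, finds it, and builds
the frameshift peptides produced by one- and two-base deletions.
"""

from msiedit import (
    find_coding_microsatellites,
    generate_frameshift_peptides,
    simulate_cds,
)

cds, locus = simulate_cds("TGFBR2", repeat_base="A", repeat_length=10, seed=42)
print(f"CDS length {len(cds.sequence)} nt; wild-type protein:")
print("  ", cds.translate())

(found,) = find_coding_microsatellites(cds)
print(f"found cMS: {found.repeat_base}x{found.repeat_length} at CDS offset {found.cds_offset}")

for pep in generate_frameshift_peptides(cds, locus):
    print(f"{pep.frame}: wt-prefix {pep.wt_prefix!r} + neo ({pep.neo_length} aa) "
          f"{pep.neo_sequence!r}" + ("  [no stop before CDS end]" if pep.no_stop else ""))
# The M1 peptide arises from a 1-base deletion (reading frame shifted by
# -1), M2 from a 2-base deletion; each carries up to 8 wild-type residues
# upstream of the divergence point so junction-spanning epitopes are kept.
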