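"""Project a reference coding region onto an isotig and locate PTCs.

Aligns an isotig against its reference transcript (semi-global, affine
gaps), maps the CDS through the alignment, translates in the projected frame
and reports completeness (>75% of the reference CDS aligned) and premature
termination codons.
"""

from isopipe import orfproj
from isopipe.syndata import SimConfig, generate_reference_panel

cfg = SimConfig(seed=4, n_genes=3)
panel = generate_reference_panel(cfg)
model = next(m for m in panel.models if m.species == "mouse")
cs, ce = model.cds_on_transcript

# 1) the reference itself round-trips
orf = orfproj.project_orf("self", model.transcript_seq, model.transcript_id,
                          model.transcript_seq, model.cds_on_transcript)
print(f"reference round-trip : fraction {orf.aligned_cds_fraction:.2f}, "
      f"protein {len(orf.protein)} aa, PTC {orf.ptc}")

# 2) a 5'-half fragment projects half the CDS
half = model.transcript_seq[: cs + (ce - cs) // 2]
orf = orfproj.project_orf("half", half, model.transcript_id,
                          model.transcript_seq, model.cds_on_transcript)
print(f"5' half fragment     : fraction {orf.aligned_cds_fraction:.2f}, "
      f"complete75 {orf.complete75}")

# 3) a nonsense mutation at codon 10 is located exactly
pos = cs + 30
mutated = model.transcript_seq[:pos] + "TGA" + model.transcript_seq[pos + 3:]
orf = orfproj.project_orf("ptc", mutated, model.transcript_id,
                          model.transcript_seq, model.cds_on_transcript)
print(f"nonsense at codon 10 : PTC {orf.ptc} at isotig position "
      f"{orf.ptc_position} (codon {(orf.ptc_position - cs) // 3}), "
      f"protein truncated to {len(orf.protein)} aa")

# The PTC position is the isotig coordinate of the premature stop codon; a
# stop at the position aligned to the reference stop is a normal terminus.
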