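"""Feature annotation: TM segments, disorder, motifs, amphipathic helices.

Builds a protein with known planted features and shows that each windowed
predictor reports them with 1-based coordinates. The disorder score is a
logistic blend of charge, flexibility and (negative) hydropathy; the
hydrophobic moment measures amphipathy on an ideal helical wheel (100
degrees per residue).
"""

from orthoprof import (
    amphipathic_scan,
    detect_caax,
    detect_wxxxfy,
    predict_disorder,
    predict_tm,
)
from orthoprof.seqsim import amphipathic_pattern

protein = (
    "MKSDE" + "EKSPQDRG" * 5          # disordered N-terminal stretch
    + "LLILVVLAFILLVAILLGVIL"          # transmembrane helix (21 aa)
    + "GSGS" + amphipathic_pattern(18)  # amphipathic helix
    + "AAWKDEFNQ"                       # WxxxF motif (W...F spacing)
    + "KQCVIS"                          # C-terminal CaaX box
)

tm = predict_tm(protein)
print(f"TM segments: {tm} (planted helix spans ~{protein.find('LLILV')+1}-"
      f"{protein.find('LLILV')+21})")

scores, calls = predict_disorder(protein)
print(f"disordered runs: {calls}; mean score {scores.mean():.2f} "
      "(1 = confidently disordered)")

caax = detect_caax(protein)
print(f"CaaX box: {caax.text} at {caax.start}-{caax.end} "
      "(C-terminal prenylation signal)")

w = detect_wxxxfy(protein)
print(f"WxxxF/Y motifs at starts: {[m.start for m in w]}")

helix_hits = amphipathic_scan(protein, moment_min=0.35)
if helix_hits:
    start, mean_h, mu = max(helix_hits, key=lambda x: x[2])
    print(f"strongest amphipathic window: start {start}, mean hydrophobicity "
          f"{mean_h:.2f}, moment {mu:.2f} (>0.35 marks a segregated helix face)")
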