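"""Dataset-construction filters: structure matching and redundancy removal.

Applies the six-criteria structure-match filter to a small hit table and
CD-HIT cluster-based redundancy removal to a toy variant list.
"""

import savpred as sp
from savpred.dataset_rules import (
    BlastHit,
    apply_redundancy_clusters,
    filter_structure_matches,
)

hits = [
    BlastHit("Q1", "GOOD_XRAY", 1e-80, 95.0, 99.0, "Homo sapiens",
             "X-RAY DIFFRACTION", True),
    BlastHit("Q1", "GOOD_NMR", 1e-90, 97.0, 99.0, "Homo sapiens",
             "SOLUTION NMR", True),
    BlastHit("Q1", "WEAK_EVALUE", 1e-40, 95.0, 99.0, "Homo sapiens",
             "X-RAY DIFFRACTION", True),
    BlastHit("Q1", "LOW_IDENTITY", 1e-80, 80.0, 99.0, "Homo sapiens",
             "X-RAY DIFFRACTION", True),
    BlastHit("Q1", "MOUSE", 1e-80, 95.0, 99.0, "Mus musculus",
             "X-RAY DIFFRACTION", True),
]
survivors = filter_structure_matches(hits)
print("surviving structure matches:", [h.subject_id for h in survivors])
print("(e-value < 1e-50 and identity > 80 are strict; among survivors the"
      " X-ray entry outranks the NMR one)\n")

clusters = {
    "Cluster 0": [("PROT_LONG", 300), ("PROT_SHORT", 120)],
    "Cluster 1": [("PROT_SOLO", 80)],
}
records = [
    sp.SAVRecord("PROT_LONG", "A", 10, 10, "A", "V", "cancer"),
    sp.SAVRecord("PROT_SHORT", "A", 5, 5, "R", "C", "neutral"),
    sp.SAVRecord("PROT_SOLO", "A", 3, 3, "G", "W", "cancer"),
]
kept = apply_redundancy_clusters(records, clusters)
print("variants kept after redundancy removal:",
      [(r.protein_id, f"{r.wt}{r.seq_pos}{r.mut}") for r in kept])
print("(one representative protein per 30%-identity cluster, longest sequence)")
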