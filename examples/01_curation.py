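"""Filter a candidate homolog set the way the reconstruction dataset is
built: identity/coverage/E-value thresholds, a minimum full-length cutoff,
and removal of re-collected duplicates."""

from ancres import HitRecord, deduplicate, filter_hits, filter_length

hits = [
    HitRecord("kidney_paralog", pident=88.0, qcov=96.0, evalue=0.0, length=532),
    HitRecord("liver_paralog", pident=54.0, qcov=90.0, evalue=0.0, length=535),
    HitRecord("distant_homolog", pident=62.0, qcov=75.0, evalue=0.0, length=540),
    HitRecord("weak_hit", pident=70.0, qcov=90.0, evalue=1e-180, length=530),
]
report = filter_hits(hits)
print("hit filter kept:", report.kept)
print("hit filter discarded:", report.discarded)
# Only hits with >55% identity, >80% coverage AND E-value 0.0 survive; the
# discard reason names the first threshold each candidate failed.

seqs = [
    ("kidney_paralog", "M" * 532),
    ("fragment", "M" * 509),          # partial sequence, one residue short
    ("kidney_copy", "M" * 532),       # re-collected duplicate
]
length_report = filter_length(seqs)
print("length filter kept:", length_report.kept)
dedup = deduplicate([s for s in seqs if s[0] in set(length_report.kept)])
print("after deduplication:", dedup.kept, "| dropped:", dedup.discarded)
# Sequences shorter than 510 residues are treated as partial and excluded;
# byte-identical sequences keep only their first-seen id.
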