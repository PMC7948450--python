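"""Dataset-construction filters applied to candidate homolog sets before
alignment: identity/coverage/E-value thresholds on search hits, a minimum
ungapped length, and exact-duplicate removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

_REASONS = ("identity", "coverage", "evalue", "length", "duplicate")


@dataclass
class HitRecord:
    """One similarity-search hit."""

    id: str
    pident: float          # percent identity, 0-100
    qcov: float            # percent query coverage, 0-100
    evalue: float
    length: int
    sequence: str | None = None

    def __post_init__(self):
        if not (0 <= self.pident <= 100):
            raise ValueError(f"{self.id}: pident {self.pident} outside [0, 100]")
        if not (0 <= self.qcov <= 100):
            raise ValueError(f"{self.id}: qcov {self.qcov} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"{self.id}: negative E-value")
        if self.length < 1:
            raise ValueError(f"{self.id}: non-positive length")


@dataclass
class CurationReport:
    """Partition of the input into kept ids and (id, reason) discards."""

    kept: list[str] = field(default_factory=list)
    discarded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        bad = {r for _, r in self.discarded} - set(_REASONS)
        if bad:
            raise ValueError(f"unknown discard reasons: {sorted(bad)}")

    @property
    def discarded_ids(self) -> list[str]:
        return [i for i, _ in self.discarded]

    def to_dict(self) -> dict:
        return {"kept": self.kept,
                "discarded": [{"id": i, "reason": r}
                              for i, r in self.discarded]}


def read_hit_table(path) -> list[HitRecord]:
    """Read a TSV hit table with columns id, pident, qcov, evalue, length."""
    df = pd.read_csv(path, sep="\t")
    required = ["id", "pident", "qcov", "evalue", "length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    hits = []
    for idx, row in df.iterrows():
        try:
            hits.append(HitRecord(
                id=str(row["id"]), pident=float(row["pident"]),
                qcov=float(row["qcov"]), evalue=float(row["evalue"]),
                length=int(row["length"]),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"hit table row {idx + 1}: {exc}") from exc
    return hits


def filter_hits(hits: list[HitRecord], min_identity: float = 55.0,
                min_coverage: float = 80.0,
                max_evalue: float = 0.0) -> CurationReport:
    """Keep hits with identity and coverage strictly above the thresholds and
    E-value at or below the cap.

    The discard reason records the first failing criterion in the order
    identity, coverage, E-value.
    """
    if not hits:
        raise ValueError("empty hit list")
    report = CurationReport()
    for hit in hits:
        if not hit.pident > min_identity:
            report.discarded.append((hit.id, "identity"))
        elif not hit.qcov > min_coverage:
            report.discarded.append((hit.id, "coverage"))
        elif not hit.evalue <= max_evalue:
            report.discarded.append((hit.id, "evalue"))
        else:
            report.kept.append(hit.id)
    return report


def filter_length(seqs, min_length: int = 510) -> CurationReport:
    """Exclude partial sequences shorter than ``min_length`` residues.

    Applies to ungapped sequences (pre-alignment); gapped input is an error.
    """
    report = CurationReport()
    for name, seq in seqs:
        if "-" in seq or "." in seq:
            raise ValueError(
                f"{name}: sequence contains gap characters; the length "
                "filter applies before alignment")
        if len(seq) >= min_length:
            report.kept.append(name)
        else:
            report.discarded.append((name, "length"))
    return report


def deduplicate(seqs) -> CurationReport:
    """Drop byte-identical re-collections (after uppercasing), keeping the
    first-seen id; input order is preserved."""
    report = CurationReport()
    seen: dict[str, str] = {}
    for name, seq in seqs:
        key = seq.upper()
        if key in seen:
            report.discarded.append((name, "duplicate"))
        else:
            seen[key] = name
            report.kept.append(name)
    return report
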