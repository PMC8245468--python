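"""Dataset-construction filters over pre-computed alignment/cluster outputs.

Structure matching keeps BLAST hits satisfying, with strict inequalities:
e-value < 1e-50, sequence identity > 80%, alignment coverage of the subject
structure > 95%, organism Homo sapiens, and a consistent SAV position in the
alignment; among a query's survivors, X-ray structures are preferred over
other experimental methods. Redundancy removal consumes CD-HIT ``.clstr``
output and keeps one representative protein per cluster.

The BLAST hit table is a TSV with a header naming the columns
``query_id  subject_id  e_value  identity_pct  coverage_pct  organism
method  sav_position_consistent`` (the last column 0/1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import FormatError, SAVRecord

E_VALUE_MAX = 1e-50
IDENTITY_MIN = 80.0
COVERAGE_MIN = 95.0
ORGANISM = "Homo sapiens"
XRAY = "X-RAY DIFFRACTION"


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    e_value: float
    identity_pct: float
    coverage_pct: float
    organism: str
    method: str
    sav_position_consistent: bool

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e-value must be non-negative")
        for pct in (self.identity_pct, self.coverage_pct):
            if not 0 <= pct <= 100:
                raise ValueError("percentages must lie in [0, 100]")


def read_blast_hits(path: str | Path) -> list[BlastHit]:
    df = pd.read_csv(path, sep="\t")
    required = [
        "query_id", "subject_id", "e_value", "identity_pct",
        "coverage_pct", "organism", "method", "sav_position_consistent",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"BLAST hit table missing columns: {missing}")
    return [
        BlastHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            e_value=float(r.e_value),
            identity_pct=float(r.identity_pct),
            coverage_pct=float(r.coverage_pct),
            organism=str(r.organism),
            method=str(r.method),
            sav_position_consistent=bool(int(r.sav_position_consistent)),
        )
        for r in df.itertuples()
    ]


def filter_structure_matches(hits: Sequence[BlastHit]) -> list[BlastHit]:
    """Apply the five hard criteria, then prefer X-ray entries per query."""
    survivors = [
        h
        for h in hits
        if h.e_value < E_VALUE_MAX
        and h.identity_pct > IDENTITY_MIN
        and h.coverage_pct > COVERAGE_MIN
        and h.organism == ORGANISM
        and h.sav_position_consistent
    ]
    xray_queries = {h.query_id for h in survivors if h.method == XRAY}
    return [
        h for h in survivors if h.method == XRAY or h.query_id not in xray_queries
    ]


# ---------------------------------------------------------------------------
# redundancy clusters

_CLSTR_MEMBER = re.compile(r"^\d+\s+(\d+)(?:aa|nt),\s+>(\S+?)\.\.\.")


def read_clstr(path: str | Path) -> dict[str, list[tuple[str, int]]]:
    """Parse CD-HIT ``.clstr`` output: cluster id -> [(member id, length)]."""
    clusters: dict[str, list[tuple[str, int]]] = {}
    current: str | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            current = line[1:].strip()
            clusters[current] = []
        elif line.strip():
            m = _CLSTR_MEMBER.match(line)
            if m is None or current is None:
                raise FormatError(f"malformed .clstr line: {line!r}")
            clusters[current].append((m.group(2), int(m.group(1))))
    return clusters


def cluster_representatives(
    clusters: Mapping[str, Sequence[tuple[str, int]]]
) -> set[str]:
    """Longest member per cluster; ties by identifier order."""
    reps = set()
    for members in clusters.values():
        reps.add(min(members, key=lambda t: (-t[1], t[0]))[0])
    return reps


def apply_redundancy_clusters(
    records: Sequence[SAVRecord],
    clusters: Mapping[str, Sequence[tuple[str, int]]],
) -> list[SAVRecord]:
    """Keep SAVs on each cluster's representative protein only."""
    member_map: dict[str, str] = {}
    for cid, members in clusters.items():
        for pid, _ in members:
            member_map[pid] = cid
    for r in records:
        if r.protein_id not in member_map:
            raise KeyError(f"protein {r.protein_id} not present in cluster assignment")
    reps = cluster_representatives(clusters)
    return [r for r in records if r.protein_id in reps]
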