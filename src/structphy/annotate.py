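"""Functional annotation by closest structural homologue.

Queries are aligned against every member of an annotated reference
library; hits are ranked by elastic Z-score and classified against the
two significance thresholds used throughout the pipeline: a top hit with
Z > 4 is a significant structural homologue (eligible for functional
aggregation), 2 <= Z <= 4 is a weak hit (reported but excluded from
aggregation), and Z < 2 means no structural homologue.  Both boundaries
are strict, following the "Z-score > 4" significance rule and the
"Z-score = 2" no-homologue convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from structphy.daliscore import (
    elastic_raw_score,
    percent_identity_structural,
    z_from_score,
)
from structphy.structio import Structure
from structphy.superpose import structural_align
from structphy.treebuild import pairwise_sequence_identity

SIGNIFICANT_Z = 4.0
NO_HOMOLOGUE_Z = 2.0

SIGNIFICANT = "significant"
WEAK = "weak"
NO_HOMOLOGUE = "no_homologue"


@dataclass
class HomologueHit:
    query_id: str
    library_id: str
    z: float
    tm: float
    percent_id_structure: float
    percent_id_sequence: float
    category: str


def search_homologues(
    query: Structure,
    library: Sequence[Structure],
    annotations: Mapping[str, str] | pd.DataFrame,
    calibration="polynomial",
) -> list[HomologueHit]:
    """Rank library entries by elastic Z against the query.

    ``annotations`` maps every library id to a functional category (or is
    a DataFrame with ``id``/``category`` columns).  Hits are sorted by Z
    descending, ties broken by library id.
    """
    if not len(library):
        raise ValueError("empty library")
    if isinstance(annotations, pd.DataFrame):
        annotations = dict(zip(annotations["id"], annotations["category"]))
    unannotated = sorted({s.id for s in library} - set(annotations))
    if unannotated:
        raise ValueError(f"unannotated library ids: {unannotated}")
    hits = []
    for member in library:
        res = structural_align(query, member)
        if res.unalignable:
            z, tm, pid_s = float("-inf"), 0.0, 0.0
        else:
            S = elastic_raw_score(query, member, res.correspondence)
            z = z_from_score(S, len(query), len(member), calibration)
            tm = res.tm_score
            pid_s = percent_identity_structural(
                query.sequence, member.sequence, res.correspondence
            )
        pid_q, _ = pairwise_sequence_identity(query.sequence, member.sequence)
        hits.append(HomologueHit(
            query_id=query.id,
            library_id=member.id,
            z=z,
            tm=tm,
            percent_id_structure=pid_s,
            percent_id_sequence=100.0 * pid_q,
            category=annotations[member.id],
        ))
    hits.sort(key=lambda h: (-h.z, h.library_id))
    return hits


def classify_hit(hits: Sequence[HomologueHit]) -> str:
    """Classify a query from its sorted hit list (strict Z boundaries)."""
    if not hits:
        return NO_HOMOLOGUE
    top = hits[0].z
    if top > SIGNIFICANT_Z:
        return SIGNIFICANT
    if top < NO_HOMOLOGUE_Z:
        return NO_HOMOLOGUE
    return WEAK


def aggregate_functions(
    hits_per_query: Mapping[str, Sequence[HomologueHit]]
) -> pd.DataFrame:
    """Count top-hit functional categories over significantly matched queries.

    Weak hits are excluded from the aggregation entirely; queries without
    a significant hit are tallied under ``no_homologue``/``weak``.
    """
    counts: dict[str, int] = {}
    status_counts = {SIGNIFICANT: 0, WEAK: 0, NO_HOMOLOGUE: 0}
    for _, hits in sorted(hits_per_query.items()):
        status = classify_hit(list(hits))
        status_counts[status] += 1
        if status == SIGNIFICANT:
            cat = hits[0].category
            counts[cat] = counts.get(cat, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items()), columns=["category", "count"]
    )
    table.attrs["status_counts"] = status_counts
    return table


def hits_table(hits: Sequence[HomologueHit]) -> pd.DataFrame:
    """Hit report with homologue, Z-score, annotation and identity columns."""
    return pd.DataFrame([{
        "query": h.query_id,
        "homologue": h.library_id,
        "z_score": h.z,
        "tm_score": h.tm,
        "annotation": h.category,
        "pct_id_structure": h.percent_id_structure,
        "pct_id_sequence": h.percent_id_sequence,
    } for h in hits])
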