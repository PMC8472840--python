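"""Distance-based assignment of query ASVs to reference genera.

Each query is globally aligned to every reference amplicon of one region and
scored by uncorrected identity. The call is the top genus when it is unique
within the tie tolerance and reaches the identity floor; ties are reported
honestly as a named ambiguity group (e.g. "Aminobacter-Mesorhizobium")
rather than resolved by external evidence.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import pandas as pd

from ._iupac import normalize_sequence
from .insilico_pcr import AmpliconRecord
from .pairwise import global_align, identity
from .reference_model import ReferenceTaxon

DEFAULT_IDENTITY_FLOOR = 0.90
DEFAULT_TIE_TOL = 0.0
_EPS = 1e-12


@dataclasses.dataclass
class AssignmentRecord:
    """Ranked reference hits and the resulting genus call for one query."""

    query_id: str
    region_label: str
    ranked_hits: list[tuple[str, float, str]]  # (genus, identity, taxon_id)
    call: str | None
    status: str  # unambiguous | tied | below_floor


def _genus_of(taxon_id: str, genus_map: Mapping[str, str] | None) -> str:
    if genus_map and taxon_id in genus_map:
        return genus_map[taxon_id]
    return taxon_id


def assign_by_distance(
    query: str,
    reference_amplicons: Sequence[AmpliconRecord],
    *,
    gap_policy: str = "pairwise_deletion",
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    tie_tol: float = DEFAULT_TIE_TOL,
    query_id: str = "query",
    genus_map: Mapping[str, str] | None = None,
) -> AssignmentRecord:
    """Assign one query sequence against one region's reference amplicons.

    Hits are ranked by identity descending, ties broken lexicographically by
    reference taxon_id. ``status`` is ``tied`` when two or more distinct
    genera lie within ``tie_tol`` of the top identity; the call then
    concatenates the tied genera sorted alphabetically.
    """
    if not query:
        raise ValueError("empty query sequence")
    if not reference_amplicons:
        raise ValueError("empty reference set")
    regions = {r.region_label for r in reference_amplicons}
    if len(regions) != 1:
        raise ValueError(f"mixed regions in reference set: {sorted(regions)}")
    region = regions.pop()
    query = normalize_sequence(query, name=query_id)

    hits = []
    for rec in reference_amplicons:
        aln = global_align(query, rec.trimmed_seq)
        frac, _ = identity(aln.seq_a_aligned, aln.seq_b_aligned, gap_policy)
        if frac is None:
            continue
        hits.append((_genus_of(rec.taxon_id, genus_map), frac, rec.taxon_id))
    if not hits:
        return AssignmentRecord(query_id, region, [], None, "below_floor")
    hits.sort(key=lambda h: (-h[1], h[2]))
    top = hits[0][1]
    if top < identity_floor - _EPS:
        return AssignmentRecord(query_id, region, hits, None, "below_floor")
    top_genera = sorted({g for g, frac, _ in hits if frac >= top - tie_tol - _EPS})
    if len(top_genera) == 1:
        return AssignmentRecord(query_id, region, hits, top_genera[0], "unambiguous")
    return AssignmentRecord(query_id, region, hits, "-".join(top_genera), "tied")


def batch_assign(
    queries: Mapping[str, str] | Sequence[tuple[str, str]],
    reference_amplicons: Sequence[AmpliconRecord],
    *,
    panel: Sequence[ReferenceTaxon] | None = None,
    gap_policy: str = "pairwise_deletion",
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> tuple[list[AssignmentRecord], dict[str, int]]:
    """Assign a batch of queries; returns records (query order preserved)
    plus per-status summary counts."""
    items = list(queries.items()) if isinstance(queries, Mapping) else list(queries)
    ids = [q for q, _ in items]
    if len(set(ids)) != len(ids):
        dup = next(q for q in ids if ids.count(q) > 1)
        raise ValueError(f"duplicate query id {dup!r}")
    genus_map = {t.taxon_id: t.genus for t in panel} if panel else None
    records = [
        assign_by_distance(
            seq,
            reference_amplicons,
            gap_policy=gap_policy,
            identity_floor=identity_floor,
            tie_tol=tie_tol,
            query_id=qid,
            genus_map=genus_map,
        )
        for qid, seq in items
    ]
    summary = {"unambiguous": 0, "tied": 0, "below_floor": 0}
    for rec in records:
        summary[rec.status] += 1
    return records, summary


def assignments_to_table(records: Sequence[AssignmentRecord]) -> pd.DataFrame:
    """Tidy table: one row per query with its call, status and best hit."""
    rows = []
    for rec in records:
        best = rec.ranked_hits[0] if rec.ranked_hits else (None, float("nan"), None)
        rows.append(
            {
                "query_id": rec.query_id,
                "region": rec.region_label,
                "call": rec.call if rec.call is not None else "",
                "status": rec.status,
                "best_identity": best[1],
                "best_reference": best[2],
            }
        )
    return pd.DataFrame(rows)
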