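"""Which taxa does a V-region tell apart at a given identity cut-off?

A taxon is *uniquely distinguishable* at a cut-off when it sits in a
singleton cluster of the single-linkage partition whose edges connect pairs
with identity at or above the cut-off — equivalently, when its identity to
every other taxon falls below the cut-off. Merged-cluster composition uses
single linkage because "merged with at least one other taxon" is a pairwise
condition whose transitive closure single linkage computes; for singleton
detection every linkage criterion coincides.

The 100% cut-off is interpreted as zero observed differences over compared
sites (the single-nucleotide, ASV-level criterion), never as a rounded
0.995+. An undefined pairwise identity (no compared sites) conservatively
counts as an edge — absence of evidence of difference — and is flagged.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .insilico_pcr import extract_amplicon
from .pairwise import SimilarityMatrix, similarity_matrix
from .reference_model import ReferenceTaxon, RegionPrimerPair

DEFAULT_THRESHOLDS = (0.97, 0.99, 1.0)
_EPS = 1e-12


def _linked(sim: SimilarityMatrix, i: int, j: int, cutoff: float) -> bool:
    v = sim.values[i, j]
    if np.isnan(v):
        return True  # undefined: cannot be told apart
    if cutoff >= 1.0 - _EPS:
        return sim.zero_difference(i, j)
    return v >= cutoff - _EPS


def cluster_at_threshold(sim: SimilarityMatrix, cutoff: float) -> list[set[str]]:
    """Single-linkage partition at an identity cut-off.

    Connected components of the graph with an edge wherever identity >=
    cutoff (within 1e-12); at cutoff 1.0 an edge requires zero observed
    differences. Returned in order of each cluster's first taxon.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    n = sim.n_taxa
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if _linked(sim, i, j, cutoff):
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    order: list[int] = []
    for i in range(n):
        root = find(i)
        if root not in groups:
            groups[root] = set()
            order.append(root)
        groups[root].add(sim.taxon_ids[i])
    return [groups[r] for r in order]


def uniquely_distinguishable(sim: SimilarityMatrix, cutoff: float) -> set[str]:
    """Taxa in singleton clusters at the cut-off.

    Equal to {i : identity(i, j) < cutoff for every j != i}: a taxon with no
    incident edge is its own component, and any incident edge already forms a
    2-cluster, so linkage choice is immaterial here.
    """
    return {c for cluster in cluster_at_threshold(sim, cutoff) if len(cluster) == 1
            for c in cluster}


@dataclasses.dataclass
class RegionResult:
    """Per-region similarity matrix plus any extraction failures."""

    sim: SimilarityMatrix | None
    failed_taxa: list[str]


@dataclasses.dataclass
class DiscriminabilityGrid:
    """Region-by-threshold map of distinguishable taxa and merged groups."""

    taxon_ids: list[str]
    regions: list[str]
    thresholds: list[float]
    clusters: dict[tuple[str, float], list[set[str]]]
    flagged_pairs: dict[str, list[tuple[str, str]]]
    failed: dict[str, list[str]]

    def distinguishable(self, region: str, threshold: float) -> set[str]:
        return {t for c in self.clusters[(region, threshold)] if len(c) == 1 for t in c}

    def n_distinguishable(self, region: str, threshold: float) -> int:
        return len(self.distinguishable(region, threshold))

    def to_table(self) -> pd.DataFrame:
        """Rows = taxa, columns = region@threshold, cells 'distinct' or
        'merged:<group-id>' (group ids stable within a column)."""
        data: dict[str, list[str]] = {}
        for region in self.regions:
            for thr in self.thresholds:
                col = []
                group_ids: dict[frozenset, str] = {}
                for taxon in self.taxon_ids:
                    cluster = next(
                        (c for c in self.clusters[(region, thr)] if taxon in c), None
                    )
                    if cluster is None:
                        col.append("failed")
                    elif len(cluster) == 1:
                        col.append("distinct")
                    else:
                        key = frozenset(cluster)
                        if key not in group_ids:
                            group_ids[key] = f"g{len(group_ids) + 1}"
                        col.append(f"merged:{group_ids[key]}")
                data[f"{region}@{thr:g}"] = col
        return pd.DataFrame(data, index=self.taxon_ids)

    def summary(self) -> pd.DataFrame:
        """region x threshold counts of uniquely distinguishable taxa."""
        return pd.DataFrame(
            {
                f"{thr:g}": [self.n_distinguishable(r, thr) for r in self.regions]
                for thr in self.thresholds
            },
            index=self.regions,
        )


def discriminability_grid(
    panel: Sequence[ReferenceTaxon],
    regions: Sequence[RegionPrimerPair],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    *,
    gap_policy: str = "pairwise_deletion",
    max_mismatch: int = 0,
) -> DiscriminabilityGrid:
    """Extract every region from every taxon, compute pairwise identities on
    the trimmed amplicons, and cluster at each threshold.

    Taxa failing extraction for a region are dropped from that region's
    matrix and recorded in ``failed`` (never silently). For a fixed region
    the number of distinguishable taxa is non-decreasing in the threshold.
    """
    if not thresholds:
        raise ValueError("at least one threshold required")
    for thr in thresholds:
        if not 0.0 < thr <= 1.0:
            raise ValueError("thresholds must be in (0, 1]")
    taxon_ids = [t.taxon_id for t in panel]
    clusters: dict[tuple[str, float], list[set[str]]] = {}
    flagged: dict[str, list[tuple[str, str]]] = {}
    failed: dict[str, list[str]] = {}
    for pair in regions:
        seqs: dict[str, str] = {}
        missing: list[str] = []
        for taxon in panel:
            try:
                rec = extract_amplicon(taxon, pair, max_mismatch)
            except ValueError:
                missing.append(taxon.taxon_id)
            else:
                seqs[taxon.taxon_id] = rec.trimmed_seq
        if missing:
            failed[pair.region_label] = missing
        if len(seqs) < 2:
            for thr in thresholds:
                clusters[(pair.region_label, float(thr))] = [
                    {t} for t in seqs
                ]
            flagged[pair.region_label] = []
            continue
        sim = similarity_matrix(
            seqs, gap_policy=gap_policy, region_label=pair.region_label
        )
        flagged[pair.region_label] = sim.undefined_pairs()
        for thr in thresholds:
            clusters[(pair.region_label, float(thr))] = cluster_at_threshold(
                sim, float(thr)
            )
    return DiscriminabilityGrid(
        taxon_ids=taxon_ids,
        regions=[p.region_label for p in regions],
        thresholds=[float(t) for t in thresholds],
        clusters=clusters,
        flagged_pairs=flagged,
        failed=failed,
    )
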