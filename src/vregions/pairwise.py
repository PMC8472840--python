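"""Pairwise global alignment and uncorrected-identity matrices.

Identity here is 1 minus the uncorrected p-distance: the fraction of compared
(non-excluded) alignment columns at which the two sequences agree. Two gap
policies are supported:

``pairwise_deletion``
    For each pair, columns gapped in either of the two rows are excluded.
``complete_deletion``
    At the matrix level, columns gapped in *any* row of the alignment are
    excluded before any pair is scored. Only meaningful for a shared multiple
    alignment, so it is rejected for unaligned input.

Ambiguity codes count as a match (and as a compared site) whenever their base
sets intersect, which is deliberately conservative toward merging taxa.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
from Bio import Align

from ._iupac import bases_intersect

GAP_POLICIES = ("pairwise_deletion", "complete_deletion")

#: EDNAFULL-like default scoring; affects alignments only, never the identity
#: definition itself.
DEFAULT_SCORING = {"match": 5.0, "mismatch": -4.0, "gap_open": 10.0, "gap_extend": 0.5}


@dataclasses.dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences: equal-length gapped strings."""

    seq_a_aligned: str
    seq_b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a_aligned) != len(self.seq_b_aligned):
            raise ValueError("aligned rows differ in length")


def _make_aligner(scoring: Mapping[str, float]) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    # gap run of length k scores -(gap_open + (k - 1) * gap_extend)
    aligner.open_gap_score = -scoring["gap_open"]
    aligner.extend_gap_score = -scoring["gap_extend"]
    return aligner


def global_align(a: str, b: str, scoring: Mapping[str, float] | None = None) -> PairwiseAlignment:
    """Optimal end-to-end alignment under affine gap penalties.

    A gap run of length k is penalized ``gap_open + (k-1) * gap_extend``; end
    gaps are penalized like internal ones (true Needleman-Wunsch). Among
    co-optimal alignments the aligner's first traceback is returned, which is
    deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("global_align requires two nonempty sequences")
    scoring = dict(DEFAULT_SCORING, **(scoring or {}))
    aligner = _make_aligner(scoring)
    alignment = next(iter(aligner.align(a.upper(), b.upper())))
    return PairwiseAlignment(alignment[0], alignment[1], float(alignment.score))


def identity(
    a_aligned: str,
    b_aligned: str,
    gap_policy: str = "pairwise_deletion",
) -> tuple[float | None, int]:
    """Uncorrected identity over compared sites of two aligned rows.

    Returns ``(fraction, compared_sites)``; the fraction is ``None`` when no
    site survives the gap policy (never coerced to 0 or 1). Under either
    policy, columns gapped in one of the two rows are excluded here;
    complete deletion additionally removes shared-alignment gap columns at the
    matrix level (see :func:`similarity_matrix`).
    """
    if len(a_aligned) != len(b_aligned):
        raise ValueError("aligned sequences differ in length")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    matches = 0
    compared = 0
    for ca, cb in zip(a_aligned.upper(), b_aligned.upper()):
        if ca == "-" or cb == "-":
            continue
        compared += 1
        if bases_intersect(ca, cb):
            matches += 1
    if compared == 0:
        return None, 0
    return matches / compared, compared


@dataclasses.dataclass
class SimilarityMatrix:
    """Symmetric pairwise-identity matrix over one region's sequences.

    ``values`` holds identities in [0, 1] with NaN for undefined pairs
    (no compared sites); ``compared_sites`` the per-pair column counts.
    """

    taxon_ids: list[str]
    values: np.ndarray
    compared_sites: np.ndarray
    gap_policy: str
    region_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.taxon_ids)
        if self.values.shape != (n, n) or self.compared_sites.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def pair(self, a: str, b: str) -> float:
        i, j = self.taxon_ids.index(a), self.taxon_ids.index(b)
        return float(self.values[i, j])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        """Taxon pairs whose identity could not be computed (0 compared sites)."""
        out = []
        for i in range(self.n_taxa):
            for j in range(i + 1, self.n_taxa):
                if np.isnan(self.values[i, j]):
                    out.append((self.taxon_ids[i], self.taxon_ids[j]))
        return out

    def zero_difference(self, i: int, j: int) -> bool:
        """True iff the pair shows no observed difference over compared sites."""
        if np.isnan(self.values[i, j]):
            return False
        matches = round(self.values[i, j] * self.compared_sites[i, j])
        return matches == self.compared_sites[i, j]

    def to_tsv(self, path) -> None:
        """Square identity matrix, taxon ids as first row/column, 6 decimals."""
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.taxon_ids) + "\n")
            for i, tid in enumerate(self.taxon_ids):
                cells = [
                    "" if np.isnan(v) else f"{v:.6f}" for v in self.values[i]
                ]
                fh.write(tid + "\t" + "\t".join(cells) + "\n")


def similarity_matrix(
    seqs: Mapping[str, str] | Sequence[tuple[str, str]],
    gap_policy: str = "pairwise_deletion",
    *,
    aligned: bool = False,
    region_label: str = "",
    scoring: Mapping[str, float] | None = None,
) -> SimilarityMatrix:
    """Pairwise identities over a taxon set for one region.

    ``seqs`` maps taxon id to sequence. With ``aligned=False`` each pair is
    globally aligned first; with ``aligned=True`` the inputs are rows of one
    multiple alignment (equal lengths, '-' gaps).
    """
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    ids = [tid for tid, _ in items]
    if len(set(ids)) != len(ids):
        dup = next(t for t in ids if ids.count(t) > 1)
        raise ValueError(f"duplicate taxon_id {dup!r}")
    if len(ids) < 2:
        raise ValueError("similarity_matrix requires at least 2 taxa")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")

    rows = [s.upper() for _, s in items]
    if aligned:
        if len({len(r) for r in rows}) != 1:
            raise ValueError("aligned input rows differ in length")
        if gap_policy == "complete_deletion":
            keep = [
                k for k in range(len(rows[0])) if all(r[k] != "-" for r in rows)
            ]
            rows = ["".join(r[k] for k in keep) for r in rows]
    elif gap_policy == "complete_deletion":
        raise ValueError("complete_deletion requires a shared multiple alignment")

    n = len(ids)
    values = np.ones((n, n))
    compared = np.zeros((n, n), dtype=int)
    for i in range(n):
        ai = rows[i]
        # self-comparison: all non-gap sites compared, identity exactly 1
        compared[i, i] = sum(c != "-" for c in ai)
        for j in range(i + 1, n):
            if aligned:
                frac, sites = identity(ai, rows[j], gap_policy="pairwise_deletion")
            else:
                aln = global_align(ai, rows[j], scoring)
                frac, sites = identity(
                    aln.seq_a_aligned, aln.seq_b_aligned, gap_policy="pairwise_deletion"
                )
            values[i, j] = values[j, i] = np.nan if frac is None else frac
            compared[i, j] = compared[j, i] = sites
    return SimilarityMatrix(ids, values, compared, gap_policy, region_label)


def slice_msa_to_region(
    msa: Mapping[str, str],
    amplicons: Mapping[str, "AmpliconRecord"],  # noqa: F821 (runtime duck-typed)
) -> tuple[dict[str, str], int]:
    """Cut a full-length multiple alignment down to one V-region.

    For every taxon the trimmed amplicon (primer sites removed) occupies a run
    of non-gap positions in its row; the retained columns are the union span
    from the first to the last alignment column occupied by any taxon's
    region. Returns the sliced rows plus the number of retained columns (the
    aligned-dataset size of the region).
    """
    missing = sorted(set(msa) - set(amplicons))
    if missing:
        raise ValueError(f"taxon {missing[0]!r} present in MSA but has no amplicon")
    first_col, last_col = None, None
    for tid, row in msa.items():
        rec = amplicons[tid]
        # trimmed region spans these 0-based ungapped offsets in the taxon seq
        u_start = rec.start + rec.fwd_len
        u_end = rec.end - rec.rev_len  # exclusive
        ungapped = -1
        cols = []
        for col, c in enumerate(row):
            if c != "-":
                ungapped += 1
                if u_start <= ungapped < u_end:
                    cols.append(col)
        if not cols:
            raise ValueError(f"taxon {tid!r}: trimmed region empty in MSA")
        lo, hi = cols[0], cols[-1]
        first_col = lo if first_col is None else min(first_col, lo)
        last_col = hi if last_col is None else max(last_col, hi)
    sliced = {tid: row[first_col : last_col + 1] for tid, row in msa.items()}
    return sliced, last_col + 1 - first_col
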