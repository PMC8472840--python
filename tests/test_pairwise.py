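"""Global alignment vs an independent recursion oracle; identity semantics."""

import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vregions.insilico_pcr import extract_region
from vregions.pairwise import (
    global_align,
    identity,
    similarity_matrix,
    slice_msa_to_region,
)

SMALL_DNA = st.text(alphabet="ACGT", min_size=1, max_size=8)


def oracle_score(a, b, match, mismatch, gap_open, gap_extend):
    """Optimal global alignment score by exhaustive recursion over the
    alignment op space (match/insert/delete with affine gap-run scoring);
    independent of the production aligner."""

    @lru_cache(maxsize=None)
    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "D" else gap_open
            best = max(best, -cost + rec(i + 1, j, "D"))
        if j < len(b):
            cost = gap_extend if prev == "I" else gap_open
            best = max(best, -cost + rec(i, j + 1, "I"))
        return best

    return rec(0, 0, "M")


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGT", "ACGT", {"match": 1, "mismatch": -1, "gap_open": 1, "gap_extend": 1})
        assert aln.score == 4
        assert aln.seq_a_aligned == aln.seq_b_aligned == "ACGT"

    def test_single_gap_linear_scoring(self):
        scoring = {"match": 1, "mismatch": -1, "gap_open": 1, "gap_extend": 1}
        aln = global_align("ACGT", "AGT", scoring)
        assert aln.score == 2
        assert aln.seq_a_aligned == "ACGT"
        assert aln.seq_b_aligned == "A-GT"

    def test_gap_removal_recovers_inputs(self):
        aln = global_align("ACGTACGT", "ACGGT")
        assert aln.seq_a_aligned.replace("-", "") == "ACGTACGT"
        assert aln.seq_b_aligned.replace("-", "") == "ACGGT"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_recursion_oracle_affine(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), rng.integers(1, 9)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(1, 9)))
        scoring = {"match": 5, "mismatch": -4, "gap_open": 10, "gap_extend": 0.5}
        got = global_align(a, b, scoring).score
        want = oracle_score(a, b, 5, -4, 10, 0.5)
        assert got == pytest.approx(want)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(a=SMALL_DNA, b=SMALL_DNA)
    def test_matches_recursion_oracle_linear(self, a, b):
        scoring = {"match": 1, "mismatch": -1, "gap_open": 1, "gap_extend": 1}
        assert global_align(a, b, scoring).score == pytest.approx(
            oracle_score(a, b, 1, -1, 1, 1)
        )


class TestIdentity:
    def test_identical_long_sequences(self):
        s = "ACGT" * 94  # 376 sites, near a real trimmed-region length
        frac, sites = identity(s, s)
        assert (frac, sites) == (1.0, len(s))

    def test_single_substitution(self):
        assert identity("ACGT", "ACGA") == (0.75, 4)

    def test_gap_column_excluded_under_pairwise_deletion(self):
        assert identity("AC-T", "ACGT") == (1.0, 3)

    def test_all_gap_pair_is_missing_not_zero_or_one(self):
        frac, sites = identity("--", "AA")
        assert frac is None and sites == 0

    def test_ambiguity_codes_match_when_sets_intersect(self):
        frac, sites = identity("ACGN", "ACGT")
        assert (frac, sites) == (1.0, 4)
        frac, _ = identity("R", "C")
        assert frac == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            identity("ACG", "AC")

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=40), st.integers(0, 39))
    def test_extra_substitution_never_raises_identity(self, seq, pos):
        """Monotone degradation at a fixed alignment."""
        pos %= len(seq)
        other = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]
        base, _ = identity(seq, seq)
        worse, _ = identity(seq, other)
        assert worse <= base


class TestSimilarityMatrix:
    def test_identical_pair_off_diagonal_one(self):
        sim = similarity_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert sim.pair("a", "b") == 1.0

    def test_matches_pair_by_pair_recomputation(self):
        rng = np.random.default_rng(8)
        seqs = {
            f"t{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(3)
        }
        sim = similarity_matrix(seqs)
        for i, a in enumerate(seqs):
            for b in list(seqs)[i + 1 :]:
                aln = global_align(seqs[a], seqs[b])
                frac, _ = identity(aln.seq_a_aligned, aln.seq_b_aligned)
                assert sim.pair(a, b) == pytest.approx(frac)

    def test_symmetry_diagonal_range(self, divergent_panel, regions):
        amplicons = extract_region(divergent_panel, regions["V4-V5"])
        sim = similarity_matrix({t: r.trimmed_seq for t, r in amplicons.items()})
        assert np.allclose(sim.values, sim.values.T)
        assert np.all(np.diag(sim.values) == 1.0)
        off = sim.values[~np.eye(sim.n_taxa, dtype=bool)]
        assert np.all((off >= 0) & (off <= 1))
        assert np.all(sim.compared_sites >= 1)

    def test_duplicate_taxon_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            similarity_matrix([("a", "ACGT"), ("a", "ACGT")])

    def test_complete_deletion_requires_msa(self):
        with pytest.raises(ValueError, match="complete_deletion"):
            similarity_matrix({"a": "ACGT", "b": "ACG"}, gap_policy="complete_deletion")

    def test_complete_deletion_drops_columns_gapped_in_any_row(self):
        rows = {"a": "ACGT", "b": "A-GT", "c": "ACGT"}
        sim = similarity_matrix(rows, gap_policy="complete_deletion", aligned=True)
        assert sim.compared_sites[0, 2] == 3  # column 2 removed for all pairs
        assert sim.pair("a", "c") == 1.0

    def test_tsv_round_trip_values(self, tmp_path):
        sim = similarity_matrix({"a": "ACGTACGT", "b": "ACGAACGT", "c": "TTTTACGT"})
        out = tmp_path / "sim.tsv"
        sim.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["taxon", "a", "b", "c"]
        assert lines[1].split("\t")[1] == "1.000000"


class TestSliceMsaToRegion:
    def _amplicons(self, panel, pair):
        return extract_region(panel, pair)

    def test_gapless_msa_gives_region_length(self, divergent_panel, regions):
        pair = regions["V4-V5"]
        amplicons = self._amplicons(divergent_panel, pair)
        msa = {t.taxon_id: t.sequence for t in divergent_panel}  # equal lengths, no gaps
        sliced, n_cols = slice_msa_to_region(msa, amplicons)
        lengths = {len(r.trimmed_seq) for r in amplicons.values()}
        assert n_cols == lengths.pop()
        first = next(iter(sliced.values()))
        assert all(len(row) == len(first) for row in sliced.values())

    def test_inserted_base_adds_one_column(self, divergent_panel, regions):
        pair = regions["V4-V5"]
        amplicons = self._amplicons(divergent_panel, pair)
        msa = {t.taxon_id: t.sequence for t in divergent_panel}
        ids = list(msa)
        # insert one base (a new alignment column) inside the region of row 0
        rec = amplicons[ids[0]]
        col = rec.start + rec.fwd_len + 5
        msa2 = {}
        for i, (tid, row) in enumerate(msa.items()):
            msa2[tid] = row[:col] + ("A" if i == 0 else "-") + row[col:]
        # row 0's ungapped sequence gained a base: its amplicon must be re-extracted
        from vregions.insilico_pcr import extract_amplicon
        from vregions.reference_model import ReferenceTaxon

        taxon0 = ReferenceTaxon(genus=ids[0], sequence=msa2[ids[0]].replace("-", ""))
        amplicons2 = dict(amplicons)
        amplicons2[ids[0]] = extract_amplicon(taxon0, pair)
        _, n_before = slice_msa_to_region(msa, amplicons)
        _, n_after = slice_msa_to_region(msa2, amplicons2)
        assert n_after == n_before + 1

    def test_missing_amplicon_rejected(self, divergent_panel, regions):
        amplicons = self._amplicons(divergent_panel, regions["V4-V5"])
        msa = {t.taxon_id: t.sequence for t in divergent_panel}
        del amplicons[divergent_panel[0].taxon_id]
        with pytest.raises(ValueError, match="no amplicon"):
            slice_msa_to_region(msa, amplicons)

    def test_agrees_with_realignment_on_gapfree_region(self, divergent_panel, regions):
        """MSA-slice identities equal re-aligned amplicon identities when the
        region is gap-free (both computation paths must coincide)."""
        for label in ("V4", "V4-V5"):
            amplicons = self._amplicons(divergent_panel, regions[label])
            msa = {t.taxon_id: t.sequence for t in divergent_panel}
            sliced, _ = slice_msa_to_region(msa, amplicons)
            sim_msa = similarity_matrix(sliced, aligned=True, region_label=label)
            sim_aln = similarity_matrix(
                {t: r.trimmed_seq for t, r in amplicons.items()}, region_label=label
            )
            assert np.allclose(sim_msa.values, sim_aln.values)
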