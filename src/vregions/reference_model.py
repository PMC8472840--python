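"""Domain types, FASTA/TSV I/O, and full-length 16S gene delineation.

The reference panel is a set of genus type species, each represented by one
full-length 16S rRNA gene sequence. Primer positions and reported coordinates
follow the Escherichia coli K-12 numbering convention universally used to
name 16S primers (27F, 515F, 1492R, ...). Internally all coordinates are
0-based half-open; anything user-facing is 1-based inclusive in E. coli
numbering.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from Bio import Align

from ._iupac import bases_intersect, normalize_sequence, validate_primer
from .pairwise import DEFAULT_SCORING, PairwiseAlignment


@dataclasses.dataclass
class ReferenceTaxon:
    """One genus type species with its full-length 16S sequence."""

    genus: str
    species: str = ""
    strain_id: str = ""
    accession: str = ""
    sequence: str = ""
    declared_full_length: int | None = None

    @property
    def taxon_id(self) -> str:
        return self.genus

    @property
    def header(self) -> str:
        return "|".join([self.genus, self.species, self.strain_id, self.accession])


@dataclasses.dataclass(frozen=True)
class RegionPrimerPair:
    """One V-region definition: a degenerate forward/reverse primer pair.

    ``expected_fwd_pos``/``expected_rev_pos`` are the E. coli-numbering
    anchors parsed from the primer names (e.g. 515F-Y -> 515); they are used
    only to break ties between equally good annealing sites.
    """

    region_label: str
    fwd_name: str
    fwd_seq: str
    rev_name: str
    rev_seq: str

    def __post_init__(self) -> None:
        validate_primer(self.fwd_seq, name=self.fwd_name)
        validate_primer(self.rev_seq, name=self.rev_name)

    @property
    def expected_fwd_pos(self) -> int:
        return _position_from_name(self.fwd_name)

    @property
    def expected_rev_pos(self) -> int:
        return _position_from_name(self.rev_name)


def _position_from_name(name: str) -> int:
    nums = re.findall(r"\d+", name)
    if not nums:
        raise ValueError(f"primer name {name!r} carries no positional number")
    return int(nums[-1])


@dataclasses.dataclass
class CoordinateMap:
    """Mapping of 1-based E. coli 16S positions to 0-based target offsets.

    Pairs are strictly increasing in both components (one pair per aligned
    match column).
    """

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (r0, t0), (r1, t1) in zip(self.pairs, self.pairs[1:]):
            if r1 <= r0 or t1 <= t0:
                raise ValueError("coordinate map must increase strictly")

    def to_ecoli(self, target_pos: int) -> int | None:
        """E. coli position aligned to a target offset, or None if gapped."""
        for ref, tgt in self.pairs:
            if tgt == target_pos:
                return ref
        return None

    def nearest_ecoli(self, target_pos: int) -> int:
        """E. coli position of the closest mapped target offset (for tiebreaks)."""
        if not self.pairs:
            raise ValueError("empty coordinate map")
        ref, tgt = min(self.pairs, key=lambda p: abs(p[1] - target_pos))
        return ref + (target_pos - tgt)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"pairs": [[r, t] for r, t in self.pairs]}, indent=0) + "\n"
        )

    @classmethod
    def from_json(cls, path) -> "CoordinateMap":
        data = json.loads(Path(path).read_text())
        return cls([(int(r), int(t)) for r, t in data["pairs"]])


# ---------------------------------------------------------------------------
# FASTA / TSV I/O


def _taxon_from_record(rec: SeqRecord) -> ReferenceTaxon:
    header = rec.description or rec.id
    seq = normalize_sequence(str(rec.seq), name=header)
    if "|" in header:
        parts = (header.split("|") + [""] * 4)[:4]
        genus, species, strain, accession = (p.strip() for p in parts)
    else:
        genus, species, strain, accession = header.split()[0], "", "", ""
    return ReferenceTaxon(genus, species, strain, accession, seq)


def read_reference_fasta(path) -> list[ReferenceTaxon]:
    """Read a reference panel, preserving record order.

    Headers either follow the ``genus|species|strain|accession`` convention or
    are free text, in which case the first whitespace token becomes the genus.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    return [_taxon_from_record(r) for r in records]


def write_reference_fasta(taxa: list[ReferenceTaxon], path) -> None:
    """Write a panel as FASTA, 80-column wrapped, headers round-trippable."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.header, description="") for t in taxa
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def load_primer_table(path=None) -> list[RegionPrimerPair]:
    """Load a region/primer table; the packaged default covers ten V-regions
    (V1-V9 near-full-length plus nine partial windows) with their standard
    degenerate primers (27F ... 1492Rmod, including the inosine-bearing 337R).
    """
    if path is None:
        source = importlib.resources.files("vregions.data") / "primer_regions.tsv"
        text = source.read_text()
        origin = "<builtin>"
    else:
        text = Path(path).read_text()
        origin = str(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    expected = ["region", "fwd_name", "fwd_seq", "rev_name", "rev_seq"]
    if header != expected:
        raise ValueError(f"{origin}: expected columns {expected}, got {header}")
    pairs: list[RegionPrimerPair] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{origin}:{lineno}: expected 5 fields, got {len(fields)}")
        region, fn, fs, rn, rs = (f.strip() for f in fields)
        if region in seen:
            raise ValueError(f"{origin}:{lineno}: duplicate region label {region!r}")
        seen.add(region)
        pairs.append(RegionPrimerPair(region, fn, fs.upper(), rn, rs.upper()))
    return pairs


# ---------------------------------------------------------------------------
# Full-length gene delineation against the E. coli-numbering reference

def _semiglobal_align(ref: str, raw: str) -> PairwiseAlignment:
    """Global alignment with free end gaps on the reference side, so genomic
    flanks of the raw sequence hang off the reference ends at no cost.

    Internal gaps are priced linearly and firmly (10 per gapped column
    rather than the matrix default affine 10/0.5): delineation must not
    scatter reference positions across unrelated sequence chasing isolated
    matches, and unrelated sequence must score visibly below the 16S-likeness
    guard.
    """
    import warnings as _warnings

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = DEFAULT_SCORING["match"]
    aligner.mismatch_score = DEFAULT_SCORING["mismatch"]
    aligner.open_gap_score = -DEFAULT_SCORING["gap_open"]
    aligner.extend_gap_score = -10.0
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # pre-1.88 attribute names
        aligner.target_left_open_gap_score = 0.0
        aligner.target_left_extend_gap_score = 0.0
        aligner.target_right_open_gap_score = 0.0
        aligner.target_right_extend_gap_score = 0.0
    alignment = next(iter(aligner.align(ref, raw)))
    return PairwiseAlignment(alignment[0], alignment[1], float(alignment.score))


_ECOLI_CACHE: str | None = None


def load_ecoli_reference() -> str:
    """The packaged 16S numbering reference sequence (1542 nt).

    This is a synthetic stand-in for the E. coli K-12 16S gene: every primer
    annealing site of the packaged region table is placed at its nominal
    E. coli coordinate over a reproducible random background (see
    ``vregions.synthetic``). It fixes the coordinate system; it is not the
    biological E. coli sequence.
    """
    global _ECOLI_CACHE
    if _ECOLI_CACHE is None:
        source = importlib.resources.files("vregions.data") / "ecoli16s_synthetic.fasta"
        with importlib.resources.as_file(source) as p:
            rec = next(SeqIO.parse(str(p), "fasta"))
        _ECOLI_CACHE = normalize_sequence(str(rec.seq), name="ecoli16s")
    return _ECOLI_CACHE


def delineate_16s(
    raw_seq: str,
    ecoli_16s: str | None = None,
    *,
    min_identity: float = 0.60,
    min_coverage: float = 0.50,
) -> tuple[str, CoordinateMap]:
    """Trim a sequence to the span aligning to the full numbering reference.

    The raw sequence (possibly carrying flanking genomic context) is aligned
    to the reference with free end gaps on the reference side; the returned
    subsequence spans the columns aligned to reference positions 1..L. The
    operation is idempotent: a sequence already delineated maps onto the
    whole reference and is returned unchanged. Raises "not 16S-like" when
    identity over aligned columns falls below ``min_identity`` or when the
    matched fraction of reference positions falls below ``min_coverage``
    (guards against unrelated sequence whose scattered best matches still
    look locally identical).
    """
    if ecoli_16s is None:
        ecoli_16s = load_ecoli_reference()
    raw_seq = normalize_sequence(raw_seq)
    if len(raw_seq) < 1200:
        raise ValueError("sequence shorter than 1200 nt cannot be a full 16S gene")
    aln = _semiglobal_align(ecoli_16s, raw_seq)
    ref_row, tgt_row = aln.seq_a_aligned, aln.seq_b_aligned

    matches = compared = 0
    pairs: list[tuple[int, int]] = []
    first_t = last_t = None
    ref_pos = 0  # 1-based after increment
    tgt_pos = -1  # 0-based offset in raw_seq
    for cr, ct in zip(ref_row, tgt_row):
        if cr != "-":
            ref_pos += 1
        if ct != "-":
            tgt_pos += 1
        if cr != "-" and ct != "-":
            compared += 1
            if bases_intersect(cr, ct):
                matches += 1
            pairs.append((ref_pos, tgt_pos))
            if first_t is None:
                first_t = tgt_pos
            last_t = tgt_pos
    if (
        compared == 0
        or matches / compared < min_identity
        or matches < min_coverage * len(ecoli_16s)
    ):
        raise ValueError("not 16S-like: alignment identity or coverage below threshold")
    trimmed = raw_seq[first_t : last_t + 1]
    offset = first_t
    cmap = CoordinateMap([(r, t - offset) for r, t in pairs])
    return trimmed, cmap
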