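"""In-silico PCR: degenerate primer site search and amplicon extraction.

A primer anneals where every primer code is compatible (base-set
intersection) with the template code under it, allowing up to
``max_mismatch`` incompatible positions. Reverse primers are given 5'->3' on
the reverse strand, so the template is scanned for their reverse complement.
Amplicon length *with* primers spans the first base of the forward site to
the last base of the reverse site; the "edited" (trimmed) sequence removes
both primer-binding windows.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import pandas as pd

from ._iupac import iupac_compatible, reverse_complement
from .reference_model import CoordinateMap, ReferenceTaxon, RegionPrimerPair

DEFAULT_MAX_MISMATCH = 0
MAX_ALLOWED_MISMATCH = 3


@dataclasses.dataclass(frozen=True)
class PrimerSite:
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    mismatches: int


@dataclasses.dataclass
class AmpliconRecord:
    """One region extracted from one taxon."""

    taxon_id: str
    region_label: str
    start: int  # 0-based inclusive, first base of the forward-primer site
    end: int  # 0-based exclusive, one past the last base of the reverse site
    length_with_primers: int
    trimmed_seq: str
    fwd_mismatches: int
    rev_mismatches: int
    fwd_len: int
    rev_len: int

    def __post_init__(self) -> None:
        if self.length_with_primers != self.end - self.start:
            raise ValueError("length_with_primers inconsistent with coordinates")
        if len(self.trimmed_seq) != self.length_with_primers - self.fwd_len - self.rev_len:
            raise ValueError("trimmed length inconsistent with primer lengths")

    @property
    def trimmed_length(self) -> int:
        return len(self.trimmed_seq)


def _count_mismatches(window: str, primer: str, max_mismatch: int) -> int | None:
    """Mismatches of primer vs window, or None once past the budget."""
    mm = 0
    for p, t in zip(primer, window):
        if not iupac_compatible(p, t):
            mm += 1
            if mm > max_mismatch:
                return None
    return mm


def find_primer_sites(
    template: str,
    primer: str,
    orientation: str = "forward",
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    *,
    expected_pos: int | None = None,
    coord_map: CoordinateMap | None = None,
) -> list[PrimerSite]:
    """All annealing windows within the mismatch budget.

    Sites are sorted by mismatch count, then (when ``expected_pos`` is given)
    by distance between the window start mapped to E. coli numbering and the
    primer's nominal position, then by position. Reverse orientation scans for
    the reverse complement of the primer as printed.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"unknown orientation {orientation!r}")
    template = template.upper()
    probe = primer.upper() if orientation == "forward" else reverse_complement(primer)
    k = len(probe)
    if len(template) < k:
        raise ValueError("template shorter than primer")
    sites = []
    for start in range(len(template) - k + 1):
        mm = _count_mismatches(template[start : start + k], probe, max_mismatch)
        if mm is not None:
            sites.append(PrimerSite(start, start + k, mm))

    def sort_key(site: PrimerSite):
        if expected_pos is None:
            return (site.mismatches, site.start)
        pos = (
            coord_map.nearest_ecoli(site.start) if coord_map is not None
            else site.start + 1
        )
        return (site.mismatches, abs(pos - expected_pos), site.start)

    return sorted(sites, key=sort_key)


def _best_unique_site(
    sites: list[PrimerSite],
    *,
    expected_pos: int | None,
    coord_map: CoordinateMap | None,
    what: str,
) -> PrimerSite:
    if not sites:
        raise ValueError(f"no annealing site: {what}")
    if len(sites) == 1:
        return sites[0]
    best, runner = sites[0], sites[1]
    if best.mismatches < runner.mismatches:
        return best

    def eco(site: PrimerSite) -> int:
        return (
            coord_map.nearest_ecoli(site.start) if coord_map is not None
            else site.start + 1
        )

    if expected_pos is not None and abs(eco(best) - expected_pos) < abs(
        eco(runner) - expected_pos
    ):
        return best
    raise ValueError(f"ambiguous site: {what}")


def extract_amplicon(
    taxon: ReferenceTaxon,
    pair: RegionPrimerPair,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    *,
    coord_map: CoordinateMap | None = None,
) -> AmpliconRecord:
    """Extract one region from one taxon.

    Requires a unique best forward and reverse site (mismatch count, then
    proximity of the E. coli-mapped start to the primer's nominal position);
    the forward site must lie upstream of the reverse site.
    """
    if not 0 <= max_mismatch <= MAX_ALLOWED_MISMATCH:
        raise ValueError(f"max_mismatch must be in [0, {MAX_ALLOWED_MISMATCH}]")
    seq = taxon.sequence
    label = f"{taxon.taxon_id}/{pair.region_label}"
    fwd = _best_unique_site(
        find_primer_sites(
            seq, pair.fwd_seq, "forward", max_mismatch,
            expected_pos=pair.expected_fwd_pos, coord_map=coord_map,
        ),
        expected_pos=pair.expected_fwd_pos,
        coord_map=coord_map,
        what=f"{label} forward primer {pair.fwd_name}",
    )
    rev = _best_unique_site(
        find_primer_sites(
            seq, pair.rev_seq, "reverse", max_mismatch,
            expected_pos=pair.expected_rev_pos, coord_map=coord_map,
        ),
        expected_pos=pair.expected_rev_pos,
        coord_map=coord_map,
        what=f"{label} reverse primer {pair.rev_name}",
    )
    if fwd.end > rev.start:
        raise ValueError(f"inverted orientation: {label}")
    return AmpliconRecord(
        taxon_id=taxon.taxon_id,
        region_label=pair.region_label,
        start=fwd.start,
        end=rev.end,
        length_with_primers=rev.end - fwd.start,
        trimmed_seq=seq[fwd.end : rev.start],
        fwd_mismatches=fwd.mismatches,
        rev_mismatches=rev.mismatches,
        fwd_len=len(pair.fwd_seq),
        rev_len=len(pair.rev_seq),
    )


def extract_region(
    panel: Sequence[ReferenceTaxon],
    pair: RegionPrimerPair,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> dict[str, AmpliconRecord]:
    """Extract one region from every taxon of a panel."""
    return {t.taxon_id: extract_amplicon(t, pair, max_mismatch) for t in panel}


def amplicon_size_table(
    panel: Sequence[ReferenceTaxon],
    regions: Sequence[RegionPrimerPair],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> pd.DataFrame:
    """Per-region min/max amplicon sizes, with and without primers.

    A region failing extraction on any taxon is flagged in the ``failed``
    column (with the failing taxa listed) rather than dropped.
    """
    if not panel:
        raise ValueError("empty panel")
    rows = []
    for pair in regions:
        lengths, trimmed, failures = [], [], []
        for taxon in panel:
            try:
                rec = extract_amplicon(taxon, pair, max_mismatch)
            except ValueError:
                failures.append(taxon.taxon_id)
            else:
                lengths.append(rec.length_with_primers)
                trimmed.append(rec.trimmed_length)
        rows.append(
            {
                "region": pair.region_label,
                "min_with_primers": min(lengths) if lengths else None,
                "max_with_primers": max(lengths) if lengths else None,
                "min_trimmed": min(trimmed) if trimmed else None,
                "max_trimmed": max(trimmed) if trimmed else None,
                "n_taxa": len(lengths),
                "failed": ",".join(failures),
            }
        )
    return pd.DataFrame(rows)
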