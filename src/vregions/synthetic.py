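"""Synthetic 16S panels and ASV count tables with known structure.

The template builder lays every primer annealing site of the region table at
its nominal E. coli coordinate on a random background, resolving degenerate
positions reproducibly, so that every region extracts with zero mismatches by
construction. Panels are mutated copies of one template with per-region
substitution divergence; primer-site columns are never mutated, which
separates region-divergence behavior from primer-failure behavior (tests
that want failing primers inject those mutations explicitly).

Count tables come from either a Fisher log-series (known alpha) or a
Dirichlet-multinomial (known concentration and depth).
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping

import numpy as np
from scipy.stats import logser

from ._iupac import base_set, reverse_complement
from .diversity import CountTable
from .insilico_pcr import find_primer_sites
from .reference_model import ReferenceTaxon, RegionPrimerPair, load_primer_table

#: 1-based inclusive start of each primer's annealing window in E. coli
#: numbering. Forward primers occupy [start, start + len - 1]; reverse
#: primers bind the plus strand over the same kind of window (their name
#: refers to the window's 3'-most coordinate).
PRIMER_SITE_START: dict[str, int] = {
    "27F": 8,
    "337R": 318,
    "341F": 341,
    "534R": 518,
    "515F": 515,
    "515F-Y": 515,
    "799F": 781,
    "805R": 785,
    "806R": 787,
    "909-928R": 909,
    "926Rb": 909,
    "928F": 905,
    "1100F": 1100,
    "1193R": 1176,
    "1492Rmod": 1492,
}

ECOLI_16S_LENGTH = 1542

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class PanelSpec:
    """Parameters of a synthetic reference panel."""

    n_taxa: int
    template_length: int = ECOLI_16S_LENGTH
    primer_table: list[RegionPrimerPair] | None = None
    per_region_divergence: Mapping[str, float] = dataclasses.field(default_factory=dict)
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primer_table is None:
            self.primer_table = load_primer_table()
        for region, d in self.per_region_divergence.items():
            if not 0.0 <= d < 0.5:
                raise ValueError(f"divergence for {region!r} must be in [0, 0.5)")
        if not 0.0 <= self.indel_rate <= 0.05:
            raise ValueError("indel_rate must be in [0, 0.05]")


@dataclasses.dataclass
class CommunitySpec:
    """Parameters of a synthetic ASV count table.

    ``abundance_model`` is either ``("log_series", {"alpha": a, "n_reads": N})``
    or ``("dirichlet_multinomial", {"concentration": c, "depth": d})``.
    """

    n_samples: int
    n_asvs: int
    abundance_model: tuple[str, Mapping[str, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        name, params = self.abundance_model
        if name == "log_series":
            if params.get("alpha", 0) <= 0:
                raise ValueError("log_series requires alpha > 0")
            if params.get("n_reads", 0) < 1:
                raise ValueError("log_series requires n_reads >= 1")
        elif name == "dirichlet_multinomial":
            if params.get("concentration", 0) <= 0:
                raise ValueError("dirichlet_multinomial requires concentration > 0")
            if params.get("depth", 0) < 1:
                raise ValueError("dirichlet_multinomial requires depth >= 1")
        else:
            raise ValueError(f"unknown abundance model {name!r}")


def primer_site_span(name: str, seq: str) -> tuple[int, int]:
    """0-based half-open template span of a primer's annealing window."""
    try:
        start1 = PRIMER_SITE_START[name]
    except KeyError:
        raise ValueError(f"no nominal coordinate known for primer {name!r}") from None
    return start1 - 1, start1 - 1 + len(seq)


def primer_spans(primer_table: list[RegionPrimerPair]) -> dict[str, tuple[int, int]]:
    """Annealing window of every distinct primer in a table."""
    spans: dict[str, tuple[int, int]] = {}
    for pair in primer_table:
        spans[pair.fwd_name] = primer_site_span(pair.fwd_name, pair.fwd_seq)
        spans[pair.rev_name] = primer_site_span(pair.rev_name, pair.rev_seq)
    return spans


def region_interior(pair: RegionPrimerPair) -> tuple[int, int]:
    """0-based half-open span between (excluding) a region's primer sites."""
    _, fwd_end = primer_site_span(pair.fwd_name, pair.fwd_seq)
    rev_start, _ = primer_site_span(pair.rev_name, pair.rev_seq)
    return fwd_end, rev_start


def make_template(spec: PanelSpec) -> str:
    """Random background with every primer site placed at its nominal
    coordinate; degenerate positions are resolved reproducibly under the seed.

    Where annealing windows overlap (e.g. 515F inside the 534R window) the
    placed base is drawn from the intersection of all covering constraints;
    an empty intersection raises, as do windows beyond the template end.
    """
    constraints: dict[int, frozenset[str]] = {}
    for pair in spec.primer_table:
        for name, seq, reverse in (
            (pair.fwd_name, pair.fwd_seq, False),
            (pair.rev_name, pair.rev_seq, True),
        ):
            placed = reverse_complement(seq) if reverse else seq
            start, end = primer_site_span(name, seq)
            if end > spec.template_length:
                raise ValueError(
                    f"primer {name!r} site [{start + 1}, {end}] exceeds "
                    f"template_length {spec.template_length}"
                )
            for off, code in enumerate(placed):
                pos = start + off
                allowed = base_set(code, primer=True)
                prev = constraints.get(pos)
                allowed = allowed if prev is None else allowed & prev
                if not allowed:
                    raise ValueError(
                        f"overlapping primer sites conflict at position {pos + 1}"
                    )
                constraints[pos] = allowed
    rng = np.random.default_rng(spec.seed)
    chars = list(rng.choice(_BASES, size=spec.template_length))
    for pos, allowed in sorted(constraints.items()):
        chars[pos] = rng.choice(sorted(allowed))
    return "".join(chars)


def _protected_positions(spec: PanelSpec) -> set[int]:
    protected: set[int] = set()
    for start, end in primer_spans(spec.primer_table).values():
        protected.update(range(start, end))
    return protected


def _mutation_probabilities(spec: PanelSpec) -> np.ndarray:
    """Per-position substitution probability (max over covering regions)."""
    prob = np.zeros(spec.template_length)
    by_label = {p.region_label: p for p in spec.primer_table}
    for label, d in spec.per_region_divergence.items():
        if label not in by_label:
            raise ValueError(f"unknown region label {label!r}")
        start, end = region_interior(by_label[label])
        prob[start:end] = np.maximum(prob[start:end], d)
    prob[sorted(_protected_positions(spec))] = 0.0
    return prob


def make_panel(spec: PanelSpec) -> list[ReferenceTaxon]:
    """Mutated copies of one template, one per taxon.

    Each taxon independently substitutes each non-primer position of each
    diverged region with its region's probability; expected pairwise identity
    within a region of length L is governed by a binomial model with
    per-pair difference probability 2 d (1 - d) per site. Single-base indels
    (never inside primer sites) are added at ``indel_rate`` when enabled.
    """
    template = make_template(spec)
    prob = _mutation_probabilities(spec)
    protected = _protected_positions(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    taxa = []
    for i in range(spec.n_taxa):
        chars = list(template)
        hit = np.nonzero(rng.random(len(chars)) < prob)[0]
        for pos in hit:
            alternatives = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = alternatives[rng.integers(3)]
        if spec.indel_rate > 0:
            out = []
            for pos, c in enumerate(chars):
                if pos in protected or rng.random() >= spec.indel_rate:
                    out.append(c)
                    continue
                if rng.random() < 0.5:
                    out.append(c)
                    out.append(str(rng.choice(_BASES)))  # insertion after pos
                # else deletion: drop c
            chars = out
        taxa.append(
            ReferenceTaxon(
                genus=f"Genus{i + 1:02d}",
                species="synthetica",
                strain_id=f"SYN-{i + 1}",
                accession=f"SYN{i + 1:05d}",
                sequence="".join(chars),
            )
        )
    return taxa


def spike_substitutions(
    sequence: str,
    interval: tuple[int, int],
    n_substitutions: int,
    seed: int,
    *,
    avoid: set[int] | frozenset[int] = frozenset(),
) -> str:
    """Copy of a sequence with exactly n substitutions inside a 0-based
    half-open interval, avoiding the given positions (e.g. primer sites).

    Used to construct taxon pairs whose divergence is confined to a known
    stretch, so a region's resolving power is known by construction.
    """
    lo, hi = interval
    candidates = [p for p in range(lo, hi) if p not in avoid]
    if len(candidates) < n_substitutions:
        raise ValueError("interval too small for requested substitutions")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_substitutions, replace=False)
    chars = list(sequence)
    for idx in chosen:
        pos = candidates[idx]
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def verify_template(template: str, primer_table: list[RegionPrimerPair]) -> None:
    """Assert every region's primers find an exact site on a template."""
    for pair in primer_table:
        for seq, orientation in ((pair.fwd_seq, "forward"), (pair.rev_seq, "reverse")):
            if not find_primer_sites(template, seq, orientation, 0):
                raise AssertionError(
                    f"{pair.region_label}: no exact site for {orientation} primer"
                )


def make_counts(spec: CommunitySpec) -> CountTable:
    """Draw an ASV count table under the spec's abundance model.

    log-series: per sample, S = round(alpha ln(1 + N/alpha)) ASV abundances
    are drawn i.i.d. from a logarithmic distribution with x = N/(N + alpha),
    so the expected abundance structure matches Fisher's model with the
    requested alpha at expected total N. n_asvs caps the table's ASV universe.

    dirichlet-multinomial: a common mean composition is drawn once; each
    sample draws its composition from Dirichlet(concentration * mean) and its
    counts from a multinomial at the requested depth.
    """
    rng = np.random.default_rng(spec.seed)
    name, params = spec.abundance_model
    sample_ids = [f"S{j + 1:02d}" for j in range(spec.n_samples)]
    if name == "log_series":
        alpha, n_reads = float(params["alpha"]), float(params["n_reads"])
        x = n_reads / (n_reads + alpha)
        s_per_sample = max(1, round(alpha * math.log1p(n_reads / alpha)))
        n_asvs = max(spec.n_asvs, s_per_sample)
        counts = np.zeros((n_asvs, spec.n_samples), dtype=np.int64)
        for j in range(spec.n_samples):
            chosen = rng.choice(n_asvs, size=s_per_sample, replace=False)
            abundances = logser.rvs(x, size=s_per_sample, random_state=rng)
            counts[chosen, j] = abundances
    else:
        conc, depth = float(params["concentration"]), int(params["depth"])
        n_asvs = spec.n_asvs
        mean_p = rng.dirichlet(np.ones(n_asvs))
        counts = np.zeros((n_asvs, spec.n_samples), dtype=np.int64)
        for j in range(spec.n_samples):
            p = rng.dirichlet(conc * mean_p)
            counts[:, j] = rng.multinomial(depth, p)
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(n_asvs)]
    return CountTable(sample_ids, asv_ids, counts)
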