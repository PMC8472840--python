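"""IUPAC nucleotide codes, degenerate-aware comparison, and reverse complement.

Template sequences may carry any IUPAC ambiguity code. Primers may additionally
carry 'I' (inosine), which is not an IUPAC template code; it is treated as
pairing with every base.
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: codes legal in a template sequence (after U -> T normalization)
TEMPLATE_CODES = frozenset(IUPAC_SETS)
#: codes legal in a primer sequence
PRIMER_CODES = TEMPLATE_CODES | {"I"}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "I": "I",
    "-": "-",
}


def base_set(code: str, *, primer: bool = False) -> frozenset[str]:
    """Set of unambiguous bases a code stands for ('I' = all four, primers only)."""
    code = code.upper()
    if primer and code == "I":
        return IUPAC_SETS["N"]
    try:
        return IUPAC_SETS[code]
    except KeyError:
        kind = "primer" if primer else "template"
        raise ValueError(f"invalid {kind} nucleotide code {code!r}") from None


def iupac_compatible(primer_char: str, template_char: str) -> bool:
    """True iff the base sets of a primer code and a template code intersect."""
    return bool(base_set(primer_char, primer=True) & base_set(template_char))


def bases_intersect(a: str, b: str) -> bool:
    """Degenerate-aware equality between two template codes."""
    return bool(base_set(a) & base_set(b))


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving degeneracy ('-' passes through for MSA rows)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot complement code {exc.args[0]!r}") from None


def normalize_sequence(seq: str, *, name: str = "<sequence>") -> str:
    """Uppercase, map U to T, and validate against the template alphabet.

    Raises ValueError naming the record and the 1-based offending position.
    """
    out = seq.upper().replace("U", "T")
    for i, c in enumerate(out):
        if c not in TEMPLATE_CODES:
            raise ValueError(
                f"record {name!r}: invalid nucleotide {c!r} at position {i + 1}"
            )
    return out


def validate_primer(seq: str, *, name: str = "<primer>") -> str:
    """Uppercase and validate a (possibly degenerate) primer sequence."""
    out = seq.upper()
    if not out:
        raise ValueError(f"primer {name!r} is empty")
    for i, c in enumerate(out):
        if c not in PRIMER_CODES:
            raise ValueError(
                f"primer {name!r}: invalid code {c!r} at position {i + 1}"
            )
    return out
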