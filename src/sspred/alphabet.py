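"""Amino-acid and secondary-structure alphabets, and the 8→3 state mappings.

Secondary structure is labelled per residue with the eight DSSP states
(H alpha-helix, G 3_10-helix, I pi-helix, E beta-strand, B beta-bridge,
T hydrogen-bonded turn, S bend, C other/coil).  The three-state problem
merges them into helix / sheet / coil.  Two merging dialects exist in the
literature: the common one maps {H,G,I}->H, {E,B}->E, {T,S,C}->C; a second
dialect, used by some benchmark sets, assigns G to coil instead of helix.
"""

from __future__ import annotations

from collections import Counter
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import ProteinRecord

# Canonical amino-acid order used for all 20-wide vectors.  Fixed once,
# alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

#: Non-standard / undetermined residue codes, pooled into one class.
NONSTANDARD = "BJOUZX"
AA_ALPHABET = frozenset(AA20) | frozenset(NONSTANDARD)

#: Eight DSSP states, ordered so that the three-state partition is contiguous:
#: helix (H, G, I), sheet (E, B), coil (T, S, C).
SS8 = "HGIEBTSC"
SS8_INDEX = {s: i for i, s in enumerate(SS8)}

#: Three-state classes: helix, sheet (extended), coil.
SS3 = "HEC"
SS3_INDEX = {s: i for i, s in enumerate(SS3)}

#: Mapping dialects: 8-state symbol -> 3-state symbol.
MAPPING_DIALECTS = {
    "default": {
        "H": "H", "G": "H", "I": "H",
        "E": "E", "B": "E",
        "T": "C", "S": "C", "C": "C",
    },
    # Identical except 3_10-helix counts as coil.
    "g_to_coil": {
        "H": "H", "G": "C", "I": "H",
        "E": "E", "B": "E",
        "T": "C", "S": "C", "C": "C",
    },
}

#: DSSP writes a blank (or '-'/'~'/'.') for residues with no assigned state;
#: such characters are normalized to the catch-all coil class.
_SS8_SYNONYMS = {" ": "C", "-": "C", "~": "C", ".": "C"}


class ValidationError(ValueError):
    """A sequence or label string violates its alphabet or length contract."""


def normalize_ss8(ss8: str) -> str:
    """Uppercase an 8-state string and fold unassigned-state characters to 'C'."""
    out = []
    for i, ch in enumerate(ss8.upper()):
        ch = _SS8_SYNONYMS.get(ch, ch)
        if ch not in SS8_INDEX:
            raise ValidationError(
                f"illegal secondary-structure symbol {ch!r} at position {i + 1}"
            )
        out.append(ch)
    return "".join(out)


def map_8_to_3(ss8: str, dialect: str = "default") -> str:
    """Map an 8-state string position-wise onto {H, E, C}.

    Parameters
    ----------
    ss8:
        String over the eight DSSP symbols.
    dialect:
        ``"default"`` ({H,G,I}->H, {E,B}->E, rest->C) or ``"g_to_coil"``
        (same except G->C).
    """
    try:
        table = MAPPING_DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown mapping dialect {dialect!r}") from None
    out = []
    for i, ch in enumerate(ss8):
        try:
            out.append(table[ch])
        except KeyError:
            raise ValidationError(
                f"illegal secondary-structure symbol {ch!r} at position {i + 1}"
            ) from None
    return "".join(out)


def class_counts(
    records: Iterable["ProteinRecord"],
    level: str = "ss3",
    dialect: str = "default",
) -> tuple[dict[str, int], dict[str, float]]:
    """Residue counts and fractions per secondary-structure class.

    All records must carry an 8-state label string.  ``level`` selects the
    8-state or the (dialect-mapped) 3-state partition.  Returns
    ``(counts, fractions)`` with one entry per class symbol; fractions sum
    to 1 over a non-empty input.
    """
    if level not in ("ss3", "ss8"):
        raise ValueError(f"level must be 'ss3' or 'ss8', got {level!r}")
    counter: Counter[str] = Counter()
    for rec in records:
        if rec.ss8 is None:
            raise ValidationError(f"record {rec.id!r} carries no ss8 labels")
        labels = rec.ss8 if level == "ss8" else map_8_to_3(rec.ss8, dialect)
        counter.update(labels)
    symbols = SS8 if level == "ss8" else SS3
    counts = {s: counter.get(s, 0) for s in symbols}
    total = sum(counts.values())
    fractions = {s: (c / total if total else 0.0) for s, c in counts.items()}
    return counts, fractions
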