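"""RNA alphabet handling shared across modules.

All sequences are stored as uppercase RNA over {A, C, G, U}.  DNA input is
transcribed (T -> U) on load; lowercase is normalized.  Anything else is an
error that names the offending positions.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

#: canonical (Watson-Crick + wobble) base pairs
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: integer encoding used by the folding engines
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

#: pair-type encoding: -1 means non-canonical
PAIR_TYPES = {
    ("A", "U"): 0,
    ("U", "A"): 1,
    ("G", "C"): 2,
    ("C", "G"): 3,
    ("G", "U"): 4,
    ("U", "G"): 5,
}

PAIR_NAMES = ["AU", "UA", "GC", "CG", "GU", "UG"]

#: index of the reversed pair type (reading the duplex from the other strand)
PAIR_REVERSE = [1, 0, 3, 2, 5, 4]


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, U} after normalization."""


def normalize_rna(seq: str) -> str:
    """Uppercase, transcribe T->U and validate an input sequence.

    Raises :class:`AlphabetError` listing 1-based positions of offending
    characters.
    """
    s = seq.upper().replace("T", "U")
    bad = [i + 1 for i, c in enumerate(s) if c not in RNA_ALPHABET]
    if bad:
        shown = ", ".join(str(p) for p in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise AlphabetError(f"non-ACGTU characters at positions {shown}{more}")
    return s


def encode(seq: str):
    """Encode an already-normalized RNA string as a list of base indices."""
    return [BASE_INDEX[c] for c in seq]


def can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def pair_type(a: int, b: int) -> int:
    """Pair-type index for encoded bases, or -1 if non-canonical."""
    return _PTYPE[a][b]


_PTYPE = [[-1] * 4 for _ in range(4)]
for (_a, _b), _t in PAIR_TYPES.items():
    _PTYPE[BASE_INDEX[_a]][BASE_INDEX[_b]] = _t
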