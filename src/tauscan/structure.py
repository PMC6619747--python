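"""Secondary-structure container and dot-bracket / CT serialization.

A :class:`SecondaryStructure` is a set of nested canonical base pairs over a
sequence length, 1-based.  Pseudoknots are outside the model everywhere in
this package, so the dot-bracket alphabet is just ``(``, ``)`` and ``.``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from .alphabet import can_pair


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested set of base pairs over a sequence of given length.

    Parameters
    ----------
    length : int
        Number of nucleotides the structure spans.
    pairs : frozenset of (int, int)
        Base pairs ``(i, j)`` with ``1 <= i < j <= length``.
    """

    length: int
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        seen = {}
        for i, j in pairs:
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair ({i},{j}) out of range 1..{self.length}")
            for k in (i, j):
                if k in seen:
                    raise StructureError(f"position {k} paired more than once")
                seen[k] = True
        # nestedness: no two pairs may cross
        sp = sorted(pairs)
        stack = []
        for i, j in sp:
            while stack and stack[-1] < i:
                stack.pop()
            if stack and not j < stack[-1]:
                raise StructureError(f"crossing (pseudoknotted) pair ({i},{j})")
            stack.append(j)

    # -- basic queries ---------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner(self) -> dict:
        """Map position -> paired position (both directions)."""
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def is_open_chain(self) -> bool:
        return not self.pairs

    def has_lone_pairs(self) -> bool:
        """True if some helix consists of a single (isolated) pair."""
        for i, j in self.pairs:
            if (i + 1, j - 1) not in self.pairs and (i - 1, j + 1) not in self.pairs:
                return True
        return False

    def validate_sequence(self, seq: str, min_hairpin: int = 3) -> None:
        """Check pairs are canonical for *seq* and hairpins are big enough."""
        if len(seq) != self.length:
            raise StructureError("sequence length does not match structure length")
        for i, j in self.pairs:
            if not can_pair(seq[i - 1], seq[j - 1]):
                raise StructureError(f"non-canonical pair {seq[i-1]}{seq[j-1]} at ({i},{j})")
            if j - i - 1 < min_hairpin and not any(
                (p, q) in self.pairs for p in range(i + 1, j) for q in range(p + 1, j)
            ):
                raise StructureError(f"hairpin loop closed by ({i},{j}) shorter than {min_hairpin}")

    # -- distances -------------------------------------------------------
    def bp_distance(self, other: "SecondaryStructure") -> int:
        """Number of pairs present in exactly one of the two structures."""
        if other.length != self.length:
            raise StructureError("structures of different length")
        return len(self.pairs ^ other.pairs)

    # -- serialization ---------------------------------------------------
    def dot_bracket(self) -> str:
        s = ["."] * self.length
        for i, j in self.pairs:
            s[i - 1] = "("
            s[j - 1] = ")"
        return "".join(s)

    @classmethod
    def from_dot_bracket(cls, db: str) -> "SecondaryStructure":
        stack, pairs = [], []
        for pos, c in enumerate(db, start=1):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif c != ".":
                raise StructureError(f"unexpected character {c!r} in dot-bracket")
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1]}")
        return cls(length=len(db), pairs=frozenset(pairs))

    def to_ct(self, seq: str, title: str = "structure") -> str:
        """Render in connectivity-table (CT) format."""
        if len(seq) != self.length:
            raise StructureError("sequence length does not match structure length")
        partner = self.partner()
        lines = [f"{self.length}\t{title}"]
        for i in range(1, self.length + 1):
            lines.append(
                f"{i}\t{seq[i-1]}\t{i-1}\t{(i+1) if i < self.length else 0}"
                f"\t{partner.get(i, 0)}\t{i}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_ct(cls, text: str) -> tuple["SecondaryStructure", str]:
        """Parse a CT file; returns (structure, sequence)."""
        lines = [ln for ln in text.splitlines() if ln.strip()]
        try:
            n = int(lines[0].split()[0])
        except (IndexError, ValueError) as exc:
            raise StructureError("malformed CT header") from exc
        seq, pairs = [], set()
        for ln in lines[1 : n + 1]:
            f = ln.split()
            i, base, j = int(f[0]), f[1], int(f[4])
            seq.append(base)
            if j > i:
                pairs.add((i, j))
        return cls(length=n, pairs=frozenset(pairs)), "".join(seq)


def loop_decomposition(structure: SecondaryStructure):
    """Decompose a structure into loops.

    Returns a list of dicts, one per loop, with keys ``kind`` (``hairpin``,
    ``stack``, ``bulge``, ``internal``, ``multibranch``, ``exterior``),
    ``closing`` (the closing pair, or None for the exterior loop),
    ``branches`` (list of directly enclosed pairs) and ``unpaired``
    (list of unpaired positions in the loop).
    """
    partner = structure.partner()
    n = structure.length

    def scan_region(lo: int, hi: int):
        """Branches and unpaired positions strictly inside [lo, hi]."""
        branches, unpaired = [], []
        k = lo
        while k <= hi:
            if k in partner and partner[k] > k:
                branches.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired.append(k)
                k += 1
        return branches, unpaired

    loops = []
    ext_branches, ext_unpaired = scan_region(1, n)
    loops.append(
        {"kind": "exterior", "closing": None, "branches": ext_branches, "unpaired": ext_unpaired}
    )
    todo = list(ext_branches)
    while todo:
        i, j = todo.pop()
        branches, unpaired = scan_region(i + 1, j - 1)
        todo.extend(branches)
        if not branches:
            kind = "hairpin"
        elif len(branches) == 1:
            (p, q) = branches[0]
            left, right = p - i - 1, j - q - 1
            if left == 0 and right == 0:
                kind = "stack"
            elif left == 0 or right == 0:
                kind = "bulge"
            else:
                kind = "internal"
        else:
            kind = "multibranch"
        loops.append({"kind": kind, "closing": (i, j), "branches": branches, "unpaired": unpaired})
    return loops
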