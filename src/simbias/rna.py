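"""RNA secondary-structure phenotypes: validation, coarse-graining and
binary encoding.

Secondary structures arrive in dot-bracket notation (matched parentheses are
base pairs, dots unpaired bases; pseudoknots are outside the model, so
nesting is enforced).  Two encodings feed the Lempel-Ziv complexity
estimator:

* full structure: ``.`` -> 00, ``(`` -> 10, ``)`` -> 01, so a length-n
  structure becomes a 2n-bit string;
* level-5 abstract shapes (stem arrangement only, strings over ``[`` and
  ``]``): ``[`` -> 0, ``]`` -> 1, and the trivial unpaired shape ``_``
  becomes the single bit 0.

The level-5 coarse-grainer implemented here reduces a dot-bracket structure
to its stem arrangement: unpaired positions are dropped, each maximal helix
becomes one bracket pair, and helices separated only by bulges or internal
loops (no intervening branching) merge into a single stem.  It is a
documented approximation of the abstract-shape level 5 of the RNAshapes
family of tools; structures may equally be supplied pre-coarse-grained.
Thermodynamic folding itself is out of scope — structure lists come from
external folding engines or databases.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .complexity import lz_complexity


class StructureValidationError(ValueError):
    """Malformed dot-bracket or abstract-shape string."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None
                         else f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class DotBracket:
    """A validated dot-bracket secondary structure."""

    text: str

    def __len__(self):
        return len(self.text)

    def __str__(self):
        return self.text


@dataclass(frozen=True)
class AbstractShape5:
    """A validated level-5 abstract shape: balanced brackets or ``_``."""

    text: str

    def __len__(self):
        return len(self.text)

    def __str__(self):
        return self.text


def validate_dotbracket(s) -> DotBracket:
    """Validate alphabet {., (, )} and proper nesting; errors carry the
    offending position."""
    if isinstance(s, DotBracket):
        return s
    depth = 0
    for i, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise StructureValidationError("unmatched ')'", i)
        elif ch != ".":
            raise StructureValidationError(f"invalid character {ch!r}", i)
    if depth != 0:
        raise StructureValidationError(f"{depth} unmatched '('", len(s))
    if not s:
        raise StructureValidationError("empty structure")
    return DotBracket(s)


def validate_level5(s) -> AbstractShape5:
    """Validate a level-5 abstract shape: ``_`` alone, or balanced ``[]``."""
    if isinstance(s, AbstractShape5):
        return s
    if s == "_":
        return AbstractShape5(s)
    depth = 0
    for i, ch in enumerate(s):
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise StructureValidationError("unmatched ']'", i)
        else:
            raise StructureValidationError(f"invalid character {ch!r}", i)
    if depth != 0:
        raise StructureValidationError(f"{depth} unmatched '['", len(s))
    if not s:
        raise StructureValidationError("empty shape")
    return AbstractShape5(s)


_DB_BITS = {".": "00", "(": "10", ")": "01"}


def encode_dotbracket(s) -> str:
    """Binary encoding of a dot-bracket structure (2 bits per position)."""
    db = validate_dotbracket(s)
    return "".join(_DB_BITS[ch] for ch in db.text)


def encode_level5(s) -> str:
    """Binary encoding of a level-5 shape; the trivial shape ``_`` is the
    single bit 0."""
    shape = validate_level5(s)
    if shape.text == "_":
        return "0"
    return "".join("0" if ch == "[" else "1" for ch in shape.text)


def _pair_tree(text: str):
    """Nesting tree of base pairs: each node is a list of child nodes; the
    virtual root collects external-loop pairs."""
    root: list = []
    stack = [root]
    for ch in text:
        if ch == "(":
            node: list = []
            stack[-1].append(node)
            stack.append(node)
        elif ch == ")":
            stack.pop()
    return root


def _contract(node: list) -> list:
    """Contract unary chains: a pair enclosing exactly one pair-group merges
    with it (helices and bulge/internal-loop-separated helices become one
    stem)."""
    while len(node) == 1:
        node = node[0]
    return [_contract(child) for child in node]


def _render(children: list) -> str:
    return "".join("[" + _render(ch) + "]" for ch in children)


def coarse_grain_level5(s) -> AbstractShape5:
    """Level-5 abstract shape of a dot-bracket structure.

    Unpaired positions are removed; every maximal stem (helices separated
    only by bulges/internal loops) becomes one ``[]`` pair enclosing its
    branches; a structure with no pairs reduces to ``_``.
    """
    db = validate_dotbracket(s)
    tree = _pair_tree(db.text)
    if not tree:
        return AbstractShape5("_")
    children = [_contract(child) for child in tree]
    return AbstractShape5(_render(children))


def structure_frequency_analysis(structures, level: str = "full"
                                 ) -> pd.DataFrame:
    """Group identical structures and attach LZ complexities.

    ``level`` is "full" for dot-bracket input or "5" for abstract shapes.
    Returns a DataFrame with columns (structure, count, probability,
    complexity), one row per distinct structure, in descending count order.
    The table joins against a second list via its ``structure`` column for
    natural-versus-sampled comparisons.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("no structures supplied")
    if level not in ("full", "5"):
        raise ValueError("level must be 'full' or '5'")
    counts: dict = {}
    for s in structures:
        text = s.text if isinstance(s, (DotBracket, AbstractShape5)) else s
        counts[text] = counts.get(text, 0) + 1
    total = len(structures)
    rows = []
    for text, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        bits = (encode_dotbracket(text) if level == "full"
                else encode_level5(text))
        rows.append({"structure": text, "count": c,
                     "probability": c / total,
                     "complexity": lz_complexity(bits).value})
    return pd.DataFrame(rows)
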