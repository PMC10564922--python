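"""RNA duplex nearest-neighbor thermodynamic parameters.

Free energies (kcal/mol, 37 °C) transcribed from the Turner 2004 RNA
parameter set (Mathews DH, Disney MD, Childs JL, Schroeder SJ, Zuker M,
Turner DH, PNAS 101:7287-7292, 2004; stacking table as distributed in the
`rna_turner2004` parameter file). Watson-Crick and G:U wobble stacks are
included; positive entries (e.g. 5'GG/3'UU) are destabilizing.

Conventions
-----------
A base pair is written ``(x, y)``: ``x`` on the strand read 5'->3' and
``y`` on the complementary strand read 3'->5'. ``stack_dg(outer, inner)``
returns the stacking free energy of the motif::

    5'-x_outer x_inner-3'
    3'-y_outer y_inner-5'
"""

from __future__ import annotations

# Gas constant x 310.15 K, kcal/mol — used for loop-length extrapolation.
_RT37 = 0.6163

_PAIR_ORDER = [("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")]

# Rows: outer pair (i,j); columns: inner pair read from the opposite strand
# (j-1, i+1), matching the published table layout. kcal/mol.
_STACK_MATRIX = [
    #  CG     GC     GU     UG     AU     UA
    [-2.40, -3.30, -2.10, -1.40, -2.10, -2.10],  # CG
    [-3.30, -3.40, -2.50, -1.50, -2.20, -2.40],  # GC
    [-2.10, -2.50, +1.30, -0.50, -1.40, -1.30],  # GU
    [-1.40, -1.50, -0.50, +0.30, -0.60, -1.00],  # UG
    [-2.10, -2.20, -1.40, -0.60, -1.10, -0.90],  # AU
    [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30],  # UA
]

_IDX = {p: i for i, p in enumerate(_PAIR_ORDER)}

#: Duplex initiation penalty, kcal/mol.
DUPLEX_INIT = 4.10

#: Penalty per helix end closed by an A:U or G:U pair, kcal/mol.
TERMINAL_AU = 0.50

# Bulge-loop penalties by length (kcal/mol); lengths beyond the table are
# extrapolated with the Jacobson-Stockmayer 1.75*RT*ln(n/6) term.
_BULGE = {1: 3.80, 2: 2.80, 3: 3.20, 4: 3.60, 5: 4.00, 6: 4.40}

#: Pairs treated as canonical (Watson-Crick plus G:U wobble).
CANONICAL_PAIRS = frozenset(_PAIR_ORDER)

WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})


def is_canonical(x: str, y: str) -> bool:
    """True if (x, y) is a Watson-Crick or G:U wobble pair."""
    return (x, y) in CANONICAL_PAIRS


def stack_dg(outer: tuple[str, str], inner: tuple[str, str]) -> float:
    """Stacking free energy of ``inner`` on ``outer`` (see module docstring)."""
    if outer not in _IDX or inner not in _IDX:
        raise ValueError(f"non-canonical pair in stack: {outer}/{inner}")
    return _STACK_MATRIX[_IDX[outer]][_IDX[inner[::-1]]]


def bulge_dg(n: int) -> float:
    """Free-energy penalty of a bulge loop of ``n`` unpaired nucleotides."""
    if n < 1:
        raise ValueError("bulge length must be >= 1")
    if n in _BULGE:
        return _BULGE[n]
    import math

    return _BULGE[6] + 1.75 * _RT37 * math.log(n / 6.0)


def terminal_penalty(pair: tuple[str, str]) -> float:
    """Helix-end penalty: 0.50 kcal/mol for A:U and G:U ends, else 0."""
    if pair in (("A", "U"), ("U", "A")) or pair in WOBBLE_PAIRS:
        return TERMINAL_AU
    return 0.0
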