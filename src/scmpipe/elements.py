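"""Monoisotopic element masses and molecular-formula arithmetic.

Masses are CODATA/IUPAC monoisotopic values (most abundant isotope), in
Da. ``formula_mass`` parses standard Hill-notation formulas, including
parenthesised groups, and is used both to build the bundled mass table
and as the independent oracle in tests.
"""

from __future__ import annotations

import re
from collections import Counter

from .errors import InvariantError

# most-abundant-isotope masses, Da
MONOISOTOPIC: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "Se": 79.9165213,
    "Fe": 55.9349375,
    "Mg": 23.9850417,
    "Ca": 39.96259098,
    "Zn": 63.9291422,
    "Si": 27.9769265325,
    "B": 11.0093054,
}

ELECTRON_MASS = 0.00054857990907  # Da

# singly charged adduct shifts: neutral mass -> observed m/z (z = 1)
PROTON = MONOISOTOPIC["H"] - ELECTRON_MASS
ADDUCT_SHIFTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (PROTON, "positive"),
    "[M+Na]+": (MONOISOTOPIC["Na"] - ELECTRON_MASS, "positive"),
    "[M+K]+": (MONOISOTOPIC["K"] - ELECTRON_MASS, "positive"),
    "[M-H]-": (-PROTON, "negative"),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def parse_formula(formula: str) -> Counter:
    """Parse ``C6H12O6``-style formulas (with optional parentheses)."""
    stack: list[Counter] = [Counter()]
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos:
            raise InvariantError(f"cannot parse formula {formula!r} at position {pos}")
        elem, count, open_p, close_p, close_n = m.groups()
        if elem:
            if elem not in MONOISOTOPIC:
                raise InvariantError(f"unknown element {elem!r} in {formula!r}")
            stack[-1][elem] += int(count) if count else 1
        elif open_p:
            stack.append(Counter())
        elif close_p:
            if len(stack) < 2:
                raise InvariantError(f"unbalanced ')' in {formula!r}")
            group = stack.pop()
            mult = int(close_n) if close_n else 1
            for el, n in group.items():
                stack[-1][el] += n * mult
        pos = m.end()
    if len(stack) != 1:
        raise InvariantError(f"unbalanced '(' in {formula!r}")
    return stack[0]


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a neutral molecular formula, Da."""
    counts = parse_formula(formula)
    return sum(MONOISOTOPIC[el] * n for el, n in counts.items())
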