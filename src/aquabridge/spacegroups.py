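"""Symmetry operators for the space groups most common in protein crystals.

Protein crystals can only adopt the 65 Sohncke space groups; the handful
bundled here covers the large majority of deposited structures (P1, the
primitive orthorhombic/monoclinic screw-axis groups, C2 and P21212).
Operators are stored as (3x3 rotation, translation in fractional
coordinates).  Unknown Hermann-Mauguin symbols raise ``SpaceGroupError`` --
this is a documented limit, not a silent fallback.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SpaceGroupError", "operators", "known_space_groups"]


class SpaceGroupError(ValueError):
    """Raised for Hermann-Mauguin symbols absent from the bundled table."""


def _op(rot, trans):
    return np.asarray(rot, dtype=float), np.asarray(trans, dtype=float)

_I = [[1, 0, 0], [0, 1, 0], [0, 0, 1]]

# rotation diagonals used by the orthorhombic / monoclinic groups
_D_XX = [[1, 0, 0], [0, -1, 0], [0, 0, -1]]   # 2-fold along a
_D_YY = [[-1, 0, 0], [0, 1, 0], [0, 0, -1]]   # 2-fold along b
_D_ZZ = [[-1, 0, 0], [0, -1, 0], [0, 0, 1]]   # 2-fold along c

_TABLE: dict[str, list] = {
    "P 1": [_op(_I, [0, 0, 0])],
    "P 1 21 1": [
        _op(_I, [0, 0, 0]),
        _op(_D_YY, [0, 0.5, 0]),
    ],
    "C 1 2 1": [
        _op(_I, [0, 0, 0]),
        _op(_D_YY, [0, 0, 0]),
        _op(_I, [0.5, 0.5, 0]),
        _op(_D_YY, [0.5, 0.5, 0]),
    ],
    # the four operators of P 21 21 21 (IT No. 19)
    "P 21 21 21": [
        _op(_I, [0, 0, 0]),
        _op(_D_ZZ, [0.5, 0, 0.5]),
        _op(_D_YY, [0, 0.5, 0.5]),
        _op(_D_XX, [0.5, 0.5, 0]),
    ],
    "P 21 21 2": [
        _op(_I, [0, 0, 0]),
        _op(_D_ZZ, [0, 0, 0]),
        _op(_D_YY, [0.5, 0.5, 0]),
        _op(_D_XX, [0.5, 0.5, 0]),
    ],
    "P 2 2 2": [
        _op(_I, [0, 0, 0]),
        _op(_D_ZZ, [0, 0, 0]),
        _op(_D_YY, [0, 0, 0]),
        _op(_D_XX, [0, 0, 0]),
    ],
}

# tolerated spelling variants (condensed PDB style)
_ALIASES = {
    "P1": "P 1",
    "P21": "P 1 21 1",
    "P 21": "P 1 21 1",
    "C2": "C 1 2 1",
    "C 2": "C 1 2 1",
    "P212121": "P 21 21 21",
    "P21212": "P 21 21 2",
    "P222": "P 2 2 2",
}


def known_space_groups() -> list[str]:
    return sorted(_TABLE)


def operators(symbol: str):
    """Return the list of (rotation, translation) operators for *symbol*.

    Raises
    ------
    SpaceGroupError
        If the symbol is not in the bundled table.
    """
    key = symbol.strip()
    key = _ALIASES.get(key, key)
    if key not in _TABLE:
        raise SpaceGroupError(
            f"space group {symbol!r} not in bundled table; "
            f"known: {', '.join(known_space_groups())}"
        )
    return [(r.copy(), t.copy()) for r, t in _TABLE[key]]
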