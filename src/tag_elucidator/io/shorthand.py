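"""Lipid shorthand grammar: ``TG(18:1(n-9,cis)/5:1/5:1)``.

Each slot is ``carbons:double_bonds`` with an optional parenthesised list
of double-bond annotations, one per double bond, separated by ``;``:
``n-x`` optionally followed by ``,cis`` or ``,trans``. Slot order encodes
sn-1/2/3 when the structure's sn assignment is resolved.
"""

from __future__ import annotations

import re

from ..chem import FattyAcyl, TagStructure
from ..errors import FormulaError

_ACYL = re.compile(r"^(\d+):(\d+)(?:\((.*)\))?$")
_DB = re.compile(r"^n-(\d+)(?:,(cis|trans))?$")


def parse_acyl_shorthand(text: str) -> FattyAcyl:
    """Parse one slot, e.g. ``"18:2(n-6,cis;n-9,cis)"``."""
    match = _ACYL.match(text.strip())
    if match is None:
        raise FormulaError(f"malformed acyl shorthand {text!r}")
    n_carbons, n_double_bonds = int(match.group(1)), int(match.group(2))
    positions: tuple[int, ...] | None = None
    geometries: tuple[str, ...] | None = None
    if match.group(3) is not None:
        pos, geom = [], []
        for part in match.group(3).split(";"):
            db_match = _DB.match(part.strip())
            if db_match is None:
                raise FormulaError(
                    f"malformed double-bond annotation {part.strip()!r} in {text!r}"
                )
            pos.append(int(db_match.group(1)))
            geom.append(db_match.group(2) or "unknown")
        positions = tuple(pos)
        geometries = tuple(geom) if any(g != "unknown" for g in geom) else None
    return FattyAcyl(n_carbons, n_double_bonds, positions, geometries)


def format_acyl_shorthand(a: FattyAcyl) -> str:
    base = f"{a.n_carbons}:{a.n_double_bonds}"
    if a.db_positions is None:
        return base
    parts = []
    for i, x in enumerate(a.db_positions):
        geometry = a.db_geometries[i] if a.db_geometries else "unknown"
        parts.append(f"n-{x},{geometry}" if geometry != "unknown" else f"n-{x}")
    return f"{base}({';'.join(parts)})"


def parse_lipid_shorthand(text: str) -> TagStructure:
    """Parse ``TG(slot/slot/slot)`` into a :class:`TagStructure`."""
    text = text.strip()
    if not (text.startswith("TG(") and text.endswith(")")):
        raise FormulaError(f"lipid shorthand must look like 'TG(...)', got {text!r}")
    body = text[3:-1]
    slots = _split_slots(body)
    if len(slots) != 3:
        raise FormulaError(f"expected three acyl slots in {text!r}, got {len(slots)}")
    acyls = tuple(parse_acyl_shorthand(s) for s in slots)
    return TagStructure(acyls=acyls)


def _split_slots(body: str) -> list[str]:
    # split on '/' at depth 0 only; annotations may not contain '/'
    slots, depth, current = [], 0, []
    for ch in body:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormulaError(f"unbalanced parentheses in {body!r}")
        if ch == "/" and depth == 0:
            slots.append("".join(current))
            current = []
        else:
            current.append(ch)
    if depth != 0:
        raise FormulaError(f"unbalanced parentheses in {body!r}")
    slots.append("".join(current))
    return slots


def format_lipid_shorthand(t: TagStructure) -> str:
    return "TG(" + "/".join(format_acyl_shorthand(a) for a in t.acyls) + ")"
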