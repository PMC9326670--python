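"""Deterministic SVG rendering of items and the response panel.

The stem is drawn as a 3x3 grid on a 600x600 canvas with 4-px cell
borders; elements are drawn in black.  ``response_panel`` mode lays out
all 20 construction elements as separately addressable groups so a
delivery layer can wire up selection.  Output is byte-deterministic for a
given item.
"""

from __future__ import annotations

from .elements import ELEMENTS, N_ELEMENTS, GlyphElement, Primitive
from .errors import UsageError
from .items import MatrixItem

CANVAS = 600
CELL = CANVAS // 3
BORDER = 4
GLYPH_STROKE = 3

MODES = ("stem", "full", "response_panel")

_ELEMENT_BY_ID: dict[int, GlyphElement] = {e.element_id: e for e in ELEMENTS}


def _fmt(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".")


def _primitive_svg(prim: Primitive, ox: float, oy: float, scale: float) -> str:
    pts = [(ox + x * scale, oy + y * scale) for x, y in prim.points]
    if prim.kind == "segment":
        (x1, y1), (x2, y2) = pts
        return (
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
            f'stroke="black" stroke-width="{GLYPH_STROKE}" stroke-linecap="round"/>'
        )
    if prim.kind == "polyline":
        coords = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        return (
            f'<polyline points="{coords}" fill="none" stroke="black" '
            f'stroke-width="{GLYPH_STROKE}"/>'
        )
    if prim.kind == "polygon":
        coords = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        return f'<polygon points="{coords}" fill="black"/>'
    if prim.kind == "arc":
        (x1, y1), (x2, y2) = pts
        r = prim.radius * scale
        return (
            f'<path d="M {_fmt(x1)} {_fmt(y1)} A {_fmt(r)} {_fmt(r)} 0 0 '
            f'{prim.sweep} {_fmt(x2)} {_fmt(y2)}" fill="none" stroke="black" '
            f'stroke-width="{GLYPH_STROKE}"/>'
        )
    raise UsageError(f"unknown primitive kind {prim.kind!r}")  # pragma: no cover


def _element_svg(element_id: int, ox: float, oy: float, scale: float) -> list[str]:
    elem = _ELEMENT_BY_ID[element_id]
    return [_primitive_svg(p, ox, oy, scale) for p in elem.geometry]


def _grid_svg(item: MatrixItem, n_cells_drawn: int) -> str:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{CANVAS}" height="{CANVAS}" '
        f'viewBox="0 0 {CANVAS} {CANVAS}">',
        f'<rect x="0" y="0" width="{CANVAS}" height="{CANVAS}" fill="white"/>',
    ]
    pad = BORDER / 2
    for i in range(9):
        row, col = divmod(i, 3)
        x0, y0 = col * CELL, row * CELL
        lines.append(f'<g id="cell-{i + 1}">')
        lines.append(
            f'<rect x="{_fmt(x0 + pad)}" y="{_fmt(y0 + pad)}" '
            f'width="{CELL - BORDER}" height="{CELL - BORDER}" fill="none" '
            f'stroke="black" stroke-width="{BORDER}"/>'
        )
        if i < n_cells_drawn:
            inset = BORDER + 2
            scale = CELL - 2 * inset
            for eid in sorted(item.cells[i]):
                lines.extend(_element_svg(eid, x0 + inset, y0 + inset, scale))
        lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def _response_panel_svg() -> str:
    cols, rows = 5, 4
    cell = 120
    width, height = cols * cell, rows * cell
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="white"/>',
    ]
    for eid in range(N_ELEMENTS):
        row, col = divmod(eid, cols)
        x0, y0 = col * cell, row * cell
        lines.append(f'<g id="element-{eid}" class="construction-element">')
        lines.append(
            f'<rect x="{_fmt(x0 + 1)}" y="{_fmt(y0 + 1)}" width="{cell - 2}" '
            f'height="{cell - 2}" fill="none" stroke="#888" stroke-width="1"/>'
        )
        inset = 8
        lines.extend(_element_svg(eid, x0 + inset, y0 + inset, cell - 2 * inset))
        lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def render_svg(item: MatrixItem, mode: str = "stem") -> str:
    """Render an item to an SVG document string.

    ``stem`` draws the eight visible cells and an empty ninth cell,
    ``full`` includes the solution, and ``response_panel`` draws all 20
    construction elements as separate groups.
    """
    if mode == "stem":
        return _grid_svg(item, 8)
    if mode == "full":
        return _grid_svg(item, 9)
    if mode == "response_panel":
        return _response_panel_svg()
    raise UsageError(f"unknown render mode {mode!r}; expected one of {MODES}")
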