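"""Block optotype glyphs on the 5x5 stroke grid (stroke = height / 5).

Each glyph is five strings of '#' (lit) / '.' (dark), top row first.
This table is data; edit or extend it to change the letter shapes.
"""

GLYPHS: dict[str, tuple[str, str, str, str, str]] = {
    "E": (
        "#####",
        "#....",
        "#####",
        "#....",
        "#####",
    ),
    "F": (
        "#####",
        "#....",
        "#####",
        "#....",
        "#....",
    ),
    "P": (
        "#####",
        "#...#",
        "#####",
        "#....",
        "#....",
    ),
    "T": (
        "#####",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
    ),
    "O": (
        "#####",
        "#...#",
        "#...#",
        "#...#",
        "#####",
    ),
    "Z": (
        "#####",
        "...#.",
        "..#..",
        ".#...",
        "#####",
    ),
    "L": (
        "#....",
        "#....",
        "#....",
        "#....",
        "#####",
    ),
    "D": (
        "####.",
        "#...#",
        "#...#",
        "#...#",
        "####.",
    ),
}

#: Number of lit cells (out of 25) per glyph, asserted against the table.
LIT_CELLS: dict[str, int] = {
    c: sum(row.count("#") for row in rows) for c, rows in GLYPHS.items()
}
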