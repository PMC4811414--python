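"""Published frequency fixture: hue-category counts per condition.

Nine hue categories by 2 preferences x 3 contexts, n = 85 participants per
condition, as printed in the source study's bootstrapped-comparison table,
together with that table's compact-letter columns (used only to compare
significance *structure* -- letter glyphs are a presentation choice).
"""

from __future__ import annotations

from .hue_categories import CATEGORY_LABELS

__all__ = ["TABLE2_N", "TABLE2_COUNTS", "TABLE2_LETTERS", "CONDITION_ORDER"]

TABLE2_N = 85

CONDITION_ORDER = [
    ("most", "general"),
    ("least", "general"),
    ("most", "walls"),
    ("least", "walls"),
    ("most", "t-shirt"),
    ("least", "t-shirt"),
]

# counts in CATEGORY_LABELS order:
# Red, Orange, Yellow, Yellow-Green, Green, Green-Blue, Blue, Purple, Achromatic
TABLE2_COUNTS = {
    ("most", "general"): (26, 5, 5, 2, 9, 23, 8, 6, 1),
    ("least", "general"): (8, 12, 34, 6, 3, 3, 0, 11, 8),
    ("most", "walls"): (21, 9, 11, 4, 5, 12, 2, 7, 14),
    ("least", "walls"): (20, 9, 13, 4, 9, 4, 2, 6, 18),
    ("most", "t-shirt"): (27, 2, 4, 3, 6, 11, 10, 6, 16),
    ("least", "t-shirt"): (6, 18, 26, 6, 7, 2, 1, 16, 3),
}

TABLE2_LETTERS = {
    ("most", "general"): ("a", "b", "b", "b", "abc", "ac", "bc", "b", "b"),
    ("least", "general"): ("ab", "a", "c", "ab", "ab", "ab", "b", "a", "ab"),
    ("most", "walls"): ("a", "abc", "abc", "bc", "bc", "abc", "b", "abc", "ac"),
    ("least", "walls"): ("a", "abc", "abc", "bc", "abc", "bc", "b", "abc", "ac"),
    ("most", "t-shirt"): ("a", "b", "bc", "bc", "bc", "abc", "abc", "bc", "ac"),
    ("least", "t-shirt"): ("abc", "ad", "d", "abc", "abc", "b", "b", "acd", "bc"),
}

assert all(sum(v) == TABLE2_N for v in TABLE2_COUNTS.values())
assert all(len(v) == len(CATEGORY_LABELS) for v in TABLE2_COUNTS.values())
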