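"""Nine-category perceptual hue binning of CIE LCh colours.

Continuous hue angles are binned into eight everyday chromatic categories
(red .. purple), each a half-open arc of the hue circle, plus an achromatic
category for colours whose chroma is at or below a cut-off (default 5, i.e.
greys from white to black).  Arcs are lower-inclusive ``[lo, hi)``: at a
printed shared boundary such as 40 deg (red/orange), the hue belongs to the
category whose arc starts there.

The scheme is data, not code: alternate schemes can be loaded from JSON for
sensitivity analyses.  The default scheme is:

=============  =========  ==========
label          focal hue  hue range
=============  =========  ==========
Red                25     346 - 40
Orange             57      40 - 72
Yellow             87      72 - 105
Yellow-Green      116     105 - 130
Green             144     130 - 166
Green-Blue        194     166 - 220
Blue              244     220 - 275
Purple            306     275 - 346
Achromatic        none    any (C <= 5)
=============  =========  ==========
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .colour_space import CIELCh

__all__ = [
    "HueCategory",
    "CategoryScheme",
    "DEFAULT_SCHEME",
    "CATEGORY_LABELS",
    "categorize",
    "focal_hue",
    "validate_scheme",
]

ACHROMATIC = "Achromatic"


@dataclass(frozen=True)
class HueCategory:
    """One named hue category.

    ``hue_range`` is a half-open arc [lo, hi) in degrees; lo > hi means the
    arc wraps through 360/0 (e.g. red, 346-40).  Achromatic categories have
    no focal hue and no arc.
    """

    label: str
    focal_hue: float | None
    hue_range: tuple[float, float] | None

    @property
    def chromatic(self) -> bool:
        return self.hue_range is not None

    def contains(self, h: float) -> bool:
        if self.hue_range is None:
            return False
        lo, hi = self.hue_range
        h = h % 360.0
        if lo <= hi:
            return lo <= h < hi
        return h >= lo or h < hi  # wrapping arc

    def width(self) -> float:
        lo, hi = self.hue_range
        return (hi - lo) % 360.0 or 360.0


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered categories plus the achromatic chroma cut-off (C <= cutoff)."""

    categories: tuple[HueCategory, ...]
    chroma_cutoff: float = 5.0

    def __post_init__(self) -> None:
        problems = validate_scheme(self)
        if problems:
            raise ValueError("invalid category scheme: " + "; ".join(problems))

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.categories]

    @property
    def chromatic_categories(self) -> list[HueCategory]:
        return [c for c in self.categories if c.chromatic]

    def __getitem__(self, label: str) -> HueCategory:
        for c in self.categories:
            if c.label == label:
                return c
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "chroma_cutoff": self.chroma_cutoff,
            "categories": [
                {
                    "label": c.label,
                    "focal_hue": c.focal_hue,
                    "hue_range": list(c.hue_range) if c.hue_range else None,
                }
                for c in self.categories
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryScheme":
        cats = tuple(
            HueCategory(
                label=c["label"],
                focal_hue=c["focal_hue"],
                hue_range=tuple(c["hue_range"]) if c["hue_range"] else None,
            )
            for c in d["categories"]
        )
        return cls(categories=cats, chroma_cutoff=float(d["chroma_cutoff"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CategoryScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def validate_scheme(scheme: CategoryScheme) -> list[str]:
    """Check that chromatic arcs partition the hue circle exactly once.

    Returns a list of human-readable violations (empty iff valid).  Coverage
    is checked analytically from the arc endpoints, which is exact for
    half-open lower-inclusive arcs.
    """
    problems: list[str] = []
    if scheme.chroma_cutoff < 0:
        problems.append(f"chroma cut-off {scheme.chroma_cutoff} < 0")
    chromatic = [c for c in scheme.categories if c.chromatic]
    achromatic = [c for c in scheme.categories if not c.chromatic]
    if len(achromatic) != 1:
        problems.append(f"expected exactly 1 achromatic category, got {len(achromatic)}")
    if not chromatic:
        problems.append("no chromatic categories")
        return problems
    total = sum(c.width() for c in chromatic)
    # Pairwise overlap: an arc pair overlaps iff one's lower endpoint lies
    # strictly inside the other.
    for i, a in enumerate(chromatic):
        if a.focal_hue is not None and not a.contains(a.focal_hue):
            problems.append(f"{a.label}: focal hue {a.focal_hue} outside its range")
        for b in chromatic[i + 1 :]:
            if a.contains(b.hue_range[0]) or b.contains(a.hue_range[0]):
                problems.append(f"overlap between {a.label} and {b.label}")
    if abs(total - 360.0) > 1e-9:
        problems.append(f"chromatic ranges cover {total} degrees, expected 360")
    return problems


def _build_scheme(rows, cutoff=5.0, validate=True) -> CategoryScheme:
    cats = tuple(HueCategory(*row) for row in rows)
    if validate:
        return CategoryScheme(cats, cutoff)
    # bypass __post_init__ validation (used to construct broken schemes in tests)
    scheme = object.__new__(CategoryScheme)
    object.__setattr__(scheme, "categories", cats)
    object.__setattr__(scheme, "chroma_cutoff", cutoff)
    return scheme


DEFAULT_SCHEME = _build_scheme(
    [
        ("Red", 25.0, (346.0, 40.0)),
        ("Orange", 57.0, (40.0, 72.0)),
        ("Yellow", 87.0, (72.0, 105.0)),
        ("Yellow-Green", 116.0, (105.0, 130.0)),
        ("Green", 144.0, (130.0, 166.0)),
        ("Green-Blue", 194.0, (166.0, 220.0)),
        ("Blue", 244.0, (220.0, 275.0)),
        ("Purple", 306.0, (275.0, 346.0)),
        (ACHROMATIC, None, None),
    ]
)

CATEGORY_LABELS = DEFAULT_SCHEME.labels


def categorize(c: CIELCh, scheme: CategoryScheme = DEFAULT_SCHEME) -> str:
    """Return the category label of an LCh colour.

    Achromatic iff C <= cut-off (independent of h and L); otherwise the
    unique chromatic category whose arc contains h.
    """
    if c.C <= scheme.chroma_cutoff:
        for cat in scheme.categories:
            if not cat.chromatic:
                return cat.label
        raise ValueError("scheme has no achromatic category")
    for cat in scheme.chromatic_categories:
        if cat.contains(c.h):
            return cat.label
    raise ValueError(f"no category contains hue {c.h}")  # pragma: no cover


def focal_hue(label: str, scheme: CategoryScheme = DEFAULT_SCHEME) -> float:
    """Focal hue angle of a chromatic category (e.g. Red -> 25)."""
    cat = scheme[label]
    if cat.focal_hue is None:
        raise ValueError(f"category {label!r} has no focal hue")
    return cat.focal_hue
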