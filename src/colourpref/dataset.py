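"""The canonical choice table: one row per participant x preference x context.

Columns
-------
participant        integer id
preference         "most" | "least"
context            "general" | "walls" | "t-shirt"
L, C, h            final colour in CIE LCh
r, g, b            derived device RGB (approximate, display-model dependent)
time_s             selection time in seconds
clicks             number of clicks (>= 1)
assoc_type         "object" | "concept" | "none"
assoc_text         free text, empty when assoc_type is "none"
valence            pleasantness of the association in [-45, 45];
                   missing exactly when assoc_type is "none"

Every participant contributes exactly six rows (2 preferences x 3 contexts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PREFERENCES",
    "CONTEXTS",
    "ASSOC_TYPES",
    "VALENCE_RANGE",
    "COLUMNS",
    "ChoiceDataset",
    "DatasetValidationError",
    "validate_choices",
]

PREFERENCES = ("most", "least")
CONTEXTS = ("general", "walls", "t-shirt")
ASSOC_TYPES = ("object", "concept", "none")
VALENCE_RANGE = (-45.0, 45.0)

COLUMNS = [
    "participant",
    "preference",
    "context",
    "L",
    "C",
    "h",
    "r",
    "g",
    "b",
    "time_s",
    "clicks",
    "assoc_type",
    "assoc_text",
    "valence",
]


class DatasetValidationError(ValueError):
    """Raised with a per-row account of what is wrong with a choice table."""


def validate_choices(df: pd.DataFrame) -> None:
    """Validate a choice table; raises :class:`DatasetValidationError`."""
    errors: list[str] = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing columns: {missing}")

    for idx, row in df.iterrows():
        where = f"row {idx} (participant {row['participant']}, {row['preference']}/{row['context']})"
        if row["preference"] not in PREFERENCES:
            errors.append(f"{where}: unknown preference {row['preference']!r}")
        if row["context"] not in CONTEXTS:
            errors.append(f"{where}: unknown context {row['context']!r}")
        if row["assoc_type"] not in ASSOC_TYPES:
            errors.append(f"{where}: unknown assoc_type {row['assoc_type']!r}")
        if not (0 <= row["L"] <= 100):
            errors.append(f"{where}: lightness {row['L']} outside [0, 100]")
        if row["C"] < 0:
            errors.append(f"{where}: negative chroma {row['C']}")
        if not (0 <= row["h"] < 360):
            errors.append(f"{where}: hue angle {row['h']} outside [0, 360)")
        if row["clicks"] < 1:
            errors.append(f"{where}: clicks {row['clicks']} < 1")
        has_valence = pd.notna(row["valence"])
        if row["assoc_type"] == "none" and has_valence:
            errors.append(f"{where}: valence present without an association")
        if row["assoc_type"] != "none" and not has_valence:
            errors.append(f"{where}: association without a valence rating")
        if has_valence and not (VALENCE_RANGE[0] <= row["valence"] <= VALENCE_RANGE[1]):
            errors.append(f"{where}: valence {row['valence']} outside {list(VALENCE_RANGE)}")

    dup = df.duplicated(subset=["participant", "preference", "context"], keep=False)
    if dup.any():
        for pid, pref, ctx in (
            df.loc[dup, ["participant", "preference", "context"]]
            .drop_duplicates()
            .itertuples(index=False)
        ):
            errors.append(f"duplicate rows for participant {pid}, {pref}/{ctx}")

    counts = df.groupby("participant").size()
    incomplete = counts[counts != 6]
    for pid, cnt in incomplete.items():
        errors.append(f"participant {pid} has {cnt} rows, expected 6")

    if errors:
        raise DatasetValidationError("\n".join(errors))


@dataclass
class ChoiceDataset:
    """A validated choice table plus generation/ingestion metadata."""

    data: pd.DataFrame
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_choices(self.data)

    @property
    def n_participants(self) -> int:
        return self.data["participant"].nunique()

    def condition(self, preference: str, context: str) -> pd.DataFrame:
        mask = (self.data["preference"] == preference) & (self.data["context"] == context)
        return self.data.loc[mask]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int | None = None) -> "ChoiceDataset":
        df = pd.read_csv(
            path,
            dtype={"assoc_text": str},
            keep_default_na=True,
        )
        df["assoc_text"] = df["assoc_text"].fillna("")
        return cls(data=df, seed=seed, metadata={"source": str(path)})

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChoiceDataset):
            return NotImplemented
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a[COLUMNS], b[COLUMNS], check_dtype=False)
        except AssertionError:
            return False
        return True
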