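"""End-to-end orchestration: choice table -> full analysis report.

Reads (or receives) a validated choice table, bins every colour into the
nine hue categories, builds per-condition frequency tables with one-decimal
percentages and compact letters from the bootstrap, runs the within-subject
ANOVAs on lightness, chroma, clicks and time, tests the association-type
distribution (Stuart-Maxwell, Wilcoxon), and summarises valence ratings.
The report is a plain JSON-serialisable dict plus a text rendering of the
frequency/letter table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .colour_space import CIELCh
from .dataset import ChoiceDataset, CONTEXTS, PREFERENCES, ASSOC_TYPES
from .fixtures import CONDITION_ORDER, TABLE2_COUNTS, TABLE2_N
from .hue_categories import CategoryScheme, DEFAULT_SCHEME, categorize
from .inference import (
    BootstrapConfig,
    bootstrap_pairwise,
    bonferroni_posthoc,
    letter_display,
    rm_anova_2x3,
    stuart_maxwell,
    wilcoxon_signed_rank,
)

__all__ = [
    "FrequencyTable",
    "read_choices",
    "frequency_table",
    "fixture_frequency_tables",
    "percent",
    "run_full_analysis",
    "summarize_valence",
    "association_distribution",
    "render_frequency_table",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Counts over the hue categories for one preference x context condition."""

    preference: str
    context: str
    counts: dict[str, int]
    n: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if sum(self.counts.values()) != self.n:
            raise ValueError("counts must sum to n")

    def proportions(self) -> dict[str, float]:
        return {k: v / self.n for k, v in self.counts.items()}

    def percentages(self) -> dict[str, float]:
        return {k: percent(v, self.n) for k, v in self.counts.items()}


def percent(count: int, n: int) -> float:
    """100*count/n rounded half-up to one decimal (table convention)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    return float(
        (Decimal(100) * Decimal(count) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def read_choices(path) -> ChoiceDataset:
    """Read and validate a choice-table CSV (documented header)."""
    return ChoiceDataset.from_csv(path)


def frequency_table(
    dataset: ChoiceDataset,
    preference: str,
    context: str,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> FrequencyTable:
    """Bin one condition's colours into hue categories and count them."""
    rows = dataset.condition(preference, context)
    if rows.empty:
        raise ValueError(f"no rows for condition {preference}/{context}")
    counts = {label: 0 for label in scheme.labels}
    for L, C, h in rows[["L", "C", "h"]].itertuples(index=False):
        counts[categorize(CIELCh(L, C, h), scheme)] += 1
    return FrequencyTable(preference, context, counts, len(rows))


def fixture_frequency_tables() -> list[FrequencyTable]:
    """The embedded published count fixture as FrequencyTable objects."""
    from .hue_categories import CATEGORY_LABELS

    return [
        FrequencyTable(pref, ctx, dict(zip(CATEGORY_LABELS, TABLE2_COUNTS[(pref, ctx)])), TABLE2_N)
        for pref, ctx in CONDITION_ORDER
    ]


def _condition_block(table: FrequencyTable, bootstrap: BootstrapConfig) -> dict:
    pairwise = bootstrap_pairwise(table.counts, bootstrap)
    letters = letter_display(pairwise, order=list(table.counts))
    return {
        "preference": table.preference,
        "context": table.context,
        "n": table.n,
        "counts": dict(table.counts),
        "percent": table.percentages(),
        "letters": letters,
        "significant_pairs": sorted(
            [r.category_i, r.category_j] for r in pairwise if r.significant
        ),
    }


def _measure_array(dataset: ChoiceDataset, column: str) -> np.ndarray:
    """Pivot one measure into an (n, 2 preference, 3 context) array."""
    wide = dataset.data.pivot_table(
        index="participant", columns=["preference", "context"], values=column
    )
    n = wide.shape[0]
    out = np.empty((n, len(PREFERENCES), len(CONTEXTS)))
    for i, pref in enumerate(PREFERENCES):
        for j, ctx in enumerate(CONTEXTS):
            out[:, i, j] = wide[(pref, ctx)].to_numpy()
    return out


def _anova_block(dataset: ChoiceDataset, column: str) -> dict:
    Y = _measure_array(dataset, column)
    res = rm_anova_2x3(Y)
    block = {"n": res.n_subjects, "effects": {}}
    for name, eff in res.effects.items():
        block["effects"][name] = {
            "F": eff.F,
            "df1": eff.df1,
            "df2": eff.df2,
            "p": eff.p_value,
            "partial_eta_sq": eff.partial_eta_sq,
            "epsilon": eff.epsilon,
            "p_gg": eff.p_gg,
        }
    block["posthoc_cells"] = {
        f"{a} vs {b}": p for (a, b), p in bonferroni_posthoc(Y, "cells").items()
    }
    block["posthoc_context"] = {
        f"{a} vs {b}": p for (a, b), p in bonferroni_posthoc(Y, "context").items()
    }
    return block


def summarize_valence(dataset: ChoiceDataset) -> dict:
    """Median/mean/quartiles/1.5*IQR fences per preference x association type."""
    df = dataset.data
    valenced = df[df["valence"].notna()]
    if valenced.empty:
        raise ValueError("no valenced records")
    out = {}
    for pref in PREFERENCES:
        for kind in ("object", "concept"):
            vals = valenced.loc[
                (valenced["preference"] == pref) & (valenced["assoc_type"] == kind),
                "valence",
            ].to_numpy()
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            out[f"{pref}/{kind}"] = {
                "n": int(len(vals)),
                "mean": float(vals.mean()),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "lower_fence": float(q1 - 1.5 * iqr),
                "upper_fence": float(q3 + 1.5 * iqr),
                "n_positive": int((vals > 0).sum()),
                "n_negative": int((vals < 0).sum()),
            }
    return out


def association_distribution(dataset: ChoiceDataset) -> dict:
    """Association-type tests: paired most-vs-least distribution and counts.

    For every participant x context, the pair (most assoc type, least assoc
    type) enters a 3x3 contingency table tested for marginal homogeneity
    (overall and per context).  Per-participant counts of object vs concept
    associations (out of the three contexts) feed paired Wilcoxon tests,
    one per preference.
    """
    df = dataset.data
    pairs = df.pivot_table(
        index=["participant", "context"],
        columns="preference",
        values="assoc_type",
        aggfunc="first",
    )

    def crosstab(sub: pd.DataFrame) -> np.ndarray:
        t = np.zeros((3, 3))
        for most, least in sub[["most", "least"]].itertuples(index=False):
            t[ASSOC_TYPES.index(most), ASSOC_TYPES.index(least)] += 1
        return t

    def sm_block(tab: np.ndarray) -> dict:
        res = stuart_maxwell(tab, labels=list(ASSOC_TYPES))
        return {
            "table": tab.astype(int).tolist(),
            "chi2": res.chi2,
            "df": res.df,
            "p": res.p_value,
            "n": res.n,
        }

    overall = crosstab(pairs)
    blocks = {"overall": sm_block(overall)}
    for ctx in CONTEXTS:
        blocks[ctx] = sm_block(crosstab(pairs.xs(ctx, level="context")))

    wilcoxon = {}
    for pref in PREFERENCES:
        sub = df[df["preference"] == pref]
        counts = (
            sub.groupby("participant")["assoc_type"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["object", "concept"], fill_value=0)
        )
        diffs = (counts["object"] - counts["concept"]).to_numpy(dtype=float)
        if np.all(diffs == 0):
            wilcoxon[pref] = {"V": None, "Z": 0.0, "p": 1.0, "note": "no nonzero differences"}
        else:
            res = wilcoxon_signed_rank(diffs, exact=False)
            wilcoxon[pref] = {"V": res.V, "Z": res.Z, "p": res.p_value, "n_nonzero": res.n_nonzero}
    return {"stuart_maxwell": blocks, "wilcoxon_object_vs_concept": wilcoxon}


def run_full_analysis(
    dataset: ChoiceDataset,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    bootstrap: BootstrapConfig | None = None,
    seed: int | None = None,
) -> dict:
    """All analyses on one dataset; deterministic given the seed.

    Returns a JSON-serialisable report: per-condition frequency/letter
    blocks, ANOVA blocks for lightness, chroma, clicks and time,
    association tests, and valence summaries, with provenance stamped in.
    """
    if bootstrap is None:
        bootstrap = BootstrapConfig(seed=seed)
    elif bootstrap.seed is None and seed is not None:
        bootstrap = BootstrapConfig(B=bootstrap.B, alpha=bootstrap.alpha, seed=seed)

    report: dict = {
        "provenance": {
            "package_version": _pkg_version,
            "seed": seed,
            "bootstrap_B": bootstrap.B,
            "alpha": bootstrap.alpha,
            "n_participants": dataset.n_participants,
            "scheme": scheme.to_dict(),
            "dataset_metadata": dict(dataset.metadata),
            "colour_note": (
                "Colours converted through a configurable display model are "
                "approximations of the original chroma-meter measurements."
            ),
        },
        "conditions": [],
    }
    for pref, ctx in CONDITION_ORDER:
        table = frequency_table(dataset, pref, ctx, scheme)
        report["conditions"].append(_condition_block(table, bootstrap))

    report["anova"] = {
        "lightness": _anova_block(dataset, "L"),
        "chroma": _anova_block(dataset, "C"),
        "clicks": _anova_block(dataset, "clicks"),
        "time_s": _anova_block(dataset, "time_s"),
    }
    report["associations"] = association_distribution(dataset)
    report["valence"] = summarize_valence(dataset)
    return report


def run_fixture_analysis(bootstrap: BootstrapConfig | None = None) -> dict:
    """Frequency/letter analysis of the embedded published count fixture.

    Only the hue-frequency stage can run from the fixture (it has no raw
    colour, process or association data).
    """
    bootstrap = bootstrap or BootstrapConfig()
    return {
        "provenance": {
            "package_version": _pkg_version,
            "source": "embedded published frequency fixture",
            "bootstrap_B": bootstrap.B,
            "alpha": bootstrap.alpha,
        },
        "conditions": [
            _condition_block(t, bootstrap) for t in fixture_frequency_tables()
        ],
    }


def render_frequency_table(report: dict) -> str:
    """Text table mirroring the published layout: count (percent) + letters."""
    conditions = report["conditions"]
    labels = list(conditions[0]["counts"])
    header = ["Hue"] + [f"{c['context']}/{c['preference']}" for c in conditions]
    rows = [header]
    for lab in labels:
        row = [lab]
        for c in conditions:
            row.append(f"{c['counts'][lab]} ({c['percent'][lab]:.1f}) {c['letters'][lab]}")
        rows.append(row)
    total = ["Total"] + [f"{c['n']} (100)" for c in conditions]
    rows.append(total)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows
    )


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
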