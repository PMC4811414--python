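"""Synthetic participant generator.

The raw study data are unpublished, so every pipeline stage is exercised on
generated datasets that emulate the published statistical structure:

* per-condition hue-category weights default to the published frequency
  table (counts over nine categories, n = 85 per condition);
* condition-specific lightness/chroma distributions encode the qualitative
  pattern: most-preferred wall colours lighter, most-preferred t-shirt
  colours darker and less chromatic, most-preferred general colours more
  chromatic;
* most-preferred choices carry more (and more object-based) valenced
  associations with positive ratings; least-preferred ones more "none" and
  concept-based associations with negative ratings;
* most-preferred selections take more clicks and more time.

Hue is sampled uniformly within the chosen category's arc (the published
record gives only category frequencies, so uniform is the maximum-entropy
stand-in); lightness and chroma are truncated normals.  Association
probabilities and valence parameters are qualitative stand-ins exposed in
the config, not published quantities.

Two modes: :func:`generate_dataset` samples colours directly;
:func:`generate_via_picker` instead draws a target colour and lets a noisy
greedy agent navigate the picker, so final colours and click counts arise
mechanistically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .colour_space import CIELCh, LCh_to_Lab, Lab_to_XYZ, XYZ_to_rgb, SRGB_D65
from .dataset import ChoiceDataset, CONTEXTS, PREFERENCES, COLUMNS
from .hue_categories import CategoryScheme, DEFAULT_SCHEME, ACHROMATIC
from .picker import AgentPolicy, PickerConfig, run_agent
from .fixtures import TABLE2_COUNTS, TABLE2_N

__all__ = [
    "ConditionColour",
    "GeneratorConfig",
    "default_config",
    "generate_dataset",
    "generate_via_picker",
]


@dataclass(frozen=True)
class ConditionColour:
    """Truncated-normal lightness/chroma parameters for one condition."""

    L_mean: float
    L_sd: float
    C_mean: float
    C_sd: float

    def __post_init__(self) -> None:
        if self.L_sd <= 0 or self.C_sd <= 0:
            raise ValueError("standard deviations must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """All distributions behind a synthetic dataset; deterministic per seed."""

    n_participants: int = 85
    # (preference, context) -> 9 category weights in default scheme order
    hue_weights: dict = field(default_factory=dict)
    colour: dict = field(default_factory=dict)
    # preference -> (p_object, p_concept, p_none)
    assoc_probs: dict = field(
        default_factory=lambda: {
            "most": (0.55, 0.25, 0.20),
            "least": (0.20, 0.33, 0.47),
        }
    )
    # preference -> (mean, sd, low, high): truncated normal on [low, high]
    valence: dict = field(
        default_factory=lambda: {
            "most": (18.0, 12.0, 0.0, 45.0),
            "least": (-18.0, 12.0, -45.0, 0.0),
        }
    )
    # preference -> mean click count (clicks = 1 + Poisson(mean - 1))
    clicks_mean: dict = field(default_factory=lambda: {"most": 18.0, "least": 13.0})
    # per-click latency: lognormal(mu, sigma) seconds
    latency_mu: float = 0.1
    latency_sigma: float = 0.35

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least 1 participant")
        for pref, probs in self.assoc_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"assoc_probs[{pref!r}] is not a probability vector")
        for pref, (_, sd, lo, hi) in self.valence.items():
            if sd <= 0 or lo >= hi or lo < -45 or hi > 45:
                raise ValueError(f"invalid valence spec for {pref!r}")
        for key, w in self.hue_weights.items():
            w = np.asarray(w, dtype=float)
            if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"hue_weights[{key}] is not a probability vector")

    def digest(self) -> str:
        def norm(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return sorted((str(k), norm(v)) for k, v in o.items())
            if isinstance(o, (list, tuple)):
                return [norm(v) for v in o]
            return o

        payload = json.dumps(norm(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config(n_participants: int = 85) -> GeneratorConfig:
    """Defaults: published per-condition hue frequencies, qualitative L/C pattern."""
    weights = {
        key: np.asarray(counts, dtype=float) / TABLE2_N
        for key, counts in TABLE2_COUNTS.items()
    }
    colour = {
        ("most", "general"): ConditionColour(55.0, 15.0, 55.0, 20.0),
        ("most", "walls"): ConditionColour(75.0, 10.0, 30.0, 15.0),
        ("most", "t-shirt"): ConditionColour(42.0, 15.0, 40.0, 18.0),
        ("least", "general"): ConditionColour(55.0, 18.0, 50.0, 20.0),
        ("least", "walls"): ConditionColour(50.0, 18.0, 35.0, 18.0),
        ("least", "t-shirt"): ConditionColour(58.0, 15.0, 55.0, 20.0),
    }
    return GeneratorConfig(
        n_participants=n_participants, hue_weights=weights, colour=colour
    )


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_colour(
    rng: np.random.Generator,
    weights: np.ndarray,
    cond: ConditionColour,
    scheme: CategoryScheme,
) -> CIELCh:
    labels = scheme.labels
    cat_label = labels[rng.choice(len(labels), p=weights)]
    cat = scheme[cat_label]
    L = float(_truncnorm(rng, cond.L_mean, cond.L_sd, 0.0, 100.0))
    if cat_label == ACHROMATIC or not cat.chromatic:
        C = float(rng.uniform(0.0, scheme.chroma_cutoff))
        h = 0.0
    else:
        lo, hi = cat.hue_range
        width = (hi - lo) % 360.0
        h = float((lo + rng.uniform(0.0, width)) % 360.0)
        # truncate just above the cut-off so the category is preserved
        C = float(
            _truncnorm(rng, cond.C_mean, cond.C_sd, scheme.chroma_cutoff + 1e-6, 128.0)
        )
    return CIELCh(L, C, h)


def _sample_process(rng, config: GeneratorConfig, pref: str):
    clicks = 1 + int(rng.poisson(max(config.clicks_mean[pref] - 1.0, 0.0)))
    latency = rng.lognormal(config.latency_mu, config.latency_sigma)
    return clicks, float(clicks * latency)


def _sample_association(rng, config: GeneratorConfig, pref: str):
    kind = ("object", "concept", "none")[rng.choice(3, p=config.assoc_probs[pref])]
    if kind == "none":
        return kind, "", np.nan
    mean, sd, lo, hi = config.valence[pref]
    valence = float(_truncnorm(rng, mean, sd, lo, hi))
    text = f"{kind}-{rng.integers(0, 100)}"
    return kind, text, valence


def _rgb_of(lch: CIELCh):
    rgb = XYZ_to_rgb(Lab_to_XYZ(LCh_to_Lab(lch), SRGB_D65.white_point), SRGB_D65)
    return rgb.r, rgb.g, rgb.b


def generate_dataset(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> ChoiceDataset:
    """Sample a full choice dataset directly from the configured distributions."""
    config = config or default_config()
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, config.n_participants + 1):
        for pref in PREFERENCES:
            for ctx in CONTEXTS:
                lch = _sample_colour(
                    rng, config.hue_weights[(pref, ctx)], config.colour[(pref, ctx)], scheme
                )
                clicks, time_s = _sample_process(rng, config, pref)
                kind, text, valence = _sample_association(rng, config, pref)
                r, g, b = _rgb_of(lch)
                rows.append(
                    (pid, pref, ctx, lch.L, lch.C, lch.h, r, g, b,
                     time_s, clicks, kind, text, valence)
                )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return ChoiceDataset(
        data=df, seed=seed, metadata={"config_digest": config.digest(), "mode": "direct"}
    )


def generate_via_picker(
    config: GeneratorConfig | None = None,
    picker_config: PickerConfig | None = None,
    seed: int | None = None,
    agent_noise: float = 0.0,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> ChoiceDataset:
    """End-to-end mode: draw target colours, navigate the picker to them.

    Final colours and click counts come from the agent's trajectory, so the
    process measures arise from the same mechanism participants faced.
    """
    config = config or default_config()
    picker_config = picker_config or PickerConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, config.n_participants + 1):
        for pref in PREFERENCES:
            for ctx in CONTEXTS:
                target_lch = _sample_colour(
                    rng, config.hue_weights[(pref, ctx)], config.colour[(pref, ctx)], scheme
                )
                traj = run_agent(
                    AgentPolicy(target=LCh_to_Lab(target_lch), noise=agent_noise),
                    picker_config,
                    seed=rng,
                )
                lch = traj.result.colour_lch
                clicks = traj.result.clicks
                latency = rng.lognormal(config.latency_mu, config.latency_sigma)
                time_s = float(clicks * latency)
                kind, text, valence = _sample_association(rng, config, pref)
                r, g, b = _rgb_of(lch)
                rows.append(
                    (pid, pref, ctx, lch.L, lch.C, lch.h, r, g, b,
                     time_s, clicks, kind, text, valence)
                )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return ChoiceDataset(
        data=df, seed=seed, metadata={"config_digest": config.digest(), "mode": "picker"}
    )
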