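"""Headless simulation of the sequential colour-picker tool.

The original instrument shows nine starting patches (eight hue families plus
grey).  Clicking one makes it the centre patch of a refinement screen with up
to eight surrounding variations: four corners moving along the two Lab
opponent axes (+/- b, yellow-blue; +/- a, red-green), upper/lower patches
moving +/- lightness, and right/left patches moving +/- chroma (radially).
Each click shrinks the variation step geometrically; when the differences
become too small to render, the outer patches disappear and the centre patch
is proposed as the final choice.  Clicking the proposed patch reopens
refinement at the last visible step sizes.

The engine navigates CIELab directly.  The display gamut is modelled as the
cylinder L in [0, 100], C <= ``chroma_max``; every centre and patch colour is
clipped into it.  Simulated "participants" are greedy agents that click, at
each frame, the patch (centre included) closest in Euclidean Lab distance to
a target colour, optionally with Gaussian noise on the comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .colour_space import CIELab, CIELCh, Lab_to_LCh, LCh_to_Lab
from .hue_categories import DEFAULT_SCHEME

__all__ = [
    "Phase",
    "PickerConfig",
    "PickerState",
    "Patch",
    "AgentPolicy",
    "Trajectory",
    "PickerError",
    "NonConvergenceError",
    "start_session",
    "available_patches",
    "click",
    "finalize",
    "run_agent",
    "termination_bound",
    "default_palette",
    "CENTRE",
]

CENTRE = "centre"

_OUTER_AXES = (
    # (name, axis, sign): axis in {"L", "C", "a", "b"}
    ("lightness+", "L", +1.0),
    ("lightness-", "L", -1.0),
    ("chroma+", "C", +1.0),
    ("chroma-", "C", -1.0),
    ("redgreen+", "a", +1.0),
    ("redgreen-", "a", -1.0),
    ("yellowblue+", "b", +1.0),
    ("yellowblue-", "b", -1.0),
)


class Phase(Enum):
    PALETTE = "palette"
    REFINE = "refine"
    PROPOSED_FINAL = "proposed-final"
    FINAL = "final"


class PickerError(RuntimeError):
    pass


class NonConvergenceError(PickerError):
    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


def default_palette() -> tuple[CIELab, ...]:
    """Nine starting patches: the eight focal hues at L=60, C=60, plus grey."""
    pal = []
    for cat in DEFAULT_SCHEME.chromatic_categories:
        pal.append(LCh_to_Lab(CIELCh(60.0, 60.0, cat.focal_hue)))
    pal.append(CIELab(60.0, 0.0, 0.0))  # grey
    return tuple(pal)


@dataclass(frozen=True)
class PickerConfig:
    """Step schedule and gamut of a picker session.

    The original tool's exact step sizes are not recoverable; the defaults
    (initial 25 Lab units per axis, shrink 0.85, threshold 2.0) give a total
    travel of ~167 units per axis, enough to reach any point of the gamut
    cylinder from the nearest starting patch.
    """

    palette: tuple[CIELab, ...] = field(default_factory=default_palette)
    initial_step_L: float = 25.0
    initial_step_C: float = 25.0
    initial_step_hue: float = 25.0  # shared by the +/- a and +/- b corners
    shrink: float = 0.85
    threshold: float = 2.0
    chroma_max: float = 128.0

    def __post_init__(self) -> None:
        if len(self.palette) != 9:
            raise ValueError(f"palette must have 9 colours, got {len(self.palette)}")
        if min(self.initial_step_L, self.initial_step_C, self.initial_step_hue) <= 0:
            raise ValueError("step sizes must be > 0")
        if not 0 < self.shrink < 1:
            raise ValueError("shrink factor must lie in (0, 1)")
        if self.threshold <= 0:
            raise ValueError("termination threshold must be > 0")

    @property
    def initial_steps(self) -> dict[str, float]:
        return {
            "L": self.initial_step_L,
            "C": self.initial_step_C,
            "a": self.initial_step_hue,
            "b": self.initial_step_hue,
        }

    def clip(self, c: CIELab) -> CIELab:
        L = min(max(c.L, 0.0), 100.0)
        C = math.hypot(c.a, c.b)
        if C > self.chroma_max:
            s = self.chroma_max / C
            return CIELab(L, c.a * s, c.b * s)
        return CIELab(L, c.a, c.b)


@dataclass(frozen=True)
class Patch:
    name: str
    colour: CIELab


@dataclass(frozen=True)
class PickerState:
    config: PickerConfig
    phase: Phase
    centre: CIELab | None
    steps: dict[str, float]
    clicks: int
    history: tuple[CIELab, ...]
    reopen_steps: dict[str, float] | None = None


def _distance(a: CIELab, b: CIELab) -> float:
    return math.sqrt((a.L - b.L) ** 2 + (a.a - b.a) ** 2 + (a.b - b.b) ** 2)


def start_session(config: PickerConfig | None = None) -> PickerState:
    """Open the starting screen: nine palette patches, zero clicks."""
    config = config or PickerConfig()
    return PickerState(
        config=config,
        phase=Phase.PALETTE,
        centre=None,
        steps=dict(config.initial_steps),
        clicks=0,
        history=(),
    )


def _outer_patches(centre: CIELab, steps: dict[str, float], config: PickerConfig) -> list[Patch]:
    patches = []
    for name, axis, sign in _OUTER_AXES:
        if axis == "L":
            cand = CIELab(centre.L + sign * steps["L"], centre.a, centre.b)
        elif axis == "a":
            cand = CIELab(centre.L, centre.a + sign * steps["a"], centre.b)
        elif axis == "b":
            cand = CIELab(centre.L, centre.a, centre.b + sign * steps["b"])
        else:  # chroma: radial move; from a neutral centre, increase along +a
            C = math.hypot(centre.a, centre.b)
            if C == 0:
                ua, ub = 1.0, 0.0
            else:
                ua, ub = centre.a / C, centre.b / C
            newC = C + sign * steps["C"]
            if newC < 0:
                newC = 0.0
            cand = CIELab(centre.L, ua * newC, ub * newC)
        cand = config.clip(cand)
        if _distance(cand, centre) >= config.threshold:
            patches.append(Patch(name, cand))
    return patches


def available_patches(state: PickerState) -> list[Patch]:
    """Patches clickable in the current frame.

    Palette phase: the nine starting patches.  Refine phase: surviving outer
    variations plus the centre patch (clicking it shrinks the steps without
    moving).  Proposed-final phase: the centre patch only (clicking reopens
    refinement).  Final phase: error.
    """
    if state.phase is Phase.FINAL:
        raise PickerError("session is final; no patches available")
    if state.phase is Phase.PALETTE:
        return [Patch(f"palette{i}", c) for i, c in enumerate(state.config.palette)]
    if state.phase is Phase.PROPOSED_FINAL:
        return [Patch(CENTRE, state.centre)]
    return _outer_patches(state.centre, state.steps, state.config) + [
        Patch(CENTRE, state.centre)
    ]


def click(state: PickerState, patch: str) -> PickerState:
    """Advance the session by clicking the named patch.

    Every refine-phase click (outer or centre) multiplies all step sizes by
    the shrink factor.  When no outer patch survives the termination
    threshold, the session moves to proposed-final, remembering the last
    visible step sizes for a possible reopen.
    """
    if state.phase is Phase.FINAL:
        raise PickerError("session is final")

    if state.phase is Phase.PALETTE:
        options = {p.name: p for p in available_patches(state)}
        if patch not in options:
            raise PickerError(f"patch {patch!r} not available in palette phase")
        centre = state.config.clip(options[patch].colour)
        new = replace(
            state,
            phase=Phase.REFINE,
            centre=centre,
            clicks=state.clicks + 1,
            history=state.history + (centre,),
        )
        return _maybe_terminate(new)

    if state.phase is Phase.PROPOSED_FINAL:
        if patch != CENTRE:
            raise PickerError("only the centre patch is clickable at proposed-final")
        return replace(
            state,
            phase=Phase.REFINE,
            steps=dict(state.reopen_steps or state.config.initial_steps),
            clicks=state.clicks + 1,
        )

    # refine phase
    options = {p.name: p for p in available_patches(state)}
    if patch not in options:
        raise PickerError(f"patch {patch!r} not available")
    centre = options[patch].colour
    shrunk = {k: v * state.config.shrink for k, v in state.steps.items()}
    new = replace(
        state,
        centre=centre,
        steps=shrunk,
        clicks=state.clicks + 1,
        history=state.history + (centre,),
    )
    return _maybe_terminate(new)


def _maybe_terminate(state: PickerState) -> PickerState:
    if _outer_patches(state.centre, state.steps, state.config):
        return state
    pre = {k: v / state.config.shrink for k, v in state.steps.items()}
    return replace(state, phase=Phase.PROPOSED_FINAL, reopen_steps=pre)


@dataclass(frozen=True)
class PickerResult:
    colour: CIELab
    colour_lch: CIELCh
    clicks: int
    trajectory_length: int


def finalize(state: PickerState) -> tuple[PickerState, PickerResult]:
    """Accept the proposed colour.  Idempotent once final."""
    if state.phase not in (Phase.PROPOSED_FINAL, Phase.FINAL):
        raise PickerError("can only finalize at proposed-final")
    final_state = replace(state, phase=Phase.FINAL)
    result = PickerResult(
        colour=state.centre,
        colour_lch=Lab_to_LCh(state.centre),
        clicks=state.clicks,
        trajectory_length=len(state.history),
    )
    return final_state, result


def termination_bound(config: PickerConfig) -> int:
    """Max refine clicks per visit before all steps fall below the threshold."""
    max_step = max(config.initial_steps.values())
    return math.ceil(math.log(config.threshold / max_step) / math.log(config.shrink))


@dataclass(frozen=True)
class AgentPolicy:
    """Greedy simulated participant aiming for a target Lab colour."""

    target: CIELab
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


@dataclass
class Trajectory:
    states: list[PickerState]
    result: PickerResult | None = None

    @property
    def clicks(self) -> int:
        return self.states[-1].clicks if self.states else 0


def run_agent(
    policy: AgentPolicy,
    config: PickerConfig | None = None,
    seed: int | np.random.Generator | None = None,
    max_clicks: int | None = None,
) -> Trajectory:
    """Navigate a full session with a greedy (optionally noisy) agent.

    At every frame the agent clicks the available patch minimising Euclidean
    Lab distance to its target, with i.i.d. Gaussian noise (sd ``noise``)
    added to each candidate's distance; ties break on patch-list order.
    Deterministic given the seed.  Raises :class:`NonConvergenceError` with
    the trajectory attached if the click cap is exceeded.
    """
    config = config or PickerConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if max_clicks is None:
        # 1 palette click + a generous multiple of the per-visit bound.
        max_clicks = 1 + 10 * termination_bound(config)

    state = start_session(config)
    traj = Trajectory(states=[state])
    while state.phase is not Phase.PROPOSED_FINAL:
        if state.clicks >= max_clicks:
            raise NonConvergenceError(
                f"agent exceeded {max_clicks} clicks", trajectory=traj
            )
        patches = available_patches(state)
        scores = np.array([_distance(p.colour, policy.target) for p in patches])
        if policy.noise > 0:
            scores = scores + rng.normal(0.0, policy.noise, size=len(scores))
        state = click(state, patches[int(np.argmin(scores))].name)
        traj.states.append(state)
    state, result = finalize(state)
    traj.states.append(state)
    traj.result = result
    return traj
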