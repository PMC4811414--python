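"""Statistical machinery for the colour-preference analysis.

Four families of procedures:

* **Bootstrap pairwise proportion comparisons.**  For one preference-by-
  context condition, the nine observed hue-category counts (n participants)
  are resampled B times as multinomial draws from the empirical
  distribution.  For every unordered category pair a percentile confidence
  interval of the proportion difference p_i - p_j is formed with tail mass
  alpha/(k*(k-1)) on each side -- the exact Bonferroni correction for the
  k*(k-1)/2 unordered pairs at familywise level alpha.  A pair differs
  significantly iff its interval strictly excludes zero.  The outcomes are
  summarised as a compact letter display (categories sharing a letter do not
  differ).

* **Stuart-Maxwell marginal-homogeneity test** for paired multi-category
  responses (generalises McNemar beyond 2x2).

* **Wilcoxon signed-rank test** with the tie-corrected normal approximation
  and an exact enumeration path for small samples.

* **2x3 within-subject ANOVA** (preference x context) with Greenhouse-
  Geisser sphericity correction, partial eta squared, and Bonferroni-
  adjusted paired-t post-hocs.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BootstrapConfig",
    "PairwiseResult",
    "StuartMaxwellResult",
    "WilcoxonResult",
    "EffectResult",
    "AnovaResult",
    "corrected_alpha",
    "bootstrap_pairwise",
    "letter_display",
    "significance_matrix",
    "stuart_maxwell",
    "wilcoxon_signed_rank",
    "rm_anova_2x3",
    "bonferroni_posthoc",
]


def corrected_alpha(alpha: float, k: int) -> float:
    """Multiplicity-corrected tail level alpha / (k*(k-1)) for k categories."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k < 2:
        raise ValueError("need at least 2 categories")
    return alpha / (k * (k - 1))


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 100_000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PairwiseResult:
    """Outcome of one unordered pairwise proportion comparison."""

    category_i: str
    category_j: str
    diff: float          # observed p_i - p_j
    ci_low: float
    ci_high: float
    significant: bool


def bootstrap_pairwise(
    counts: Mapping[str, int] | Sequence[int],
    config: BootstrapConfig | None = None,
    labels: Sequence[str] | None = None,
) -> list[PairwiseResult]:
    """Bootstrap pairwise comparisons of category choice proportions.

    ``counts`` are the observed per-category counts for one condition
    (n = their sum).  B multinomial resamples of size n are drawn from the
    empirical proportions; each of the k*(k-1)/2 unordered pairs gets a
    percentile CI of p_i - p_j with tail mass alpha/(k*(k-1)) per side.
    Bit-reproducible given ``config.seed``.
    """
    config = config or BootstrapConfig()
    if isinstance(counts, Mapping):
        labels = list(counts.keys())
        vec = np.asarray([counts[l] for l in labels], dtype=float)
    else:
        vec = np.asarray(counts, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(len(vec))]
    if np.any(vec < 0):
        raise ValueError("counts must be >= 0")
    n = vec.sum()
    if n == 0:
        raise ValueError("empty frequency table (n = 0)")
    k = len(vec)
    p_obs = vec / n
    a_tail = corrected_alpha(config.alpha, k)

    rng = np.random.default_rng(config.seed)
    resamples = rng.multinomial(int(n), p_obs, size=config.B) / n

    results = []
    for i, j in itertools.combinations(range(k), 2):
        d = resamples[:, i] - resamples[:, j]
        lo, hi = np.quantile(d, [a_tail, 1.0 - a_tail])
        results.append(
            PairwiseResult(
                category_i=labels[i],
                category_j=labels[j],
                diff=float(p_obs[i] - p_obs[j]),
                ci_low=float(lo),
                ci_high=float(hi),
                significant=bool(lo > 0 or hi < 0),
            )
        )
    return results


def significance_matrix(
    pairwise: Sequence[PairwiseResult],
) -> tuple[list[str], np.ndarray]:
    """Categories (first-appearance order) and boolean significant matrix."""
    labels: list[str] = []
    for r in pairwise:
        for lab in (r.category_i, r.category_j):
            if lab not in labels:
                labels.append(lab)
    k = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    sig = np.zeros((k, k), dtype=bool)
    for r in pairwise:
        i, j = idx[r.category_i], idx[r.category_j]
        if sig[i, j] != sig[j, i]:  # pragma: no cover - symmetric by fill
            raise ValueError("inconsistent pairwise input")
        sig[i, j] = sig[j, i] = r.significant
    return labels, sig


def letter_display(
    pairwise: Sequence[PairwiseResult] | tuple[Sequence[str], np.ndarray],
    order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Categories sharing at least one letter do not differ significantly;
    categories with no letter in common differ.  Letters are assigned
    lowercase in the given display ``order`` (defaults to input order).
    Letter *names* are a presentation choice; only the sharing structure is
    meaningful.
    """
    if isinstance(pairwise, tuple):
        labels, sig = pairwise
        labels = list(labels)
        sig = np.asarray(sig, dtype=bool)
        if sig.shape != (len(labels), len(labels)) or not np.array_equal(sig, sig.T):
            raise ValueError("significance matrix must be square and symmetric")
    else:
        labels, sig = significance_matrix(pairwise)
    k = len(labels)
    order = list(order) if order is not None else labels
    if set(order) != set(labels):
        raise ValueError("display order must contain exactly the input categories")
    pos = {lab: order.index(lab) for lab in labels}

    # Insert-and-absorb: maintain letter groups (sets of category indices);
    # each significant pair splits every group containing both members.
    groups: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        new_groups: list[set[int]] = []
        for g in groups:
            if i in g and j in g:
                new_groups.append(g - {i})
                new_groups.append(g - {j})
            else:
                new_groups.append(g)
        # absorb: drop groups contained in another group
        new_groups = [
            g
            for g in new_groups
            if g and not any(g < h for h in new_groups)
        ]
        # deduplicate
        groups = []
        for g in new_groups:
            if g not in groups:
                groups.append(g)

    groups.sort(key=lambda g: min(pos[labels[i]] for i in g))
    if len(groups) > len(string.ascii_lowercase):  # pragma: no cover
        raise ValueError("more letter groups than available letters")
    out = {lab: "" for lab in labels}
    for letter, g in zip(string.ascii_lowercase, groups):
        for i in sorted(g, key=lambda i: pos[labels[i]]):
            out[labels[i]] += letter
    return out


@dataclass(frozen=True)
class StuartMaxwellResult:
    chi2: float
    df: int
    p_value: float
    n: int
    dropped_categories: tuple[str, ...] = ()


def stuart_maxwell(
    table: np.ndarray | Sequence[Sequence[int]],
    labels: Sequence[str] | None = None,
) -> StuartMaxwellResult:
    """Stuart-Maxwell chi-square test of marginal homogeneity.

    ``table[i, j]`` counts pairs with first response i and second response j.
    With d the vector of marginal differences (row - column sums, one
    category dropped) and S its covariance under homogeneity
    (S_ii = row_i + col_i - 2 t_ii, S_ij = -(t_ij + t_ji)), the statistic is
    chi2 = d' S^-1 d on k-1 df.  Categories with no off-diagonal mass are
    dropped first; if S is still singular a pseudo-inverse is used and the
    effective df equals rank(S).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("paired table must be square")
    k = t.shape[0]
    if k < 2:
        raise ValueError("need at least 2 categories")
    if labels is None:
        labels = [str(i) for i in range(k)]
    n = int(round(t.sum()))

    row = t.sum(axis=1)
    col = t.sum(axis=0)
    # categories contributing no off-diagonal information
    off = row + col - 2 * np.diag(t)
    keep = off > 0
    dropped = tuple(labels[i] for i in range(k) if not keep[i])
    t = t[np.ix_(keep, keep)]
    kk = t.shape[0]
    if kk < 2:
        return StuartMaxwellResult(0.0, 0, 1.0, n, dropped)

    row = t.sum(axis=1)
    col = t.sum(axis=0)
    d = (row - col)[:-1]  # drop last category
    S = np.empty((kk - 1, kk - 1))
    for i in range(kk - 1):
        for j in range(kk - 1):
            if i == j:
                S[i, j] = row[i] + col[i] - 2 * t[i, i]
            else:
                S[i, j] = -(t[i, j] + t[j, i])
    rank = int(np.linalg.matrix_rank(S))
    if rank == kk - 1:
        chi2 = float(d @ np.linalg.solve(S, d))
        df = kk - 1
    else:
        chi2 = float(d @ np.linalg.pinv(S) @ d)
        df = rank
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return StuartMaxwellResult(chi2, df, p, n, dropped)


@dataclass(frozen=True)
class WilcoxonResult:
    V: float            # sum of positive-signed ranks
    Z: float            # tie-corrected normal approximation
    p_value: float      # two-sided
    n_nonzero: int
    exact: bool = False


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    exact: bool | None = None,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    V is the sum of ranks of positive differences.  The two-sided p-value
    uses the tie-corrected normal approximation for Z, or (``exact=True``,
    only without ties, n <= 25) full 2^n sign enumeration.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    Z = (V - mu) / math.sqrt(var) if var > 0 else 0.0

    has_ties = bool((tie_counts > 1).any())
    if exact is None:
        exact = n <= 25 and not has_ties
    if exact:
        if has_ties:
            raise ValueError("exact enumeration requires untied absolute values")
        # null distribution of V: each rank enters with prob 1/2
        pmf = np.zeros(int(n * (n + 1) / 2) + 1)
        pmf[0] = 1.0
        for r in ranks.astype(int):
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[:-r] if r > 0 else pmf
            pmf = 0.5 * (pmf + shifted)
        lo = pmf[: int(V) + 1].sum()
        hi = pmf[int(V):].sum()
        p = min(1.0, 2.0 * min(lo, hi))
        return WilcoxonResult(V, Z, float(p), n, exact=True)
    p = float(2.0 * stats.norm.sf(abs(Z)))
    return WilcoxonResult(V, Z, p, n, exact=False)


@dataclass(frozen=True)
class EffectResult:
    F: float
    df1: float
    df2: float
    p_value: float
    partial_eta_sq: float
    epsilon: float          # Greenhouse-Geisser (1.0 for 1-df effects)
    p_gg: float             # p after multiplying both dfs by epsilon


@dataclass(frozen=True)
class AnovaResult:
    effects: dict  # {"preference": EffectResult, "context": ..., "interaction": ...}
    n_subjects: int


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subjects-by-levels scores.

    Computed from the double-centred covariance matrix of the repeated
    measures; equals (sum of eigenvalues)^2 / ((k-1) * sum of squared
    eigenvalues), bounded to (1/(k-1), 1].
    """
    k = scores.shape[1]
    S = np.cov(scores, rowvar=False, ddof=1)
    centred = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    tr = np.trace(centred)
    denom = (k - 1) * float((centred * centred).sum())
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(min(max(eps, 1.0 / (k - 1)), 1.0))


def rm_anova_2x3(values: np.ndarray) -> AnovaResult:
    """Two-way fully within-subject ANOVA on an (n, 2, 3) array.

    Axis 1 is preference (most/least), axis 2 context (general/walls/
    t-shirt).  Each effect is tested against its own subject-interaction
    error term; partial eta^2 = SS_effect / (SS_effect + SS_error).
    Greenhouse-Geisser epsilon is estimated for the 2-df effects (context
    from subject-by-context means, interaction from the per-context
    preference difference scores) and applied multiplicatively to both dfs
    for the corrected p-value.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 3 or Y.shape[1] != 2 or Y.shape[2] != 3:
        raise ValueError("expected an (n, 2, 3) within-subject array")
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    if not np.isfinite(Y).all():
        raise ValueError("missing cells are not supported")
    a, b = 2, 3

    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))           # (n,)
    A = Y.mean(axis=(0, 2))              # (2,)
    B = Y.mean(axis=(0, 1))              # (3,)
    AB = Y.mean(axis=0)                  # (2, 3)
    AS = Y.mean(axis=2)                  # (n, 2)
    BS = Y.mean(axis=1)                  # (n, 3)

    ss_a = n * b * ((A - grand) ** 2).sum()
    ss_as = b * ((AS - subj[:, None] - A[None, :] + grand) ** 2).sum()
    ss_b = n * a * ((B - grand) ** 2).sum()
    ss_bs = a * ((BS - subj[:, None] - B[None, :] + grand) ** 2).sum()
    ss_ab = n * ((AB - A[:, None] - B[None, :] + grand) ** 2).sum()
    resid = (
        Y
        - AS[:, :, None]
        - BS[:, None, :]
        - AB[None, :, :]
        + subj[:, None, None]
        + A[None, :, None]
        + B[None, None, :]
        - grand
    )
    ss_abs = (resid**2).sum()

    # SS below this are floating-point residue of exactly-null effects
    ss_tol = 1e-12 * max(float(((Y - grand) ** 2).sum()), 1.0)

    def effect(ss_e, ss_err, df1, df2, eps):
        if ss_e < ss_tol:
            ss_e = 0.0
        if ss_err < ss_tol:
            ss_err = 0.0
        ms_e = ss_e / df1
        ms_err = ss_err / df2
        if ms_err == 0:
            F = 0.0 if ms_e == 0 else math.inf
        else:
            F = ms_e / ms_err
        p = float(stats.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
        p_gg = float(stats.f.sf(F, eps * df1, eps * df2)) if math.isfinite(F) else 0.0
        eta = ss_e / (ss_e + ss_err) if (ss_e + ss_err) > 0 else 0.0
        return EffectResult(float(F), df1, df2, p, float(eta), float(eps), p_gg)

    eps_b = _gg_epsilon(BS)
    eps_ab = _gg_epsilon(Y[:, 0, :] - Y[:, 1, :])

    effects = {
        "preference": effect(ss_a, ss_as, 1, n - 1, 1.0),
        "context": effect(ss_b, ss_bs, b - 1, (b - 1) * (n - 1), eps_b),
        "interaction": effect(ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), eps_ab),
    }
    return AnovaResult(effects=effects, n_subjects=n)


def bonferroni_posthoc(
    values: np.ndarray,
    effect: str,
    preference_labels: Sequence[str] = ("most", "least"),
    context_labels: Sequence[str] = ("general", "walls", "t-shirt"),
) -> dict[tuple[str, str], float]:
    """Bonferroni-adjusted paired t-tests after the 2x3 within-subject ANOVA.

    ``effect`` is ``"preference"`` (1 comparison of the two preference
    means), ``"context"`` (3 comparisons of context means), or ``"cells"``
    (all 15 comparisons of the six preference-by-context cell means).
    Raw two-sided p-values are multiplied by the number of comparisons and
    capped at 1.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 3 or Y.shape[1] != len(preference_labels) or Y.shape[2] != len(context_labels):
        raise ValueError("values must be (n, preferences, contexts)")
    if effect == "preference":
        series = {lab: Y[:, i, :].mean(axis=1) for i, lab in enumerate(preference_labels)}
    elif effect == "context":
        series = {lab: Y[:, :, j].mean(axis=1) for j, lab in enumerate(context_labels)}
    elif effect == "cells":
        series = {
            f"{p}/{c}": Y[:, i, j]
            for i, p in enumerate(preference_labels)
            for j, c in enumerate(context_labels)
        }
    else:
        raise ValueError("effect must be 'preference', 'context' or 'cells'")
    names = list(series)
    m = len(names) * (len(names) - 1) // 2
    out = {}
    for x, y in itertools.combinations(names, 2):
        dx = series[x] - series[y]
        if np.allclose(dx, 0):
            out[(x, y)] = 1.0
            continue
        p = stats.ttest_rel(series[x], series[y]).pvalue
        out[(x, y)] = float(min(1.0, p * m))
    return out
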