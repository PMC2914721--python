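"""Cochran–Armitage trend test, Bonferroni adjustment, and table rendering.

The Cochran–Armitage test assesses a monotone (graded) relationship
between an ordered grouping — here the six-level infection severity
ranking — and a binary outcome such as one-year amputation.  With group
scores :math:`s_i`, event counts :math:`x_i`, group sizes :math:`n_i`,
:math:`N = \\sum n_i` and pooled proportion :math:`\\bar p = \\sum x_i / N`,
the statistic is

.. math::

    Z = \\frac{\\sum_i s_i (x_i - n_i \\bar p)}
             {\\sqrt{\\bar p (1 - \\bar p)
               \\left[\\sum_i n_i s_i^2 - (\\sum_i n_i s_i)^2 / N\\right]}}

which is asymptotically standard normal under the null of equal
proportions.  An exact conditional (permutation) method is provided as
an oracle: conditional on the margins, the event vector follows a
multivariate hypergeometric law, under which :math:`Z` is a monotone
function of the score sum, so the exact two-sided p-value is the tail
probability of :math:`|Z|` over that law (full enumeration for small
tables, Monte-Carlo sampling otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codes import RANKED_CATEGORIES, SEVERITY_RANK, InfectionCategory

__all__ = [
    "TrendTestResult",
    "cochran_armitage",
    "bonferroni",
    "format_percent",
    "render_table1",
    "render_table2",
    "render_table3",
    "render_tables",
]


@dataclass(frozen=True)
class TrendTestResult:
    z_statistic: float
    p_value: float
    scores: tuple[float, ...]
    events: tuple[int, ...]
    totals: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def _z_statistic(
    events: np.ndarray,
    totals: np.ndarray,
    scores: np.ndarray,
    continuity: float = 0.0,
) -> float:
    n_tot = totals.sum()
    pbar = events.sum() / n_tot
    num = float(np.sum(scores * (events - totals * pbar)))
    if continuity:
        num = np.sign(num) * max(abs(num) - continuity, 0.0)
    var = pbar * (1 - pbar) * (
        np.sum(totals * scores**2) - np.sum(totals * scores) ** 2 / n_tot
    )
    return num / np.sqrt(var)


def cochran_armitage(
    events: Sequence[int],
    totals: Sequence[int],
    scores: Optional[Sequence[float]] = None,
    method: str = "asymptotic",
    continuity_correction: bool = False,
    n_resamples: int = 100_000,
    max_enumeration: int = 2_000_000,
    seed: Optional[int] = None,
) -> TrendTestResult:
    """Two-sided Cochran–Armitage test for trend in binomial proportions.

    Parameters
    ----------
    events, totals
        Event counts and group sizes in severity order (most severe
        first by convention; any consistent order works).
    scores
        Per-group scores; default equally spaced severity ranks
        ``k, k-1, ..., 1``.  The statistic is invariant under affine
        transformations of the scores.
    method
        ``asymptotic`` (normal approximation) or ``exact_permutation``
        (conditional on margins; full enumeration when the state space
        has at most ``max_enumeration`` tables, otherwise Monte-Carlo
        with ``n_resamples`` draws seeded by ``seed``).
    continuity_correction
        Subtract half the minimum score spacing from the numerator
        (off by default).

    Raises
    ------
    ValueError
        On fewer than two groups, counts out of range, or a degenerate
        table (no events, or all subjects events) where the trend
        variance is zero and Z is undefined.
    """
    x = np.asarray(events, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need >= 2 groups with matching events/totals")
    if np.any(x < 0) or np.any(x > n) or np.any(n <= 0):
        raise ValueError("require 0 <= events_i <= totals_i and totals_i > 0")
    if scores is None:
        s = np.arange(len(x), 0, -1, dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
        if s.shape != x.shape:
            raise ValueError("scores must match the number of groups")
        if np.allclose(s, s[0]):
            raise ValueError("scores must not be constant")
    total_events = x.sum()
    if total_events == 0 or total_events == n.sum():
        raise ValueError(
            "degenerate table: all events 0 or all subjects events; the "
            "trend variance is zero and Z is undefined"
        )

    cc = 0.0
    if continuity_correction:
        cc = 0.5 * np.min(np.abs(np.diff(np.sort(np.unique(s)))))
    z = _z_statistic(x, n, s, continuity=cc)

    if method == "asymptotic":
        p = 2.0 * stats.norm.sf(abs(z))
        p = min(p, 1.0)
    elif method == "exact_permutation":
        p = _exact_p(
            x.astype(int), n.astype(int), s, n_resamples, max_enumeration, seed
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    return TrendTestResult(
        z_statistic=float(z),
        p_value=float(p),
        scores=tuple(s),
        events=tuple(int(v) for v in x),
        totals=tuple(int(v) for v in n),
        method=method,
    )


def _exact_p(
    events: np.ndarray,
    totals: np.ndarray,
    scores: np.ndarray,
    n_resamples: int,
    max_enumeration: int,
    seed: Optional[int],
) -> float:
    """Exact conditional two-sided p-value.

    Conditional on the margins, Z is monotone in U = sum(s_i * x_i), so
    the two-sided tail is P(|U - E[U]| >= |U_obs - E[U]|) under the
    multivariate hypergeometric law with colors = groups.
    """
    T = int(events.sum())
    N = int(totals.sum())
    mean_u = float(np.sum(scores * totals)) * T / N
    u_obs = float(np.sum(scores * events))
    dev_obs = abs(u_obs - mean_u) - 1e-9  # tie tolerance

    state_space = int(np.prod(totals + 1.0))
    if state_space <= max_enumeration:
        # DP over groups: sparse map from (allocated, U) to log-free weight
        # using binomial coefficients C(n_i, x_i).
        from math import comb

        dist: dict[tuple[int, float], float] = {(0, 0.0): 1.0}
        for n_i, s_i in zip(totals, scores):
            new: dict[tuple[int, float], float] = {}
            for (alloc, u), w in dist.items():
                for x_i in range(n_i + 1):
                    if alloc + x_i > T:
                        break
                    key = (alloc + x_i, round(u + s_i * x_i, 9))
                    new[key] = new.get(key, 0.0) + w * comb(n_i, x_i)
            dist = new
        total_w = 0.0
        tail_w = 0.0
        for (alloc, u), w in dist.items():
            if alloc != T:
                continue
            total_w += w
            if abs(u - mean_u) >= dev_obs:
                tail_w += w
        return tail_w / total_w

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(totals, T, size=n_resamples)
    u = draws @ scores
    return float(np.mean(np.abs(u - mean_u) >= dev_obs))


def bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> list[bool]:
    """Bonferroni multiple-comparison decisions: reject iff p < alpha / m.

    Raises
    ------
    ValueError
        On an empty family (m = 0) or alpha outside (0, 1).
    """
    p = list(p_values)
    if not p:
        raise ValueError("empty p-value family (m = 0)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    threshold = alpha / len(p)
    return [pi < threshold for pi in p]


# ---------------------------------------------------------------------------
# table rendering

def format_percent(proportion: float, mask_below: Optional[float] = None) -> str:
    """Render a proportion as a one-decimal percentage string.

    With ``mask_below`` set (e.g. 0.01), nonzero proportions under the
    threshold render as ``"< 1%"`` — the small-cell display convention.
    """
    if pd.isna(proportion):
        return "-"
    if mask_below is not None and 0 < proportion < mask_below:
        return f"< {mask_below * 100:.0f}%"
    return f"{proportion * 100:.1f}%"


_GROUP_LABELS = {
    InfectionCategory.GANGRENE: "Gangrene",
    InfectionCategory.OSTEOMYELITIS: "Osteomyelitis",
    InfectionCategory.ULCER: "Ulcer",
    InfectionCategory.FOOT_CELLULITIS_ABSCESS: "Foot cellulitis/abscess",
    InfectionCategory.TOE_CELLULITIS_ABSCESS: "Toe cellulitis/abscess",
    InfectionCategory.PARONYCHIA: "Paronychia",
    InfectionCategory.OTHER: "Other",
}


def _group_order(with_other: bool = False) -> list[str]:
    cats = [c.value for c in RANKED_CATEGORIES]
    if with_other:
        cats.append(InfectionCategory.OTHER.value)
    return cats


def render_table1(coinfection: pd.DataFrame, group_sizes: pd.Series) -> pd.DataFrame:
    """Co-infection proportions by group, masked below 1%, with group sizes."""
    cats = _group_order()
    out = pd.DataFrame(index=cats, columns=cats, dtype=object)
    for r in cats:
        for g in cats:
            v = coinfection.loc[r, g] if r in coinfection.index else np.nan
            out.loc[r, g] = (
                "-" if pd.isna(v) else format_percent(v, mask_below=0.01)
            )
    out.loc["n", :] = [int(group_sizes.get(g, 0)) for g in cats]
    return out


def render_table2(cohort: pd.DataFrame, comorbidities: Sequence[str]) -> pd.DataFrame:
    """Demographics and comorbidity prevalences per group (plus Any)."""
    cats = _group_order(with_other=True)
    cols = ["Any"] + cats
    rows: dict[str, list] = {}
    subsets = {"Any": cohort} | {
        g: cohort[cohort["group"] == g] for g in cats
    }

    def add(name: str, fn) -> None:
        rows[name] = [fn(subsets[c]) for c in cols]

    add("n", len)
    add("Male", lambda d: format_percent((d["sex"] == "M").mean()) if len(d) else "-")
    add("Mean age", lambda d: f"{d['age_at_index'].mean():.1f}" if len(d) else "-")
    add("SD age", lambda d: f"{d['age_at_index'].std():.1f}" if len(d) else "-")
    for race in ("WHITE", "AFRICAN_AMERICAN", "OTHER", "UNKNOWN"):
        add(
            race.capitalize().replace("_", "-"),
            lambda d, race=race: format_percent((d["race"] == race).mean())
            if len(d)
            else "-",
        )
    for cond in comorbidities:
        add(
            cond,
            lambda d, cond=cond: format_percent(d[cond].mean()) if len(d) else "-",
        )
    return pd.DataFrame(rows, index=cols).T


def render_table3(
    cohort: pd.DataFrame,
    outcomes: pd.DataFrame,
    horizon: int = 365,
) -> pd.DataFrame:
    """Length of stay, amputation history, and one-year outcomes per group."""
    from .outcomes import outcome_table

    cats = _group_order(with_other=True)
    merged = cohort.merge(
        outcomes.drop(columns=["group"], errors="ignore"), on="patient_id"
    )
    tab = outcome_table(cohort, outcomes, horizon=horizon)
    rows: dict[str, list] = {}

    def add(name: str, fn) -> None:
        rows[name] = [fn(merged[merged["group"] == g]) for g in cats]

    add("n", len)
    add("Median LOS", lambda d: f"{d['los_days'].median():.0f}" if len(d) else "-")
    add(
        "Mean LOS (SD)",
        lambda d: f"{d['los_days'].mean():.1f} ({d['los_days'].std():.1f})"
        if len(d)
        else "-",
    )
    add(
        "Any current amputation",
        lambda d: format_percent(d["current_amputation"].mean()) if len(d) else "-",
    )
    add(
        "Any past amputation",
        lambda d: format_percent(d["past_amputation"].mean()) if len(d) else "-",
    )
    for label, col in (
        ("Amputations", "amputation"),
        ("Long-term care", "ltc"),
        ("Long-term care (whole-group denominator)", "ltc_all"),
        ("Death", "death"),
    ):
        rows[label] = [
            format_percent(tab.loc[g, col]) if g in tab.index else "-" for g in cats
        ]
    return pd.DataFrame(rows, index=cats).T


def render_tables(
    cohort: pd.DataFrame,
    coinfection: pd.DataFrame,
    outcomes: pd.DataFrame,
    comorbidities: Sequence[str] = ("PVD", "NEUROPATHY", "EYE", "CVD", "MI", "RENAL"),
) -> dict[str, pd.DataFrame]:
    """All three study-style reports from a cohort and its outcomes."""
    sizes = cohort.groupby("group")["patient_id"].nunique()
    return {
        "table1": render_table1(coinfection, sizes),
        "table2": render_table2(cohort, comorbidities),
        "table3": render_table3(cohort, outcomes),
    }
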