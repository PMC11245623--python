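"""Two-way ANOVA, Tukey-Kramer post hoc, and compact letter display.

The statistical machinery behind per-condition morphometric comparisons:
a balanced fixed-effects two-way ANOVA (charring condition × duration),
all-pairs Tukey-Kramer comparisons using the studentized range distribution
(with the Kramer correction for unequal group sizes), and the
insert-and-absorb compact letter display in which two groups share a letter
exactly when their comparison is non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_uppercase
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UnbalancedDesignError",
    "TukeyResult",
    "TukeyLetters",
    "two_way_anova",
    "tukey_kramer",
    "compact_letters",
    "letter_display",
]


class UnbalancedDesignError(ValueError):
    """Only balanced designs (equal cell counts) are supported."""


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> pd.DataFrame:
    """Balanced fixed-effects two-way ANOVA with interaction.

    Returns a table with rows ``factor_a``, ``factor_b``, ``interaction``,
    ``residual`` and columns ``sum_sq``, ``df``, ``mean_sq``, ``F``, ``p``.
    With one replicate per cell the interaction cannot be separated from
    error and becomes the residual (additive model).  Unbalanced designs
    raise :class:`UnbalancedDesignError`.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    a_levels, a_idx = np.unique(a, return_inverse=True)
    b_levels, b_idx = np.unique(b, return_inverse=True)
    I, J = a_levels.size, b_levels.size
    if I < 2 or J < 2:
        raise ValueError("need at least 2 levels per factor")
    counts = np.zeros((I, J), dtype=int)
    np.add.at(counts, (a_idx, b_idx), 1)
    if counts.min() < 1:
        raise UnbalancedDesignError("empty cells in the design")
    n = int(counts[0, 0])
    if not np.all(counts == n):
        raise UnbalancedDesignError("unequal cell counts; balanced design required")

    grand = y.mean()
    cell_sums = np.zeros((I, J))
    np.add.at(cell_sums, (a_idx, b_idx), y)
    cell_means = cell_sums / n
    a_means = cell_means.mean(axis=1)
    b_means = cell_means.mean(axis=0)

    ss_a = n * J * float(np.sum((a_means - grand) ** 2))
    ss_b = n * I * float(np.sum((b_means - grand) ** 2))
    ss_cells = n * float(np.sum((cell_means - grand) ** 2))
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float(np.sum((y - grand) ** 2))
    ss_res = ss_total - ss_cells

    rows: list[dict] = []
    if n >= 2:
        effects = [
            ("factor_a", ss_a, I - 1),
            ("factor_b", ss_b, J - 1),
            ("interaction", ss_ab, (I - 1) * (J - 1)),
        ]
        df_res = I * J * (n - 1)
    else:
        effects = [("factor_a", ss_a, I - 1), ("factor_b", ss_b, J - 1)]
        ss_res = ss_ab
        df_res = (I - 1) * (J - 1)
    ms_res = ss_res / df_res if df_res > 0 else 0.0
    for name, ss, df in effects:
        ms = ss / df
        f = ms / ms_res if ms_res > 0 else 0.0
        p = float(stats.f.sf(f, df, df_res)) if ms_res > 0 and df_res > 0 else 1.0
        rows.append(
            {"effect": name, "sum_sq": ss, "df": df, "mean_sq": ms, "F": f, "p": p}
        )
    rows.append(
        {
            "effect": "residual",
            "sum_sq": ss_res,
            "df": df_res,
            "mean_sq": ms_res,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("effect")


@dataclass(frozen=True)
class TukeyResult:
    q: np.ndarray  # pairwise studentized-range statistics
    p: np.ndarray  # pairwise p-values
    significant: np.ndarray  # boolean matrix
    q_critical: float
    alpha: float


def tukey_kramer(
    group_means: Sequence[float],
    group_ns: Sequence[int],
    ms_within: float,
    df_within: float,
    alpha: float = 0.05,
) -> TukeyResult:
    """All-pairs studentized-range comparisons with the Kramer correction.

    Pair (i, j) is significant when
    q = |m_i − m_j| / sqrt((MS_within / 2)(1/n_i + 1/n_j)) exceeds the
    studentized-range critical value at ``alpha`` for k groups and
    ``df_within`` error degrees of freedom.  Critical values come from the
    distribution function, not from printed tables.
    """
    means = np.asarray(group_means, dtype=float)
    ns = np.asarray(group_ns, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if ms_within <= 0:
        raise ValueError("ms_within must be positive")
    if df_within < 1:
        raise ValueError("df_within must be at least 1")
    diff = np.abs(means[:, None] - means[None, :])
    se = np.sqrt((ms_within / 2.0) * (1.0 / ns[:, None] + 1.0 / ns[None, :]))
    q = diff / se
    np.fill_diagonal(q, 0.0)
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_within))
    p = stats.studentized_range.sf(q, k, df_within)
    np.fill_diagonal(p, 1.0)
    sig = q > q_crit
    np.fill_diagonal(sig, False)
    return TukeyResult(q=q, p=np.asarray(p), significant=sig, q_critical=q_crit, alpha=alpha)


@dataclass(frozen=True)
class TukeyLetters:
    """Compact letter display: groups sharing a letter are not separated."""

    letters: Mapping[object, str]
    means: Mapping[object, float]
    ns: Mapping[object, int]
    alpha: float


def compact_letters(
    significant: np.ndarray, group_order: Sequence
) -> dict[object, str]:
    """Insert-and-absorb letter assignment from a pairwise significance matrix.

    Guarantees exactly: two groups share at least one letter if and only if
    their comparison is non-significant.
    """
    sig = np.asarray(significant, dtype=bool)
    k = len(group_order)
    if sig.shape != (k, k) or not np.array_equal(sig, sig.T):
        raise ValueError("significance matrix must be symmetric k x k")
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    new_cols.extend([col - {i}, col - {j}])
                else:
                    new_cols.append(col)
            # absorb: drop any column contained in another
            columns = [
                c
                for idx, c in enumerate(new_cols)
                if c
                and not any(
                    c < other or (c == other and idx > jdx)
                    for jdx, other in enumerate(new_cols)
                    if jdx != idx
                )
            ]
    columns.sort(key=lambda c: sorted(c))
    out: dict[object, str] = {g: "" for g in group_order}
    for letter, col in zip(_letter_stream(), columns):
        for member in sorted(col):
            out[group_order[member]] += letter
    return out


def _letter_stream():
    i = 0
    while True:
        quotient, remainder = divmod(i, 26)
        yield ascii_uppercase[remainder] * (quotient + 1)
        i += 1


def letter_display(
    values: Sequence[float],
    groups: Sequence,
    ms_within: float | None = None,
    df_within: float | None = None,
    alpha: float = 0.05,
) -> TukeyLetters:
    """Group means with Tukey-Kramer compact letters.

    When ``ms_within``/``df_within`` are omitted they default to the pooled
    within-group variance (one-way layout).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels, idx = np.unique(g, return_inverse=True)
    ns = np.bincount(idx)
    means = np.array([y[idx == c].mean() for c in range(levels.size)])
    if ms_within is None or df_within is None:
        ss_within = sum(
            float(np.sum((y[idx == c] - means[c]) ** 2)) for c in range(levels.size)
        )
        df_within = int(y.size - levels.size)
        ms_within = ss_within / df_within
    res = tukey_kramer(means, ns, ms_within, df_within, alpha=alpha)
    letters = compact_letters(res.significant, list(levels))
    return TukeyLetters(
        letters=letters,
        means={lv: float(m) for lv, m in zip(levels, means)},
        ns={lv: int(n) for lv, n in zip(levels, ns)},
        alpha=alpha,
    )
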