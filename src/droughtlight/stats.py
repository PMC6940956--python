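"""Group statistics: one-way ANOVA with Tukey HSD letters, signed R^2,
qPCR fold change, dehydration water loss and percent-of-control summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA F/p plus Tukey HSD pairwise p's and letter display."""

    f_statistic: float
    p: float
    pairwise: pd.DataFrame  # columns: group1, group2, diff, q, p_adj
    letters: dict[str, str]
    group_means: dict[str, float]


def anova_tukey(
    data: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey's HSD with a compact letter display.

    Pairwise p-values come from the studentized-range distribution with the
    Tukey-Kramer standard error for unbalanced groups. Letters are assigned
    by insert-and-absorb over the significant-difference graph with groups
    ordered by mean descending: groups sharing a letter are not
    significantly different at ``alpha``.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in data.items()}
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValidationError("need >= 2 replicates per group")
    values = np.concatenate(list(groups.values()))
    k = len(groups)
    n_total = len(values)
    df_within = n_total - k
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    if ss_within <= 0:
        raise ValidationError("zero within-group variance; ANOVA undefined")
    ms_between = ss_between / (k - 1)
    mse = ss_within / df_within
    f_stat = ms_between / mse
    p = float(sps.f.sf(f_stat, k - 1, df_within))

    rows = []
    sig_pairs: set[frozenset[str]] = set()
    for g1, g2 in itertools.combinations(groups, 2):
        v1, v2 = groups[g1], groups[g2]
        diff = v1.mean() - v2.mean()
        se = math.sqrt(mse / 2.0 * (1.0 / len(v1) + 1.0 / len(v2)))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_within))
        rows.append({"group1": g1, "group2": g2, "diff": diff,
                     "q": q, "p_adj": p_adj})
        if p_adj <= alpha:
            sig_pairs.add(frozenset((g1, g2)))
    pairwise = pd.DataFrame(rows)

    letters = _compact_letter_display(
        sorted(groups, key=lambda g: -groups[g].mean()), sig_pairs
    )
    return AnovaTukeyResult(
        f_statistic=float(f_stat), p=p, pairwise=pairwise, letters=letters,
        group_means={g: float(v.mean()) for g, v in groups.items()},
    )


def _compact_letter_display(
    ordered_groups: list[str], sig_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment over the difference graph."""
    # each letter set is a set of groups that are mutually non-different
    letter_sets: list[set[str]] = []
    for g in ordered_groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in sig_pairs for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
            # re-check earlier groups: any group not different from g joins
            for other in ordered_groups:
                if other != g and frozenset((g, other)) not in sig_pairs:
                    if all(frozenset((other, m)) not in sig_pairs
                           for m in letter_sets[-1]):
                        letter_sets[-1].add(other)
    # absorb letter sets fully contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in ordered_groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in ordered_groups:
            if g in s:
                letters[g] += letter
    return letters


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Signed squared Pearson correlation: sign(r) * r^2.

    The sign convention lets negatively correlated parameter pairs be
    reported with negative R^2 values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("x and y must be equal-length 1-D series of >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant series: correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    return math.copysign(r * r, r)


def qpcr_fold_change(
    ct: Mapping[str, float],
    efficiency: float,
    treated: str,
    control: str,
    reference_ct: Mapping[str, float] | None = None,
) -> float:
    """Relative expression FC = E^-(Ct_treated - Ct_control).

    ``ct`` maps condition -> mean Ct of the gene of interest. If
    ``reference_ct`` (the reference gene's Ct per condition) is supplied,
    delta-delta-Ct style pre-subtraction is applied first; the default is no
    reference normalization. Down-regulation gives FC < 1.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValidationError(f"efficiency must be in (1, 2], got {efficiency}")
    for cond in (treated, control):
        if cond not in ct:
            raise ValidationError(f"condition {cond!r} missing from Ct table")
        if ct[cond] <= 0:
            raise ValidationError(f"Ct for {cond!r} must be positive")
    d_ct = ct[treated] - ct[control]
    if reference_ct is not None:
        d_ct -= reference_ct[treated] - reference_ct[control]
    return float(efficiency ** (-d_ct))


def signed_fold_change(fc: float) -> float:
    """Display convention: down-regulation (FC < 1) as a negative fold."""
    if fc <= 0:
        raise ValidationError("fold change must be > 0")
    return fc if fc >= 1.0 else -1.0 / fc


def water_loss(fresh_weight: float, dehydrated_weight: float) -> tuple[float, bool]:
    """Dehydration water loss WL = Dw * 100% / Fw.

    Returns (WL percent, reached_target) where the target is the 30%-loss
    stop rule, i.e. WL <= 70.
    """
    if fresh_weight <= 0:
        raise ValidationError("fresh weight must be positive")
    if not 0 < dehydrated_weight <= fresh_weight:
        raise ValidationError("dehydrated weight must be in (0, fresh weight]")
    wl = dehydrated_weight * 100.0 / fresh_weight
    return wl, wl <= 70.0


def percent_of_control(
    means: Mapping[str, float], control_label: str
) -> dict[str, float]:
    """Each group mean as a percentage of the control mean."""
    if control_label not in means:
        raise ValidationError(f"control group {control_label!r} absent")
    control = means[control_label]
    if control == 0:
        raise ValidationError("control mean is zero; percent-of-control undefined")
    return {g: 100.0 * m / control for g, m in means.items()}


def group_summary(
    values: Mapping[str, Sequence[float]], control_label: str | None = None
) -> pd.DataFrame:
    """Mean, SE and optionally percent-of-control per group."""
    rows = []
    for g, v in values.items():
        v = np.asarray(v, dtype=float)
        rows.append({"group": g, "n": len(v), "mean": v.mean(),
                     "se": v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else np.nan})
    table = pd.DataFrame(rows).set_index("group")
    if control_label is not None:
        pct = percent_of_control(table["mean"].to_dict(), control_label)
        table["percent_of_control"] = pd.Series(pct)
    return table
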