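"""Group-comparison statistics and community-composition utilities.

Treatment effects on rate data are tested with the non-parametric
Kruskal-Wallis omnibus test (chi-squared approximation, df = groups-1),
followed by pairwise comparisons of mean ranks in the style of Fisher's
least-significant-difference criterion applied to the ranks, with
Holm's step-down adjustment of the pairwise p-values. Groups sharing a
significance letter are not distinguishable at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "composition_percentages", "compare_groups",
           "holm_adjust"]


def composition_percentages(counts: dict) -> dict[str, float]:
    """Percent share per label from labelled non-negative counts.

    Percentages sum to 100 exactly (up to floating point).
    """
    if not counts:
        raise ValueError("no counts given")
    values = {k: float(v) for k, v in counts.items()}
    if any(v < 0 for v in values.values()):
        raise ValueError("counts must be non-negative")
    total = sum(values.values())
    if total <= 0:
        raise ValueError("total count must be > 0")
    return {k: 100.0 * v / total for k, v in values.items()}


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Ties in the raw p-values keep their original comparison order (a
    stable sort), so the adjustment is reproducible.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


@dataclass
class GroupComparison:
    """Omnibus Kruskal-Wallis result plus pairwise rank comparisons."""

    h: float
    p: float
    df: int
    pairwise: pd.DataFrame  # group1, group2, p_raw, p_holm, significant
    letters: dict[str, str]


def compare_groups(groups: dict, alpha: float = 0.05) -> GroupComparison:
    """Kruskal-Wallis omnibus plus Holm-adjusted pairwise rank LSD.

    ``groups`` maps group labels to 1-D value sequences (n >= 1 each,
    at least two groups). When every value is tied across all groups
    the omnibus is H = 0, p = 1 and no pair differs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    if any(s.size < 1 for s in samples):
        raise ValueError("every group needs at least one value")

    all_vals = np.concatenate(samples)
    if np.all(all_vals == all_vals[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    df = len(names) - 1

    # mean ranks and tie-corrected rank variance for the pairwise LSD
    ranks = sps.rankdata(all_vals)
    sizes = np.array([s.size for s in samples])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {names[i]: float(ranks[bounds[i]:bounds[i + 1]].mean())
                  for i in range(len(names))}
    n_total = all_vals.size
    s2 = float(np.var(ranks, ddof=1)) if n_total > 1 else 0.0
    dof = n_total - len(names)

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            diff = abs(mean_ranks[a] - mean_ranks[b])
            # tie-corrected H can exceed n-1; a non-positive residual
            # factor means the ranks are fully explained by the groups
            factor = max(n_total - 1 - h, 0.0) / dof if dof > 0 else 0.0
            if s2 <= 0 or dof <= 0:
                p_raw = 1.0
            elif factor == 0.0:
                p_raw = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(s2 * factor
                             * (1.0 / sizes[i] + 1.0 / sizes[j]))
                t = diff / se
                p_raw = float(2.0 * sps.t.sf(t, dof))
            rows.append({"group1": a, "group2": b, "p_raw": p_raw})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    pairwise["significant"] = pairwise["p_holm"] < alpha

    letters = _assign_letters(names, mean_ranks, pairwise)
    return GroupComparison(h=float(h), p=float(p), df=df,
                           pairwise=pairwise, letters=letters)


def _assign_letters(names, mean_ranks, pairwise) -> dict[str, str]:
    """Compact letter display: groups not significantly different share
    a letter; ordered by mean rank."""
    different = {
        frozenset((r.group1, r.group2))
        for r in pairwise.itertuples(index=False) if r.significant}
    ordered = sorted(names, key=lambda k: mean_ranks[k])
    clusters: list[set[str]] = []
    for name in ordered:
        placed = False
        for cluster in clusters:
            if all(frozenset((name, other)) not in different
                   for other in cluster):
                cluster.add(name)
                placed = True
        if not placed:
            clusters.append({name})
    # drop clusters fully contained in another (absorb step)
    clusters = [c for c in clusters
                if not any(c < other for other in clusters)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for letter, cluster in zip(alphabet, clusters):
        for name in ordered:
            if name in cluster:
                letters[name] += letter
    return letters
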