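"""Nonparametric group comparison of RI values.

Kruskal–Wallis (tie-corrected H, chi-square approximation) across species or
acclimation temperatures, followed by the rank-sum multiple-comparison
procedure of Siegel & Castellan: pair (i, j) differs when

    |Rbar_i - Rbar_j| > z_{1 - alpha / (k(k-1))} * sqrt( N(N+1)/12 * (1/n_i + 1/n_j) )

where Rbar are mean ranks over the pooled sample. Significant pairs are
condensed into a compact letter display (groups sharing a letter do not
differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["KWResult", "PosthocResult", "kruskal_wallis", "posthoc_mc", "letter_display"]


@dataclass(frozen=True)
class KWResult:
    h_statistic: float
    df: int
    p_value: float
    n_total: int
    group_sizes: tuple[int, ...]


@dataclass
class PosthocResult:
    pairs: list[dict]  # group_a, group_b, abs_mean_rank_diff, critical_diff, significant
    alpha: float
    letters: dict[str, str]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with the chi-square approximation.

    All-identical observations give H = 0, p = 1 (no evidence, not an error).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    n_total = int(sum(g.size for g in groups))
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, len(groups) - 1, 1.0, n_total, tuple(g.size for g in groups))
    h, p = sps.kruskal(*groups)
    return KWResult(float(h), len(groups) - 1, float(p), n_total, tuple(g.size for g in groups))


def _mean_ranks(groups: list[np.ndarray]) -> np.ndarray:
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # midranks for ties
    out = np.empty(len(groups))
    i = 0
    for gi, g in enumerate(groups):
        out[gi] = ranks[i : i + g.size].mean()
        i += g.size
    return out


def posthoc_mc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> PosthocResult:
    """Pairwise mean-rank comparisons after a Kruskal–Wallis rejection."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    k = len(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    labels = [str(l) for l in labels]
    n = np.array([g.size for g in groups])
    n_total = int(n.sum())
    rbar = _mean_ranks(groups)
    z = sps.norm.ppf(1.0 - alpha / (k * (k - 1)))
    pairs = []
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            cd = z * np.sqrt(n_total * (n_total + 1) / 12.0 * (1.0 / n[i] + 1.0 / n[j]))
            diff = abs(rbar[i] - rbar[j])
            s = bool(diff > cd)
            sig[i, j] = sig[j, i] = s
            pairs.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "abs_mean_rank_diff": float(diff),
                    "critical_diff": float(cd),
                    "significant": s,
                }
            )
    letters = letter_display(labels, sig, order=np.argsort(-rbar))
    return PosthocResult(pairs=pairs, alpha=alpha, letters=letters)


def letter_display(
    labels: Sequence[str], sig: np.ndarray, order: Sequence[int] | None = None
) -> dict[str, str]:
    """Compact letter display by greedy insert-absorb.

    ``sig[i, j]`` is True when groups i and j differ significantly. Groups
    sharing any letter are not significantly different; every non-significant
    pair shares at least one letter.
    """
    k = len(labels)
    if order is None:
        order = range(k)
    letter_sets: list[set[int]] = []
    for idx in order:
        placed = False
        for s in letter_sets:
            if not any(sig[idx, m] for m in s):
                s.add(idx)
                placed = True
        if not placed:
            letter_sets.append({idx})
    # absorb: drop sets contained in another, dedupe, keep insertion order
    final: list[set[int]] = []
    for s in letter_sets:
        if any(s <= t for t in letter_sets if t is not s and not t <= s) or s in final:
            continue
        final.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {str(l): "" for l in labels}
    for li, s in enumerate(final):
        ch = alphabet[li % len(alphabet)]
        for m in sorted(s):
            out[str(labels[m])] += ch
    return out
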