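"""Group comparison of marker-positive fractions across subject groups.

Standard machinery: one-way ANOVA across groups (e.g. healthy donors and
cancer stages I-IV) and all pairwise two-sample Welch t-tests, unadjusted by
default with Holm correction available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupTable", "anova_fp", "pairwise_fp"]


@dataclass
class GroupTable:
    """Named groups of per-subject F_p values."""

    groups: list[tuple[str, list[float]]]

    def validate(self, min_per_group: int = 2) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for name, vals in self.groups:
            if len(vals) < min_per_group:
                raise ValueError(f"group {name!r} needs >= {min_per_group} values")


def anova_fp(table: GroupTable) -> tuple[float, float]:
    """One-way ANOVA over the groups: (F statistic, p value)."""
    table.validate()
    f, p = sps.f_oneway(*[np.asarray(v, dtype=float) for _, v in table.groups])
    return float(f), float(p)


def pairwise_fp(
    table: GroupTable, equal_var: bool = False, holm: bool = False
) -> tuple[list[str], np.ndarray]:
    """All pairwise two-sample t-tests (Welch by default).

    Returns (group names, symmetric p-value matrix with unit diagonal).
    Holm step-down adjustment over the upper triangle when ``holm=True``.
    """
    table.validate()
    names = [name for name, _ in table.groups]
    g = len(names)
    pmat = np.ones((g, g))
    pvals = []
    pairs = []
    for i in range(g):
        for j in range(i + 1, g):
            _, p = sps.ttest_ind(
                np.asarray(table.groups[i][1], dtype=float),
                np.asarray(table.groups[j][1], dtype=float),
                equal_var=equal_var,
            )
            pvals.append(float(p))
            pairs.append((i, j))
    if holm and pvals:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, o in enumerate(order):
            running = max(running, (m - rank) * pvals[o])
            adj[o] = min(1.0, running)
        pvals = adj.tolist()
    for (i, j), p in zip(pairs, pvals):
        pmat[i, j] = pmat[j, i] = p
    return names, pmat
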