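"""Motif-class prevalence comparisons between protein sets.

Differentially regulated protein sets (up, down) are compared against
each other and against the full identified background by the proportion
of proteins carrying at least one motif of each KFERQ-like class, and
the association between set membership and motif carriage is formalised
with Fisher's exact test on the 2×2 table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import MotifClass, MotifReport

logger = logging.getLogger("cmakit")

__all__ = ["ContingencyTable2x2", "fisher_association", "motif_class_prevalence"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of with-motif / without-motif × set1 / set2.

    Layout::

            with    without
        set1   a       b
        set2   c       d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a nonnegative integer, got {v}")


def fisher_association(table: ContingencyTable2x2) -> dict:
    """Odds ratio and two-sided exact p for a 2×2 table.

    The odds ratio is the cross-product ``(a·d)/(b·c)`` (reported as
    inf and flagged when ``b·c = 0``).  The two-sided p-value follows
    the common exact convention: the sum of hypergeometric
    probabilities of all tables with the same margins whose probability
    does not exceed the observed table's (no continuity correction;
    sample sizes in this setting are small, so only the exact test is
    offered).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty contingency table")
    if b * c == 0:
        odds_ratio = math.inf if a * d > 0 else math.nan
        degenerate_or = True
    else:
        odds_ratio = (a * d) / (b * c)
        degenerate_or = False

    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    p = min(float(p), 1.0)
    return {
        "odds_ratio": odds_ratio,
        "odds_ratio_degenerate": degenerate_or,
        "p_value": p,
        "table": (a, b, c, d),
    }


def motif_class_prevalence(
    report: MotifReport,
    sets: Mapping[str, Iterable[str]],
    compare: tuple[str, str] = ("up", "down"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-set, per-class motif prevalence with pairwise differences.

    ``sets`` names protein-id collections (typically ``up``, ``down``
    and a ``background`` superset of both).  Returns two tables: the
    tidy prevalence table (set, class, n_with_motif, n_total,
    proportion) and a comparison table for the ``compare`` pair with
    the proportion difference and Fisher association per class.
    """
    materialized = {name: list(ids) for name, ids in sets.items()}
    for name, ids in materialized.items():
        if not ids:
            raise ValueError(f"empty set {name!r}")
        unknown = [pid for pid in ids if pid not in report.counts]
        if unknown:
            raise ValueError(f"set {name!r} has unknown proteins: {unknown[:5]}")
    if "background" in materialized:
        bg = set(materialized["background"])
        for name in materialized:
            if name != "background" and not set(materialized[name]) <= bg:
                raise ValueError(f"set {name!r} is not contained in background")

    prevalence_rows = []
    for name, ids in materialized.items():
        for cls in MotifClass:
            n_with = sum(1 for pid in ids if report.has_class(pid, cls))
            prevalence_rows.append(
                {
                    "set": name,
                    "motif_class": cls.value,
                    "n_with_motif": n_with,
                    "n_total": len(ids),
                    "proportion": n_with / len(ids),
                }
            )
    prevalence = pd.DataFrame(prevalence_rows)

    set1, set2 = compare
    comparison_rows = []
    if set1 in materialized and set2 in materialized:
        for cls in MotifClass:
            ids1, ids2 = materialized[set1], materialized[set2]
            a = sum(1 for pid in ids1 if report.has_class(pid, cls))
            c = sum(1 for pid in ids2 if report.has_class(pid, cls))
            fisher = fisher_association(
                ContingencyTable2x2(a, len(ids1) - a, c, len(ids2) - c)
            )
            comparison_rows.append(
                {
                    "motif_class": cls.value,
                    f"proportion_{set1}": a / len(ids1),
                    f"proportion_{set2}": c / len(ids2),
                    "difference": a / len(ids1) - c / len(ids2),
                    "odds_ratio": fisher["odds_ratio"],
                    "p_value": fisher["p_value"],
                }
            )
    comparison = pd.DataFrame(comparison_rows)
    return prevalence, comparison
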