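"""The CMA activation score: a weighted, signed aggregate of CMA-network
gene expression used as a transcriptional proxy for chaperone-mediated
autophagy activation.

Each gene in the network carries a direction (+1 for effectors and
positive modulators, -1 for negative modulators) and a weight.  Genes
present as *n* paralogous copies share their influence: each paralog
receives weight 1/n.  The LAMP2A family is the exception — as the
rate-limiting receptor of CMA it receives a family weight of 2,
divided among its paralogs in proportion to their measured relative
contribution to CMA activity (equal split when contributions are not
supplied).

The per-sample score is the weighted signed sum of transformed
expression values.  Under the default log2-fold-change transform the
reference group is centred at 0 per gene, so a control sample scores
≈ 0 and the score is additive in log2 effect sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionTable

logger = logging.getLogger("cmakit")

__all__ = [
    "CmaNetworkElement",
    "CmaNetwork",
    "CmaScoreResult",
    "assign_weights",
    "compute_cma_score",
    "compare_scores",
]

TRANSFORMS = ("log2_fold_change", "fold_change", "zscore")
MISSING_POLICIES = ("exclude", "exclude_renormalize")

#: log2 fold change assigned to an undetected (zero) transcript whose
#: gene is detected in the reference group.  2^-10 ≈ 0.1% of reference:
#: far below qPCR dynamic range, so a knockout drags the score down
#: decisively without producing an infinity.
UNDETECTED_LOG2_FLOOR = -10.0


@dataclass(frozen=True)
class CmaNetworkElement:
    """One CMA-network gene.

    ``direction`` is +1 when the gene promotes CMA (effectors, positive
    modulators) and -1 when it inhibits it.  ``weight`` is assigned by
    :func:`assign_weights`; ``explicit_weight`` (e.g. from the network
    config file) overrides the derived value.
    """

    gene_id: str
    functional_group: str
    direction: int
    paralog_family: str
    explicit_weight: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if not self.paralog_family:
            raise ValueError(f"{self.gene_id}: paralog_family must be non-empty")
        for w in (self.explicit_weight, self.weight):
            if w is not None and w <= 0:
                raise ValueError(f"{self.gene_id}: weight must be positive")

    @property
    def is_lamp2a_family(self) -> bool:
        return self.paralog_family.lower() == "lamp2a"


@dataclass
class CmaNetwork:
    """A validated CMA gene network."""

    elements: list[CmaNetworkElement]

    def __post_init__(self) -> None:
        ids = [el.gene_id for el in self.elements]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in network")
        if not self.elements:
            raise ValueError("empty network")

    @property
    def families(self) -> dict[str, list[CmaNetworkElement]]:
        fams: dict[str, list[CmaNetworkElement]] = {}
        for el in self.elements:
            fams.setdefault(el.paralog_family, []).append(el)
        return fams

    @property
    def gene_ids(self) -> list[str]:
        return [el.gene_id for el in self.elements]

    @property
    def is_weighted(self) -> bool:
        return all(el.weight is not None for el in self.elements)

    def total_abs_weight(self) -> float:
        if not self.is_weighted:
            raise ValueError("network is not weighted; call assign_weights first")
        return sum(el.weight for el in self.elements)  # type: ignore[misc]

    def __getitem__(self, gene_id: str) -> CmaNetworkElement:
        for el in self.elements:
            if el.gene_id == gene_id:
                return el
        raise KeyError(gene_id)


@dataclass
class CmaScoreResult:
    """Per-sample score with bookkeeping of what entered the sum."""

    sample_id: str
    score: float
    n_genes_used: int
    genes_excluded: list[str]
    transform: str
    contributions: dict[str, float] = field(default_factory=dict)


def assign_weights(
    network: CmaNetwork,
    lamp2a_contributions: Mapping[str, float] | None = None,
) -> CmaNetwork:
    """Derive per-gene weights from paralog-family structure.

    Every gene in a non-LAMP2A family of size *n* receives weight 1/n,
    so each family contributes a total of 1.  The LAMP2A family — the
    rate-limiting step of CMA — receives a family total of 2, split
    between its paralogs according to ``lamp2a_contributions``
    (fractions summing to 1; default equal split).  Explicit per-gene
    weights from the config override the derived values and are logged.
    """
    families = network.families
    lamp2a_members: list[str] = []
    for fam, members in families.items():
        if members and members[0].is_lamp2a_family:
            lamp2a_members = [el.gene_id for el in members]

    if lamp2a_contributions is not None:
        if not lamp2a_members:
            raise ValueError("lamp2a_contributions given but no lamp2a family in network")
        if set(lamp2a_contributions) != set(lamp2a_members):
            raise ValueError(
                f"lamp2a_contributions keys {sorted(lamp2a_contributions)} do not match "
                f"lamp2a family members {sorted(lamp2a_members)}"
            )
        total = sum(lamp2a_contributions.values())
        if any(v <= 0 for v in lamp2a_contributions.values()):
            raise ValueError("lamp2a contributions must be positive")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"lamp2a contributions must sum to 1, got {total!r}")

    new_elements: list[CmaNetworkElement] = []
    for el in network.elements:
        family_size = len(families[el.paralog_family])
        if el.explicit_weight is not None:
            weight = el.explicit_weight
            logger.info(
                "assign_weights: %s uses explicit weight %.4g (derived would be %s)",
                el.gene_id, weight,
                "lamp2a rule" if el.is_lamp2a_family else f"1/{family_size}",
            )
        elif el.is_lamp2a_family:
            if lamp2a_contributions is not None:
                frac = lamp2a_contributions[el.gene_id]
            else:
                frac = 1.0 / family_size
            weight = 2.0 * frac
        else:
            weight = 1.0 / family_size
        new_elements.append(replace(el, weight=weight))
    return CmaNetwork(new_elements)


def _gene_transform(
    expr: ExpressionTable,
    gene: str,
    transform: str,
    reference_sample_ids: Sequence[str] | None,
    undetected_floor_log2: float,
) -> tuple[pd.Series, pd.Series]:
    """Transform one gene's column.

    Returns ``(values, usable)`` where ``usable`` is False for samples
    whose value cannot enter the score (missing, or undetected under a
    policy that excludes them).  NaN in ``values`` marks unusable cells.
    """
    col = expr.values[gene]
    detected = col.notna() & (col != 0)

    if transform == "zscore":
        x = col.where(detected)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            sd = 1.0
        vals = (x - mu) / sd
        return vals, detected

    assert reference_sample_ids is not None
    ref = col.loc[list(reference_sample_ids)]
    ref_pos = ref[ref.notna() & (ref > 0)]
    if ref_pos.empty:
        # gene undetected in the whole reference group: no centre exists
        return pd.Series(np.nan, index=col.index), pd.Series(False, index=col.index)
    center = math.exp(np.log(ref_pos).mean())  # geometric mean

    if transform == "fold_change":
        vals = col / center
        return vals, col.notna()

    # log2_fold_change
    vals = pd.Series(np.nan, index=col.index)
    usable = pd.Series(False, index=col.index)
    pos = col.notna() & (col > 0)
    vals[pos] = np.log2(col[pos] / center)
    usable[pos] = True
    zero = col.notna() & (col == 0)
    if zero.any():
        if math.isfinite(undetected_floor_log2):
            vals[zero] = undetected_floor_log2
            usable[zero] = True
            logger.warning(
                "compute_cma_score: gene %s undetected in %d sample(s); "
                "log2 fold change floored at %.1f", gene, int(zero.sum()),
                undetected_floor_log2,
            )
        else:
            logger.warning(
                "compute_cma_score: gene %s undetected in %d sample(s); excluded "
                "under the log2 transform", gene, int(zero.sum()),
            )
    return vals, usable


def compute_cma_score(
    expr: ExpressionTable,
    network: CmaNetwork,
    transform: str = "log2_fold_change",
    reference_sample_ids: Sequence[str] | None = None,
    missing_policy: str = "exclude_renormalize",
    undetected_floor_log2: float = UNDETECTED_LOG2_FLOOR,
    average: bool = False,
) -> list[CmaScoreResult]:
    """Compute the per-sample CMA activation score.

    Per sample, ``score = Σ_g weight_g × direction_g × T(x_{s,g})`` over
    the usable network genes, where T is the chosen transform:

    * ``log2_fold_change`` (default): log2 of expression over the
      reference group's per-gene geometric mean; the reference group
      then scores 0 on average by construction.  An undetected (zero)
      transcript is assigned the floor ``undetected_floor_log2``
      (pass ``-inf`` — or ``float('-inf')`` — to exclude such cells
      instead).
    * ``fold_change``: plain ratio to the reference centre.
    * ``zscore``: per-gene standardisation across all samples
      (no reference group needed).

    Missing (unmeasured) genes are excluded per sample; with
    ``missing_policy="exclude_renormalize"`` the weights of the used
    genes are rescaled so their sum equals the full network's total
    weight, keeping scores comparable across tissues that detect
    different gene subsets.  ``average=True`` divides by the total
    weight, turning the sum into a weighted mean.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(
            f"unknown missing_policy {missing_policy!r}; choose from {MISSING_POLICIES}"
        )
    if not network.is_weighted:
        raise ValueError("network must be weighted; call assign_weights first")
    if transform in ("log2_fold_change", "fold_change"):
        if not reference_sample_ids:
            raise ValueError(f"transform {transform!r} requires reference_sample_ids")
        missing_ref = set(reference_sample_ids) - set(expr.samples)
        if missing_ref:
            raise ValueError(f"unknown reference samples: {sorted(missing_ref)}")

    present = [g for g in network.gene_ids if g in expr.values.columns]
    absent = [g for g in network.gene_ids if g not in expr.values.columns]
    if not present:
        raise ValueError("all network genes are missing from the expression table")
    if absent:
        logger.warning(
            "compute_cma_score: %d network gene(s) absent from table: %s",
            len(absent), absent,
        )

    transformed: dict[str, pd.Series] = {}
    usable: dict[str, pd.Series] = {}
    for gene in present:
        vals, ok = _gene_transform(
            expr, gene, transform, reference_sample_ids, undetected_floor_log2
        )
        transformed[gene] = vals
        usable[gene] = ok

    total_weight = network.total_abs_weight()
    results: list[CmaScoreResult] = []
    for sample in expr.samples:
        used_genes = [g for g in present if bool(usable[g].loc[sample])]
        excluded = absent + [g for g in present if g not in used_genes]
        if not used_genes:
            raise ValueError(f"sample {sample!r}: no usable network genes")
        used_weight = sum(network[g].weight for g in used_genes)  # type: ignore[misc]
        scale = 1.0
        if missing_policy == "exclude_renormalize" and used_weight < total_weight:
            scale = total_weight / used_weight
        contributions = {
            g: scale
            * network[g].weight  # type: ignore[operator]
            * network[g].direction
            * float(transformed[g].loc[sample])
            for g in used_genes
        }
        score = sum(contributions.values())
        if average:
            score /= total_weight
        results.append(
            CmaScoreResult(
                sample_id=sample,
                score=score,
                n_genes_used=len(used_genes),
                genes_excluded=excluded,
                transform=transform,
                contributions=contributions,
            )
        )
    logger.info(
        "compute_cma_score: %d samples scored (%s transform, %s policy, "
        "total weight %.3f, %s)", len(results), transform, missing_policy,
        total_weight, "weighted mean" if average else "weighted sum",
    )
    return results


def scores_to_frame(results: Sequence[CmaScoreResult]) -> pd.DataFrame:
    """Tabulate score results, one row per sample."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "score": r.score,
                "n_genes_used": r.n_genes_used,
                "genes_excluded": ";".join(r.genes_excluded),
                "transform": r.transform,
            }
            for r in results
        ]
    )


def compare_scores(
    results: Sequence[CmaScoreResult],
    group_labels: Mapping[str, str] | Mapping[str, tuple[str, str]],
    design: str = "two_group",
) -> dict:
    """Compare CMA scores between experimental groups.

    ``design="two_group"`` runs a two-tailed Student t-test between the
    two groups named in ``group_labels`` (sample_id -> group).
    ``design="tissue_by_condition"`` fits a two-way ANOVA with additive
    tissue and condition factors (sample_id -> (tissue, condition)).
    Statistical tests are delegated to scipy/statsmodels; the summary
    records which test ran.
    """
    scores = {r.sample_id: r.score for r in results}
    unknown = set(group_labels) - set(scores)
    if unknown:
        raise ValueError(f"group labels reference unknown samples: {sorted(unknown)}")

    if design == "two_group":
        groups: dict[str, list[float]] = {}
        for sid, g in group_labels.items():
            groups.setdefault(str(g), []).append(scores[sid])
        if len(groups) != 2:
            raise ValueError(f"two_group design needs exactly 2 groups, got {len(groups)}")
        for g, vals in groups.items():
            if len(vals) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        (name1, vals1), (name2, vals2) = sorted(groups.items())
        t, p = stats.ttest_ind(vals2, vals1, equal_var=True)
        summary = {
            "design": "two_group",
            "test": "two-tailed Student t-test (equal variances)",
            "groups": {
                name1: {"n": len(vals1), "mean": float(np.mean(vals1)),
                        "sd": float(np.std(vals1, ddof=1))},
                name2: {"n": len(vals2), "mean": float(np.mean(vals2)),
                        "sd": float(np.std(vals2, ddof=1))},
            },
            "mean_difference": float(np.mean(vals2) - np.mean(vals1)),
            "statistic": float(t),
            "p_value": float(p),
        }
    elif design == "tissue_by_condition":
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rows = []
        for sid, label in group_labels.items():
            tissue, condition = label  # type: ignore[misc]
            rows.append({"score": scores[sid], "tissue": tissue, "condition": condition})
        df = pd.DataFrame(rows)
        counts = df.groupby(["tissue", "condition"]).size()
        if (counts < 2).any():
            raise ValueError("every tissue × condition cell needs at least 2 samples")
        model = ols("score ~ C(tissue) + C(condition)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        summary = {
            "design": "tissue_by_condition",
            "test": "two-way ANOVA (tissue + condition, type II)",
            "anova": {
                factor: {
                    "F": float(anova.loc[factor, "F"]),
                    "p_value": float(anova.loc[factor, "PR(>F)"]),
                }
                for factor in anova.index
                if factor != "Residual"
            },
            "cell_means": {
                f"{t}|{c}": float(m)
                for (t, c), m in df.groupby(["tissue", "condition"])["score"].mean().items()
            },
        }
    else:
        raise ValueError(f"unknown design {design!r}")

    logger.info("compare_scores: %s -> p=%s", summary["test"],
                summary.get("p_value", summary.get("anova")))
    return summary
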