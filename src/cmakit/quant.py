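"""Label-free protein quantification by median-ratio fitting.

For each protein, the abundance ratio between every pair of LC-MS runs
is estimated as the median of its ion ratios over the ions observed in
both runs.  The per-run protein abundances are then reconstructed by
least squares over the log2 ratio equations ``x_r − x_s = log2 M[r,s]``
(one per defined run pair); the additive gauge freedom of that system
is fixed by rescaling so the per-run abundances sum to the protein's
total observed ion abundance.  Working in log2 space keeps up- and
down-ratios symmetric and makes the reconstruction linear.

Differential abundance between two groups of runs is assessed with a
two-tailed pooled-variance Student t-test on log2 abundances, and hits
are called by joint p-value and fold-change thresholds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger("cmakit")

__all__ = [
    "ion_matrix",
    "pairwise_median_ratios",
    "fit_protein_abundances",
    "quantify_proteins",
    "differential_test",
    "classify_hits",
    "DisconnectedRunsError",
]

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_FC_THRESHOLD = 1.41


class DisconnectedRunsError(ValueError):
    """The graph of runs linked by shared ions is not connected."""


@dataclass
class ProteinRunAbundance:
    """Fitted per-run abundances for one protein.

    ``abundances`` is indexed by run id; runs with no observed ions are
    NaN.  ``rescaled`` records that the fitted profile was scaled to
    the protein's total observed ion abundance.
    """

    protein_id: str
    abundances: pd.Series
    rescaled: bool = True


def ion_matrix(ion_df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pivot a long ion table into per-protein ions × runs matrices.

    Zero abundances are demoted to missing: the downstream ratio and
    log-space computations are undefined at zero, and label-free zero
    intensities denote non-observation rather than true absence.
    """
    required = {"protein_id", "ion_id", "run_id", "abundance"}
    missing = required - set(ion_df.columns)
    if missing:
        raise ValueError(f"ion table lacks columns {sorted(missing)}")
    df = ion_df.copy()
    n_zero = int((df["abundance"] == 0).sum())
    if n_zero:
        logger.warning("ion_matrix: %d zero abundances treated as missing", n_zero)
        df.loc[df["abundance"] == 0, "abundance"] = np.nan
    all_proteins = set(df["protein_id"])
    df = df.dropna(subset=["abundance"])
    lost = all_proteins - set(df["protein_id"])
    if lost:
        raise ValueError(f"proteins with no observed ions: {sorted(lost)[:5]}")
    out: dict[str, pd.DataFrame] = {}
    for pid, sub in df.groupby("protein_id", sort=True):
        mat = sub.pivot_table(
            index="ion_id", columns="run_id", values="abundance", aggfunc="sum"
        )
        if mat.notna().sum().sum() == 0:
            raise ValueError(f"protein {pid!r} has no observed ions")
        out[str(pid)] = mat
    return out


def pairwise_median_ratios(ions: pd.DataFrame) -> pd.DataFrame:
    """Run × run protein-ratio matrix from one protein's ion matrix.

    ``M[r, s]`` is the median over ions of ``a[i, r] / a[i, s]``,
    computed only over ions observed in both runs (pairwise-complete
    policy); an even ion count uses the mean of the two middle ratios.
    The lower triangle is filled with reciprocals so that
    ``M[s, r] = 1 / M[r, s]`` holds by construction, the diagonal is 1,
    and pairs with no shared ion are left NaN (undefined).
    """
    if ions.shape[0] == 0:
        raise ValueError("protein has zero ions")
    runs = list(ions.columns)
    vals = ions.to_numpy(dtype=float)
    n = len(runs)
    M = np.full((n, n), np.nan)
    np.fill_diagonal(M, 1.0)
    for i, j in itertools.combinations(range(n), 2):
        both = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
        if not both.any():
            continue
        ratios = vals[both, i] / vals[both, j]
        M[i, j] = np.median(ratios)
        M[j, i] = 1.0 / M[i, j]
    return pd.DataFrame(M, index=runs, columns=runs)


def fit_protein_abundances(
    ratio_matrix: pd.DataFrame,
    ion_total: float,
    protein_id: str = "",
) -> ProteinRunAbundance:
    """Reconstruct per-run protein abundances from pairwise ratios.

    Solves the log2 least-squares system with one equation
    ``x_r − x_s = log2 M[r, s]`` per defined unordered pair, then fixes
    the additive gauge by rescaling so ``Σ_r 2^(x_r)`` equals
    ``ion_total`` (the protein's summed observed ion abundance across
    all runs).  With a single run the system is gauge-only and the
    run's abundance is ``ion_total`` itself.

    Raises
    ------
    DisconnectedRunsError
        If the defined pairs do not connect all runs; the message names
        the components.
    """
    runs = list(ratio_matrix.columns)
    n = len(runs)
    if ion_total <= 0:
        raise ValueError("ion_total must be positive")
    if n == 1:
        return ProteinRunAbundance(protein_id, pd.Series([ion_total], index=runs))

    M = ratio_matrix.to_numpy(dtype=float)
    pairs = [
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if np.isfinite(M[i, j])
    ]
    if not pairs:
        raise DisconnectedRunsError(
            f"protein {protein_id!r}: no run pair shares an ion"
        )
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), tuple(zip(*pairs))), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [
            [runs[k] for k in range(n) if labels[k] == c] for c in range(n_comp)
        ]
        raise DisconnectedRunsError(
            f"protein {protein_id!r}: run graph is disconnected; components: {comps}"
        )

    A = np.zeros((len(pairs), n))
    b = np.empty(len(pairs))
    for row, (i, j) in enumerate(pairs):
        A[row, i] = 1.0
        A[row, j] = -1.0
        b[row] = np.log2(M[i, j])
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    x -= x.max()  # keep 2**x away from overflow before rescaling
    raw = 2.0 ** x
    abundances = pd.Series(raw * (ion_total / raw.sum()), index=runs)
    return ProteinRunAbundance(protein_id, abundances)


def quantify_proteins(ion_df: pd.DataFrame) -> pd.DataFrame:
    """Full median-ratio quantification of a long ion table.

    Returns a proteins × runs abundance table.  Proteins whose run
    graph is disconnected are skipped with a warning rather than
    aborting the whole table.
    """
    matrices = ion_matrix(ion_df)
    all_runs = sorted(ion_df["run_id"].astype(str).unique())
    rows: dict[str, pd.Series] = {}
    skipped: list[str] = []
    for pid, mat in matrices.items():
        observed = mat.loc[:, mat.notna().any(axis=0)]
        total = float(np.nansum(observed.to_numpy()))
        ratios = pairwise_median_ratios(observed)
        try:
            fit = fit_protein_abundances(ratios, total, pid)
        except DisconnectedRunsError as exc:
            logger.warning("quantify_proteins: skipping %s (%s)", pid, exc)
            skipped.append(pid)
            continue
        rows[pid] = fit.abundances
    table = pd.DataFrame(rows).T.reindex(columns=all_runs)
    table.index.name = "protein_id"
    logger.info(
        "quantify_proteins: %d proteins fitted over %d runs (%d skipped)",
        len(table), len(all_runs), len(skipped),
    )
    return table


def differential_test(
    abundances: pd.DataFrame,
    groups: dict[str, str],
    group1: str,
    group2: str,
) -> pd.DataFrame:
    """Per-protein differential abundance between two groups of runs.

    ``abundances`` is proteins × runs; ``groups`` maps run id to group
    label.  Per protein, the log2 fold change is
    ``mean log2(group2) − mean log2(group1)`` and the p-value comes
    from a two-tailed pooled-variance (equal-variance) Student t-test
    on log2 abundances.  Nonpositive or missing abundances are
    excluded per protein; proteins with fewer than two usable runs in
    either group are skipped and logged.  When both groups have zero
    variance the t-test is degenerate: p is reported as NaN (means
    differ) or 1 (means equal) with ``degenerate=True``.
    """
    for g in (group1, group2):
        if sum(1 for v in groups.values() if v == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 runs")
    runs1 = [r for r in abundances.columns if groups.get(r) == group1]
    runs2 = [r for r in abundances.columns if groups.get(r) == group2]

    records = []
    skipped = 0
    for pid, row in abundances.iterrows():
        v1 = row[runs1].to_numpy(dtype=float)
        v2 = row[runs2].to_numpy(dtype=float)
        v1 = v1[np.isfinite(v1) & (v1 > 0)]
        v2 = v2[np.isfinite(v2) & (v2 > 0)]
        if len(v1) < 2 or len(v2) < 2:
            skipped += 1
            logger.warning(
                "differential_test: %s skipped (%d vs %d usable runs)",
                pid, len(v1), len(v2),
            )
            continue
        l1, l2 = np.log2(v1), np.log2(v2)
        lfc = float(l2.mean() - l1.mean())
        degenerate = l1.std(ddof=1) == 0 and l2.std(ddof=1) == 0
        if degenerate:
            p = 1.0 if lfc == 0 else float("nan")
        else:
            _, p = stats.ttest_ind(l2, l1, equal_var=True)
            p = float(p)
        records.append(
            {
                "protein_id": pid,
                "log2_fold_change": lfc,
                "p_value": p,
                "n_group1": len(v1),
                "n_group2": len(v2),
                "degenerate": degenerate,
            }
        )
    if skipped:
        logger.info("differential_test: %d proteins skipped", skipped)
    return pd.DataFrame(
        records,
        columns=[
            "protein_id", "log2_fold_change", "p_value",
            "n_group1", "n_group2", "degenerate",
        ],
    )


def classify_hits(
    records: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Call up/down/ns per protein and summarise counts.

    A protein is *up* when ``p < p_threshold`` and its fold change
    ``2**log2FC`` exceeds ``fc_threshold``; *down* when the fold change
    is below ``1/fc_threshold`` at the same significance; otherwise
    *ns*.  Degenerate p-values (NaN) never pass the significance gate.
    The summary reports identified/up/down counts with percentages to
    one decimal.
    """
    if p_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = records.copy()
    fc = 2.0 ** out["log2_fold_change"]
    sig = out["p_value"] < p_threshold  # NaN compares False
    out["call"] = "ns"
    out.loc[sig & (fc > fc_threshold), "call"] = "up"
    out.loc[sig & (fc < 1.0 / fc_threshold), "call"] = "down"
    n = len(out)
    n_up = int((out["call"] == "up").sum())
    n_down = int((out["call"] == "down").sum())
    summary = {
        "n_identified": n,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": round(100.0 * n_up / n, 1) if n else 0.0,
        "pct_down": round(100.0 * n_down / n, 1) if n else 0.0,
        "p_threshold": p_threshold,
        "fc_threshold": fc_threshold,
    }
    logger.info(
        "classify_hits: %d identified, %d up (%.1f%%), %d down (%.1f%%) at "
        "p<%g, FC>%g", n, n_up, summary["pct_up"], n_down, summary["pct_down"],
        p_threshold, fc_threshold,
    )
    return out, summary
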