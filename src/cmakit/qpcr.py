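"""qPCR relative-expression computations and the lysosomal uptake arithmetic.

Two standard relative-expression formulas are provided: the ΔCT method,
which assumes perfect doubling per PCR cycle, and the
efficiency-corrected E-method, which uses the measured amplification
factor per cycle for each primer pair.  Fold induction versus a
reference group divides each sample's ratio by the reference group's
geometric mean — Ct-derived ratios are log-scale quantities, so the
geometric (not arithmetic) mean is the appropriate centre.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger("cmakit")

__all__ = [
    "QpcrMeasurement",
    "relative_expression_dct",
    "relative_expression_emethod",
    "fold_induction",
    "uptake_from_association_binding",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One Ct measurement with its primer amplification efficiency.

    ``efficiency`` is the amplification factor per cycle, in (1, 2];
    2 corresponds to perfect doubling (the ΔCT assumption).
    """

    sample_id: str
    gene_id: str
    ct: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not (self.ct > 0 and math.isfinite(self.ct)):
            raise ValueError(f"ct must be a positive finite number, got {self.ct}")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError(f"efficiency must be in (1, 2], got {self.efficiency}")


def relative_expression_dct(ct_target: float, ct_reference: float) -> float:
    """Relative expression of target vs reference gene by the ΔCT method.

    Returns ``2 ** -(ct_target - ct_reference)``: one cycle of advantage
    doubles expression.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_target - ct_reference))


def relative_expression_emethod(
    ct_target: float, e_target: float, ct_reference: float, e_reference: float
) -> float:
    """Efficiency-corrected relative expression (E-method).

    Returns ``e_target**(-ct_target) / e_reference**(-ct_reference)``,
    computed in log space for numerical stability at high cycle counts.
    With both efficiencies equal to 2 this reduces to the ΔCT method.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    for name, e in (("e_target", e_target), ("e_reference", e_reference)):
        if not (1.0 < e <= 2.0):
            raise ValueError(f"{name} must be in (1, 2], got {e}")
    log_ratio = -ct_target * math.log(e_target) + ct_reference * math.log(e_reference)
    return math.exp(log_ratio)


def fold_induction(
    values: Sequence[float], reference_indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Fold change of each value versus the reference group's geometric mean.

    ``values`` are per-sample expression ratios for one gene;
    ``reference_indices`` select the reference group (e.g. the wild-type
    fish).  Zero values — undetectable expression, as for a knocked-out
    transcript — yield fold 0 and are flagged rather than dropped.

    Returns ``(folds, undetected_flags)``.  The geometric mean of the
    reference group's outputs is 1 by construction.  Negative values and
    an all-zero or empty reference group raise ``ValueError``.
    """
    vals = np.asarray(values, dtype=float)
    if len(reference_indices) == 0:
        raise ValueError("reference group must be non-empty")
    if np.any(vals < 0):
        raise ValueError("expression values must be nonnegative")
    ref = vals[list(reference_indices)]
    if np.any(ref <= 0):
        raise ValueError("all reference values must be positive")
    geo_mean = math.exp(np.mean(np.log(ref)))
    folds = vals / geo_mean
    undetected = vals == 0.0
    if undetected.any():
        logger.warning("fold_induction: %d undetected (zero) values flagged", undetected.sum())
    return folds, undetected


def uptake_from_association_binding(
    association: float, binding: float
) -> tuple[float, bool]:
    """Substrate uptake from the lysosomal binding/uptake assay.

    In the assay, lysosomes incubated with substrate plus protease
    inhibitors retain bound *and* translocated substrate (association),
    while lysosomes without inhibitors retain only membrane-bound
    substrate (binding); uptake is their difference, in the same
    densitometric units.  A negative difference — noise dominating a
    near-zero uptake — is returned but flagged.

    Returns ``(uptake, negative_flag)``.
    """
    if association < 0 or binding < 0:
        raise ValueError("densitometric quantities must be nonnegative")
    uptake = association - binding
    flagged = uptake < 0
    if flagged:
        logger.warning(
            "uptake_from_association_binding: negative uptake %.4g (binding exceeds "
            "association; likely noise)", uptake,
        )
    return uptake, flagged
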