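"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed
(NumPy ``default_rng``, i.e. PCG64), returns the data together with a
ground-truth table, and emulates one of the study designs:

* a proteome with planted KFERQ-like motifs of known class and
  position, on a motif-free background;
* CMA-network expression tables for a knockout design (one gene driven
  to zero/undetected) or a stressor design (coordinated up-shift of
  the positive network elements, as under hypoxia);
* multi-run ion-abundance tables with known per-run protein factors,
  lognormal (log2-normal) noise and missingness constrained to keep
  each protein's run graph connected;
* qPCR Ct tables with known fold changes.

Noise is multiplicative (normal in log2) for abundances and
expression, and additive in cycles for Ct values, matching the
error structure of both assay types.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionTable, ProteinRecord
from .motifs import (
    HYDROPHOBIC,
    NEGATIVE,
    PHOSPHO_ACCEPTOR,
    POSITIVE,
    MotifClass,
    classify_pentapeptide,
    scan_protein,
)
from .score import CmaNetwork, CmaNetworkElement, assign_weights

logger = logging.getLogger("cmakit")

__all__ = [
    "example_network",
    "generate_proteome",
    "generate_network_expression",
    "generate_ion_abundances",
    "generate_qpcr_table",
]

_ALPHABET = sorted("ACDEFGHIKLMNPQRSTVWY")
#: Glycine flank: belongs to no residue-chemistry class, so padding a
#: planted motif with G prevents flanking windows from becoming motifs.
_NEUTRAL = "G"
_PAD = 4


def example_network() -> CmaNetwork:
    """A small weighted CMA network modelled on the salmonid situation.

    Salmonid genome duplication leaves many CMA genes as paralog pairs;
    notably two lamp2 genes (chromosomes 14 and 31) each encoding a
    LAMP2A splice variant.  Effectors and positive modulators carry
    direction +1, negative modulators -1.
    """
    rows = [
        ("lamp2a_c31", "effector", +1, "lamp2a"),
        ("lamp2a_c14", "effector", +1, "lamp2a"),
        ("hspa8a", "effector", +1, "hspa8"),
        ("hspa8b", "effector", +1, "hspa8"),
        ("gfap", "positive_modulator", +1, "gfap"),
        ("nfe2l2", "positive_modulator", +1, "nfe2l2"),
        ("rac1", "positive_modulator", +1, "rac1"),
        ("akt1a", "negative_modulator", -1, "akt1"),
        ("akt1b", "negative_modulator", -1, "akt1"),
        ("mtor", "negative_modulator", -1, "mtor"),
        ("plin2", "negative_modulator", -1, "plin2"),
    ]
    net = CmaNetwork(
        [
            CmaNetworkElement(
                gene_id=g, functional_group=grp, direction=d, paralog_family=fam
            )
            for g, grp, d, fam in rows
        ]
    )
    return assign_weights(net)


def _motif_free_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence guaranteed to contain no KFERQ-like window.

    Draws from the full alphabet, then neutralises any motif window by
    replacing its anchor residues (Q or K at the window ends) with
    glycine; removing an anchor can never create a new motif, so the
    loop terminates.
    """
    seq = list(rng.choice(_ALPHABET, size=length))
    while True:
        hits = scan_protein(ProteinRecord(id="tmp", sequence="".join(seq)))
        if not hits:
            return "".join(seq)
        for hit in hits:
            for pos in (hit.start, hit.start + 4):
                if seq[pos] in ("Q", "K"):
                    seq[pos] = _NEUTRAL


def _random_motif(rng: np.random.Generator, cls: MotifClass) -> str:
    """Random pentapeptide whose class set is exactly ``{cls}``."""
    hydro, pos, neg, pho = map(sorted, (HYDROPHOBIC, POSITIVE, NEGATIVE, PHOSPHO_ACCEPTOR))
    while True:
        anchor_first = bool(rng.integers(2))
        if cls is MotifClass.ACETYL_GENERATED:
            anchor = "K"
        else:
            anchor = "Q"
        if cls is MotifClass.PHOSPHO_GENERATED:
            special = [str(rng.choice(pho))]
        else:
            special = [str(rng.choice(neg))]
        n_h = int(rng.integers(1, 3))
        body = special + list(rng.choice(hydro, size=n_h)) + list(
            rng.choice(pos, size=3 - n_h)
        )
        rng.shuffle(body)
        pent = anchor + "".join(body) if anchor_first else "".join(body) + anchor
        if classify_pentapeptide(pent) == frozenset({cls}):
            return pent


def generate_proteome(
    n_proteins: int = 50,
    length_range: tuple[int, int] = (80, 300),
    planted: Mapping[MotifClass, int] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Synthetic proteome with known per-protein motif-class counts.

    ``planted`` gives the total number of motifs per class to plant
    across the proteome (default: 10 canonical, 10 phospho-generated,
    10 acetyl-generated).  Backgrounds are motif-free by construction
    and each planted pentapeptide is padded with neutral glycine
    flanks, so a scan recovers exactly the planted hits.

    Returns the records and a truth table with one row per planted
    motif (protein_id, start, motif_class, pentapeptide).
    """
    if planted is None:
        planted = {cls: 10 for cls in MotifClass}
    lo, hi = length_range
    if lo < 5:
        raise ValueError("minimum protein length is 5")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    sequences = [list(_motif_free_sequence(rng, int(L))) for L in lengths]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_proteins)]

    jobs = [
        cls for cls in MotifClass for _ in range(int(planted.get(cls, 0)))
    ]
    truth_rows = []
    span = 5 + 2 * _PAD
    for cls in jobs:
        pent = _random_motif(rng, cls)
        for _attempt in range(10_000):
            p = int(rng.integers(0, n_proteins))
            if len(sequences[p]) < span:
                continue
            start = int(rng.integers(_PAD, len(sequences[p]) - 5 - _PAD + 1))
            window = (start - _PAD, start + 5 + _PAD)
            if any(window[0] < e and s < window[1] for s, e in occupied[p]):
                continue
            seg = _NEUTRAL * _PAD + pent + _NEUTRAL * _PAD
            sequences[p][window[0] : window[1]] = list(seg)
            occupied[p].append(window)
            truth_rows.append(
                {
                    "protein_id": f"prot{p + 1:04d}",
                    "start": start,
                    "motif_class": cls.value,
                    "pentapeptide": pent,
                }
            )
            break
        else:
            raise ValueError(
                "infeasible planting: no room left for a motif "
                f"({n_proteins} proteins of length {length_range})"
            )

    records = [
        ProteinRecord(
            id=f"prot{i + 1:04d}",
            sequence="".join(seq),
            description="synthetic",
        )
        for i, seq in enumerate(sequences)
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "start", "motif_class", "pentapeptide"]
    ).sort_values(["protein_id", "start"], ignore_index=True)
    logger.info(
        "generate_proteome: %d proteins, %d planted motifs (seed %d)",
        n_proteins, len(truth), seed,
    )
    return records, truth


def generate_network_expression(
    network: CmaNetwork | None = None,
    design: Mapping[str, object] | None = None,
    n_per_group: int = 7,
    noise_sd_log2: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionTable, dict]:
    """Two-group CMA-network expression table with a known effect.

    ``design`` selects the perturbation:

    * ``{"kind": "knockout", "gene_id": g}`` — the target transcript is
      undetectable (0) in the perturbed group, as after a CRISPR
      deletion;
    * ``{"kind": "stressor", "fold": f}`` — every positive-direction
      network element is multiplied by ``f`` in the perturbed group,
      emulating the coordinated induction seen under hypoxia
      (default fold 2).

    Controls sit at baseline 1 with log2-normal noise of SD
    ``noise_sd_log2``.  Sample ids are ``control_i`` / ``treated_i``.
    The truth records the design and the expected sign of the
    (treated − control) score difference.
    """
    if network is None:
        network = example_network()
    if design is None:
        design = {"kind": "stressor", "fold": 2.0}
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    rng = np.random.default_rng(seed)
    genes = network.gene_ids
    kind = design["kind"]

    samples = [f"control_{i + 1}" for i in range(n_per_group)] + [
        f"treated_{i + 1}" for i in range(n_per_group)
    ]
    noise = rng.normal(0.0, noise_sd_log2, size=(2 * n_per_group, len(genes)))
    values = pd.DataFrame(2.0 ** noise, index=samples, columns=genes)

    treated = values.index.str.startswith("treated")
    if kind == "knockout":
        gene = str(design["gene_id"])
        if gene not in genes:
            raise ValueError(f"knockout gene {gene!r} is not in the network")
        values.loc[treated, gene] = 0.0
        expected_sign = -int(network[gene].direction)
        truth = {"kind": "knockout", "gene_id": gene, "expected_sign": expected_sign}
    elif kind == "stressor":
        fold = float(design.get("fold", 2.0))
        if fold <= 0:
            raise ValueError("stressor fold must be positive")
        targets = [g for g in genes if network[g].direction == +1]
        values.loc[treated, targets] *= fold
        expected_sign = int(np.sign(np.log2(fold))) if fold != 1.0 else 0
        truth = {
            "kind": "stressor",
            "fold": fold,
            "targets": targets,
            "expected_sign": expected_sign,
        }
    else:
        raise ValueError(f"unknown design kind {kind!r}")

    truth["control_samples"] = [s for s in samples if s.startswith("control")]
    truth["treated_samples"] = [s for s in samples if s.startswith("treated")]
    logger.info(
        "generate_network_expression: %s design, %d+%d samples (seed %d)",
        kind, n_per_group, n_per_group, seed,
    )
    return ExpressionTable(values), truth


def _repair_connectivity(
    observed: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unmask the fewest random cells so that (i) every ion is observed
    somewhere and (ii) the run graph (runs linked by a shared ion) is
    connected."""
    n_ions, n_runs = observed.shape
    for i in range(n_ions):
        if not observed[i].any():
            observed[i, rng.integers(n_runs)] = True

    def components() -> list[set[int]]:
        comp: list[set[int]] = []
        assigned = {}
        parent = list(range(n_runs))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n_ions):
            runs = np.flatnonzero(observed[i])
            for a, b in zip(runs, runs[1:]):
                ra, rb = find(int(a)), find(int(b))
                if ra != rb:
                    parent[ra] = rb
        for r in range(n_runs):
            root = find(r)
            assigned.setdefault(root, set()).add(r)
        return list(assigned.values())

    comps = components()
    while len(comps) > 1:
        # bridge two components through a random ion
        ion = int(rng.integers(n_ions))
        r1 = int(rng.choice(sorted(comps[0])))
        r2 = int(rng.choice(sorted(comps[1])))
        observed[ion, r1] = True
        observed[ion, r2] = True
        comps = components()
    return observed


def generate_ion_abundances(
    n_proteins: int = 10,
    runs: Sequence[str] | int = 6,
    true_run_factors: pd.DataFrame | None = None,
    ions_per_protein: int = 5,
    noise_sd_log2: float = 0.0,
    missing_rate: float = 0.0,
    factor_sd_log2: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Long-format ion table with known per-run protein factors.

    Each ion's abundance is ``base_i × factor[p, r] × 2**ε`` with
    ε ~ Normal(0, ``noise_sd_log2``); ion bases are log2-normal around
    2^20 (≈10^6, a typical LC-MS intensity scale).  ``true_run_factors``
    (proteins × runs) may be supplied; otherwise factors are drawn
    log2-normally with SD ``factor_sd_log2``.  Cells are removed at
    ``missing_rate`` subject to every ion staying observed and every
    protein's run graph staying connected.

    Returns the long table (missing cells omitted) and a truth dict
    with the factor table and ion bases.
    """
    if ions_per_protein < 1:
        raise ValueError("ions_per_protein must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if isinstance(runs, int):
        run_ids = [f"run{r + 1}" for r in range(runs)]
    else:
        run_ids = list(runs)
    protein_ids = [f"prot{p + 1:04d}" for p in range(n_proteins)]

    if true_run_factors is None:
        factors = pd.DataFrame(
            2.0 ** rng.normal(0.0, factor_sd_log2, size=(n_proteins, len(run_ids))),
            index=protein_ids,
            columns=run_ids,
        )
    else:
        factors = true_run_factors.copy()
        factors.index = protein_ids[: len(factors)]
        factors.columns = run_ids

    rows = []
    bases: dict[str, float] = {}
    for pid in protein_ids:
        base = 2.0 ** rng.normal(20.0, 2.0, size=ions_per_protein)
        eps = rng.normal(0.0, noise_sd_log2, size=(ions_per_protein, len(run_ids)))
        observed = rng.random((ions_per_protein, len(run_ids))) >= missing_rate
        observed = _repair_connectivity(observed, rng)
        for i in range(ions_per_protein):
            ion_id = f"{pid}_ion{i + 1}"
            bases[ion_id] = float(base[i])
            for j, rid in enumerate(run_ids):
                if not observed[i, j]:
                    continue
                value = base[i] * factors.loc[pid, rid] * 2.0 ** eps[i, j]
                rows.append(
                    {
                        "protein_id": pid,
                        "ion_id": ion_id,
                        "run_id": rid,
                        "abundance": float(value),
                    }
                )
    table = pd.DataFrame(rows, columns=["protein_id", "ion_id", "run_id", "abundance"])
    truth = {"factors": factors, "ion_bases": bases}
    logger.info(
        "generate_ion_abundances: %d proteins x %d runs x %d ions, noise %.2f, "
        "missing %.2f (seed %d)", n_proteins, len(run_ids), ions_per_protein,
        noise_sd_log2, missing_rate, seed,
    )
    return table, truth


def generate_qpcr_table(
    groups: Mapping[str, int],
    true_fold_changes: Mapping[str, float],
    ct_baseline: float = 20.0,
    noise_sd_cycles: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Ct table for a target gene with known fold changes per group.

    ``groups`` maps group name to sample count; ``true_fold_changes``
    maps group name to the target's true expression fold relative to
    the reference gene.  Target Ct is
    ``baseline − log2(fold) + Normal(0, noise_sd_cycles)``; the
    reference gene is held at baseline.
    """
    for g, fold in true_fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold for group {g!r} must be positive")
    if set(groups) != set(true_fold_changes):
        raise ValueError("groups and true_fold_changes must name the same groups")
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        fold = true_fold_changes[group]
        for i in range(groups[group]):
            sid = f"{group}_{i + 1}"
            ct_t = ct_baseline - np.log2(fold) + rng.normal(0.0, noise_sd_cycles)
            rows.append(
                {"sample_id": sid, "group": group, "gene_id": "target", "ct": float(ct_t)}
            )
            rows.append(
                {"sample_id": sid, "group": group, "gene_id": "reference",
                 "ct": float(ct_baseline)}
            )
    table = pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "ct"])
    truth = {"fold_changes": dict(true_fold_changes), "ct_baseline": ct_baseline}
    logger.info(
        "generate_qpcr_table: %d samples in %d groups (seed %d)",
        sum(groups.values()), len(groups), seed,
    )
    return table, truth
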