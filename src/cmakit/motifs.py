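"""KFERQ-like motif detection and classification.

Chaperone-mediated autophagy (CMA) substrates carry a pentapeptide
targeting signal recognised by HSC70.  The signal is built from four
residue chemistries around a glutamine anchor:

* hydrophobic residues (F, I, L, V),
* positively charged residues (K, R),
* negatively charged residues (D, E),
* the anchor Q, which may sit at either end of the pentapeptide.

A *canonical* motif has a Q anchor and a four-residue body composed of
1-2 hydrophobic, 1-2 positive and exactly one negative residue.  Two
further classes become functional only after post-translational
modification: *phosphorylation-generated* motifs replace the acidic
residue with a phospho-acceptor (S, T or Y), and *acetylation-generated*
motifs carry a lysine in the anchor position whose acetylated form
mimics glutamine.

The rule table lives in :func:`classify_pentapeptide`; the scanner
evaluates every window of width five and reports all satisfied classes,
because a single window can be read with the anchor at either end.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import AMINO_ACIDS, ProteinRecord

__all__ = [
    "MotifClass",
    "MotifHit",
    "classify_pentapeptide",
    "scan_protein",
    "scan_proteins",
    "summarize_motifs",
    "hits_to_frame",
    "HYDROPHOBIC",
    "POSITIVE",
    "NEGATIVE",
    "PHOSPHO_ACCEPTOR",
]

WINDOW = 5

# Residue chemistry classes of the motif rule table.  C and W are *not*
# counted as hydrophobic and N does not substitute for Q; both choices
# are configurable via the ``hydrophobic=``/``anchors=`` arguments.
HYDROPHOBIC = frozenset("FILV")
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")
PHOSPHO_ACCEPTOR = frozenset("STY")


class MotifClass(enum.Enum):
    """Closed enumeration of KFERQ-like motif classes."""

    CANONICAL = "canonical"
    PHOSPHO_GENERATED = "phospho_generated"
    ACETYL_GENERATED = "acetyl_generated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MotifHit:
    """One pentapeptide window satisfying at least one motif class.

    ``start`` is a 0-based offset; the window is ``[start, start + 5)``
    and ``pentapeptide`` is the literal sequence slice.
    """

    protein_id: str
    start: int
    pentapeptide: str
    classes: frozenset[MotifClass]

    def __post_init__(self) -> None:
        if len(self.pentapeptide) != WINDOW:
            raise ValueError("pentapeptide must have length 5")
        if not self.classes:
            raise ValueError("a MotifHit must carry at least one class")


def _body_composition_ok(
    body: Sequence[str],
    *,
    negative_source: frozenset[str],
    hydrophobic: frozenset[str],
    positive: frozenset[str],
) -> bool:
    """Check the 4-residue body: 1-2 hydrophobic, 1-2 positive, exactly
    one residue from ``negative_source``, and nothing outside these
    three classes."""
    n_hydro = n_pos = n_neg = 0
    for aa in body:
        if aa in hydrophobic:
            n_hydro += 1
        elif aa in positive:
            n_pos += 1
        elif aa in negative_source:
            n_neg += 1
        else:
            return False
    return 1 <= n_hydro <= 2 and 1 <= n_pos <= 2 and n_neg == 1


def classify_pentapeptide(
    pent: str,
    *,
    hydrophobic: frozenset[str] = HYDROPHOBIC,
    positive: frozenset[str] = POSITIVE,
    negative: frozenset[str] = NEGATIVE,
    phospho: frozenset[str] = PHOSPHO_ACCEPTOR,
) -> frozenset[MotifClass]:
    """Classify a 5-residue window against the KFERQ-like rule table.

    The anchor may sit at either end of the window (position 0 or 4).
    For each anchor reading, the remaining four residues form the body:

    * CANONICAL: anchor is Q; body has 1-2 hydrophobic, 1-2 positive
      and exactly one of D/E, nothing else.
    * PHOSPHO_GENERATED: anchor is Q; body has no D/E but exactly one
      phospho-acceptor (S/T/Y) supplying the missing negative charge,
      plus 1-2 hydrophobic and 1-2 positive, nothing else.
    * ACETYL_GENERATED: anchor is K (acetyl-lysine mimics Q); body
      satisfies the canonical composition.  The anchor K does not count
      toward the body's positive quota.

    All satisfied classes over both anchor readings are returned; an
    empty set means the window is not KFERQ-like.  A Q in a body
    position belongs to no chemistry class and therefore invalidates
    that reading.  Windows containing X (or any residue outside the
    20-letter alphabet) raise ``ValueError``.
    """
    if len(pent) != WINDOW:
        raise ValueError(f"pentapeptide must have length 5, got {len(pent)}")
    for aa in pent:
        if aa not in AMINO_ACIDS:
            raise ValueError(f"invalid amino acid {aa!r} in pentapeptide {pent!r}")

    classes: set[MotifClass] = set()
    for anchor_idx in (0, WINDOW - 1):
        anchor = pent[anchor_idx]
        body = pent[:anchor_idx] + pent[anchor_idx + 1 :]
        if anchor == "Q":
            if _body_composition_ok(
                body, negative_source=negative, hydrophobic=hydrophobic, positive=positive
            ):
                classes.add(MotifClass.CANONICAL)
            if _body_composition_ok(
                body, negative_source=phospho, hydrophobic=hydrophobic, positive=positive
            ):
                classes.add(MotifClass.PHOSPHO_GENERATED)
        elif anchor == "K":
            if _body_composition_ok(
                body, negative_source=negative, hydrophobic=hydrophobic, positive=positive
            ):
                classes.add(MotifClass.ACETYL_GENERATED)
    return frozenset(classes)


def scan_protein(record: ProteinRecord) -> list[MotifHit]:
    """Scan every width-5 window of a protein; return hits ordered by start.

    Overlapping hits are all reported.  Windows containing an ambiguity
    code (X) are skipped rather than raising, so records validated with
    ``allow_ambiguous=True`` can still be scanned.
    """
    seq = record.sequence
    hits: list[MotifHit] = []
    for start in range(len(seq) - WINDOW + 1):
        pent = seq[start : start + WINDOW]
        if "X" in pent:
            continue
        classes = classify_pentapeptide(pent)
        if classes:
            hits.append(MotifHit(record.id, start, pent, classes))
    return hits


def scan_proteins(records: Iterable[ProteinRecord]) -> list[MotifHit]:
    """Scan a collection of proteins, concatenating per-protein hits."""
    hits: list[MotifHit] = []
    for rec in records:
        hits.extend(scan_protein(rec))
    return hits


@dataclass
class MotifReport:
    """Per-protein class counts and per-set prevalence of each class.

    ``counts`` maps protein id -> Counter of MotifClass (number of hits
    carrying that class); ``set_proportions`` is a tidy table with one
    row per (set, class): ``n_with_motif`` proteins in the set having at
    least one hit of the class, ``n_total`` set size, and their ratio.
    """

    counts: dict[str, Counter] = field(default_factory=dict)
    set_proportions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def has_class(self, protein_id: str, cls: MotifClass) -> bool:
        return self.counts.get(protein_id, Counter())[cls] > 0


def summarize_motifs(
    records: Sequence[ProteinRecord],
    hits: Sequence[MotifHit],
    protein_sets: Mapping[str, Iterable[str]],
) -> MotifReport:
    """Summarise motif hits into per-protein counts and per-set proportions.

    A protein with several hits of one class still counts once toward
    that class's prevalence in a set (has-class semantics).
    """
    known_ids = {r.id for r in records}
    counts: dict[str, Counter] = {r.id: Counter() for r in records}
    for hit in hits:
        if hit.protein_id not in known_ids:
            raise ValueError(f"hit references unknown protein {hit.protein_id!r}")
        for cls in hit.classes:
            counts[hit.protein_id][cls] += 1

    rows = []
    for set_name, members in protein_sets.items():
        member_ids = list(members)
        if not member_ids:
            raise ValueError(f"empty set {set_name!r}")
        unknown = set(member_ids) - known_ids
        if unknown:
            raise ValueError(
                f"set {set_name!r} references unknown proteins: {sorted(unknown)[:5]}"
            )
        for cls in MotifClass:
            n_with = sum(1 for pid in member_ids if counts[pid][cls] > 0)
            rows.append(
                {
                    "set": set_name,
                    "motif_class": cls.value,
                    "n_with_motif": n_with,
                    "n_total": len(member_ids),
                    "proportion": n_with / len(member_ids),
                }
            )
    return MotifReport(counts=counts, set_proportions=pd.DataFrame(rows))


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Tabulate hits as (protein_id, start, pentapeptide, classes)."""
    return pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "start": h.start,
                "pentapeptide": h.pentapeptide,
                "classes": ";".join(sorted(c.value for c in h.classes)),
            }
            for h in hits
        ],
        columns=["protein_id", "start", "pentapeptide", "classes"],
    )
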