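"""Atlas of RNA-dependent proteins within an annotation-defined universe.

The atlas intersects a protein universe selected by GO-term matching (e.g.
mitosis-related terms) with two lines of RNA-linkage evidence: prior
knowledge (an RBP2GO-style flag aggregated from published RBP screens) and
the current screen's shift calls. A protein counts as RNA dependent if
either source supports it; precipitated proteins count as shifted. The
headline statistics are the RNA-dependent fraction of the universe and the
share of RNA-dependent proteins without any known RNA-binding domain
("unconventional" RBP candidates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable

import pandas as pd

from .compare import ScreenTable


@dataclass(frozen=True)
class AnnotationRecord:
    protein_id: str
    go_terms: frozenset[str]
    localization_labels: frozenset[str] = frozenset()
    rna_linked_prior: bool = False
    has_known_rbd: bool = False
    rbp2go_like_score: float = 0.0


@dataclass
class AtlasTable:
    universe: set[str]
    rna_dependent: set[str]
    from_prior: set[str]
    from_screen_only: set[str]
    per_structure: dict[str, dict[str, int]]
    fraction_rna_dependent: float  # percent of the universe
    fraction_without_rbd: float  # percent of rna_dependent
    unannotated_screen_proteins: set[str] = field(default_factory=set)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up decimal rounding (0.05 at one decimal rounds to 0.1)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: int, whole: int, decimals: int = 1) -> float:
    """Half-up rounded percentage; 0 for an empty denominator."""
    if whole == 0:
        return 0.0
    return round_half_up(100.0 * part / whole, decimals)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read the annotation TSV.

    Columns: ``protein_id``, ``go_terms`` (semicolon-separated),
    ``localization_labels`` (semicolon-separated, may be empty),
    ``rna_linked_prior`` (0/1), ``has_known_rbd`` (0/1),
    ``rbp2go_like_score`` (float).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str}, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AnnotationRecord(
                protein_id=row.protein_id,
                go_terms=frozenset(t for t in str(row.go_terms).split(";") if t),
                localization_labels=frozenset(
                    t for t in str(row.localization_labels).split(";") if t
                ),
                rna_linked_prior=bool(int(row.rna_linked_prior)),
                has_known_rbd=bool(int(row.has_known_rbd)),
                rbp2go_like_score=float(row.rbp2go_like_score),
            )
        )
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "go_terms": ";".join(sorted(r.go_terms)),
                "localization_labels": ";".join(sorted(r.localization_labels)),
                "rna_linked_prior": int(r.rna_linked_prior),
                "has_known_rbd": int(r.has_known_rbd),
                "rbp2go_like_score": r.rbp2go_like_score,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def build_atlas(
    annotations: Iterable[AnnotationRecord],
    screen: ScreenTable | None,
    go_term_filter: set[str],
) -> AtlasTable:
    """Build the atlas: universe by GO filter, RNA dependence by union of
    prior knowledge and screen shift calls.

    ``rna_dependent = (universe with prior RNA linkage) UNION (universe
    proteins shifted in the screen)``; the union deduplicates proteins
    supported by both sources. Screen proteins missing from the annotation
    table cannot enter the universe and are reported with a warning.
    """
    if not go_term_filter:
        raise ValueError("go_term_filter must be non-empty")
    by_id = {r.protein_id: r for r in annotations}
    universe = {
        pid for pid, r in by_id.items() if r.go_terms & go_term_filter
    }
    prior = {pid for pid in universe if by_id[pid].rna_linked_prior}
    screen_shifted: set[str] = set()
    unannotated: set[str] = set()
    if screen is not None:
        shifted = screen.shifted
        unannotated = {pid for pid in screen.calls if pid not in by_id}
        if unannotated:
            warnings.warn(
                f"{len(unannotated)} screen proteins missing from annotations",
                stacklevel=2,
            )
        screen_shifted = shifted & universe
    rna_dependent = prior | screen_shifted
    per_structure: dict[str, dict[str, int]] = {}
    for pid in universe:
        for label in by_id[pid].localization_labels:
            entry = per_structure.setdefault(label, {"universe": 0, "rna_dependent": 0})
            entry["universe"] += 1
            if pid in rna_dependent:
                entry["rna_dependent"] += 1
    n_no_rbd = sum(1 for pid in rna_dependent if not by_id[pid].has_known_rbd)
    return AtlasTable(
        universe=universe,
        rna_dependent=rna_dependent,
        from_prior=prior,
        from_screen_only=screen_shifted - prior,
        per_structure=per_structure,
        fraction_rna_dependent=percent(len(rna_dependent), len(universe)),
        fraction_without_rbd=percent(n_no_rbd, len(rna_dependent)),
        unannotated_screen_proteins=unannotated,
    )


def rbd_breakdown(
    atlas: AtlasTable, annotations: Iterable[AnnotationRecord]
) -> tuple[int, float]:
    """Count and percentage of atlas RNA-dependent proteins lacking any
    known RNA-binding domain."""
    by_id = {r.protein_id: r for r in annotations}
    n = sum(1 for pid in atlas.rna_dependent if not by_id[pid].has_known_rbd)
    return n, percent(n, len(atlas.rna_dependent))


def screen_overlap(
    current_detected: set[str], reference_detected: set[str]
) -> tuple[float, set[str]]:
    """Coverage of a reference screen by the current one.

    Returns (percentage of the reference also detected now, rounded half-up
    to the nearest integer; set of newly added proteins).
    """
    if not reference_detected:
        raise ValueError("reference set is empty")
    covered = current_detected & reference_detected
    coverage = round_half_up(100.0 * len(covered) / len(reference_detected), 0)
    return coverage, current_detected - reference_detected


def atlas_to_summary(atlas: AtlasTable) -> dict:
    return {
        "n_universe": len(atlas.universe),
        "n_rna_dependent": len(atlas.rna_dependent),
        "n_from_prior": len(atlas.from_prior),
        "n_from_screen_only": len(atlas.from_screen_only),
        "fraction_rna_dependent_pct": atlas.fraction_rna_dependent,
        "fraction_without_rbd_pct": atlas.fraction_without_rbd,
        "per_structure": atlas.per_structure,
    }
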