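"""Screen construction and differential comparison of two screens.

A "screen" is one complete gradient experiment (e.g. mitotic HeLa cells):
all proteins' shift calls plus each protein's total raw amount. Comparing
two screens - typically mitosis vs. interphase - asks which proteins shift
in both, in one, or in neither cell-cycle state, which shift in opposite
directions, and which are differentially expressed between the states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

from . import gaussfit, profiles as prof
from .shifts import ShiftCall, call_protein

ExpressionClass = Literal["higher_in_a", "higher_in_b", "equal"]
DEFAULT_FOLD_THRESHOLD = 2.0


@dataclass
class ScreenTable:
    """All shift calls of one screen plus per-protein total amounts."""

    screen_id: str
    calls: dict[str, ShiftCall]
    total_amount: dict[str, float]
    condition_missing: set[str] = field(default_factory=set)
    not_evaluable: set[str] = field(default_factory=set)

    @property
    def detected(self) -> set[str]:
        """Proteins with an evaluable shift call."""
        return {p for p, c in self.calls.items() if c.category != "not_evaluable"}

    @property
    def shifted(self) -> set[str]:
        return {p for p, c in self.calls.items() if c.shifted}


def build_screen(
    all_profiles: Iterable[prof.FractionProfile],
    screen_id: str,
    alpha: float = 0.05,
    complete_threshold: float = 0.75,
    min_replicates: int = 2,
    k_max: int = gaussfit.DEFAULT_K_MAX,
    test_positions: str = "control",
) -> ScreenTable:
    """Normalize, average, fit and call every protein of one screen.

    Proteins detected in only one condition are excluded from shift calling
    and listed in ``condition_missing``; proteins whose profiles cannot be
    normalized or averaged land in ``not_evaluable``.
    """
    all_profiles = list(all_profiles)
    totals = prof.total_amounts(all_profiles)
    means, failed = prof.collect_mean_profiles(all_profiles, min_replicates=min_replicates)

    by_protein: dict[str, dict[str, prof.MeanProfile]] = {}
    for (pid, cond), mp in means.items():
        by_protein.setdefault(pid, {})[cond] = mp

    calls: dict[str, ShiftCall] = {}
    condition_missing: set[str] = set()
    not_evaluable = {pid for (pid, _cond) in failed}
    for pid, conds in by_protein.items():
        if "control" not in conds or "rnase" not in conds:
            condition_missing.add(pid)
            continue
        ctrl, rnase = conds["control"], conds["rnase"]
        m_ctrl = gaussfit.fit(ctrl, k_max=k_max)
        m_rnase = gaussfit.fit(rnase, k_max=k_max)
        call = call_protein(
            m_ctrl, m_rnase,
            ctrl.replicate_values, rnase.replicate_values,
            alpha=alpha, complete_threshold=complete_threshold,
            test_positions=test_positions,
        )
        calls[pid] = call
        if call.category == "not_evaluable":
            not_evaluable.add(pid)
    return ScreenTable(
        screen_id=screen_id,
        calls=calls,
        total_amount=totals,
        condition_missing=condition_missing,
        not_evaluable=not_evaluable,
    )


@dataclass
class ComparisonReport:
    """Partition of the proteins detected in both screens by shift behavior
    plus expression classes; the four shift-behavior sets are disjoint and
    cover ``common_detected`` exactly."""

    screen_a: str
    screen_b: str
    common_detected: set[str]
    both_shifted: set[str]
    a_only_shift: set[str]
    b_only_shift: set[str]
    neither: set[str]
    opposite_direction: set[str]
    expression_class: dict[str, ExpressionClass]
    a_exclusive_detected: set[str]
    b_exclusive_detected: set[str]
    fold_threshold: float


def compare(
    screen_a: ScreenTable,
    screen_b: ScreenTable,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> ComparisonReport:
    """Cross-tabulate two screens' shift calls and expression levels.

    A protein is "higher expressed" in one screen when its summed raw
    amount exceeds the other screen's by at least ``fold_threshold``.
    Opposite-direction proteins shift in both screens but with opposite
    net displacement signs (e.g. left in mitosis, right in interphase).
    """
    det_a, det_b = screen_a.detected, screen_b.detected
    common = det_a & det_b
    if not common:
        warnings.warn(
            f"screens {screen_a.screen_id} and {screen_b.screen_id} share no "
            "evaluable proteins", stacklevel=2,
        )
    shift_a = screen_a.shifted & common
    shift_b = screen_b.shifted & common
    both = shift_a & shift_b
    opposite = set()
    for pid in both:
        na = screen_a.calls[pid].net_distance
        nb = screen_b.calls[pid].net_distance
        if na * nb < 0:
            opposite.add(pid)
    expression: dict[str, ExpressionClass] = {}
    for pid in common:
        ta = screen_a.total_amount.get(pid, 0.0)
        tb = screen_b.total_amount.get(pid, 0.0)
        if tb > 0 and ta >= fold_threshold * tb:
            expression[pid] = "higher_in_a"
        elif ta > 0 and tb >= fold_threshold * ta:
            expression[pid] = "higher_in_b"
        else:
            expression[pid] = "equal"
    return ComparisonReport(
        screen_a=screen_a.screen_id,
        screen_b=screen_b.screen_id,
        common_detected=common,
        both_shifted=both,
        a_only_shift=shift_a - shift_b,
        b_only_shift=shift_b - shift_a,
        neither=common - shift_a - shift_b,
        opposite_direction=opposite,
        expression_class=expression,
        a_exclusive_detected=det_a - det_b,
        b_exclusive_detected=det_b - det_a,
        fold_threshold=fold_threshold,
    )


def category_breakdown(
    report: ComparisonReport,
    screen_a: ScreenTable,
    screen_b: ScreenTable,
) -> dict[str, dict[str, int]]:
    """Per-screen counts of screen-specific shifters split by direction.

    For each screen: proteins detected in both screens but shifting only
    there ("differential", split into left/right/precipitated), proteins
    shifting among those detected in that screen only, and the specific
    total. The direction subcounts always sum to the differential total.
    """
    out: dict[str, dict[str, int]] = {}
    for label, table, only in (
        ("a", screen_a, report.a_only_shift),
        ("b", screen_b, report.b_only_shift),
    ):
        by_cat = {"left": 0, "right": 0, "precipitated": 0}
        for pid in only:
            by_cat[table.calls[pid].category] += 1
        exclusive = (
            report.a_exclusive_detected if label == "a" else report.b_exclusive_detected
        )
        exclusive_shifted = len(table.shifted & exclusive)
        differential_total = sum(by_cat.values())
        assert differential_total == len(only)  # arithmetic closure
        out[table.screen_id] = {
            "differential_left": by_cat["left"],
            "differential_right": by_cat["right"],
            "differential_precipitated": by_cat["precipitated"],
            "differential_total": differential_total,
            "exclusive_detected_shifted": exclusive_shifted,
            "specific_total": differential_total + exclusive_shifted,
        }
    return out


def report_to_summary(report: ComparisonReport) -> dict:
    """JSON-ready count summary of a comparison."""
    expr = report.expression_class
    return {
        "screen_a": report.screen_a,
        "screen_b": report.screen_b,
        "n_common_detected": len(report.common_detected),
        "n_both_shifted": len(report.both_shifted),
        "n_a_only_shift": len(report.a_only_shift),
        "n_b_only_shift": len(report.b_only_shift),
        "n_neither": len(report.neither),
        "n_opposite_direction": len(report.opposite_direction),
        "n_higher_in_a": sum(1 for v in expr.values() if v == "higher_in_a"),
        "n_higher_in_b": sum(1 for v in expr.values() if v == "higher_in_b"),
        "n_equal_expression": sum(1 for v in expr.values() if v == "equal"),
        "n_a_exclusive_detected": len(report.a_exclusive_detected),
        "n_b_exclusive_detected": len(report.b_exclusive_detected),
        "fold_threshold": report.fold_threshold,
    }
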