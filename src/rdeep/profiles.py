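"""Fraction-profile containers, I/O, normalization and replicate averaging.

A gradient run yields, per protein and replicate, 25 quantities (one per
sucrose fraction, numbered 1..25 from top to bottom). Profiles are
normalized per protein so that the 25 values sum to 100, which makes
control and RNase gradients directly comparable regardless of total signal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_FRACTIONS = 25
FRACTION_COLUMNS = [f"F{i:02d}" for i in range(1, N_FRACTIONS + 1)]
NORM_TOTAL = 100.0

CONDITIONS = ("control", "rnase")


class ProfileError(ValueError):
    """Malformed fraction profile or matrix."""


class NotEvaluableError(ProfileError):
    """Profile cannot enter downstream analysis (e.g. all-zero signal)."""


@dataclass(frozen=True)
class FractionProfile:
    """One protein's quantification across the 25 fractions.

    Parameters
    ----------
    protein_id:
        Identifier, unique within one matrix file.
    condition:
        ``"control"`` or ``"rnase"``.
    replicate:
        1-based replicate number.
    values:
        25 finite, non-negative quantities for fractions 1..25.
    """

    protein_id: str
    condition: str
    replicate: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ProfileError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.replicate < 1:
            raise ProfileError("replicate numbers are 1-based")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (N_FRACTIONS,):
            raise ProfileError(
                f"expected exactly {N_FRACTIONS} fraction values, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ProfileError(f"{self.protein_id}: non-finite fraction value")
        if np.any(vals < 0):
            raise ProfileError(f"{self.protein_id}: negative fraction value")
        object.__setattr__(self, "values", vals)

    @property
    def total(self) -> float:
        """Summed raw amount over all fractions."""
        return float(self.values.sum())

    @property
    def is_normalized(self) -> bool:
        return abs(self.total - NORM_TOTAL) <= 1e-6


@dataclass(frozen=True)
class MeanProfile:
    """Fraction-wise mean of the normalized replicate profiles of one protein.

    ``replicate_values`` retains the individual normalized replicates
    (shape ``(n_replicates, 25)``); the per-fraction values at integer
    positions are what the shift significance test consumes.
    """

    protein_id: str
    condition: str
    values: np.ndarray = field(repr=False)
    replicate_values: np.ndarray = field(repr=False)

    @property
    def n_replicates(self) -> int:
        return self.replicate_values.shape[0]


def normalize(profile: FractionProfile) -> FractionProfile:
    """Scale a profile so its 25 values sum to exactly 100.

    Each protein is self-normalized: the scaling factor is per profile, so
    the normalized values describe the distribution of the protein across
    the gradient, not its abundance.

    Raises
    ------
    NotEvaluableError
        If the profile is all-zero (no signal to distribute); the profile
        is flagged not-evaluable instead of being divided by zero.
    """
    total = profile.values.sum()
    if total <= 0:
        raise NotEvaluableError(
            f"{profile.protein_id} ({profile.condition}, rep {profile.replicate}): "
            "all-zero profile is not evaluable"
        )
    return replace(profile, values=profile.values * (NORM_TOTAL / total))


def mean_profile(
    profiles: Sequence[FractionProfile], min_replicates: int = 2
) -> MeanProfile:
    """Average the normalized replicates of one protein/condition.

    Raises
    ------
    ProfileError
        If the profiles mix protein ids or conditions.
    NotEvaluableError
        If fewer than ``min_replicates`` replicates are evaluable.
    """
    if not profiles:
        raise ProfileError("no profiles given")
    pid = profiles[0].protein_id
    cond = profiles[0].condition
    for p in profiles:
        if p.protein_id != pid or p.condition != cond:
            raise ProfileError(
                f"mixed profiles: expected {pid}/{cond}, got {p.protein_id}/{p.condition}"
            )
    normalized = []
    for p in profiles:
        try:
            normalized.append(normalize(p) if not p.is_normalized else p)
        except NotEvaluableError:
            continue
    if len(normalized) < min_replicates:
        raise NotEvaluableError(
            f"{pid}/{cond}: {len(normalized)} evaluable replicates "
            f"(minimum {min_replicates})"
        )
    reps = np.vstack([p.values for p in normalized])
    return MeanProfile(
        protein_id=pid, condition=cond, values=reps.mean(axis=0), replicate_values=reps
    )


def read_matrix(
    path: str | Path | io.TextIOBase, condition: str, replicate: int
) -> list[FractionProfile]:
    """Read one fraction matrix (TSV: ``protein_id`` + F01..F25) as profiles.

    One file holds one condition x replicate. Duplicate protein ids, a wrong
    column count, and negative or non-numeric values are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    value_cols = list(df.columns[1:])
    if len(value_cols) != N_FRACTIONS:
        raise ProfileError(
            f"expected {N_FRACTIONS} value columns after the id column, "
            f"found {len(value_cols)}"
        )
    ids = df.iloc[:, 0]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ProfileError(f"duplicate protein ids in matrix: {sorted(set(dup))}")
    values = df[value_cols].to_numpy(dtype=float)  # raises on non-numeric
    return [
        FractionProfile(protein_id=pid, condition=condition, replicate=replicate, values=row)
        for pid, row in zip(ids, values)
    ]


def write_matrix(profiles: Iterable[FractionProfile], path: str | Path) -> None:
    """Write profiles of one condition x replicate as a TSV matrix."""
    profiles = list(profiles)
    df = pd.DataFrame(
        np.vstack([p.values for p in profiles]),
        index=pd.Index([p.protein_id for p in profiles], name="protein_id"),
        columns=FRACTION_COLUMNS,
    )
    df.to_csv(path, sep="\t")


def collect_mean_profiles(
    profiles: Iterable[FractionProfile], min_replicates: int = 2
) -> tuple[dict[tuple[str, str], MeanProfile], dict[tuple[str, str], str]]:
    """Group profiles by (protein, condition) and average replicates.

    Returns the mean profiles plus a map of (protein, condition) ->
    reason string for entries that are not evaluable (all-zero signal or
    too few replicates). Proteins missing in one condition entirely are
    left to the caller (the shift caller reports them as condition-missing).
    """
    grouped: dict[tuple[str, str], list[FractionProfile]] = {}
    for p in profiles:
        grouped.setdefault((p.protein_id, p.condition), []).append(p)
    means: dict[tuple[str, str], MeanProfile] = {}
    failed: dict[tuple[str, str], str] = {}
    for key, group in grouped.items():
        try:
            means[key] = mean_profile(group, min_replicates=min_replicates)
        except NotEvaluableError as exc:
            failed[key] = str(exc)
    return means, failed


def total_amounts(profiles: Iterable[FractionProfile]) -> dict[str, float]:
    """Summed raw (pre-normalization) amount per protein over all
    fractions, conditions and replicates; used for expression comparison."""
    totals: dict[str, float] = {}
    for p in profiles:
        totals[p.protein_id] = totals.get(p.protein_id, 0.0) + p.total
    return totals
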