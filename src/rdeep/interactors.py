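"""IP-MS interactor screen: detection filter, imputation, ratio tests.

Input is a table of log2 iBAQ-like intensities over three conditions -
IgG control IP, bait IP, and bait IP after RNase treatment - each in >= 2
replicates, with missing values where a protein was not quantified.
Processing mirrors standard label-free IP-MS practice: keep proteins
detected in at least 70% of samples, impute the remaining gaps per sample
from a Gaussian centered at the sample median, form per-replicate log2
ratios, test them against zero, and control the FDR across proteins with
Benjamini-Hochberg. An interactor needs at least a two-fold bait/IgG
enrichment at adjusted p < 0.05; an RNase-sensitive interactor additionally
needs a two-fold drop upon RNase treatment at adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("igg", "bait", "bait_rnase")
DEFAULT_MIN_DETECTION = 0.70
DEFAULT_IMPUTE_SD_SCALE = 0.3
OutlierStrategy = Literal["clip", "winsorize", "none"]


class ImputationError(ValueError):
    """A sample has too few observed values to estimate its distribution."""


@dataclass
class InteractorCall:
    protein_id: str
    log2fc_enrichment: float  # mean of per-replicate bait - igg
    log2fc_sensitivity: float  # mean of per-replicate bait - bait_rnase
    replicate_enrichment: tuple[float, ...]
    replicate_sensitivity: tuple[float, ...]
    p_enrichment: float
    p_sensitivity: float
    adj_p_enrichment: float
    adj_p_sensitivity: float
    is_interactor: bool
    is_rnase_sensitive: bool


def _check_table(table: pd.DataFrame) -> None:
    if not isinstance(table.columns, pd.MultiIndex) or table.columns.nlevels != 2:
        raise ValueError(
            "expected MultiIndex columns (condition, replicate); "
            "see read_ip_table for the flat TSV layout"
        )
    conds = set(table.columns.get_level_values(0))
    missing = set(CONDITIONS) - conds
    if missing:
        raise ValueError(f"missing conditions: {sorted(missing)}")
    for cond in CONDITIONS:
        if len(table[cond].columns) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")


def read_ip_table(path, excluded_replicates: Sequence[tuple[str, int]] = ()) -> pd.DataFrame:
    """Read a wide TSV of log2 intensities: ``protein_id`` plus columns
    named ``<condition>_<replicate>`` (e.g. ``bait_1``); empty cells are
    missing. Replicates listed in ``excluded_replicates`` (condition,
    replicate) pairs are dropped before analysis."""
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    cols = []
    for name in df.columns:
        cond, _, rep = name.rpartition("_")
        cols.append((cond, int(rep)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["condition", "replicate"])
    for cond, rep in excluded_replicates:
        if (cond, rep) in df.columns:
            df = df.drop(columns=[(cond, rep)])
    _check_table(df)
    return df


def write_ip_table(table: pd.DataFrame, path) -> None:
    flat = table.copy()
    flat.columns = [f"{c}_{r}" for c, r in table.columns]
    flat.to_csv(path, sep="\t", index_label="protein_id")


def filter_detection(
    table: pd.DataFrame, min_frac: float = DEFAULT_MIN_DETECTION
) -> pd.DataFrame:
    """Keep proteins quantified in at least ``min_frac`` of all samples.

    The fraction is computed over every sample in the table (e.g. 3
    conditions x 3 replicates = 9 samples: 7/9 passes, 6/9 does not).
    """
    detected = table.notna().mean(axis=1)
    return table.loc[detected >= min_frac]


def impute(
    table: pd.DataFrame,
    seed: int,
    sd_scale: float = DEFAULT_IMPUTE_SD_SCALE,
    outlier_strategy: OutlierStrategy = "clip",
) -> pd.DataFrame:
    """Fill missing values per sample from N(sample median, sd_scale * sample SD).

    Outlier adjustment of the imputed draws is a strategy switch:
    ``clip`` pulls draws above the sample mean down to the sample mean
    (imputed values stand in for undetected, hence low-abundance, proteins),
    ``winsorize`` limits draws to the observed [5th, 95th] percentile range,
    ``none`` leaves them as drawn. Deterministic for a fixed seed.

    Raises
    ------
    ImputationError
        If any sample has fewer than 3 observed values.
    """
    _check_table(table)
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col in sorted(out.columns):
        values = out[col]
        observed = values.dropna()
        n_missing = int(values.isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 3:
            raise ImputationError(
                f"sample {col}: only {len(observed)} observed values, "
                "cannot impute"
            )
        draws = rng.normal(observed.median(), sd_scale * observed.std(ddof=1), n_missing)
        if outlier_strategy == "clip":
            draws = np.minimum(draws, observed.mean())
        elif outlier_strategy == "winsorize":
            lo, hi = np.percentile(observed, [5, 95])
            draws = np.clip(draws, lo, hi)
        elif outlier_strategy != "none":
            raise ValueError(f"unknown outlier strategy {outlier_strategy!r}")
        out.loc[values.isna(), col] = draws
    return out


def _paired_ratios(table: pd.DataFrame, num: str, den: str) -> pd.DataFrame:
    """Per-replicate log2 differences num - den over shared replicates."""
    reps = sorted(set(table[num].columns) & set(table[den].columns))
    if len(reps) < 2:
        raise ValueError(f"fewer than 2 shared replicates between {num} and {den}")
    return table[num][reps].to_numpy() - table[den][reps].to_numpy()


def call_interactors(
    table: pd.DataFrame,
    fold: float = 2.0,
    alpha: float = 0.05,
) -> list[InteractorCall]:
    """Call bait interactors and their RNase sensitivity.

    Per protein, per-replicate log2 ratios bait/IgG and bait/(bait+RNase)
    are tested against zero with a two-sided one-sample t-test; p-values
    are Benjamini-Hochberg adjusted across proteins within each contrast.
    ``is_interactor`` requires mean enrichment >= log2(fold) and adjusted
    p < alpha; ``is_rnase_sensitive`` additionally requires the same on the
    RNase contrast.
    """
    _check_table(table)
    if table.isna().any().any():
        raise ValueError("table contains missing values; impute first")
    enr = _paired_ratios(table, "bait", "igg")
    sen = _paired_ratios(table, "bait", "bait_rnase")
    lfc_thresh = np.log2(fold)

    def _pvals(ratios: np.ndarray) -> np.ndarray:
        res = stats.ttest_1samp(ratios, 0.0, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
        # constant nonzero ratios have zero SE: deterministic difference
        sd = ratios.std(axis=1, ddof=1)
        mean = ratios.mean(axis=1)
        p[(sd == 0) & (mean != 0)] = 0.0
        p[(sd == 0) & (mean == 0)] = 1.0
        return p

    p_enr = _pvals(enr)
    p_sen = _pvals(sen)
    adj_enr = multipletests(p_enr, method="fdr_bh")[1]
    adj_sen = multipletests(p_sen, method="fdr_bh")[1]

    calls = []
    for i, pid in enumerate(table.index):
        mean_enr = float(enr[i].mean())
        mean_sen = float(sen[i].mean())
        is_int = bool(mean_enr >= lfc_thresh and adj_enr[i] < alpha)
        is_sens = bool(is_int and mean_sen >= lfc_thresh and adj_sen[i] < alpha)
        calls.append(
            InteractorCall(
                protein_id=str(pid),
                log2fc_enrichment=mean_enr,
                log2fc_sensitivity=mean_sen,
                replicate_enrichment=tuple(enr[i]),
                replicate_sensitivity=tuple(sen[i]),
                p_enrichment=float(p_enr[i]),
                p_sensitivity=float(p_sen[i]),
                adj_p_enrichment=float(adj_enr[i]),
                adj_p_sensitivity=float(adj_sen[i]),
                is_interactor=is_int,
                is_rnase_sensitive=is_sens,
            )
        )
    return calls


def intersect_comigrating(
    rnase_sensitive: set[str],
    screen,
    at_fraction: int,
    tolerance: int = 0,
) -> set[str]:
    """RNase-sensitive interactors that are RNA dependent in the gradient
    screen AND co-migrate with the bait.

    A protein co-migrates when its control model has a peak whose integer
    maximum lies within ``tolerance`` fractions of ``at_fraction`` (the
    bait's control maximum, e.g. 21 for AURKA).
    """
    out = set()
    for pid in rnase_sensitive:
        call = screen.calls.get(pid)
        if call is None or not call.shifted or call.control_model is None:
            continue
        if any(
            abs(p.integer_center - at_fraction) <= tolerance
            for p in call.control_model.peaks
        ):
            out.add(pid)
    return out


def calls_to_frame(calls: Iterable[InteractorCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "log2fc_enrichment": c.log2fc_enrichment,
                "log2fc_sensitivity": c.log2fc_sensitivity,
                "adj_p_enrichment": c.adj_p_enrichment,
                "adj_p_sensitivity": c.adj_p_sensitivity,
                "is_interactor": c.is_interactor,
                "is_rnase_sensitive": c.is_rnase_sensitive,
            }
            for c in calls
        ]
    )
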