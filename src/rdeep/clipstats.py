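"""Post-hoc summaries of iCLIP binding sites.

Works on already-called binding sites (7-nt windows with a PureCLIP-style
score, a gene assignment, a gene-type label and a transcript-region label):
rRNA read fraction, score-tail trimming, gene-type spectrum, per-region
site proportions and length-normalized enrichment, and a pentamer frequency
contrast between the strongest and weakest sites.

Sequences are handled in the RNA alphabet; T on input is mapped to U.
"""

from __future__ import annotations

import itertools
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

RNA_ALPHABET = "ACGU"
SITE_WIDTH = 7
PENTAMERS = ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=5)]
DEFAULT_TAIL_FRACTION = 0.05
DEFAULT_CONTRAST_QUANTILE = 0.20

SITE_COLUMNS = [
    "site_id", "chrom", "start", "end", "strand",
    "score", "gene_id", "gene_type", "region", "sequence",
]


def _clean_sequence(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if len(seq) != SITE_WIDTH:
        raise ValueError(f"site sequence must be {SITE_WIDTH} nt, got {seq!r}")
    if set(seq) - set(RNA_ALPHABET):
        raise ValueError(f"non-ACGU/T character in site sequence {seq!r}")
    return seq


def validate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a site table (sequences to RNA alphabet)."""
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    out = sites.copy()
    out["sequence"] = out["sequence"].map(_clean_sequence)
    if not np.isfinite(out["score"]).all():
        raise ValueError("non-finite site scores")
    return out


def read_sites(bed_path: str | Path, sidecar_path: str | Path) -> pd.DataFrame:
    """Read binding sites from BED6 (score column = PureCLIP-style score)
    plus a TSV sidecar keyed by ``site_id`` carrying ``gene_id``,
    ``gene_type``, ``region`` and ``sequence``."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "site_id", "score", "strand"],
    )
    side = pd.read_csv(sidecar_path, sep="\t")
    merged = bed.merge(side, on="site_id", how="inner", validate="one_to_one")
    return validate_sites(merged[SITE_COLUMNS])


def write_sites(sites: pd.DataFrame, bed_path: str | Path, sidecar_path: str | Path) -> None:
    sites[["chrom", "start", "end", "site_id", "score", "strand"]].to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    sites[["site_id", "gene_id", "gene_type", "region", "sequence"]].to_csv(
        sidecar_path, sep="\t", index=False
    )


def rrna_fraction(rrna_reads: int, total_reads: int) -> float:
    """Percentage of sequenced reads mapping to rRNA."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 <= rrna_reads <= total_reads:
        raise ValueError("need 0 <= rrna_reads <= total_reads")
    return 100.0 * rrna_reads / total_reads


def trim_score_tails(
    sites: pd.DataFrame, tail_frac: float = DEFAULT_TAIL_FRACTION
) -> pd.DataFrame:
    """Drop the lowest- and highest-scoring tails of the site table.

    Sites scoring strictly below the ``tail_frac`` quantile or strictly
    above the ``1 - tail_frac`` quantile are removed; sites tied with a
    boundary value are retained, so a table of all-equal scores is left
    untouched. With distinct scores this removes 2 * tail_frac of the sites
    (5% per tail by default). Tables too small to define the tails are
    returned unchanged with a warning.
    """
    n = len(sites)
    if n < 1.0 / tail_frac:
        warnings.warn(
            f"{n} sites is too few for {tail_frac:.0%} tails; no trimming",
            stacklevel=2,
        )
        return sites
    lo = sites["score"].quantile(tail_frac)
    hi = sites["score"].quantile(1.0 - tail_frac)
    return sites[(sites["score"] >= lo) & (sites["score"] <= hi)]


def gene_type_spectrum(sites: pd.DataFrame) -> pd.Series:
    """Site counts per gene-type label, descending."""
    return sites["gene_type"].value_counts()


def region_enrichment(
    sites: pd.DataFrame, region_lengths: dict[str, float]
) -> pd.DataFrame:
    """Per-region site counts, proportions and length-normalized enrichment.

    ``enrichment`` is the number of sites divided by the summed nucleotide
    length of the bound transcript regions of that type, i.e. sites per nt.
    """
    unknown = set(sites["region"]) - set(region_lengths)
    if unknown:
        raise ValueError(f"regions missing from the length table: {sorted(unknown)}")
    counts = sites["region"].value_counts()
    rows = []
    for region in region_lengths:
        length = region_lengths[region]
        if length <= 0:
            raise ValueError(f"region {region!r} has non-positive length")
        n = int(counts.get(region, 0))
        rows.append(
            {
                "region": region,
                "site_count": n,
                "summed_length": length,
                "proportion": n / len(sites) if len(sites) else 0.0,
                "enrichment": n / length,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def site_pentamers(sequence: str) -> list[str]:
    """The 3 overlapping pentamers of a 7-nt site."""
    return [sequence[i : i + 5] for i in range(SITE_WIDTH - 5 + 1)]


def _pentamer_freq(sequences: pd.Series) -> pd.Series:
    counts = pd.Series(0.0, index=PENTAMERS)
    for seq in sequences:
        for p in site_pentamers(seq):
            counts[p] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("empty group: no pentamers to count")
    return counts / total


def pentamer_contrast(
    sites: pd.DataFrame, quantile: float = DEFAULT_CONTRAST_QUANTILE
) -> pd.DataFrame:
    """Pentamer frequencies in the strongest vs. weakest sites.

    The strongest and weakest ``quantile`` of sites (by score; ties broken
    by table order, so the split is deterministic) each contribute the 3
    overlapping pentamers of every 7-nt site; frequencies are normalized
    within each group. Returns a 4^5-row table with columns
    ``freq_strong`` and ``freq_weak``.
    """
    sites = validate_sites(sites)
    n_group = int(round(quantile * len(sites)))
    if n_group < 1:
        raise ValueError("quantile selects an empty group")
    order = sites["score"].to_numpy().argsort(kind="stable")
    weak = sites.iloc[order[:n_group]]
    strong = sites.iloc[order[-n_group:]]
    return pd.DataFrame(
        {
            "freq_strong": _pentamer_freq(strong["sequence"]),
            "freq_weak": _pentamer_freq(weak["sequence"]),
        }
    )
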