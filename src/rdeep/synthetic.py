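"""Seedable generators for every input the pipeline consumes.

The generators emulate the statistical structure of a density-gradient
(R-DeeP) experiment and its companion assays, with known ground truth:

- gradient screens: per-protein multi-Gaussian profiles over 25 fractions,
  3 replicates by default, multiplicative log-normal fraction noise
  (MS intensity noise is heteroscedastic), and RNase-induced left/right/
  precipitation displacements of controlled magnitude. Precipitation is
  generated as an RNase peak in fractions 24-25, past the fraction-23 rule
  boundary.
- IP-MS tables: log-normal intensities around a per-protein base level,
  shifted by true enrichment/sensitivity folds, with Bernoulli missingness.
- iCLIP site tables: 7-nt sites with regions drawn proportionally to region
  length, gene types from a stated mix, log-normal scores, and an optional
  uridine bias injected into the weak-score sites.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi, sqrt, log
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import FractionProfile, N_FRACTIONS

X_GRID = np.arange(1, N_FRACTIONS + 1, dtype=float)

DEFAULT_NOISE_CV = 0.1
DEFAULT_N_REPLICATES = 3  # three gradient replicates per condition
MOVE_DISTANCE = 1.0  # a generating peak "moved" if its center changed by more
PRECIPITATION_FRACTION = 23


class SpecError(ValueError):
    """A generator spec violates its invariants; names the offending field."""


Peak = tuple[float, float, float]  # (center, amplitude, width)


def _check_peaks(peaks: Sequence[Peak], which: str, protein_id: str) -> None:
    if not peaks:
        raise SpecError(f"{protein_id}: {which} must contain at least one peak")
    for c, a, w in peaks:
        if not 1.0 <= c <= 25.0:
            raise SpecError(f"{protein_id}: {which} center {c} outside [1, 25]")
        if a <= 0:
            raise SpecError(f"{protein_id}: {which} amplitude {a} must be > 0")
        if not 0.5 <= w <= 5.0:
            raise SpecError(f"{protein_id}: {which} width {w} outside [0.5, 5]")


def _peak_area(p: Peak) -> float:
    return p[1] * p[2] * sqrt(2.0 * pi)


def _greedy_match(
    control: Sequence[Peak], rnase: Sequence[Peak]
) -> list[tuple[int, int]]:
    """Greedy nearest-center pairing (same rule the analysis applies)."""
    pairs = sorted(
        ((abs(r[0] - c[0]), ci, ri) for ci, c in enumerate(control)
         for ri, r in enumerate(rnase)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_c: set[int] = set()
    used_r: set[int] = set()
    out = []
    for _, ci, ri in pairs:
        if ci in used_c or ri in used_r:
            continue
        out.append((ci, ri))
        used_c.add(ci)
        used_r.add(ri)
    return out


@dataclass(frozen=True)
class ProfileSpec:
    """Generating model of one protein's control and RNase profiles.

    The true shifting coefficient and category are computed from the
    generating peaks, not supplied: a control peak counts as moved when its
    matched RNase peak center lies more than one fraction away, and the
    coefficient is the moved share of the total control peak area - exactly
    the quantity the analysis estimates.
    """

    protein_id: str
    peaks_control: tuple[Peak, ...]
    peaks_rnase: tuple[Peak, ...]
    total_amount_mitosis: float = 1000.0
    total_amount_interphase: float = 1000.0
    noise_cv: float = DEFAULT_NOISE_CV
    n_replicates: int = DEFAULT_N_REPLICATES
    shifting_coefficient_true: float = field(init=False)
    category_true: str = field(init=False)
    max_abs_distance_true: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks_control", tuple(map(tuple, self.peaks_control)))
        object.__setattr__(self, "peaks_rnase", tuple(map(tuple, self.peaks_rnase)))
        _check_peaks(self.peaks_control, "peaks_control", self.protein_id)
        _check_peaks(self.peaks_rnase, "peaks_rnase", self.protein_id)
        if self.total_amount_mitosis < 0 or self.total_amount_interphase < 0:
            raise SpecError(f"{self.protein_id}: total amounts must be >= 0")
        if self.noise_cv < 0:
            raise SpecError(f"{self.protein_id}: noise_cv must be >= 0")
        if self.n_replicates < 2:
            raise SpecError(f"{self.protein_id}: n_replicates must be >= 2")
        coeff, category, max_d = self._ground_truth()
        object.__setattr__(self, "shifting_coefficient_true", coeff)
        object.__setattr__(self, "category_true", category)
        object.__setattr__(self, "max_abs_distance_true", max_d)

    def _ground_truth(self) -> tuple[float, str, float]:
        matches = _greedy_match(self.peaks_control, self.peaks_rnase)
        total = sum(_peak_area(p) for p in self.peaks_control)
        moved: list[tuple[Peak, Peak, float]] = []
        max_d = 0.0
        for ci, ri in matches:
            c, r = self.peaks_control[ci], self.peaks_rnase[ri]
            d = r[0] - c[0]
            max_d = max(max_d, abs(d))
            if abs(d) > MOVE_DISTANCE:
                moved.append((c, r, d))
        coeff = sum(_peak_area(c) for c, _, _ in moved) / total
        if not moved:
            return 0.0, "no_shift", max_d
        if any(int(np.floor(r[0] + 0.5)) > PRECIPITATION_FRACTION for _, r, _ in moved):
            return coeff, "precipitated", max_d
        net = sum(_peak_area(c) * d for c, _, d in moved) / sum(
            _peak_area(c) for c, _, _ in moved
        )
        return coeff, ("left" if net < 0 else "right"), max_d

    def curve(self, condition: str) -> np.ndarray:
        peaks = self.peaks_control if condition == "control" else self.peaks_rnase
        y = np.zeros_like(X_GRID)
        for c, a, w in peaks:
            y = y + a * np.exp(-((X_GRID - c) ** 2) / (2.0 * w * w))
        return y


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and the stated CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = sqrt(log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def generate_screen(
    specs: Sequence[ProfileSpec],
    seed: int,
    phase: str = "mitosis",
) -> tuple[list[FractionProfile], pd.DataFrame]:
    """Generate one full screen (control + RNase, all replicates).

    Profiles are the generating Gaussian mixtures evaluated at integer
    fractions 1..25, scaled so the noiseless raw total equals the spec's
    total amount for the requested cell-cycle ``phase``, then multiplied by
    per-fraction log-normal noise. Returns the flat profile list and the
    ground-truth table (one row per protein: true category, shifting
    coefficient, largest peak displacement).
    """
    if not specs:
        raise SpecError("specs must be non-empty")
    if phase not in ("mitosis", "interphase"):
        raise SpecError(f"unknown phase {phase!r}")
    rng = np.random.default_rng(seed)
    profiles: list[FractionProfile] = []
    truth_rows = []
    for spec in specs:
        amount = (
            spec.total_amount_mitosis if phase == "mitosis"
            else spec.total_amount_interphase
        )
        for condition in ("control", "rnase"):
            base = spec.curve(condition)
            scale = amount / base.sum() if base.sum() > 0 else 0.0
            noise = _lognormal_noise(rng, spec.noise_cv, (spec.n_replicates, N_FRACTIONS))
            for rep in range(1, spec.n_replicates + 1):
                profiles.append(
                    FractionProfile(
                        protein_id=spec.protein_id,
                        condition=condition,
                        replicate=rep,
                        values=base * scale * noise[rep - 1],
                    )
                )
        truth_rows.append(
            {
                "protein_id": spec.protein_id,
                "category_true": spec.category_true,
                "shifting_coefficient_true": spec.shifting_coefficient_true,
                "max_abs_distance_true": spec.max_abs_distance_true,
                "n_peaks_control": len(spec.peaks_control),
                "total_amount": amount,
            }
        )
    return profiles, pd.DataFrame(truth_rows).set_index("protein_id")


def write_screen(
    profiles: Sequence[FractionProfile], truth: pd.DataFrame, outdir: str | Path
) -> list[Path]:
    """Write one TSV matrix per condition x replicate plus the truth table."""
    from .profiles import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    keys = sorted({(p.condition, p.replicate) for p in profiles})
    for condition, rep in keys:
        path = outdir / f"{condition}_rep{rep}.tsv"
        write_matrix(
            [p for p in profiles if p.condition == condition and p.replicate == rep],
            path,
        )
        written.append(path)
    truth_path = outdir / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t")
    written.append(truth_path)
    return written


def random_screen_specs(
    n: int,
    seed: int,
    proportions: Mapping[str, float] | None = None,
    noise_cv: float = DEFAULT_NOISE_CV,
    n_replicates: int = DEFAULT_N_REPLICATES,
    two_peak_prob: float = 0.3,
    min_shift: float = 2.0,
    max_shift: float = 10.0,
) -> list[ProfileSpec]:
    """A realistic random population of generating specs.

    Default category mix (no shift 60%, left 20%, right 12%, precipitated
    8%) reflects that most detected proteins do not change migration upon
    RNase treatment while left shifts dominate among those that do. Shifted
    proteins carry one or, with probability ``two_peak_prob``, two control
    peaks of which only one moves (a partial dependence).
    """
    proportions = dict(
        proportions
        if proportions is not None
        else {"no_shift": 0.60, "left": 0.20, "right": 0.12, "precipitated": 0.08}
    )
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise SpecError("category proportions must sum to 1")
    rng = np.random.default_rng(seed)
    categories = rng.choice(
        list(proportions), size=n, p=list(proportions.values())
    )
    specs = []
    for i, cat in enumerate(categories):
        pid = f"P{i:04d}"
        width = float(rng.uniform(1.0, 2.5))
        amp = float(rng.uniform(5.0, 30.0))
        if cat == "precipitated":
            center = float(rng.uniform(5.0, 18.0))
            control = [(center, amp, width)]
            rnase = [(float(rng.uniform(24.0, 25.0)), amp, width)]
        elif cat == "no_shift":
            center = float(rng.uniform(4.0, 22.0))
            control = [(center, amp, width)]
            rnase = list(control)
        else:
            shift = float(rng.uniform(min_shift, max_shift))
            if cat == "left":
                center = float(rng.uniform(4.0 + shift, 22.0))
                target = center - shift
            else:
                center = float(rng.uniform(4.0, 21.0 - shift))
                target = center + shift
            control = [(center, amp, width)]
            rnase = [(target, amp, width)]
            if rng.uniform() < two_peak_prob:
                # add a stationary second peak well clear of both positions
                for _ in range(50):
                    extra = float(rng.uniform(4.0, 21.0))
                    if abs(extra - center) > 5.0 and abs(extra - target) > 5.0:
                        extra_amp = float(rng.uniform(5.0, 30.0))
                        control.append((extra, extra_amp, width))
                        rnase.append((extra, extra_amp, width))
                        break
        amount_m = float(rng.lognormal(mean=7.0, sigma=0.8))
        ratio = float(rng.lognormal(mean=0.0, sigma=0.7))
        specs.append(
            ProfileSpec(
                protein_id=pid,
                peaks_control=tuple(control),
                peaks_rnase=tuple(rnase),
                total_amount_mitosis=amount_m,
                total_amount_interphase=amount_m * ratio,
                noise_cv=noise_cv,
                n_replicates=n_replicates,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# IP-MS tables


@dataclass(frozen=True)
class InteractorSpec:
    """Generating model of one protein in the IP-MS screen.

    ``true_enrichment_bait_over_igg`` and ``true_rnase_sensitivity`` are
    linear folds: the bait IP intensity sits ``log2(enrichment)`` above the
    IgG level and the RNase-treated bait IP sits ``log2(sensitivity)``
    below the bait level.
    """

    protein_id: str
    true_enrichment_bait_over_igg: float = 1.0
    true_rnase_sensitivity: float = 1.0
    base_intensity: float = 25.0  # log2 scale, iBAQ-like
    missing_prob_per_sample: float = 0.0

    def __post_init__(self) -> None:
        if self.true_enrichment_bait_over_igg <= 0:
            raise SpecError(f"{self.protein_id}: true_enrichment_bait_over_igg must be > 0")
        if self.true_rnase_sensitivity <= 0:
            raise SpecError(f"{self.protein_id}: true_rnase_sensitivity must be > 0")
        if not 0.0 <= self.missing_prob_per_sample <= 1.0:
            raise SpecError(f"{self.protein_id}: missing_prob_per_sample outside [0, 1]")


def generate_ip_table(
    specs: Sequence[InteractorSpec],
    n_replicates: int = 3,
    seed: int = 0,
    replicate_sd: float = 0.25,
) -> pd.DataFrame:
    """Log2 intensity table over {igg, bait, bait_rnase} x replicates.

    Intensities are Gaussian on the log2 scale (log-normal linear scale)
    around the spec's base level shifted by the true folds, with
    ``replicate_sd`` log2 units of replicate noise; each sample is missing
    independently with the spec's probability.
    """
    if n_replicates < 2:
        raise SpecError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    conditions = ("igg", "bait", "bait_rnase")
    columns = pd.MultiIndex.from_product(
        [conditions, range(1, n_replicates + 1)], names=["condition", "replicate"]
    )
    data = np.empty((len(specs), len(columns)))
    for i, spec in enumerate(specs):
        levels = {
            "igg": spec.base_intensity,
            "bait": spec.base_intensity + np.log2(spec.true_enrichment_bait_over_igg),
        }
        levels["bait_rnase"] = levels["bait"] - np.log2(spec.true_rnase_sensitivity)
        row = []
        for cond in conditions:
            row.extend(levels[cond] + rng.normal(0.0, replicate_sd, n_replicates))
        row = np.asarray(row)
        missing = rng.uniform(size=len(row)) < spec.missing_prob_per_sample
        row[missing] = np.nan
        data[i] = row
    return pd.DataFrame(
        data, index=pd.Index([s.protein_id for s in specs], name="protein_id"),
        columns=columns,
    )


def random_interactor_specs(
    n: int,
    seed: int,
    interactor_frac: float = 0.55,
    sensitive_frac_of_interactors: float = 0.30,
    background_missing_prob: float = 0.20,
    interactor_missing_prob: float = 0.05,
) -> list[InteractorSpec]:
    """A realistic random population for the IP-MS screen.

    A bait IP enriches its interactome, so most quantified proteins in a
    filtered table are genuine interactors with strong (4-64 fold) bait/IgG
    enrichment, and a minority of those lose the interaction upon RNase
    treatment (a drop back toward background, 4-64 fold). Background proteins sit at the IgG level
    and are missing more often (their intensities hug the detection limit).
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        pid = f"I{i:04d}"
        base = float(rng.uniform(22.0, 28.0))
        if rng.uniform() < interactor_frac:
            enr = float(2.0 ** rng.uniform(2.0, 6.0))  # 4x .. 64x
            sens = (
                float(2.0 ** rng.uniform(2.0, 6.0))  # complete loss: 4x .. 64x
                if rng.uniform() < sensitive_frac_of_interactors
                else 1.0
            )
            missing = interactor_missing_prob
        else:
            enr, sens, missing = 1.0, 1.0, background_missing_prob
        specs.append(
            InteractorSpec(
                protein_id=pid,
                true_enrichment_bait_over_igg=enr,
                true_rnase_sensitivity=sens,
                base_intensity=base,
                missing_prob_per_sample=missing,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# iCLIP site tables


@dataclass(frozen=True)
class SiteSpec:
    """Generating model of an iCLIP binding-site table.

    Regions are drawn proportionally to their summed length (the null of
    uniform binding per nucleotide), gene types from ``gene_type_mix``,
    scores log-normally, and, when ``uridine_bias_weak`` > 0, the weakest
    20% of sites receive U-enriched sequences (U probability 0.25 +
    0.5 * bias per position) - mirroring the tendency of low-score CLIP
    sites to be uridine-rich background.
    """

    n_sites: int
    region_length_table: Mapping[str, float] = field(
        default_factory=lambda: {
            "intron": 600_000.0, "CDS": 120_000.0, "3'UTR": 80_000.0,
            "5'UTR": 20_000.0, "noncoding": 60_000.0,
        }
    )
    gene_type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"protein_coding": 0.80, "lncRNA": 0.12, "snRNA": 0.08}
    )
    score_mu: float = 1.0
    score_sigma: float = 0.8
    uridine_bias_weak: float = 0.0
    n_genes: int = 200

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise SpecError("n_sites must be >= 1")
        if abs(sum(self.gene_type_mix.values()) - 1.0) > 1e-9:
            raise SpecError("gene_type_mix proportions must sum to 1")
        if any(v <= 0 for v in self.region_length_table.values()):
            raise SpecError("region_length_table lengths must be > 0")
        if not 0.0 <= self.uridine_bias_weak <= 1.0:
            raise SpecError("uridine_bias_weak outside [0, 1]")


def _random_sequences(
    rng: np.random.Generator, n: int, u_prob: float
) -> list[str]:
    other = (1.0 - u_prob) / 3.0
    letters = np.array(list("ACGU"))
    draws = rng.choice(letters, size=(n, 7), p=[other, other, other, u_prob])
    return ["".join(row) for row in draws]


def generate_sites(
    spec: SiteSpec, seed: int
) -> tuple[pd.DataFrame, dict[str, float], pd.DataFrame]:
    """Generate a site table, its region-length table and per-gene counts."""
    rng = np.random.default_rng(seed)
    n = spec.n_sites
    regions = list(spec.region_length_table)
    lengths = np.array([spec.region_length_table[r] for r in regions], dtype=float)
    region_draw = rng.choice(regions, size=n, p=lengths / lengths.sum())
    types = list(spec.gene_type_mix)
    type_draw = rng.choice(types, size=n, p=list(spec.gene_type_mix.values()))
    scores = rng.lognormal(spec.score_mu, spec.score_sigma, size=n)
    genes = rng.integers(0, spec.n_genes, size=n)

    u_base = 0.25
    sequences = np.array(_random_sequences(rng, n, u_base), dtype=object)
    if spec.uridine_bias_weak > 0:
        order = scores.argsort(kind="stable")
        weak_idx = order[: max(1, int(round(0.2 * n)))]
        u_prob = u_base + 0.5 * spec.uridine_bias_weak
        sequences[weak_idx] = _random_sequences(rng, len(weak_idx), u_prob)

    starts = rng.integers(1_000, 1_000_000, size=n)
    sites = pd.DataFrame(
        {
            "site_id": [f"site_{i:06d}" for i in range(n)],
            "chrom": rng.choice([f"chr{c}" for c in range(1, 23)], size=n),
            "start": starts,
            "end": starts + 7,
            "strand": rng.choice(["+", "-"], size=n),
            "score": scores,
            "gene_id": [f"G{g:04d}" for g in genes],
            "gene_type": type_draw,
            "region": region_draw,
            "sequence": sequences,
        }
    )
    gene_counts = (
        sites.groupby("gene_id").size().rename("n_sites").reset_index()
    )
    gene_counts["crosslink_reads"] = rng.poisson(
        50.0 * gene_counts["n_sites"].to_numpy()
    )
    return sites, dict(spec.region_length_table), gene_counts


# ---------------------------------------------------------------------------
# Annotation tables


def generate_annotations(
    screen_protein_ids: Iterable[str],
    shifted_ids: Iterable[str],
    seed: int,
    go_term: str = "GO:mitotic_cell_cycle",
    universe_prob: float = 0.5,
    prior_prob: float = 0.4,
    rbd_prob_prior: float = 0.35,
    rbd_prob_other: float = 0.05,
    n_extra_prior_only: int = 50,
    localizations: Sequence[str] = (
        "spindle pole", "spindle midzone", "kinetochore",
        "chromosome", "centrosome", "midbody",
    ),
):
    """Synthetic annotation records for atlas construction.

    Screen proteins enter the GO-defined universe with ``universe_prob``;
    prior RNA linkage, known-RBD flags and localization labels are drawn
    independently. ``n_extra_prior_only`` universe proteins outside the
    screen carry prior evidence only, so the atlas union genuinely mixes
    both evidence sources.
    """
    from .atlas import AnnotationRecord

    rng = np.random.default_rng(seed)
    shifted = set(shifted_ids)
    records = []

    def _record(pid: str, in_universe: bool, prior: bool) -> AnnotationRecord:
        rbd_p = rbd_prob_prior if prior else rbd_prob_other
        locs = rng.choice(
            localizations, size=rng.integers(1, 3), replace=False
        ) if in_universe else []
        return AnnotationRecord(
            protein_id=pid,
            go_terms=frozenset([go_term] if in_universe else ["GO:other_process"]),
            localization_labels=frozenset(map(str, locs)),
            rna_linked_prior=prior,
            has_known_rbd=bool(rng.uniform() < rbd_p),
            rbp2go_like_score=float(
                rng.uniform(25, 55) if prior else rng.uniform(0, 25)
            ),
        )

    for pid in screen_protein_ids:
        in_universe = bool(rng.uniform() < universe_prob)
        prior = bool(rng.uniform() < prior_prob) if in_universe else False
        records.append(_record(pid, in_universe, prior))
    for j in range(n_extra_prior_only):
        records.append(_record(f"X{j:04d}", True, True))
    return records
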