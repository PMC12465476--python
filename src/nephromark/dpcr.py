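"""Digital-PCR quantification mathematics for the methylation panel.

A digital-PCR reaction splits the sample over N partitions; an assay's
target concentration is inferred from the fraction of positive partitions
k/N through Poisson statistics (lambda = -ln(1 - k/N) mean copies per
partition).  Marker levels are reported relative to the albumin internal
control, which counts total genome copies regardless of methylation, so
the ratio is the fraction of genomes carrying the (methylated) marker.

Bisulfite conversion, required for methylation-specific detection,
degrades most of the input DNA (historically 67-80% loss); the detection
model here treats each input copy as surviving independently with
probability r = 1 - loss and being detected with per-copy efficiency q,
giving P(detect) = 1 - (1 - r*q)^n0 for n0 input copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SaturationError",
    "BisulfiteLossModel",
    "ControlExpectation",
    "DPCRReaction",
    "QuantFragment",
    "poisson_concentration",
    "ratio_to_albumin",
    "quantify_reaction",
    "quantify_plate",
    "validate_controls",
    "replicate_sd",
    "copies_from_mass",
    "detection_probability",
    "estimate_lod",
    "copies_per_ml_plasma",
    "read_plate",
    "write_plate",
]

#: mass of one haploid human genome equivalent, picograms
HAPLOID_GENOME_PG = 3.3


class SaturationError(ValueError):
    """All partitions positive: concentration not estimable, dilute upstream."""


@dataclass(frozen=True)
class BisulfiteLossModel:
    """Fractional DNA loss through bisulfite conversion and cleanup."""

    loss_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.loss_fraction < 1):
            raise ValueError("loss_fraction must be in [0, 1)")

    @property
    def retention(self) -> float:
        return 1.0 - self.loss_fraction


@dataclass(frozen=True)
class ControlExpectation:
    """Acceptance bands for assay validation controls.

    Fully methylated control DNA must show a methylation rate
    (marker-to-albumin ratio) inside ``methylated_band``; fully
    unmethylated control DNA must show no marker signal beyond
    ``false_positive_partitions`` positive partitions.
    """

    methylated_band: tuple[float, float] = (0.58, 0.98)
    false_positive_partitions: int = 0


@dataclass
class DPCRReaction:
    """One well: per-assay positive-partition counts for a panel."""

    reaction_id: str
    sample_id: str
    total_partitions: int
    partition_volume_nl: float
    positives: dict[str, int]
    control_type: str = "sample"  # sample | methylated | unmethylated
    input_mass_ng: float | None = None
    plasma_volume_ml: float | None = None
    eluate_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.total_partitions < 1:
            raise ValueError("total_partitions must be positive")
        if self.partition_volume_nl <= 0:
            raise ValueError("partition_volume_nl must be positive")
        for assay, k in self.positives.items():
            if not (0 <= k <= self.total_partitions):
                raise ValueError(
                    f"reaction {self.reaction_id!r}, assay {assay!r}: "
                    f"positives {k} outside [0, {self.total_partitions}]"
                )


@dataclass(frozen=True)
class QuantFragment:
    """Poisson quantification of one assay in one reaction."""

    p_hat: float
    lam: float
    copies_per_reaction: float
    copies_per_ul: float
    ci95_low: float  # on copies_per_reaction
    ci95_high: float


# ---------------------------------------------------------------------------
# Core estimators
# ---------------------------------------------------------------------------

def poisson_concentration(k: int, n: int, partition_volume_nl: float) -> QuantFragment:
    """Estimate copies from k positive of n partitions.

    lambda = -ln(1 - k/n) mean copies per partition; copies per reaction is
    lambda*n; the 95% CI is a Wilson interval on p = k/n transformed through
    -ln(1 - p), which stays sane at k = 0.
    """
    if k < 0 or n < 1:
        raise ValueError("require 0 <= k and n >= 1")
    if k > n:
        raise ValueError(f"positives k={k} exceeds partitions n={n}")
    if k == n:
        raise SaturationError(
            f"all {n} partitions positive: concentration not estimable"
        )
    p_hat = k / n
    lam = -math.log1p(-p_hat)
    p_lo, p_hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    lam_lo = -math.log1p(-min(p_lo, 1.0 - 1e-15))
    lam_hi = -math.log1p(-min(p_hi, 1.0 - 1e-15))
    return QuantFragment(
        p_hat=p_hat,
        lam=lam,
        copies_per_reaction=lam * n,
        copies_per_ul=lam / (partition_volume_nl * 1e-3),
        ci95_low=max(lam_lo, 0.0) * n,
        ci95_high=lam_hi * n,
    )


def ratio_to_albumin(marker: QuantFragment, albumin: QuantFragment) -> float:
    """Marker level as a percentage of albumin genome copies.

    May exceed 100% (reported as-is, flagged downstream, never clipped).
    """
    if albumin.copies_per_reaction <= 0:
        raise ZeroDivisionError(
            "albumin copies are zero: marker-to-albumin ratio undefined"
        )
    return 100.0 * marker.copies_per_reaction / albumin.copies_per_reaction


def quantify_reaction(
    reaction: DPCRReaction, albumin_assay: str = "ALB"
) -> pd.DataFrame:
    """Quantify every assay in a reaction; one row per assay.

    Columns mirror :class:`QuantFragment` plus ``ratio_to_albumin_pct``
    (NaN for the albumin assay itself or when albumin is zero) and an
    ``over_100pct`` flag.
    """
    if albumin_assay not in reaction.positives:
        raise KeyError(
            f"reaction {reaction.reaction_id!r}: albumin assay "
            f"{albumin_assay!r} has no positives entry"
        )
    frags = {
        a: poisson_concentration(
            k, reaction.total_partitions, reaction.partition_volume_nl
        )
        for a, k in reaction.positives.items()
    }
    alb = frags[albumin_assay]
    rows = []
    for assay, f in frags.items():
        if assay == albumin_assay or alb.copies_per_reaction <= 0:
            ratio = float("nan")
        else:
            ratio = ratio_to_albumin(f, alb)
        rows.append(
            {
                "reaction_id": reaction.reaction_id,
                "sample_id": reaction.sample_id,
                "assay_name": assay,
                "positives": reaction.positives[assay],
                "total_partitions": reaction.total_partitions,
                "p_hat": f.p_hat,
                "lambda": f.lam,
                "copies_per_reaction": f.copies_per_reaction,
                "copies_per_ul": f.copies_per_ul,
                "ci95_low": f.ci95_low,
                "ci95_high": f.ci95_high,
                "ratio_to_albumin_pct": ratio,
                "over_100pct": bool(ratio > 100) if not math.isnan(ratio) else False,
            }
        )
    return pd.DataFrame(rows)


def quantify_plate(
    reactions: Iterable[DPCRReaction], albumin_assay: str = "ALB"
) -> pd.DataFrame:
    """Quantify a list of reactions into one long report table."""
    frames = [quantify_reaction(r, albumin_assay) for r in reactions]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# Assay validation and reproducibility
# ---------------------------------------------------------------------------

def validate_controls(
    reactions: Sequence[DPCRReaction],
    expectation: ControlExpectation | None = None,
    albumin_assay: str = "ALB",
) -> pd.DataFrame:
    """Check control wells against their acceptance bands.

    A methylated control passes when each marker's methylation rate
    (ratio to albumin) lies inside the expected band; an unmethylated
    control passes when each marker shows at most the false-positive
    partition allowance.
    """
    if expectation is None:
        expectation = ControlExpectation()
    lo, hi = expectation.methylated_band
    rows = []
    for r in reactions:
        if r.control_type not in ("methylated", "unmethylated"):
            continue
        if albumin_assay not in r.positives:
            raise KeyError(
                f"control reaction {r.reaction_id!r}: missing albumin counts"
            )
        quant = quantify_reaction(r, albumin_assay)
        for row in quant.itertuples(index=False):
            if row.assay_name == albumin_assay:
                continue
            if r.control_type == "methylated":
                rate = row.ratio_to_albumin_pct / 100.0
                ok = lo <= rate <= hi
                detail = f"methylation rate {rate:.3f}"
            else:
                ok = row.positives <= expectation.false_positive_partitions
                detail = f"{row.positives} positive partition(s)"
            rows.append(
                {
                    "reaction_id": r.reaction_id,
                    "control_type": r.control_type,
                    "assay_name": row.assay_name,
                    "pass": ok,
                    "detail": detail,
                }
            )
    return pd.DataFrame(rows)


def replicate_sd(ratios: pd.DataFrame | Mapping[str, Sequence[float]]) -> pd.Series:
    """Per-assay sample SD of repeated ratio measurements, plus the mean.

    ``ratios``: replicates x assays (percentage units).  Returns a Series of
    per-assay SDs with an extra ``mean_sd`` entry — the reproducibility
    statistic quoted for the assay (mean SD across assays, in percentage
    points of the albumin ratio).
    """
    df = pd.DataFrame(ratios)
    if len(df) < 2:
        raise ValueError("replicate_sd requires >= 2 replicates")
    sds = df.std(axis=0, ddof=1)
    sds["mean_sd"] = sds.mean()
    return sds


# ---------------------------------------------------------------------------
# Input-mass and detection-limit arithmetic
# ---------------------------------------------------------------------------

def copies_from_mass(mass_ng: float, haploid_genome_pg: float = HAPLOID_GENOME_PG) -> float:
    """Haploid genome-equivalent copies in a DNA mass.

    One haploid human genome weighs ~3.3 pg, so 0.03 ng is ~9.1 copies of
    any single-locus biomarker.
    """
    if mass_ng < 0:
        raise ValueError("mass_ng must be non-negative")
    return mass_ng * 1000.0 / haploid_genome_pg


def detection_probability(
    n0: int, loss: BisulfiteLossModel, per_copy_detection: float = 1.0
) -> tuple[float, float]:
    """P(at least one detected copy) and expected surviving copies.

    Each of n0 input copies independently survives conversion with
    probability r = 1 - loss and is then detected with probability q.
    """
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    q = per_copy_detection
    if not (0 < q <= 1):
        raise ValueError("per_copy_detection must be in (0, 1]")
    rq = loss.retention * q
    return 1.0 - (1.0 - rq) ** n0, n0 * rq


def simulate_detection(
    n0: int,
    loss: BisulfiteLossModel,
    per_copy_detection: float = 1.0,
    trials: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo detection frequency under independent binomial thinning."""
    if rng is None:
        rng = np.random.default_rng()
    rq = loss.retention * per_copy_detection
    survivors = rng.binomial(n0, rq, size=trials)
    return float(np.mean(survivors >= 1))


@dataclass(frozen=True)
class LoDEstimate:
    closed_form: int
    monte_carlo: int
    target_probability: float


def estimate_lod(
    loss: BisulfiteLossModel,
    per_copy_detection: float = 1.0,
    target_probability: float = 0.95,
    mc_trials: int = 10_000,
    rng: np.random.Generator | None = None,
) -> LoDEstimate:
    """Smallest input copy number detected with the target probability.

    Closed form: ceil(ln(1 - target) / ln(1 - r*q)).  A Monte-Carlo scan of
    simulated dilution series is returned alongside as a cross-check.
    """
    if not (0 < target_probability < 1):
        raise ValueError("target_probability must be in (0, 1)")
    rq = loss.retention * per_copy_detection
    if rq >= 1.0:
        closed = 1
    else:
        closed = math.ceil(math.log(1.0 - target_probability) / math.log(1.0 - rq))
    if rng is None:
        rng = np.random.default_rng()
    mc = closed
    # scan outward from the analytic answer until the empirical frequency
    # first reaches the target
    n0 = 1
    while True:
        freq = simulate_detection(n0, loss, per_copy_detection, mc_trials, rng)
        if freq >= target_probability:
            mc = n0
            break
        n0 += 1
        if n0 > 10 * closed + 50:  # guard against pathological q
            mc = n0
            break
    return LoDEstimate(closed_form=closed, monte_carlo=mc,
                       target_probability=target_probability)


def copies_per_ml_plasma(
    copies_per_reaction: float,
    eluate_fraction: float,
    plasma_volume_ml: float,
) -> float:
    """Convert copies/reaction to copies/mL plasma.

    ``eluate_fraction`` is the fraction of the extracted (and converted)
    eluate loaded into the reaction.
    """
    if not (0 < eluate_fraction <= 1):
        raise ValueError("eluate_fraction must be in (0, 1]")
    if plasma_volume_ml <= 0:
        raise ValueError("plasma_volume_ml must be positive")
    return copies_per_reaction / eluate_fraction / plasma_volume_ml


# ---------------------------------------------------------------------------
# Plate file I/O (long CSV, one row per reaction x assay)
# ---------------------------------------------------------------------------

_PLATE_COLUMNS = [
    "reaction_id", "sample_id", "control_type", "assay_name", "positives",
    "total_partitions", "partition_volume_nl", "input_mass_ng",
    "plasma_volume_ml",
]


def write_plate(reactions: Sequence[DPCRReaction], path: str | Path) -> None:
    rows = []
    for r in reactions:
        for assay, k in r.positives.items():
            rows.append(
                {
                    "reaction_id": r.reaction_id,
                    "sample_id": r.sample_id,
                    "control_type": r.control_type,
                    "assay_name": assay,
                    "positives": k,
                    "total_partitions": r.total_partitions,
                    "partition_volume_nl": r.partition_volume_nl,
                    "input_mass_ng": r.input_mass_ng,
                    "plasma_volume_ml": r.plasma_volume_ml,
                }
            )
    pd.DataFrame(rows, columns=_PLATE_COLUMNS).to_csv(path, index=False)


def read_plate(path: str | Path) -> list[DPCRReaction]:
    df = pd.read_csv(path, dtype={"reaction_id": str, "sample_id": str})
    missing = [c for c in _PLATE_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"plate file missing column(s): {missing}")
    reactions = []
    for rid, grp in df.groupby("reaction_id", sort=False):
        first = grp.iloc[0]
        reactions.append(
            DPCRReaction(
                reaction_id=str(rid),
                sample_id=str(first["sample_id"]),
                control_type=str(first.get("control_type", "sample")),
                total_partitions=int(first["total_partitions"]),
                partition_volume_nl=float(first["partition_volume_nl"]),
                positives={
                    str(a): int(k)
                    for a, k in zip(grp["assay_name"], grp["positives"])
                },
                input_mass_ng=(
                    None if pd.isna(first.get("input_mass_ng")) else float(first["input_mass_ng"])
                ),
                plasma_volume_ml=(
                    None if pd.isna(first.get("plasma_volume_ml")) else float(first["plasma_volume_ml"])
                ),
            )
        )
    return reactions
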