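"""Seeded generators for atlas, dPCR plate, and cohort inputs.

These stand in for the study's three data sources: a multi-tissue WGBS
methylation atlas (21 anatomical groups in triplicate, including kidney
subcompartments and blood cell types), digital-PCR plates for the 10-plex
panel, and the transplant cohort (170 patient-biopsy pairs, 44 with
rejection).  Every generator is a pure function of its spec and seed and
emits a machine-readable truth table sufficient to score recovery tests.

The generators model only the statistical structure the analysis relies
on — per-group beta distributions, binomial partition counting, class-
conditional marker/covariate distributions — not the marginal
distributions or correlation structure of real methylomes or cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasMatrix, GenomicBlock, SampleInfo
from .dpcr import DPCRReaction
from .screen import DEFAULT_PANEL, PanelDefinition, TargetSpec

__all__ = [
    "AtlasGenSpec",
    "CohortGenSpec",
    "gen_atlas",
    "gen_dpcr_plate",
    "gen_cohort",
    "default_target_specs",
    "implied_logit_coefficients",
]

# ---------------------------------------------------------------------------
# Group roster
# ---------------------------------------------------------------------------

KIDNEY_EPITHELIAL_GROUPS = (
    "kidney_tubular_epithelium",
    "kidney_glomerular_epithelium",
    "kidney_podocyte",
)
KIDNEY_ENDOTHELIAL_GROUPS = (
    "kidney_peritubular_endothelium",
    "kidney_glomerular_endothelium",
)
KIDNEY_GROUPS = KIDNEY_EPITHELIAL_GROUPS + KIDNEY_ENDOTHELIAL_GROUPS
BLOOD_GROUPS = (
    "blood_granulocyte",
    "blood_monocyte",
    "blood_b_cell",
    "blood_t_cell",
    "blood_nk_cell",
)
OTHER_GROUPS = (
    "liver", "lung", "heart", "brain", "colon", "pancreas",
    "adipose", "skeletal_muscle", "skin", "breast", "prostate",
)
DEFAULT_GROUPS = KIDNEY_GROUPS + BLOOD_GROUPS + OTHER_GROUPS  # 21 groups

COMPARTMENT_TARGETS: dict[str, tuple[str, ...]] = {
    "pan_renal": KIDNEY_GROUPS,
    "endothelial": KIDNEY_ENDOTHELIAL_GROUPS,
    "epithelial": KIDNEY_EPITHELIAL_GROUPS,
}


def default_target_specs() -> dict[str, TargetSpec]:
    """The three compartment screens over the default group roster."""
    return {
        comp: TargetSpec(
            name=comp,
            target_groups=frozenset(targets),
            blood_groups=frozenset(BLOOD_GROUPS),
        )
        for comp, targets in COMPARTMENT_TARGETS.items()
    }


# ---------------------------------------------------------------------------
# Atlas generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtlasGenSpec:
    """Synthetic atlas: planted compartment markers among null blocks.

    Planted marker blocks draw target-group betas from Beta(a_hi, b_hi)
    (strongly methylated), blood-group betas from Beta(a_blood, b_blood)
    (essentially unmethylated — real panel markers were selected for blood
    negativity, so planted truth is blood-negative by construction), and
    remaining background betas from Beta(a_lo, b_lo).  Null blocks share a
    single per-block Beta whose mean is uniform on
    ``null_mean_range`` with concentration ``null_concentration`` across
    all samples, so they carry no compartment signal.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_replicates: int = 3
    n_null_blocks: int = 2000
    planted_per_compartment: Mapping[str, int] = field(
        default_factory=lambda: {"pan_renal": 1, "endothelial": 6, "epithelial": 2}
    )
    a_hi: float = 50.0
    b_hi: float = 2.0
    a_lo: float = 2.0
    b_lo: float = 50.0
    a_blood: float = 1.0
    b_blood: float = 199.0
    null_mean_range: tuple[float, float] = (0.05, 0.95)
    null_concentration: float = 52.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group in roster")
        unknown = set(self.planted_per_compartment) - set(COMPARTMENT_TARGETS)
        if unknown:
            raise ValueError(f"unknown compartment(s): {sorted(unknown)}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


def gen_atlas(spec: AtlasGenSpec) -> tuple[AtlasMatrix, dict]:
    """Generate an atlas plus its truth table.

    The truth table records the planted block ids per compartment and all
    generator parameters; it is sufficient to score a marker-recovery test
    without re-deriving anything.
    """
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.groups)
    blood = [g for g in BLOOD_GROUPS if g in groups]
    samples = [
        SampleInfo(f"{g}_rep{r}", g, r)
        for g in groups
        for r in range(1, spec.n_replicates + 1)
    ]
    sample_groups = np.array([s.group for s in samples])
    n_samples = len(samples)

    planted: list[tuple[str, str]] = []  # (compartment, kind) rows
    for comp, count in spec.planted_per_compartment.items():
        planted += [(comp, "planted")] * count
    n_planted = len(planted)
    n_blocks = spec.n_null_blocks + n_planted

    # place planted blocks at random positions among the nulls
    positions = rng.choice(n_blocks, size=n_planted, replace=False)
    kind = np.array(["null"] * n_blocks, dtype=object)
    comp_of = np.array([""] * n_blocks, dtype=object)
    for pos, (comp, _) in zip(positions, planted):
        kind[pos] = "planted"
        comp_of[pos] = comp

    beta = np.empty((n_blocks, n_samples))
    for i in range(n_blocks):
        if kind[i] == "null":
            m = rng.uniform(*spec.null_mean_range)
            c = spec.null_concentration
            beta[i] = rng.beta(m * c, (1 - m) * c, size=n_samples)
        else:
            targets = set(COMPARTMENT_TARGETS[comp_of[i]])
            for j, g in enumerate(sample_groups):
                if g in targets:
                    beta[i, j] = rng.beta(spec.a_hi, spec.b_hi)
                elif g in blood:
                    beta[i, j] = rng.beta(spec.a_blood, spec.b_blood)
                else:
                    beta[i, j] = rng.beta(spec.a_lo, spec.b_lo)

    if spec.missing_rate > 0:
        mask = rng.random(beta.shape) < spec.missing_rate
        beta[mask] = np.nan

    width = len(str(n_blocks))
    blocks = [
        GenomicBlock("chr1", 1000 * i, 1000 * i + 500, f"block{str(i).zfill(width)}")
        for i in range(n_blocks)
    ]
    beta_df = pd.DataFrame(
        beta,
        index=pd.Index([b.block_id for b in blocks], name="block_id"),
        columns=[s.sample_id for s in samples],
    )
    atlas = AtlasMatrix(blocks=blocks, samples=samples, beta=beta_df)

    truth = {
        "seed": spec.seed,
        "planted": {
            comp: sorted(
                blocks[i].block_id for i in range(n_blocks) if comp_of[i] == comp
            )
            for comp in spec.planted_per_compartment
        },
        "n_null_blocks": spec.n_null_blocks,
        "params": {
            "a_hi": spec.a_hi, "b_hi": spec.b_hi,
            "a_lo": spec.a_lo, "b_lo": spec.b_lo,
            "a_blood": spec.a_blood, "b_blood": spec.b_blood,
            "missing_rate": spec.missing_rate,
            "n_replicates": spec.n_replicates,
        },
    }
    return atlas, truth


# ---------------------------------------------------------------------------
# dPCR plate generator
# ---------------------------------------------------------------------------

def gen_dpcr_plate(
    true_copies: Mapping[str, Mapping[str, float]],
    panel: PanelDefinition = DEFAULT_PANEL,
    n_partitions: int = 20_000,
    partition_volume_nl: float = 0.82,
    seed: int = 0,
    control_types: Mapping[str, str] | None = None,
    replicates: int = 1,
) -> tuple[list[DPCRReaction], dict]:
    """Simulate a plate from true per-assay copy numbers.

    ``true_copies`` maps sample_id -> assay -> copies per reaction.
    Positives are Binomial(N, 1 - exp(-copies/N)) independently per assay;
    replicate wells share the truth but draw independent counts.
    ``control_types`` optionally labels samples "methylated"/"unmethylated".
    """
    rng = np.random.default_rng(seed)
    control_types = dict(control_types or {})
    reactions: list[DPCRReaction] = []
    for sample_id, assays in true_copies.items():
        bad = sorted(set(assays) - set(panel.assay_names))
        if bad:
            raise ValueError(f"sample {sample_id!r}: assay(s) not in panel: {bad}")
        for rep in range(1, replicates + 1):
            positives = {}
            for assay in panel.assay_names:
                copies = float(assays.get(assay, 0.0))
                if copies < 0:
                    raise ValueError(f"negative true copies for {assay!r}")
                p = 1.0 - np.exp(-copies / n_partitions)
                positives[assay] = int(rng.binomial(n_partitions, p))
            reactions.append(
                DPCRReaction(
                    reaction_id=f"{sample_id}_r{rep}",
                    sample_id=sample_id,
                    control_type=control_types.get(sample_id, "sample"),
                    total_partitions=n_partitions,
                    partition_volume_nl=partition_volume_nl,
                    positives=positives,
                )
            )
    truth = {
        "seed": seed,
        "n_partitions": n_partitions,
        "partition_volume_nl": partition_volume_nl,
        "replicates": replicates,
        "true_copies": {s: dict(a) for s, a in true_copies.items()},
        "control_types": control_types,
    }
    return reactions, truth


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGenSpec:
    """Synthetic transplant cohort with planted diagnostic structure.

    Outcome bookkeeping defaults mirror the study: 170 patient-biopsy
    pairs, 44 rejections split 24 ABMR / 13 TCMR / 7 mixed, biopsy
    contexts 89 indication / 76 surveillance (34 and 10 of the rejections
    respectively) with the remainder context-unlabeled.

    Marker levels (percent of albumin) are log-normal at baseline;
    rejection multiplies them by planted fold-changes: endothelial markers
    by ``endothelial_fold`` in ABMR/mixed (the antibody-mediated process
    injures the microvascular endothelium), the pan-renal marker by
    ``pan_renal_fold`` in any rejection, epithelial markers by
    ``epithelial_fold`` in TCMR/mixed (tubulitis).  ``effect_scope`` can
    widen the endothelial/epithelial effects to all rejections, which
    makes the class-conditional model a homogeneous Gaussian shift on the
    log scale (useful for coefficient-recovery tests).  eGFR is Gaussian,
    lower under rejection; DSA is Bernoulli with a higher rate in
    ABMR/mixed.  Non-rejection records can carry other histological
    lesions with a milder marker elevation.
    """

    n: int = 170
    n_rejection: int = 44
    n_abmr: int = 24
    n_tcmr: int = 13
    n_mixed: int = 7
    n_indication: int = 89
    n_surveillance: int = 76
    rejections_indication: int = 34
    rejections_surveillance: int = 10

    endothelial_fold: float = 3.0
    pan_renal_fold: float = 2.0
    epithelial_fold: float = 1.5
    effect_scope: str = "subtype"  # "subtype" | "any_rejection"

    lesion_rate_nonrejection: float = 0.35
    lesion_fold: float = 1.5

    egfr_mean_norejection: float = 50.0
    egfr_mean_rejection: float = 40.0
    egfr_sd: float = 15.0
    dsa_rate_abmr_mixed: float = 0.60
    dsa_rate_other: float = 0.15

    baseline_log10_pct: float = -0.5  # median marker level ~0.32% of albumin
    sigma_log10: float = 0.35
    paxgene_fraction: float = 0.5

    counting_noise: bool = False
    n_partitions: int = 20_000
    partition_volume_nl: float = 0.82
    albumin_copies: float = 10_000.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_abmr + self.n_tcmr + self.n_mixed != self.n_rejection:
            raise ValueError("subtype counts must sum to n_rejection")
        if self.n_rejection > self.n:
            raise ValueError("n_rejection exceeds n")
        if self.n_indication + self.n_surveillance > self.n:
            raise ValueError("biopsy-context counts exceed n")
        if self.rejections_indication + self.rejections_surveillance != self.n_rejection:
            raise ValueError("per-context rejection counts must sum to n_rejection")
        if self.rejections_indication > self.n_indication:
            raise ValueError("more indication rejections than indication biopsies")
        if self.rejections_surveillance > self.n_surveillance:
            raise ValueError("more surveillance rejections than surveillance biopsies")
        if self.effect_scope not in ("subtype", "any_rejection"):
            raise ValueError("effect_scope must be 'subtype' or 'any_rejection'")


def _marker_roles(panel: PanelDefinition) -> dict[str, str]:
    return {e.assay_name: e.role for e in panel.entries if e.role != "internal_control"}


def gen_cohort(
    spec: CohortGenSpec, panel: PanelDefinition = DEFAULT_PANEL
) -> tuple[pd.DataFrame, dict]:
    """Generate the cohort table and its truth table."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    subtype = np.array(["none"] * n, dtype=object)
    subtype[: spec.n_abmr] = "ABMR"
    subtype[spec.n_abmr: spec.n_abmr + spec.n_tcmr] = "TCMR"
    subtype[spec.n_abmr + spec.n_tcmr: spec.n_rejection] = "mixed"
    rejection = subtype != "none"

    # biopsy context: exact counts within rejection / non-rejection strata
    context = np.array(["unlabeled"] * n, dtype=object)
    rej_idx = rng.permutation(np.flatnonzero(rejection))
    context[rej_idx[: spec.rejections_indication]] = "indication"
    context[rej_idx[spec.rejections_indication:]] = "surveillance"
    non_idx = rng.permutation(np.flatnonzero(~rejection))
    n_ind_non = spec.n_indication - spec.rejections_indication
    n_sur_non = spec.n_surveillance - spec.rejections_surveillance
    context[non_idx[:n_ind_non]] = "indication"
    context[non_idx[n_ind_non: n_ind_non + n_sur_non]] = "surveillance"

    abmr_like = (subtype == "ABMR") | (subtype == "mixed")
    tcmr_like = (subtype == "TCMR") | (subtype == "mixed")

    egfr = np.where(
        rejection,
        rng.normal(spec.egfr_mean_rejection, spec.egfr_sd, n),
        rng.normal(spec.egfr_mean_norejection, spec.egfr_sd, n),
    )
    egfr = np.clip(egfr, 5.0, None)

    dsa = rng.random(n) < np.where(
        abmr_like, spec.dsa_rate_abmr_mixed, spec.dsa_rate_other
    )
    tube = np.where(rng.random(n) < spec.paxgene_fraction, "PAXgene", "EDTA")

    # any-lesion flag: rejection always a lesion; a fraction of the rest
    other_lesion = ~rejection & (rng.random(n) < spec.lesion_rate_nonrejection)
    any_lesion = rejection | other_lesion

    if spec.effect_scope == "any_rejection":
        endo_hit = rejection
        epi_hit = rejection
    else:
        endo_hit = abmr_like
        epi_hit = tcmr_like
    pan_hit = rejection

    roles = _marker_roles(panel)
    fold_of_role = {
        "endothelial": (endo_hit, spec.endothelial_fold),
        "epithelial": (epi_hit, spec.epithelial_fold),
        "pan_renal": (pan_hit, spec.pan_renal_fold),
    }
    levels: dict[str, np.ndarray] = {}
    for marker, role in roles.items():
        hit, fold = fold_of_role[role]
        log10_mu = np.full(n, spec.baseline_log10_pct)
        log10_mu[hit] += np.log10(fold)
        log10_mu[other_lesion] += np.log10(spec.lesion_fold)
        lv = 10 ** rng.normal(log10_mu, spec.sigma_log10)
        levels[marker] = lv

    if spec.counting_noise:
        # pass each level through binomial partition counting
        for marker in levels:
            copies = levels[marker] / 100.0 * spec.albumin_copies
            p = 1.0 - np.exp(-copies / spec.n_partitions)
            k = rng.binomial(spec.n_partitions, p)
            lam = -np.log1p(-np.minimum(k / spec.n_partitions, 1 - 1e-12))
            est = lam * spec.n_partitions
            levels[marker] = est / spec.albumin_copies * 100.0

    df = pd.DataFrame(
        {
            "patient_id": [f"P{str(i + 1).zfill(3)}" for i in range(n)],
            "tube_type": tube,
            "biopsy_context": context,
            "rejection": rejection,
            "rejection_subtype": subtype,
            "any_banff_lesion": any_lesion,
            "egfr": np.round(egfr, 2),
            "dsa": dsa,
        }
    )
    for marker in roles:
        df[marker] = levels[marker]

    # shuffle row order so outcome is not positional
    perm = rng.permutation(n)
    df = df.iloc[perm].reset_index(drop=True)

    truth = {
        "seed": spec.seed,
        "counts": {
            "n": n,
            "rejection": int(spec.n_rejection),
            "ABMR": int(spec.n_abmr),
            "TCMR": int(spec.n_tcmr),
            "mixed": int(spec.n_mixed),
        },
        "effects": {
            "endothelial_fold": spec.endothelial_fold,
            "pan_renal_fold": spec.pan_renal_fold,
            "epithelial_fold": spec.epithelial_fold,
            "effect_scope": spec.effect_scope,
            "lesion_fold": spec.lesion_fold,
            "egfr_shift": spec.egfr_mean_rejection - spec.egfr_mean_norejection,
            "dsa_rate_abmr_mixed": spec.dsa_rate_abmr_mixed,
            "dsa_rate_other": spec.dsa_rate_other,
        },
        "baseline": {
            "baseline_log10_pct": spec.baseline_log10_pct,
            "sigma_log10": spec.sigma_log10,
        },
        "marker_roles": roles,
        "implied_logit_coefficients": implied_logit_coefficients(spec, panel),
    }
    return df, truth


def implied_logit_coefficients(
    spec: CohortGenSpec, panel: PanelDefinition = DEFAULT_PANEL
) -> dict[str, float] | None:
    """Closed-form logistic slopes implied by the generative model.

    Only defined when effects are homogeneous within the rejection class
    (``effect_scope='any_rejection'``): then each log10 marker level is a
    class-conditional Gaussian with a mean shift d = log10(fold) and common
    SD s, so the discriminant (= logistic) slope is d/s^2; eGFR likewise
    shift/sd^2; DSA's slope is the log odds ratio of its two rates.
    Returns None for subtype-dependent effects (mixture alternative).
    """
    if spec.effect_scope != "any_rejection" or spec.lesion_rate_nonrejection > 0:
        return None
    s2 = spec.sigma_log10 ** 2
    roles = _marker_roles(panel)
    fold = {
        "endothelial": spec.endothelial_fold,
        "epithelial": spec.epithelial_fold,
        "pan_renal": spec.pan_renal_fold,
    }
    coefs = {
        f"log10_{m}": float(np.log10(fold[r]) / s2) for m, r in roles.items()
    }
    coefs["egfr"] = float(
        (spec.egfr_mean_rejection - spec.egfr_mean_norejection) / spec.egfr_sd ** 2
    )
    p1, p0 = spec.dsa_rate_abmr_mixed, spec.dsa_rate_other
    if p1 == p0:
        coefs["dsa"] = 0.0
    else:
        coefs["dsa"] = float(
            np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
        )
    return coefs
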