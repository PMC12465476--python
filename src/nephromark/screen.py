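"""Tissue-specific methylation marker screen and panel assembly.

Scores every atlas block for compartment-specific hypermethylation: a
candidate marker must be strongly methylated in every target group
(kidney compartment) and essentially unmethylated in every other
anatomical region, with a stricter cap on blood cell groups — blood cells
are the dominant source of plasma cfDNA, so any blood methylation would
swamp a kidney signal.  Passing blocks are ranked by their worst-case
specificity margin (min target mean beta minus max background mean beta)
and assembled into a fixed-size multiplex assay panel with an internal
copy-number control on the albumin locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .atlas import AtlasMatrix, aggregate_by_group

__all__ = [
    "TargetSpec",
    "ScreenConfig",
    "MarkerScore",
    "PanelEntry",
    "PanelDefinition",
    "DEFAULT_PANEL",
    "score_block",
    "screen_markers",
    "select_panel",
    "screen_report",
    "write_panel_yaml",
    "read_panel_yaml",
]


@dataclass(frozen=True)
class TargetSpec:
    """A compartment screen: which groups are target, background, blood.

    ``background_groups`` defaults (at screen time) to all atlas groups not
    in the target set; ``blood_groups`` is the subset of background flagged
    as contaminant-critical.
    """

    name: str
    target_groups: frozenset[str]
    blood_groups: frozenset[str]
    background_groups: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.target_groups:
            raise ValueError(f"target spec {self.name!r}: empty target set")
        if self.background_groups is not None:
            if self.target_groups & self.background_groups:
                raise ValueError(
                    f"target spec {self.name!r}: target and background overlap"
                )
            if not self.blood_groups <= self.background_groups:
                raise ValueError(
                    f"target spec {self.name!r}: blood groups not a subset of background"
                )

    def resolve_background(self, atlas_groups: Sequence[str]) -> frozenset[str]:
        if self.background_groups is not None:
            return self.background_groups
        return frozenset(atlas_groups) - self.target_groups


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the specificity screen.

    tau_target
        Minimum mean beta required in every target group.
    tau_background
        Maximum mean beta tolerated in any background group.
    tau_blood
        Stricter cap applied to blood groups.
    min_margin
        Minimum worst-case separation (min target - max background).
    top_k
        Optional truncation of the ranked passing list.
    """

    tau_target: float = 0.5
    tau_background: float = 0.15
    tau_blood: float = 0.05
    min_margin: float = 0.3
    top_k: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.tau_blood <= self.tau_background < self.tau_target <= 1):
            raise ValueError(
                "require 0 <= tau_blood <= tau_background < tau_target <= 1"
            )
        if not (0 <= self.min_margin <= 1):
            raise ValueError("min_margin must be in [0, 1]")


@dataclass(frozen=True)
class MarkerScore:
    """Per-block screen result."""

    block_id: str
    target_min_beta: float
    background_max_beta: float
    blood_max_beta: float
    margin: float
    direction: str  # "hyper" (methylated in target) or "hypo"
    pass_target: bool
    pass_background: bool
    pass_blood: bool
    pass_margin: bool
    evaluable: bool = True

    @property
    def passes(self) -> bool:
        return (
            self.evaluable
            and self.pass_target
            and self.pass_background
            and self.pass_blood
            and self.pass_margin
        )


@dataclass(frozen=True)
class PanelEntry:
    assay_name: str
    block_id: str | None  # None for the internal control
    role: str  # pan_renal | endothelial | epithelial | internal_control
    channel_id: int


@dataclass(frozen=True)
class PanelDefinition:
    """An ordered multiplex assay panel with exactly one internal control."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        names = [e.assay_name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate assay names in panel")
        n_ctrl = sum(e.role == "internal_control" for e in self.entries)
        if n_ctrl != 1:
            raise ValueError(f"panel must have exactly one internal control, got {n_ctrl}")

    @property
    def assay_names(self) -> list[str]:
        return [e.assay_name for e in self.entries]

    @property
    def marker_names(self) -> list[str]:
        return [e.assay_name for e in self.entries if e.role != "internal_control"]

    @property
    def control_name(self) -> str:
        return next(e.assay_name for e in self.entries if e.role == "internal_control")


def _default_panel() -> PanelDefinition:
    roster = [
        ("CTDP1", "pan_renal"),
        ("ARID3A", "endothelial"),
        ("GATA2", "endothelial"),
        ("LOC124903692", "endothelial"),
        ("RHBDF2", "endothelial"),
        ("SEPT5-GP1BB", "endothelial"),
        ("TNS2-AS1", "endothelial"),
        ("PAX2", "epithelial"),
        ("ACSL5", "epithelial"),
        ("ALB", "internal_control"),
    ]
    return PanelDefinition(
        tuple(
            PanelEntry(name, None if role == "internal_control" else name, role, i + 1)
            for i, (name, role) in enumerate(roster)
        )
    )


#: the 10-plex assay roster: 1 pan-renal + 6 endothelial + 2 epithelial
#: markers plus the albumin copy-number control.
DEFAULT_PANEL: PanelDefinition = _default_panel()

#: compartment quota matching the default panel's 1 + 6 + 2 split
DEFAULT_QUOTA: dict[str, int] = {"pan_renal": 1, "endothelial": 6, "epithelial": 2}


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _score_from_means(
    block_id: str,
    means: Mapping[str, float],
    n_obs: Mapping[str, int],
    spec: TargetSpec,
    config: ScreenConfig,
    background: frozenset[str],
) -> MarkerScore:
    target = sorted(spec.target_groups)
    if any(n_obs.get(g, 0) < 1 for g in target):
        return MarkerScore(
            block_id, float("nan"), float("nan"), float("nan"), float("nan"),
            "hyper", False, False, False, False, evaluable=False,
        )
    # blood groups are judged by their own stricter cap; the generic
    # background criterion covers the remaining non-blood regions
    bg_obs = [
        g for g in sorted(background - spec.blood_groups) if n_obs.get(g, 0) >= 1
    ]
    blood_obs = [g for g in sorted(spec.blood_groups) if n_obs.get(g, 0) >= 1]
    t_min = min(means[g] for g in target)
    b_max = max((means[g] for g in bg_obs), default=float("nan"))
    bl_max = max((means[g] for g in blood_obs), default=0.0)
    margin = t_min - b_max
    t_max = max(means[g] for g in target)
    direction = "hyper" if t_min >= b_max else ("hypo" if t_max <= b_max else "hyper")
    return MarkerScore(
        block_id=block_id,
        target_min_beta=t_min,
        background_max_beta=b_max,
        blood_max_beta=bl_max,
        margin=margin,
        direction=direction,
        pass_target=t_min >= config.tau_target,
        pass_background=b_max <= config.tau_background,
        pass_blood=bl_max <= config.tau_blood,
        pass_margin=margin >= config.min_margin,
    )


def score_block(
    summary: pd.DataFrame,
    block_id: str,
    spec: TargetSpec,
    config: ScreenConfig,
    atlas_groups: Sequence[str] | None = None,
) -> MarkerScore:
    """Score one block from a :func:`~nephromark.atlas.aggregate_by_group` table.

    The block passes when its minimum target-group mean beta is at least
    ``tau_target``, no background group exceeds ``tau_background``, no blood
    group exceeds ``tau_blood``, and the margin is at least ``min_margin``.
    A block with an unobserved target group is returned as not evaluable.
    """
    rows = summary[summary["block_id"] == block_id]
    if rows.empty:
        raise KeyError(f"block {block_id!r} absent from summary")
    groups = atlas_groups if atlas_groups is not None else list(rows["group"].unique())
    background = spec.resolve_background(groups)
    means = dict(zip(rows["group"], rows["mean_beta"]))
    n_obs = dict(zip(rows["group"], rows["n_replicates_observed"]))
    return _score_from_means(block_id, means, n_obs, spec, config, background)


def screen_markers(
    atlas: AtlasMatrix,
    spec: TargetSpec,
    config: ScreenConfig,
) -> list[MarkerScore]:
    """Score every evaluable block; return passing blocks ranked by margin.

    Ranking is by margin descending with ties broken by block_id ascending,
    truncated to ``config.top_k`` when set.  Deterministic and invariant to
    the atlas's block and sample ordering.
    """
    groups = atlas.groups
    missing = sorted((spec.target_groups | spec.blood_groups) - set(groups))
    if missing:
        raise KeyError(f"target spec group(s) absent from atlas: {missing}")
    background = spec.resolve_background(groups)

    summary = aggregate_by_group(atlas)
    means = summary.pivot(index="block_id", columns="group", values="mean_beta")
    n_obs = summary.pivot(
        index="block_id", columns="group", values="n_replicates_observed"
    )
    scores: list[MarkerScore] = []
    for bid in atlas.block_ids:
        m = means.loc[bid].to_dict()
        n = n_obs.loc[bid].to_dict()
        scores.append(_score_from_means(bid, m, n, spec, config, background))
    passing = [s for s in scores if s.passes]
    passing.sort(key=lambda s: (-s.margin, s.block_id))
    if config.top_k is not None:
        passing = passing[: config.top_k]
    return passing


def select_panel(
    screens: Mapping[str, list[MarkerScore]],
    quota: Mapping[str, int] | None = None,
    control_name: str = "ALB",
    assay_names: Mapping[str, str] | None = None,
) -> PanelDefinition:
    """Assemble the assay panel from ranked per-compartment screens.

    Takes the top-``quota`` passing markers per compartment and appends the
    internal control.  A block passing two screens is assigned to the
    compartment where its margin is larger (tie -> pan_renal); channel ids
    follow declaration order.
    """
    if quota is None:
        quota = DEFAULT_QUOTA
    unknown = sorted(set(quota) - set(screens))
    if unknown:
        raise KeyError(f"quota compartment(s) without a screen: {unknown}")

    # resolve multi-compartment blocks to their best compartment
    best: dict[str, str] = {}
    margin_of: dict[tuple[str, str], float] = {}
    for comp, scores in screens.items():
        for s in scores:
            margin_of[(comp, s.block_id)] = s.margin
            cur = best.get(s.block_id)
            if cur is None:
                best[s.block_id] = comp
            else:
                m_new, m_cur = s.margin, margin_of[(cur, s.block_id)]
                if m_new > m_cur or (m_new == m_cur and comp == "pan_renal"):
                    best[s.block_id] = comp

    entries: list[PanelEntry] = []
    channel = 1
    for comp in quota:
        want = quota[comp]
        eligible = [s for s in screens[comp] if best[s.block_id] == comp]
        if len(eligible) < want:
            raise ValueError(
                f"compartment {comp!r}: need {want} markers, only "
                f"{len(eligible)} passing (shortfall {want - len(eligible)})"
            )
        for s in eligible[:want]:
            name = (assay_names or {}).get(s.block_id, s.block_id)
            entries.append(PanelEntry(name, s.block_id, comp, channel))
            channel += 1
    entries.append(PanelEntry(control_name, None, "internal_control", channel))
    return PanelDefinition(tuple(entries))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def screen_report(screens: Mapping[str, list[MarkerScore]]) -> pd.DataFrame:
    """Flatten ranked screens into the tabular report format."""
    rows = []
    for comp, scores in screens.items():
        for rank, s in enumerate(scores, start=1):
            rows.append(
                {
                    "block_id": s.block_id,
                    "compartment": comp,
                    "target_min_beta": s.target_min_beta,
                    "background_max_beta": s.background_max_beta,
                    "blood_max_beta": s.blood_max_beta,
                    "margin": s.margin,
                    "pass_target": s.pass_target,
                    "pass_background": s.pass_background,
                    "pass_blood": s.pass_blood,
                    "pass_margin": s.pass_margin,
                    "pass": s.passes,
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)


def write_panel_yaml(panel: PanelDefinition, path: str | Path) -> None:
    data = {
        "panel": [
            {
                "assay_name": e.assay_name,
                "block_id": e.block_id,
                "role": e.role,
                "channel_id": e.channel_id,
            }
            for e in panel.entries
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_panel_yaml(path: str | Path) -> PanelDefinition:
    data = yaml.safe_load(Path(path).read_text())
    return PanelDefinition(
        tuple(
            PanelEntry(d["assay_name"], d.get("block_id"), d["role"], d["channel_id"])
            for d in data["panel"]
        )
    )
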