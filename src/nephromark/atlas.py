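"""Block-level methylation atlas container and I/O.

The atlas is a matrix of methylation fractions (beta values) over genomic
blocks (rows) and purified tissue / cell-type samples (columns), with each
sample annotated by an anatomical group and a replicate index.  It is the
substrate of the tissue-specific marker screen: candidate marker blocks are
required to be observed in a minimum number of replicates of every group
("replication filter") and are then scored on per-group aggregate betas.

Coordinates are 0-based half-open (BED convention).  Missing beta values
are encoded ``NA`` on disk and ``NaN`` in memory; a beta of 0 is data
(a fully unmethylated block), never a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicBlock",
    "SampleInfo",
    "AtlasMatrix",
    "AtlasValidationError",
    "read_atlas",
    "write_atlas",
    "filter_blocks_by_replication",
    "aggregate_by_group",
    "write_blocks_bed",
]

#: fixed on-disk precision for beta values (decimal places)
BETA_DECIMALS = 6

_BLOCK_COLUMNS = ["chrom", "start", "end", "block_id"]
_SHEET_COLUMNS = ["sample_id", "group", "replicate"]


class AtlasValidationError(ValueError):
    """Raised when an atlas or one of its files violates an invariant."""


@dataclass(frozen=True)
class GenomicBlock:
    """A genomic interval (0-based, half-open) with a unique identifier."""

    chrom: str
    start: int
    end: int
    block_id: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AtlasValidationError(f"block {self.block_id!r}: empty chrom")
        if not (0 <= self.start < self.end):
            raise AtlasValidationError(
                f"block {self.block_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class SampleInfo:
    """One atlas column: a replicate of an anatomical group."""

    sample_id: str
    group: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise AtlasValidationError(
                f"sample {self.sample_id!r}: replicate index must be >= 1"
            )


@dataclass
class AtlasMatrix:
    """Block x sample beta-value matrix with group/replicate annotations.

    Parameters
    ----------
    blocks
        Ordered block annotations.
    samples
        Ordered sample annotations; order matches the beta columns.
    beta
        DataFrame indexed by ``block_id`` with one column per ``sample_id``;
        values in [0, 1] or NaN for missing.
    coverage
        Optional read-count matrix of the same shape.
    """

    blocks: list[GenomicBlock]
    samples: list[SampleInfo]
    beta: pd.DataFrame
    coverage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def block_ids(self) -> list[str]:
        return [b.block_id for b in self.blocks]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in sample-sheet order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return list(seen)

    @property
    def sample_groups(self) -> pd.Series:
        """Group label per sample_id (sheet order)."""
        return pd.Series(
            [s.group for s in self.samples], index=self.sample_ids, name="group"
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def validate(self) -> None:
        ids = self.block_ids
        dup = pd.Index(ids)[pd.Index(ids).duplicated()]
        if len(dup):
            raise AtlasValidationError(f"duplicate block_id(s): {sorted(set(dup))}")
        pairs = [(s.group, s.replicate) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise AtlasValidationError("duplicate (group, replicate) pair in samples")
        sids = self.sample_ids
        if len(set(sids)) != len(sids):
            raise AtlasValidationError("duplicate sample_id")
        if list(self.beta.index) != ids or list(self.beta.columns) != sids:
            raise AtlasValidationError(
                "beta matrix index/columns do not match block and sample order"
            )
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            r, c = np.argwhere(bad & ~np.isnan(vals))[0]
            raise AtlasValidationError(
                f"beta out of [0, 1] at block {ids[r]!r}, sample {sids[c]!r}: "
                f"{vals[r, c]}"
            )
        if self.coverage is not None:
            if self.coverage.shape != self.beta.shape:
                raise AtlasValidationError("coverage shape differs from beta shape")
            cov = self.coverage.to_numpy(dtype=float)
            if np.any(cov[~np.isnan(cov)] < 0):
                raise AtlasValidationError("negative coverage value")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_atlas(beta_table_path: str | Path, sample_sheet_path: str | Path) -> AtlasMatrix:
    """Read an atlas from its TSV beta table and sample sheet.

    The beta table has columns ``chrom  start  end  block_id`` followed by
    one column per sample; missing betas are ``NA``.  The sample sheet has
    columns ``sample_id  group  replicate``.  Every beta column must match
    a sample-sheet row and vice versa.
    """
    sheet = pd.read_csv(
        sample_sheet_path, sep="\t", dtype={"sample_id": str, "group": str}
    )
    missing_cols = [c for c in _SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise AtlasValidationError(
            f"sample sheet missing column(s): {missing_cols}"
        )
    table = pd.read_csv(
        beta_table_path,
        sep="\t",
        dtype={"chrom": str, "block_id": str},
        na_values=["NA"],
        keep_default_na=False,
    )
    missing_cols = [c for c in _BLOCK_COLUMNS if c not in table.columns]
    if missing_cols:
        raise AtlasValidationError(f"beta table missing column(s): {missing_cols}")

    sample_cols = [c for c in table.columns if c not in _BLOCK_COLUMNS]
    sheet_ids = list(sheet["sample_id"])
    unmatched = sorted(set(sample_cols) - set(sheet_ids))
    if unmatched:
        raise AtlasValidationError(
            f"beta column(s) not present in sample sheet: {unmatched}"
        )
    absent = sorted(set(sheet_ids) - set(sample_cols))
    if absent:
        raise AtlasValidationError(
            f"sample sheet sample(s) missing from beta table: {absent}"
        )

    blocks = [
        GenomicBlock(row.chrom, int(row.start), int(row.end), row.block_id)
        for row in table[_BLOCK_COLUMNS].itertuples(index=False)
    ]
    samples = [
        SampleInfo(str(r.sample_id), str(r.group), int(r.replicate))
        for r in sheet.itertuples(index=False)
    ]
    beta = table[[s.sample_id for s in samples]].astype(float)
    beta.index = pd.Index([b.block_id for b in blocks], name="block_id")
    return AtlasMatrix(blocks=blocks, samples=samples, beta=beta)


def write_atlas(
    atlas: AtlasMatrix,
    beta_table_path: str | Path,
    sample_sheet_path: str | Path,
) -> None:
    """Write an atlas to TSV files readable by :func:`read_atlas`.

    Betas are printed with fixed 6-decimal precision so that
    write -> read -> write is byte-stable.
    """
    fmt = f"%.{BETA_DECIMALS}f"
    header = "\t".join(_BLOCK_COLUMNS + atlas.sample_ids)
    lines = [header]
    vals = atlas.beta.to_numpy(dtype=float)
    for i, b in enumerate(atlas.blocks):
        cells = [
            "NA" if np.isnan(v) else fmt % v for v in vals[i]
        ]
        lines.append(f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\t" + "\t".join(cells)
                     if cells else f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}")
    Path(beta_table_path).write_text("\n".join(lines) + "\n")

    sheet_lines = ["\t".join(_SHEET_COLUMNS)]
    sheet_lines += [f"{s.sample_id}\t{s.group}\t{s.replicate}" for s in atlas.samples]
    Path(sample_sheet_path).write_text("\n".join(sheet_lines) + "\n")


def write_blocks_bed(blocks: Iterable[GenomicBlock], path: str | Path) -> None:
    """Export blocks as a 4-column BED file (chrom, start, end, block_id)."""
    lines = [f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}" for b in blocks]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Replication filter & aggregation
# ---------------------------------------------------------------------------

def _per_group_counts(atlas: AtlasMatrix) -> pd.DataFrame:
    """Non-missing replicate count per (block, group): blocks x groups."""
    groups = atlas.sample_groups
    return atlas.beta.notna().T.groupby(groups).sum().T


def filter_blocks_by_replication(
    atlas: AtlasMatrix,
    min_replicates: int,
    required_groups: Sequence[str] | None = None,
) -> AtlasMatrix:
    """Keep blocks observed in >= ``min_replicates`` samples of EVERY required group.

    This mirrors the pre-screen availability filter applied to the
    multi-tissue atlas: a block is only a candidate marker if its beta is
    measured in enough replicates of every anatomical region.  Sample set
    and block order are preserved.
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    groups = atlas.groups
    if required_groups is None:
        required_groups = groups
    unknown = sorted(set(required_groups) - set(groups))
    if unknown:
        raise AtlasValidationError(f"unknown group(s) in required_groups: {unknown}")
    counts = _per_group_counts(atlas)
    keep = (counts[list(required_groups)] >= min_replicates).all(axis=1)
    keep_ids = set(keep.index[keep])
    blocks = [b for b in atlas.blocks if b.block_id in keep_ids]
    beta = atlas.beta.loc[[b.block_id for b in blocks]]
    cov = (
        atlas.coverage.loc[beta.index] if atlas.coverage is not None else None
    )
    return AtlasMatrix(blocks=blocks, samples=list(atlas.samples), beta=beta, coverage=cov)


def aggregate_by_group(atlas: AtlasMatrix) -> pd.DataFrame:
    """Per-(block, group) replicate count, mean, min and max beta.

    Returns a long DataFrame with columns ``block_id, group,
    n_replicates_observed, mean_beta, min_beta, max_beta, missing`` where
    ``missing`` marks (block, group) cells with zero observations (their
    statistics are NaN, never silently 0).
    """
    groups = atlas.sample_groups
    by = atlas.beta.T.groupby(groups)
    n = by.count().T
    mean = by.mean().T
    lo = by.min().T
    hi = by.max().T
    out = pd.DataFrame(
        {
            "n_replicates_observed": n.stack(),
            "mean_beta": mean.stack(),
            "min_beta": lo.stack(),
            "max_beta": hi.stack(),
        }
    )
    out.index.names = ["block_id", "group"]
    out = out.reset_index()
    out["missing"] = out["n_replicates_observed"] == 0
    return out
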