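"""Per-block NFI normalization and per-group aggregation.

For each block: flagged spots are discarded, each spot's background is
subtracted (per-spot local background by default, or the block-wide mean),
negatives are floored at 0, the replicate median is taken per lectin, and
the medians are closed to fractions of their block sum (NFIs, summing to 1).
Group profiles average block NFIs (sample SD, n-1 denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from glycolect.array_core import Panel, SpotRecord, GroupManifest
from glycolect.errors import DegenerateBlockError, EmptyBlockError

__all__ = [
    "BlockProfile",
    "GroupProfile",
    "subtract_background",
    "block_profile",
    "group_profile",
    "profiles_from_slides",
    "BG_MODES",
]

BG_MODES = ("per-spot", "block-mean")


@dataclass(frozen=True)
class BlockProfile:
    """One block's background-subtracted replicate medians and their NFIs.

    ``missing`` lists panel lectins with no unflagged spot in the block;
    they are excluded from the normalization sum and absent from ``nfi``.
    """

    slide_id: str
    block: int
    net_median: Mapping[str, float]
    nfi: Mapping[str, float]
    missing: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupProfile:
    """Per-group mean/SD of block NFIs; block-level vectors are retained."""

    group_id: str
    mean_nfi: Mapping[str, float]
    sd_nfi: Mapping[str, float]
    n_blocks: int
    block_nfi: Mapping[str, tuple[float, ...]]

    def blocks_for(self, lectin: str) -> np.ndarray:
        return np.asarray(self.block_nfi[lectin], dtype=float)


def subtract_background(spot: SpotRecord, bg_estimate: float) -> float:
    """Net intensity: foreground minus background, floored at 0."""
    return max(0.0, spot.fg_median - bg_estimate)


def block_profile(records: Sequence[SpotRecord], panel: Panel,
                  bg_mode: str = "per-spot") -> BlockProfile:
    """Collapse one block's spots into per-lectin net medians and NFIs.

    ``bg_mode='per-spot'`` subtracts each spot's own local background;
    ``'block-mean'`` subtracts the mean background over the block's
    unflagged spots.
    """
    if bg_mode not in BG_MODES:
        raise ValueError(f"bg_mode must be one of {BG_MODES}, got {bg_mode!r}")
    if not records:
        raise EmptyBlockError("no records supplied")
    keys = {(r.slide_id, r.block) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple blocks: {sorted(keys)}")
    slide_id, block = next(iter(keys))

    good = [r for r in records if not r.is_flagged]
    if not good:
        raise EmptyBlockError(f"{slide_id} block {block}: every spot is flagged")

    block_bg = float(np.mean([r.bg_median for r in good]))

    by_lectin: dict[str, list[float]] = {}
    for r in good:
        bg = r.bg_median if bg_mode == "per-spot" else block_bg
        by_lectin.setdefault(r.lectin, []).append(subtract_background(r, bg))

    net_median: dict[str, float] = {}
    missing: list[str] = []
    for lectin in panel.names:
        nets = by_lectin.get(lectin)
        if not nets:
            missing.append(lectin)
            continue
        net_median[lectin] = float(np.median(nets))
    if missing:
        warnings.warn(
            f"{slide_id} block {block}: no usable spots for {missing}; "
            "excluded from the normalization sum",
            stacklevel=2,
        )

    total = sum(net_median.values())
    if total <= 0:
        raise DegenerateBlockError(
            f"{slide_id} block {block}: all net medians are zero"
        )
    nfi = {lectin: net / total for lectin, net in net_median.items()}
    return BlockProfile(slide_id, block, net_median, nfi, tuple(missing))


def group_profile(blocks: Sequence[BlockProfile], group_id: str) -> GroupProfile:
    """Average block NFIs per lectin (sample SD; missing blocks skipped)."""
    if not blocks:
        raise ValueError(f"group {group_id!r}: no blocks")
    lectins: list[str] = []
    for bp in blocks:
        for lec in bp.nfi:
            if lec not in lectins:
                lectins.append(lec)

    mean_nfi: dict[str, float] = {}
    sd_nfi: dict[str, float] = {}
    block_nfi: dict[str, tuple[float, ...]] = {}
    for lec in lectins:
        vals = np.array([bp.nfi[lec] for bp in blocks if lec in bp.nfi], dtype=float)
        block_nfi[lec] = tuple(float(v) for v in vals)
        mean_nfi[lec] = float(vals.mean())
        sd_nfi[lec] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return GroupProfile(group_id, mean_nfi, sd_nfi, len(blocks), block_nfi)


def split_blocks(records: Iterable[SpotRecord]) -> dict[tuple[str, int], list[SpotRecord]]:
    out: dict[tuple[str, int], list[SpotRecord]] = {}
    for r in records:
        out.setdefault((r.slide_id, r.block), []).append(r)
    return out


def write_profiles(profiles: Mapping[str, "GroupProfile"], path) -> None:
    """Write group profiles as TSV: group, lectin, mean_nfi, sd_nfi, n_blocks."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\tlectin\tmean_nfi\tsd_nfi\tn_blocks\n")
        for gid, prof in profiles.items():
            for lec in prof.mean_nfi:
                fh.write(
                    f"{gid}\t{lec}\t{float(prof.mean_nfi[lec])!r}\t"
                    f"{float(prof.sd_nfi[lec])!r}\t{prof.n_blocks}\n"
                )


def write_block_nfis(profiles: Mapping[str, "GroupProfile"], path) -> None:
    """Long-format block-level NFIs (needed to re-run the t-test from disk)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\tlectin\tblock_index\tnfi\n")
        for gid, prof in profiles.items():
            for lec, vals in prof.block_nfi.items():
                for i, v in enumerate(vals):
                    fh.write(f"{gid}\t{lec}\t{i}\t{float(v)!r}\n")


def read_profiles(path, blocks_path=None) -> dict[str, GroupProfile]:
    """Rebuild GroupProfiles from :func:`write_profiles` output.

    Without ``blocks_path`` the block vectors are empty and p-gated calling
    is impossible (fold-change-only mode).
    """
    import csv

    rows = list(csv.DictReader(open(path, encoding="utf-8"), delimiter="\t"))
    blocks: dict[tuple[str, str], list[float]] = {}
    if blocks_path is not None:
        for r in csv.DictReader(open(blocks_path, encoding="utf-8"), delimiter="\t"):
            blocks.setdefault((r["group"], r["lectin"]), []).append(float(r["nfi"]))
    profiles: dict[str, GroupProfile] = {}
    by_group: dict[str, list[dict]] = {}
    for r in rows:
        by_group.setdefault(r["group"], []).append(r)
    for gid, grows in by_group.items():
        mean_nfi = {r["lectin"]: float(r["mean_nfi"]) for r in grows}
        sd_nfi = {r["lectin"]: float(r["sd_nfi"]) for r in grows}
        n_blocks = int(grows[0]["n_blocks"])
        block_nfi = {
            lec: tuple(blocks.get((gid, lec), ())) for lec in mean_nfi
        }
        profiles[gid] = GroupProfile(gid, mean_nfi, sd_nfi, n_blocks, block_nfi)
    return profiles


def profiles_from_slides(
    slides: Mapping[str, Sequence[SpotRecord]],
    manifests: Sequence[GroupManifest],
    panel: Panel,
    bg_mode: str = "per-spot",
) -> dict[str, GroupProfile]:
    """Run the block → group aggregation for every manifest group."""
    profiles: dict[str, GroupProfile] = {}
    for manifest in manifests:
        blocks: list[BlockProfile] = []
        for slide_id in manifest.slide_ids:
            if slide_id not in slides:
                raise KeyError(f"group {manifest.group_id!r}: slide {slide_id!r} not provided")
            for (_, _), recs in sorted(split_blocks(slides[slide_id]).items()):
                blocks.append(block_profile(recs, panel, bg_mode))
        profiles[manifest.group_id] = group_profile(blocks, manifest.group_id)
    return profiles
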