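"""Promoter-anchored virtual-4C tracks from Hi-C valid read pairs.

Pairs with exactly one end inside a 2 kb window centered on a TSS
contribute their other end to a 10 bp-binned genome-wide track; the raw
track is scaled to counts per million valid pairs, and signal can be
averaged over the top-k interacting regions on a common offset grid.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from hapi.io import GenomicInterval, ValidPair, header_comment

__all__ = [
    "V4CTrack",
    "build_v4c_track",
    "scale_track",
    "average_anchor_signal",
    "write_profile",
]

WINDOW = 2_000
BIN_WIDTH = 10
TOP_K = 50


@dataclass
class V4CTrack:
    """Binned contact signal anchored at one promoter window."""

    anchor_window: GenomicInterval
    bin_width: int = BIN_WIDTH
    bins: dict[tuple[str, int], float] = field(default_factory=dict)
    total_pairs: int = 0
    scaled: bool = False

    def value_at(self, chrom: str, pos: int) -> float:
        bin_start = (pos // self.bin_width) * self.bin_width
        return self.bins.get((chrom, bin_start), 0.0)


def build_v4c_track(
    pairs: Iterable[ValidPair],
    chrom: str,
    tss: int,
    window: int = WINDOW,
    bin_width: int = BIN_WIDTH,
    both_ends_policy: str = "farther",
) -> V4CTrack:
    """Bin the distal ends of pairs anchored in [tss - window/2, tss + window/2).

    ``both_ends_policy`` controls pairs with both ends inside the anchor
    window: "farther" counts the end farther from the TSS once, "drop"
    discards them.  ``total_pairs`` records the full stream length for
    library scaling.
    """
    if window % bin_width != 0 or window % 2 != 0:
        raise ValueError("window must be an even multiple of bin_width")
    if both_ends_policy not in ("farther", "drop"):
        raise ValueError(f"unknown both_ends_policy: {both_ends_policy!r}")
    lo, hi = tss - window // 2, tss + window // 2
    track = V4CTrack(
        anchor_window=GenomicInterval(chrom, max(0, lo), hi),
        bin_width=bin_width,
    )
    total = 0
    for pair in pairs:
        total += 1
        in1 = pair.chrom1 == chrom and lo <= pair.pos1 < hi
        in2 = pair.chrom2 == chrom and lo <= pair.pos2 < hi
        if in1 and in2:
            if both_ends_policy == "drop":
                continue
            if abs(pair.pos1 - tss) >= abs(pair.pos2 - tss):
                other_chrom, other_pos = pair.chrom1, pair.pos1
            else:
                other_chrom, other_pos = pair.chrom2, pair.pos2
        elif in1:
            other_chrom, other_pos = pair.chrom2, pair.pos2
        elif in2:
            other_chrom, other_pos = pair.chrom1, pair.pos1
        else:
            continue
        key = (other_chrom, (other_pos // bin_width) * bin_width)
        track.bins[key] = track.bins.get(key, 0) + 1
    track.total_pairs = total
    return track


def scale_track(track: V4CTrack, per: float = 1e6) -> V4CTrack:
    """Scale every bin by ``per / total_pairs`` (counts per million by default)."""
    if track.scaled:
        raise ValueError("track is already scaled")
    if track.total_pairs <= 0:
        raise ValueError("cannot scale a track with total_pairs = 0")
    factor = per / track.total_pairs
    return replace(
        track,
        bins={k: v * factor for k, v in track.bins.items()},
        scaled=True,
    )


def average_anchor_signal(
    track: V4CTrack,
    regions: Sequence[GenomicInterval],
    ranks: Mapping[GenomicInterval, float],
    k: int = TOP_K,
) -> pd.DataFrame:
    """Mean track signal over the top-k regions, re-centered on region midpoints.

    Regions are ranked by their interaction strength with the anchor
    promoter (``ranks``, e.g. PET counts), ties broken by coordinate.  The
    track is sampled for each selected region on a common offset grid
    spanning the widest selected region, and the per-offset mean and SEM
    are returned as a DataFrame (offset, mean, sem, n).
    """
    if not regions:
        raise ValueError("no regions supplied")
    missing = [r for r in regions if r not in ranks]
    if missing:
        raise ValueError(f"regions without a rank value: {missing[:3]}")
    chroms = {r.chrom for r in regions}
    if len(chroms) > 1:
        raise ValueError(f"regions span multiple chromosomes: {sorted(chroms)}")
    if k > len(regions):
        warnings.warn(
            f"k={k} exceeds the {len(regions)} available regions; using all",
            stacklevel=2,
        )
        k = len(regions)
    selected = sorted(regions, key=lambda r: (-ranks[r], r.chrom, r.start, r.end))[:k]

    bw = track.bin_width
    half_bins = max((r.end - r.start + bw - 1) // (2 * bw) for r in selected)
    offsets = np.arange(-half_bins, half_bins + 1) * bw
    profiles = np.zeros((len(selected), offsets.size))
    for i, region in enumerate(selected):
        center_bin = (int(region.midpoint) // bw) * bw
        for j, off in enumerate(offsets):
            profiles[i, j] = track.bins.get((region.chrom, center_bin + int(off)), 0.0)
    mean = profiles.mean(axis=0)
    if len(selected) > 1:
        sem = profiles.std(axis=0, ddof=1) / np.sqrt(len(selected))
    else:
        sem = np.zeros_like(mean)
    return pd.DataFrame({"offset": offsets, "mean": mean, "sem": sem, "n": len(selected)})


def write_profile(profile: pd.DataFrame, path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(**params) + "\n")
        profile.to_csv(fh, sep="\t", index=False)
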