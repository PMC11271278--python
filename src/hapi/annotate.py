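"""Loop filtering, span classification, and promoter/enhancer annotation.

Loops are filtered on PET support and blacklist overlap, classified by
the distance between anchor midpoints into local (``NORMAL``), long-range
cis (``ABNORMAL_CIS``) and inter-chromosomal (``TRANS``) groups, and their
anchors are annotated as promoters (within +/- 2.5 kb of a TSS) or
enhancers.  Loops with a promoter in exactly one anchor become
enhancer-promoter loops; promoter-promoter and enhancer-enhancer loops
are excluded and counted.
"""

from __future__ import annotations

import enum
import json
from bisect import bisect_right
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from hapi.io import GenomicInterval, Loop, TSSRecord, header_comment

__all__ = [
    "LoopClass",
    "AnchorAnnotation",
    "EPLoop",
    "FilterReport",
    "ExclusionCounts",
    "filter_loops",
    "classify_loop",
    "annotate_anchors",
    "extract_ep_loops",
    "write_annotated_loops",
]

MIN_PETS = 3
PROMOTER_HALFWIDTH = 2_500
MIN_SPAN = 5_000
MAX_NORMAL_SPAN = 2_000_000


class LoopClass(enum.Enum):
    NORMAL = "normal"
    ABNORMAL_CIS = "abnormal_cis"
    TRANS = "trans"
    DROPPED_SHORT = "dropped_short"


@dataclass(frozen=True)
class AnchorAnnotation:
    """Anchor role: PROMOTER iff at least one TSS window overlaps it."""

    genes: frozenset[str] = frozenset()

    @property
    def role(self) -> str:
        return "PROMOTER" if self.genes else "ENHANCER"

    @property
    def is_promoter(self) -> bool:
        return bool(self.genes)


@dataclass(frozen=True)
class EPLoop:
    """One enhancer-promoter loop assigned to one gene."""

    gene: str
    promoter_anchor: GenomicInterval
    enhancer_anchor: GenomicInterval
    pets: int
    loop_class: LoopClass

    def __post_init__(self) -> None:
        if self.loop_class is LoopClass.DROPPED_SHORT:
            raise ValueError("EP loops cannot carry the DROPPED_SHORT class")


@dataclass
class FilterReport:
    input: int = 0
    pet_removed: int = 0
    blacklist_removed: int = 0
    kept: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class ExclusionCounts:
    promoter_promoter: int = 0
    enhancer_enhancer: int = 0
    ep_loops: int = 0
    fanout_genes: int = 0


class _IntervalSet:
    """Merged per-chromosome intervals supporting >= 1 bp overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._merged: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._merged[chrom] = ([s for s, _ in merged], [e for _, e in merged])

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self._merged.get(iv.chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, iv.end - 1) - 1  # last interval starting before iv.end
        return i >= 0 and ends[i] > iv.start


def filter_loops(
    loops: Sequence[Loop],
    blacklist: Iterable[GenomicInterval] = (),
    min_pets: int = MIN_PETS,
) -> tuple[list[Loop], FilterReport]:
    """Drop loops with PETs below ``min_pets`` or an anchor overlapping the blacklist.

    PET filtering is applied first; blacklist removals are counted among
    the PET survivors only, so report reasons plus kept equal the input
    count.
    """
    report = FilterReport(input=len(loops))
    blk = _IntervalSet(blacklist)
    kept: list[Loop] = []
    for loop in loops:
        if loop.pets < min_pets:
            report.pet_removed += 1
        elif blk.overlaps(loop.anchor1) or blk.overlaps(loop.anchor2):
            report.blacklist_removed += 1
        else:
            kept.append(loop)
    report.kept = len(kept)
    return kept, report


def classify_loop(
    loop: Loop,
    min_span: int = MIN_SPAN,
    max_normal_span: int = MAX_NORMAL_SPAN,
) -> LoopClass:
    """Classify one loop by chromosome and midpoint-to-midpoint span.

    Inter-chromosomal loops are TRANS.  Cis loops are NORMAL on the open
    interval (min_span, max_normal_span), ABNORMAL_CIS at or beyond
    max_normal_span, and DROPPED_SHORT at or below min_span
    (self-ligation range).
    """
    if loop.is_trans:
        return LoopClass.TRANS
    span = loop.span
    if span <= min_span:
        return LoopClass.DROPPED_SHORT
    if span < max_normal_span:
        return LoopClass.NORMAL
    return LoopClass.ABNORMAL_CIS


def annotate_anchors(
    loops: Iterable[Loop],
    tss: Sequence[TSSRecord],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> dict[GenomicInterval, AnchorAnnotation]:
    """Annotate every distinct anchor as PROMOTER (with its gene set) or ENHANCER.

    An anchor is a promoter for every gene with a TSS whose window
    ``[tss - hw, tss + hw)`` overlaps the anchor by >= 1 bp.  The role is
    anchor-global: an anchor promoting any gene is a promoter for all
    downstream purposes.
    """
    if not tss:
        raise ValueError("TSS annotation is empty")
    # TSS windows have one fixed width, so both overlap bounds reduce to
    # conditions on the sorted window starts.
    per_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {t.chrom for t in tss}:
        recs = sorted((t.tss - promoter_halfwidth, t.gene) for t in tss if t.chrom == chrom)
        per_chrom[chrom] = (np.array([s for s, _ in recs]), [g for _, g in recs])

    width = 2 * promoter_halfwidth
    annotations: dict[GenomicInterval, AnchorAnnotation] = {}
    anchors = {a for loop in loops for a in (loop.anchor1, loop.anchor2)}
    for anchor in anchors:
        genes: frozenset[str] = frozenset()
        entry = per_chrom.get(anchor.chrom)
        if entry is not None:
            starts, names = entry
            lo = int(np.searchsorted(starts, anchor.start - width, side="right"))
            hi = int(np.searchsorted(starts, anchor.end, side="left"))
            genes = frozenset(names[lo:hi])
        annotations[anchor] = AnchorAnnotation(genes=genes)
    return annotations


def extract_ep_loops(
    loops: Iterable[Loop],
    annotations: Mapping[GenomicInterval, AnchorAnnotation],
    min_span: int = MIN_SPAN,
    max_normal_span: int = MAX_NORMAL_SPAN,
) -> tuple[list[EPLoop], ExclusionCounts]:
    """Keep loops with a promoter in exactly one anchor; fan out per gene.

    Promoter-promoter and enhancer-enhancer loops are excluded and
    counted.  A promoter anchor shared by several genes yields one EPLoop
    per gene, each inheriting the full PET count and the loop class.
    """
    ep: list[EPLoop] = []
    counts = ExclusionCounts()
    for loop in loops:
        try:
            ann1 = annotations[loop.anchor1]
            ann2 = annotations[loop.anchor2]
        except KeyError as exc:
            raise RuntimeError(f"unannotated anchor: {exc.args[0]}") from None
        loop_class = classify_loop(loop, min_span, max_normal_span)
        if loop_class is LoopClass.DROPPED_SHORT:
            raise ValueError("DROPPED_SHORT loop reached EP extraction; drop short loops first")
        if ann1.is_promoter and ann2.is_promoter:
            counts.promoter_promoter += 1
            continue
        if not ann1.is_promoter and not ann2.is_promoter:
            counts.enhancer_enhancer += 1
            continue
        if ann1.is_promoter:
            promoter, enhancer, genes = loop.anchor1, loop.anchor2, ann1.genes
        else:
            promoter, enhancer, genes = loop.anchor2, loop.anchor1, ann2.genes
        counts.ep_loops += 1
        if len(genes) > 1:
            counts.fanout_genes += len(genes) - 1
        for gene in sorted(genes):
            ep.append(EPLoop(gene, promoter, enhancer, loop.pets, loop_class))
    return ep, counts


def write_annotated_loops(
    loops: Sequence[Loop],
    annotations: Mapping[GenomicInterval, AnchorAnnotation],
    path: str | Path,
    min_span: int = MIN_SPAN,
    max_normal_span: int = MAX_NORMAL_SPAN,
    **params,
) -> None:
    """One row per loop: anchors, PETs, span class, anchor roles, gene lists."""
    with open(path, "w") as fh:
        fh.write(header_comment(min_span=min_span, max_normal_span=max_normal_span, **params) + "\n")
        fh.write(
            "chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tpets\tclass\t"
            "role1\tgenes1\trole2\tgenes2\n"
        )
        for loop in loops:
            cls = classify_loop(loop, min_span, max_normal_span)
            ann1 = annotations[loop.anchor1]
            ann2 = annotations[loop.anchor2]
            fh.write(
                f"{loop.anchor1.chrom}\t{loop.anchor1.start}\t{loop.anchor1.end}\t"
                f"{loop.anchor2.chrom}\t{loop.anchor2.start}\t{loop.anchor2.end}\t"
                f"{loop.pets}\t{cls.value}\t"
                f"{ann1.role}\t{','.join(sorted(ann1.genes)) or '.'}\t"
                f"{ann2.role}\t{','.join(sorted(ann2.genes)) or '.'}\n"
            )
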