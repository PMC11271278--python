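"""Quantify where each gene's enhancer activity comes from and flag hijacking.

Per gene, each loop class contributes an activity term
``log10(class PET sum) * class anchor count``; the class fractions of the
term total locate the enhancer activity as local (< 2 Mb cis), long-range
cis (>= 2 Mb) or trans.  Called genes with more than 25% of activity in
trans or long-range cis are enhancer-hijacking candidates.  Contributions
can additionally be partitioned against a donor locus (own / donor /
other enhancers) and annotated with SNP-array copy number.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from hapi.annotate import EPLoop, LoopClass
from hapi.core import GeneProfile, HapiCall
from hapi.io import CNSegment, GenomicInterval, TSSRecord, header_comment

__all__ = [
    "ContributionRecord",
    "LocusPartition",
    "HIJACK_THRESHOLD",
    "HIGH_COPY_LOG2CN",
    "contribution",
    "call_hijacking",
    "partition_by_locus",
    "attach_copy_number",
    "write_contribution_table",
    "write_candidate_table",
    "write_partition_table",
    "write_circos_links",
]

HIJACK_THRESHOLD = 0.25
HIGH_COPY_LOG2CN = 2.0
DONOR_WINDOW = 2_000_000


@dataclass(frozen=True)
class ContributionRecord:
    gene: str
    term_local: float
    term_cis: float
    term_trans: float
    frac_local: float
    frac_cis: float
    frac_trans: float
    is_trans_hijack: bool
    is_cis_hijack: bool
    log2cn: float | None = None
    high_copy: bool = False


@dataclass(frozen=True)
class LocusPartition:
    gene: str
    donor_locus: GenomicInterval
    frac_own: float
    frac_donor: float
    frac_other: float


def _term(pets: int, anchors: int) -> float:
    if anchors == 0 or pets == 0:
        return 0.0
    return math.log10(pets) * anchors


def contribution(profile: GeneProfile, threshold: float = HIJACK_THRESHOLD) -> ContributionRecord:
    """Split one gene's enhancer activity into local / long-range-cis / trans fractions."""
    t_local = _term(profile.pets_local, profile.anchors_local)
    t_cis = _term(profile.pets_cis, profile.anchors_cis)
    t_trans = _term(profile.pets_trans, profile.anchors_trans)
    total = t_local + t_cis + t_trans
    if total > 0:
        f_local, f_cis, f_trans = t_local / total, t_cis / total, t_trans / total
    else:
        f_local = f_cis = f_trans = 0.0
    return ContributionRecord(
        gene=profile.gene,
        term_local=t_local,
        term_cis=t_cis,
        term_trans=t_trans,
        frac_local=f_local,
        frac_cis=f_cis,
        frac_trans=f_trans,
        is_trans_hijack=f_trans > threshold,
        is_cis_hijack=f_cis > threshold,
    )


def call_hijacking(
    records: Iterable[ContributionRecord],
    hapi: Iterable[HapiCall],
) -> pd.DataFrame:
    """Candidate table: called genes with a trans or long-range-cis hijack flag.

    Candidates are labeled trans / cis / both and sorted by their largest
    hijack fraction, descending.  Only genes called in the cohort are
    eligible.
    """
    hapi_genes = {c.gene for c in hapi if c.is_hapi}
    scores = {c.gene: c for c in hapi}
    rows = []
    for rec in records:
        if rec.gene not in hapi_genes:
            continue
        if not (rec.is_trans_hijack or rec.is_cis_hijack):
            continue
        if rec.is_trans_hijack and rec.is_cis_hijack:
            label = "both"
        elif rec.is_trans_hijack:
            label = "trans"
        else:
            label = "cis"
        call = scores[rec.gene]
        rows.append(
            dict(
                gene=rec.gene,
                label=label,
                contact_value=call.contact_value,
                intensity=call.intensity,
                frac_local=rec.frac_local,
                frac_cis=rec.frac_cis,
                frac_trans=rec.frac_trans,
                max_hijack_frac=max(rec.frac_trans, rec.frac_cis),
                log2cn=rec.log2cn,
                high_copy=rec.high_copy,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "label", "contact_value", "intensity", "frac_local",
            "frac_cis", "frac_trans", "max_hijack_frac", "log2cn", "high_copy",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["max_hijack_frac", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def partition_by_locus(
    gene: str,
    ep_loops: Sequence[EPLoop],
    reference_promoter: GenomicInterval,
    window: int = DONOR_WINDOW,
) -> LocusPartition:
    """Partition a gene's enhancer activity into own / donor-locus / other.

    Enhancer anchors within ``window`` of the gene's own (primary)
    promoter midpoint on the same chromosome are "own"; otherwise anchors
    within ``window`` of the reference promoter midpoint (any chromosome)
    are "donor"; the rest are "other".  Own wins when both apply.  Each
    category is weighted as log10(category PET sum) * category anchor
    count before normalizing.
    """
    mine = [lp for lp in ep_loops if lp.gene == gene]
    if not mine:
        raise ValueError(f"gene {gene!r} has no enhancer-promoter loops")

    per_promoter: dict[GenomicInterval, int] = {}
    for lp in mine:
        per_promoter[lp.promoter_anchor] = per_promoter.get(lp.promoter_anchor, 0) + lp.pets
    best = max(per_promoter.values())
    own_promoter = min(
        (p for p, t in per_promoter.items() if t == best),
        key=lambda p: (p.chrom, p.start, p.end),
    )
    ref_mid = reference_promoter.midpoint
    own_mid = own_promoter.midpoint

    cats: dict[str, dict[GenomicInterval, int]] = {"own": {}, "donor": {}, "other": {}}
    for lp in mine:
        if lp.promoter_anchor != own_promoter:
            continue
        e = lp.enhancer_anchor
        if e.chrom == own_promoter.chrom and abs(e.midpoint - own_mid) <= window:
            cat = "own"
        elif e.chrom == reference_promoter.chrom and abs(e.midpoint - ref_mid) <= window:
            cat = "donor"
        else:
            cat = "other"
        cats[cat][e] = cats[cat].get(e, 0) + lp.pets

    terms = {
        cat: _term(sum(anchors.values()), len(anchors)) for cat, anchors in cats.items()
    }
    total = sum(terms.values())
    if total > 0:
        fracs = {cat: t / total for cat, t in terms.items()}
    else:
        fracs = {cat: 0.0 for cat in terms}
    return LocusPartition(
        gene=gene,
        donor_locus=GenomicInterval(
            reference_promoter.chrom,
            max(0, int(ref_mid) - window),
            int(ref_mid) + window,
        ),
        frac_own=fracs["own"],
        frac_donor=fracs["donor"],
        frac_other=fracs["other"],
    )


def attach_copy_number(
    records: Iterable[ContributionRecord],
    segments: Sequence[CNSegment],
    tss: Sequence[TSSRecord],
) -> list[ContributionRecord]:
    """Fill log2cn from the segment containing each gene's primary TSS.

    Segments must come from a single sample.  Genes with multiple TSS
    records use the smallest-coordinate one; genes whose TSS falls in a
    coverage gap keep log2cn missing.  high_copy means log2cn > 2.
    """
    first_tss: dict[str, TSSRecord] = {}
    for rec in sorted(tss, key=lambda t: (t.chrom, t.tss)):
        first_tss.setdefault(rec.gene, rec)

    per_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        per_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in per_chrom.values():
        segs.sort(key=lambda s: s.start)

    out: list[ContributionRecord] = []
    for rec in records:
        t = first_tss.get(rec.gene)
        log2cn = None
        if t is not None:
            for seg in per_chrom.get(t.chrom, ()):
                if seg.contains(t.chrom, t.tss):
                    log2cn = seg.log2cn
                    break
        out.append(
            replace(
                rec,
                log2cn=log2cn,
                high_copy=(log2cn is not None and log2cn > HIGH_COPY_LOG2CN),
            )
        )
    return out


def _fmt_opt(value: float | None) -> str:
    return "NA" if value is None else repr(float(value))


def write_contribution_table(
    records: Sequence[ContributionRecord], path: str | Path, **params
) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(**params) + "\n")
        fh.write(
            "gene\tterm_local\tterm_cis\tterm_trans\tfrac_local\tfrac_cis\t"
            "frac_trans\tis_trans_hijack\tis_cis_hijack\tlog2cn\thigh_copy\n"
        )
        for r in records:
            fh.write(
                f"{r.gene}\t{r.term_local!r}\t{r.term_cis!r}\t{r.term_trans!r}\t"
                f"{r.frac_local!r}\t{r.frac_cis!r}\t{r.frac_trans!r}\t"
                f"{int(r.is_trans_hijack)}\t{int(r.is_cis_hijack)}\t"
                f"{_fmt_opt(r.log2cn)}\t{int(r.high_copy)}\n"
            )


def write_candidate_table(candidates: pd.DataFrame, path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(**params) + "\n")
        candidates.to_csv(fh, sep="\t", index=False, na_rep="NA")


def write_partition_table(
    partitions: Sequence[LocusPartition], path: str | Path, **params
) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(**params) + "\n")
        fh.write("gene\tdonor_chrom\tdonor_start\tdonor_end\tfrac_own\tfrac_donor\tfrac_other\n")
        for p in partitions:
            fh.write(
                f"{p.gene}\t{p.donor_locus.chrom}\t{p.donor_locus.start}\t"
                f"{p.donor_locus.end}\t{p.frac_own!r}\t{p.frac_donor!r}\t{p.frac_other!r}\n"
            )


def write_circos_links(
    ep_loops: Iterable[EPLoop],
    genes: Iterable[str],
    path: str | Path,
    **params,
) -> None:
    """Link file (anchor pair + PETs) for the EP loops of selected genes."""
    wanted = set(genes)
    with open(path, "w") as fh:
        fh.write(header_comment(**params) + "\n")
        fh.write("gene\tchrom1\tstart1\tend1\tchrom2\tstart2\tend2\tpets\tclass\n")
        for lp in ep_loops:
            if lp.gene not in wanted:
                continue
            fh.write(
                f"{lp.gene}\t{lp.promoter_anchor.chrom}\t{lp.promoter_anchor.start}\t"
                f"{lp.promoter_anchor.end}\t{lp.enhancer_anchor.chrom}\t"
                f"{lp.enhancer_anchor.start}\t{lp.enhancer_anchor.end}\t"
                f"{lp.pets}\t{lp.loop_class.value}\n"
            )
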