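"""Per-gene aggregation of enhancer-promoter loops and highly-interactive gene calls.

Each gene is scored twice: the enhancer contact value (number of
distinct enhancer anchors looped to its primary promoter) and the
interaction intensity (summed PETs over those loops).  Ranking all genes
by either score yields a hockey-stick curve whose inflection point —
where a line of slope (max - min) / N is tangent to the sorted curve —
sets the per-cohort cutoff.  Genes at or above both cutoffs are called.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from hapi.annotate import EPLoop, LoopClass
from hapi.io import GenomicInterval, header_comment

__all__ = [
    "GeneProfile",
    "HapiCall",
    "build_gene_profiles",
    "inflection_cutoff",
    "call_hapi_genes",
    "write_hapi_table",
    "read_hapi_table",
    "write_hockey_data",
]

# Classes contributing to gene profiles; NORMAL-span loops are "local".
_PROFILE_CLASSES = (LoopClass.NORMAL, LoopClass.ABNORMAL_CIS, LoopClass.TRANS)


@dataclass
class GeneProfile:
    """Class-wise anchor counts and PET sums at one gene's primary promoter."""

    gene: str
    primary_promoter: GenomicInterval
    anchors_local: int = 0
    pets_local: int = 0
    anchors_cis: int = 0
    pets_cis: int = 0
    anchors_trans: int = 0
    pets_trans: int = 0

    @property
    def contact_value(self) -> int:
        """C: total distinct enhancer anchors over all loop classes."""
        return self.anchors_local + self.anchors_cis + self.anchors_trans

    @property
    def intensity(self) -> int:
        """I: total PETs over all enhancer-promoter loops."""
        return self.pets_local + self.pets_cis + self.pets_trans

    def anchors(self, cls: LoopClass) -> int:
        return {
            LoopClass.NORMAL: self.anchors_local,
            LoopClass.ABNORMAL_CIS: self.anchors_cis,
            LoopClass.TRANS: self.anchors_trans,
        }[cls]

    def pets(self, cls: LoopClass) -> int:
        return {
            LoopClass.NORMAL: self.pets_local,
            LoopClass.ABNORMAL_CIS: self.pets_cis,
            LoopClass.TRANS: self.pets_trans,
        }[cls]


@dataclass(frozen=True)
class HapiCall:
    gene: str
    contact_value: int
    intensity: int
    cutoff_contact: float
    cutoff_intensity: float
    is_hapi: bool


def build_gene_profiles(ep_loops: Iterable[EPLoop]) -> list[GeneProfile]:
    """Aggregate EP loops per gene at its primary promoter anchor.

    For genes with several promoter anchors, only loops at the anchor with
    the largest total PET sum count; ties break toward the smallest
    coordinate.  Within each loop class, an enhancer anchor connected by
    several loops is counted once, with its PETs summed.
    """
    by_gene: dict[str, dict[GenomicInterval, list[EPLoop]]] = {}
    for lp in ep_loops:
        by_gene.setdefault(lp.gene, {}).setdefault(lp.promoter_anchor, []).append(lp)

    profiles: list[GeneProfile] = []
    for gene in sorted(by_gene):
        per_promoter = by_gene[gene]
        totals = {p: sum(lp.pets for lp in loops) for p, loops in per_promoter.items()}
        best = max(totals.values())
        # tie -> smallest-coordinate promoter anchor
        primary = min(
            (p for p, t in totals.items() if t == best),
            key=lambda p: (p.chrom, p.start, p.end),
        )
        profile = GeneProfile(gene=gene, primary_promoter=primary)
        for cls in _PROFILE_CLASSES:
            loops = [lp for lp in per_promoter[primary] if lp.loop_class is cls]
            anchors = {lp.enhancer_anchor for lp in loops}
            pets = sum(lp.pets for lp in loops)
            if cls is LoopClass.NORMAL:
                profile.anchors_local, profile.pets_local = len(anchors), pets
            elif cls is LoopClass.ABNORMAL_CIS:
                profile.anchors_cis, profile.pets_cis = len(anchors), pets
            else:
                profile.anchors_trans, profile.pets_trans = len(anchors), pets
        profiles.append(profile)
    return profiles


def inflection_cutoff(values: Sequence[float] | np.ndarray) -> float:
    """Cutoff at the tangency point of a slope-(max-min)/N line on the sorted curve.

    Sort ascending to v_1..v_N, set s = (max - min) / N, and take the
    value at k = argmin_i (v_i - s*i): sliding the slope-s line up from
    below, this is where it first touches the curve.  Ties break toward
    the largest index (the more stringent cutoff).  A constant list is
    its own cutoff.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("inflection_cutoff requires a non-empty list")
    if v[0] == v[-1]:
        return float(v[0])
    s = (v[-1] - v[0]) / n
    f = v - s * np.arange(1, n + 1)
    k = n - 1 - int(np.argmin(f[::-1]))  # largest index attaining the minimum
    return float(v[k])


def call_hapi_genes(profiles: Sequence[GeneProfile]) -> list[HapiCall]:
    """Call genes whose contact value and intensity both reach the cohort cutoffs."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 gene profiles to derive cutoffs")
    cutoff_c = inflection_cutoff([p.contact_value for p in profiles])
    cutoff_i = inflection_cutoff([p.intensity for p in profiles])
    calls = [
        HapiCall(
            gene=p.gene,
            contact_value=p.contact_value,
            intensity=p.intensity,
            cutoff_contact=cutoff_c,
            cutoff_intensity=cutoff_i,
            is_hapi=(p.contact_value >= cutoff_c and p.intensity >= cutoff_i),
        )
        for p in profiles
    ]
    calls.sort(key=lambda c: (-c.intensity, -c.contact_value, c.gene))
    return calls


def write_hapi_table(
    profiles: Sequence[GeneProfile],
    calls: Sequence[HapiCall],
    path: str | Path,
    **params,
) -> None:
    by_gene = {p.gene: p for p in profiles}
    cutoffs = {}
    if calls:
        cutoffs = dict(
            cutoff_contact=calls[0].cutoff_contact,
            cutoff_intensity=calls[0].cutoff_intensity,
        )
    with open(path, "w") as fh:
        fh.write(header_comment(**cutoffs, **params) + "\n")
        fh.write(
            "gene\tchrom\tpromoter_start\tpromoter_end\t"
            "anchors_local\tpets_local\tanchors_cis\tpets_cis\t"
            "anchors_trans\tpets_trans\tcontact_value\tintensity\t"
            "cutoff_contact\tcutoff_intensity\tis_hapi\n"
        )
        for call in calls:
            p = by_gene[call.gene]
            fh.write(
                f"{p.gene}\t{p.primary_promoter.chrom}\t{p.primary_promoter.start}\t"
                f"{p.primary_promoter.end}\t{p.anchors_local}\t{p.pets_local}\t"
                f"{p.anchors_cis}\t{p.pets_cis}\t{p.anchors_trans}\t{p.pets_trans}\t"
                f"{call.contact_value}\t{call.intensity}\t"
                f"{call.cutoff_contact!r}\t{call.cutoff_intensity!r}\t"
                f"{int(call.is_hapi)}\n"
            )


def read_hapi_table(path: str | Path) -> tuple[list[GeneProfile], list[HapiCall]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles, calls = [], []
    for row in df.itertuples(index=False):
        profiles.append(
            GeneProfile(
                gene=row.gene,
                primary_promoter=GenomicInterval(row.chrom, row.promoter_start, row.promoter_end),
                anchors_local=row.anchors_local,
                pets_local=row.pets_local,
                anchors_cis=row.anchors_cis,
                pets_cis=row.pets_cis,
                anchors_trans=row.anchors_trans,
                pets_trans=row.pets_trans,
            )
        )
        calls.append(
            HapiCall(
                gene=row.gene,
                contact_value=row.contact_value,
                intensity=row.intensity,
                cutoff_contact=row.cutoff_contact,
                cutoff_intensity=row.cutoff_intensity,
                is_hapi=bool(row.is_hapi),
            )
        )
    return profiles, calls


def write_hockey_data(values: Sequence[float], path: str | Path, metric: str, **params) -> None:
    """Emit (rank, value) pairs of the ascending-sorted curve for plotting."""
    v = np.sort(np.asarray(values, dtype=float))
    with open(path, "w") as fh:
        fh.write(header_comment(metric=metric, **params) + "\n")
        fh.write("rank\tvalue\n")
        for i, val in enumerate(v, start=1):
            fh.write(f"{i}\t{val!r}\n")
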