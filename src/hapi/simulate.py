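"""Synthetic fixture generation with implanted, ground-truthed hijacking events.

Generates a toy genome with background genes (few local loops), boosted
genes (many strong local loops that clear both calling cutoffs) and
hijack genes (boosted genes additionally wired in trans to a clustered
donor locus so that their analytic trans fraction exceeds the hijack
threshold by a configurable margin).  Low-PET decoy loops and
blacklist-anchored loops exercise both filter branches.  Every emitted
file parses cleanly through :mod:`hapi.io` and the truth table is
consistent with the loop file by construction.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hapi.io import (
    GenomicInterval,
    Loop,
    TSSRecord,
    header_comment,
    write_bed,
    write_loops,
    write_tss,
)

__all__ = ["HijackEvent", "FixtureConfig", "Fixture", "generate_fixture", "generate_valid_pairs"]

ANCHOR_HALFWIDTH = 1_000
_TSS_CLEARANCE = 4_000  # enhancer centers keep this distance from every TSS


@dataclass(frozen=True)
class HijackEvent:
    """One implanted trans-hijacking gene."""

    gene: str
    donor_chrom: str | None = None  # default: the next chromosome over
    donor_start: int | None = None  # left edge of the 2 Mb donor window
    n_trans_anchors: int = 8
    pet_rate: float = 12.0


@dataclass
class FixtureConfig:
    n_chroms: int = 4
    chrom_length: int = 60_000_000
    n_genes: int = 200
    n_hapi_boosted: int = 10
    hijack_events: tuple[HijackEvent, ...] = ()
    background_anchor_range: tuple[int, int] = (1, 4)
    boosted_anchor_range: tuple[int, int] = (15, 25)
    pet_mean: float = 10.0
    pet_dispersion: float = 3.0
    boosted_pet_mean: float = 14.0
    min_pets: int = 3
    n_decoy_low_pet: int = 20
    n_blacklist: int = 5
    n_blacklisted_loops: int = 10
    hijack_threshold: float = 0.25
    hijack_margin: float = 0.05
    donor_window: int = 2_000_000
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_chroms, self.chrom_length, self.n_genes) <= 0:
            raise ValueError("genome shape and gene counts must be positive")
        if self.hijack_events and self.n_chroms < 2:
            raise ValueError("trans hijack events need >= 2 chromosomes")
        if self.chrom_length < 12_000_000:
            raise ValueError("chrom_length too small for the reserved margins")


@dataclass
class Fixture:
    config: FixtureConfig
    tss_path: Path
    loops_path: Path
    blacklist_path: Path
    seg_path: Path
    truth_path: Path
    truth: pd.DataFrame
    hijack_genes: list[str]
    sample: str = "SIM"


class _Genome:
    def __init__(self, config: FixtureConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
        self.tss_by_chrom: dict[str, list[int]] = {c: [] for c in self.chroms}

    def place_genes(self, names: Sequence[str]) -> list[TSSRecord]:
        cfg = self.config
        margin = 5_000_000
        per_chrom: dict[str, list[str]] = {c: [] for c in self.chroms}
        for i, name in enumerate(names):
            per_chrom[self.chroms[i % len(self.chroms)]].append(name)
        records: list[TSSRecord] = []
        for chrom, gene_names in per_chrom.items():
            if not gene_names:
                continue
            usable = cfg.chrom_length - 2 * margin
            spacing = usable / (len(gene_names) + 1)
            if spacing < 50_000:
                raise ValueError(
                    f"infeasible config: {len(gene_names)} genes on {chrom} "
                    f"leave only {spacing:.0f} bp spacing"
                )
            jitter_max = int(min(10_000, spacing / 4))
            for j, gene in enumerate(gene_names, start=1):
                tss = int(margin + j * spacing) + int(self.rng.integers(-jitter_max, jitter_max + 1))
                strand = "+" if self.rng.random() < 0.5 else "-"
                records.append(TSSRecord(gene=gene, chrom=chrom, tss=tss, strand=strand))
                self.tss_by_chrom[chrom].append(tss)
        for positions in self.tss_by_chrom.values():
            positions.sort()
        return records

    def clear_of_tss(self, chrom: str, pos: int) -> bool:
        positions = self.tss_by_chrom[chrom]
        i = np.searchsorted(positions, pos)
        for j in (i - 1, i):
            if 0 <= j < len(positions) and abs(positions[j] - pos) < _TSS_CLEARANCE:
                return False
        return True

    def sample_enhancer_center(
        self, chrom: str, lo: int, hi: int, used: set[int], tries: int = 200
    ) -> int:
        lo = max(lo, ANCHOR_HALFWIDTH)
        hi = min(hi, self.config.chrom_length - ANCHOR_HALFWIDTH)
        if lo >= hi:
            raise ValueError("infeasible config: enhancer placement range is empty")
        for _ in range(tries):
            pos = int(self.rng.integers(lo, hi))
            if pos not in used and self.clear_of_tss(chrom, pos):
                used.add(pos)
                return pos
        raise ValueError("infeasible config: could not place an enhancer anchor")


def _draw_pets(rng: np.random.Generator, mean: float, dispersion: float, minimum: int) -> int:
    # negative binomial shifted so the loop-level PET filter passes by construction
    excess = max(mean - minimum, 0.5)
    p = dispersion / (dispersion + excess)
    return minimum + int(rng.negative_binomial(dispersion, p))


def _anchor(chrom: str, center: int) -> GenomicInterval:
    return GenomicInterval(chrom, center - ANCHOR_HALFWIDTH, center + ANCHOR_HALFWIDTH)


def _contribution_fracs(
    pets_local: int, anchors_local: int,
    pets_cis: int, anchors_cis: int,
    pets_trans: int, anchors_trans: int,
) -> tuple[float, float, float]:
    def term(pets: int, anchors: int) -> float:
        return math.log10(pets) * anchors if anchors and pets else 0.0

    t = (term(pets_local, anchors_local), term(pets_cis, anchors_cis),
         term(pets_trans, anchors_trans))
    total = sum(t)
    if total == 0:
        return 0.0, 0.0, 0.0
    return t[0] / total, t[1] / total, t[2] / total


def generate_fixture(config: FixtureConfig, outdir: str | Path) -> Fixture:
    """Write TSS, loop, blacklist, SEG and truth files; return paths and truth."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome = _Genome(config, rng)

    bg_names = [f"BG{i:04d}" for i in range(config.n_genes)]
    boost_names = [f"HI{i:03d}" for i in range(config.n_hapi_boosted)]
    hijack_names = [ev.gene for ev in config.hijack_events]
    if len(set(hijack_names)) != len(hijack_names):
        raise ValueError("duplicate gene names in hijack_events")
    tss_records = genome.place_genes(bg_names + boost_names + hijack_names)
    tss_of = {t.gene: t for t in tss_records}

    loops: list[Loop] = []
    truth_rows: list[dict] = []
    # enhancer centers land within +/- 5 kb of the sampled distance; keep the
    # resulting midpoint spans strictly inside the NORMAL range (5 kb, 2 Mb)
    lo_span, hi_span = 12_000, 1_890_000

    def add_local_loops(gene: str, n_anchors: int, pet_mean: float) -> tuple[int, int]:
        rec = tss_of[gene]
        promoter = _anchor(rec.chrom, rec.tss)
        used: set[int] = set()
        total_pets = 0
        for _ in range(n_anchors):
            sign = -1 if rng.random() < 0.5 else 1
            d = int(rng.integers(lo_span, hi_span))
            lo = rec.tss + (d if sign > 0 else -d) - 5_000
            center = genome.sample_enhancer_center(rec.chrom, lo, lo + 10_000, used)
            pets = _draw_pets(rng, pet_mean, config.pet_dispersion, config.min_pets)
            total_pets += pets
            loops.append(Loop(promoter, _anchor(rec.chrom, center), pets))
        return n_anchors, total_pets

    def add_trans_loops(gene: str, event: HijackEvent) -> tuple[int, int, str, int]:
        rec = tss_of[gene]
        promoter = _anchor(rec.chrom, rec.tss)
        donor_chrom = event.donor_chrom
        if donor_chrom is None:
            idx = genome.chroms.index(rec.chrom)
            donor_chrom = genome.chroms[(idx + 1) % len(genome.chroms)]
        if donor_chrom == rec.chrom:
            raise ValueError(f"donor chromosome equals gene chromosome for {gene}")
        donor_start = event.donor_start
        if donor_start is None:
            donor_start = config.chrom_length // 2
        donor_end = donor_start + config.donor_window
        used: set[int] = set()
        anchors, total_pets = 0, 0
        for _ in range(event.n_trans_anchors):
            center = genome.sample_enhancer_center(donor_chrom, donor_start, donor_end, used)
            pets = _draw_pets(rng, event.pet_rate, config.pet_dispersion, config.min_pets)
            loops.append(Loop(promoter, _anchor(donor_chrom, center), pets))
            anchors += 1
            total_pets += pets
        return anchors, total_pets, donor_chrom, donor_start

    for gene in bg_names:
        n = int(rng.integers(config.background_anchor_range[0], config.background_anchor_range[1] + 1))
        a, p = add_local_loops(gene, n, config.pet_mean)
        fl, fc, ft = _contribution_fracs(p, a, 0, 0, 0, 0)
        truth_rows.append(dict(
            gene=gene, chrom=tss_of[gene].chrom, tss=tss_of[gene].tss,
            is_boosted=False, is_hijack=False,
            anchors_local=a, pets_local=p, anchors_cis=0, pets_cis=0,
            anchors_trans=0, pets_trans=0,
            frac_local=fl, frac_cis=fc, frac_trans=ft,
        ))

    for gene in boost_names:
        n = int(rng.integers(config.boosted_anchor_range[0], config.boosted_anchor_range[1] + 1))
        a, p = add_local_loops(gene, n, config.boosted_pet_mean)
        fl, fc, ft = _contribution_fracs(p, a, 0, 0, 0, 0)
        truth_rows.append(dict(
            gene=gene, chrom=tss_of[gene].chrom, tss=tss_of[gene].tss,
            is_boosted=True, is_hijack=False,
            anchors_local=a, pets_local=p, anchors_cis=0, pets_cis=0,
            anchors_trans=0, pets_trans=0,
            frac_local=fl, frac_cis=fc, frac_trans=ft,
        ))

    for event in config.hijack_events:
        gene = event.gene
        n = int(rng.integers(config.boosted_anchor_range[0], config.boosted_anchor_range[1] + 1))
        a_loc, p_loc = add_local_loops(gene, n, config.boosted_pet_mean)
        a_tr, p_tr, donor_chrom, donor_start = add_trans_loops(gene, event)
        # top up trans anchors until the analytic trans fraction clears the
        # hijack threshold with margin
        rec = tss_of[gene]
        promoter = _anchor(rec.chrom, rec.tss)
        used = {lp.anchor2.start + ANCHOR_HALFWIDTH for lp in loops
                if lp.anchor1 == promoter and lp.anchor2.chrom == donor_chrom}
        for _ in range(500):
            _, _, ft = _contribution_fracs(p_loc, a_loc, 0, 0, p_tr, a_tr)
            if ft > config.hijack_threshold + config.hijack_margin:
                break
            center = genome.sample_enhancer_center(
                donor_chrom, donor_start, donor_start + config.donor_window, used
            )
            pets = _draw_pets(rng, event.pet_rate, config.pet_dispersion, config.min_pets)
            loops.append(Loop(promoter, _anchor(donor_chrom, center), pets))
            a_tr += 1
            p_tr += pets
        else:
            raise ValueError(f"infeasible config: cannot reach hijack fraction for {gene}")
        fl, fc, ft = _contribution_fracs(p_loc, a_loc, 0, 0, p_tr, a_tr)
        truth_rows.append(dict(
            gene=gene, chrom=rec.chrom, tss=rec.tss,
            is_boosted=True, is_hijack=True,
            anchors_local=a_loc, pets_local=p_loc, anchors_cis=0, pets_cis=0,
            anchors_trans=a_tr, pets_trans=p_tr,
            frac_local=fl, frac_cis=fc, frac_trans=ft,
        ))

    # blacklist region and loops anchored inside it (survive the PET filter,
    # die to the blacklist filter)
    blacklist: list[GenomicInterval] = []
    for i in range(config.n_blacklist):
        start = 1_000_000 + i * 500_000
        blacklist.append(GenomicInterval(genome.chroms[0], start, start + 10_000))
    for i in range(config.n_blacklisted_loops):
        blk = blacklist[i % len(blacklist)]
        a1 = GenomicInterval(blk.chrom, blk.start + 2_000, blk.start + 4_000)
        far = blk.start + 300_000 + i * 1_000
        a2 = GenomicInterval(blk.chrom, far, far + 2_000)
        loops.append(Loop(a1, a2, _draw_pets(rng, config.pet_mean, config.pet_dispersion, config.min_pets)))

    # low-PET decoys (fail the PET filter); kept away from genes and blacklist
    for i in range(config.n_decoy_low_pet):
        chrom = genome.chroms[i % len(genome.chroms)]
        base = 4_500_000 + (i // len(genome.chroms)) * 20_000
        pets = 1 + int(rng.integers(0, max(config.min_pets - 1, 1)))
        loops.append(Loop(
            GenomicInterval(chrom, base, base + 2_000),
            GenomicInterval(chrom, base + 100_000, base + 102_000),
            pets,
        ))

    order = rng.permutation(len(loops))
    loops = [loops[i] for i in order]

    truth = pd.DataFrame(truth_rows)
    tss_path = outdir / "tss.tsv"
    loops_path = outdir / "loops.bedpe"
    blacklist_path = outdir / "blacklist.bed"
    seg_path = outdir / "copynumber.seg"
    truth_path = outdir / "truth.tsv"

    write_tss(tss_records, tss_path, seed=config.seed)
    write_loops(loops, loops_path, seed=config.seed)
    write_bed(blacklist, blacklist_path, seed=config.seed)
    _write_seg(config, [tss_of[g] for g in hijack_names], seg_path)
    with open(truth_path, "w") as fh:
        fh.write(header_comment(seed=config.seed) + "\n")
        truth.to_csv(fh, sep="\t", index=False)

    return Fixture(
        config=config,
        tss_path=tss_path,
        loops_path=loops_path,
        blacklist_path=blacklist_path,
        seg_path=seg_path,
        truth_path=truth_path,
        truth=truth,
        hijack_genes=list(hijack_names),
    )


def _write_seg(config: FixtureConfig, high_copy_tss: list[TSSRecord], path: Path) -> None:
    """One-sample SEG: 1 Mb high-copy segments around hijack TSSs, background elsewhere."""
    sample = "SIM"
    half = 500_000
    per_chrom: dict[str, list[tuple[int, int, float]]] = {
        f"chr{i + 1}": [] for i in range(config.n_chroms)
    }
    for rec in high_copy_tss:
        start = max(0, rec.tss - half)
        per_chrom[rec.chrom].append((start, min(rec.tss + half, config.chrom_length), 3.0))
    lines = []
    for chrom, highs in per_chrom.items():
        highs.sort()
        cursor = 0
        for start, end, value in highs:
            if cursor < start:
                lines.append((chrom, cursor, start, 0.2))
            lines.append((chrom, start, end, value))
            cursor = end
        if cursor < config.chrom_length:
            lines.append((chrom, cursor, config.chrom_length, 0.2))
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for chrom, start, end, value in lines:
            # SEG is 1-based inclusive
            fh.write(f"{sample}\t{chrom}\t{start + 1}\t{end}\t100\t{value}\n")


def generate_valid_pairs(
    path: str | Path,
    chrom: str,
    tss: int,
    peak_regions: Sequence[GenomicInterval],
    n_pairs: int = 10_000,
    signal_fraction: float = 0.6,
    window: int = 2_000,
    bin_width: int = 10,
    chrom_length: int = 60_000_000,
    seed: int = 0,
) -> tuple[dict[tuple[str, int], int], int]:
    """Write a validPairs file with signal concentrated at the given peaks.

    Signal pairs have one end uniform in the 2 kb anchor window and the
    other uniform inside a randomly chosen peak; background pairs avoid
    the window entirely.  Returns the expected raw per-bin counts (the
    generation ledger) and the total pair count.
    """
    rng = np.random.default_rng(seed)
    lo, hi = tss - window // 2, tss + window // 2
    for region in peak_regions:
        if region.chrom == chrom and region.start < hi and lo < region.end:
            raise ValueError(f"peak {region} overlaps the anchor window")

    ledger: dict[tuple[str, int], int] = {}
    lines: list[str] = []

    def random_outside_window() -> tuple[str, int]:
        while True:
            pos = int(rng.integers(0, chrom_length))
            if not (lo <= pos < hi):
                return chrom, pos

    for i in range(n_pairs):
        if rng.random() < signal_fraction and peak_regions:
            end_a = (chrom, int(rng.integers(lo, hi)))
            peak = peak_regions[int(rng.integers(0, len(peak_regions)))]
            end_b = (peak.chrom, int(rng.integers(peak.start, peak.end)))
            key = (end_b[0], (end_b[1] // bin_width) * bin_width)
            ledger[key] = ledger.get(key, 0) + 1
        else:
            end_a = random_outside_window()
            end_b = random_outside_window()
        if rng.random() < 0.5:
            end_a, end_b = end_b, end_a
        s1 = "+" if rng.random() < 0.5 else "-"
        s2 = "+" if rng.random() < 0.5 else "-"
        lines.append(
            f"r{i}\t{end_a[0]}\t{end_a[1]}\t{s1}\t{end_b[0]}\t{end_b[1]}\t{s2}\tfrag"
        )
    order = rng.permutation(len(lines))
    with open(path, "w") as fh:
        for idx in order:
            fh.write(lines[idx] + "\n")
    return ledger, n_pairs
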