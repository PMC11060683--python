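"""Interval arithmetic over methylation, TE and TFBS tracks.

All interval math is done on BED-style 0-based half-open coordinates; the
1-based inclusive GFF3 coordinates carried by GeneModel are converted exactly
once on entry.  Flanks are strand-aware: upstream is 5' of the TSS and
downstream is 3' of the TES, clipped at chromosome ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlankSpec",
    "gene_flank",
    "region_methylation_mean",
    "te_occupancy",
    "nearest_te_distance",
    "te_pair_features",
    "tfbs_pair_features",
    "breakpoint_te_randomization",
    "merge_intervals",
]

METHYL_CONTEXTS = ("CG", "CHG", "CHH")

#: columns of a methylation site table (DeepSignal-plant-style frequencies)
METHYL_COLUMNS = ["chrom", "position", "strand", "context", "n_methylated", "n_total", "frequency"]

#: columns of a TE interval table (0-based half-open)
TE_COLUMNS = ["chrom", "start", "end", "te_class", "superfamily", "family"]


@dataclass(frozen=True)
class FlankSpec:
    anchor: str  # "upstream" | "downstream"
    width: int

    def __post_init__(self) -> None:
        if self.anchor not in ("upstream", "downstream"):
            raise ValueError("anchor must be 'upstream' or 'downstream'")
        if self.width <= 0:
            raise ValueError("flank width must be positive")


def gene_span0(gene) -> tuple[int, int]:
    """Gene span as 0-based half-open."""
    return gene.start - 1, gene.end


def gene_flank(gene, spec: FlankSpec, chrom_length: Optional[int] = None) -> tuple[int, int]:
    """Strand-aware flank of a gene as a 0-based half-open interval.

    Upstream is 5' of the transcription start, downstream 3' of the end;
    reversing the strand swaps the two exactly.  Clipped to [0, chrom_length).
    """
    s0, e0 = gene_span0(gene)
    five_prime = gene.strand == "+"
    want_left = (spec.anchor == "upstream") == five_prime
    if want_left:
        start, end = s0 - spec.width, s0
    else:
        start, end = e0, e0 + spec.width
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, max(start, end)


def region_methylation_mean(
    sites: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    context: str,
    min_coverage: int = 5,
    coverage_weighted: bool = False,
) -> float:
    """Mean methylation frequency of sites of one context in [start, end).

    Sites with read depth below ``min_coverage`` are excluded (the standard
    >= 5-read site filter).  Returns NaN when no site qualifies.  The default
    is the unweighted mean of per-site frequencies; ``coverage_weighted``
    weights by read depth instead.
    """
    if context not in METHYL_CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    pos0 = sites["position"].to_numpy() - 1  # 1-based site -> 0-based
    mask = (
        (sites["chrom"].to_numpy() == chrom)
        & (pos0 >= start)
        & (pos0 < end)
        & (sites["context"].to_numpy() == context)
        & (sites["n_total"].to_numpy() >= min_coverage)
    )
    sel = sites.loc[mask]
    if sel.empty:
        return float("nan")
    freq = sel["frequency"].to_numpy(dtype=float)
    if coverage_weighted:
        w = sel["n_total"].to_numpy(dtype=float)
        return float(np.average(freq, weights=w))
    return float(freq.mean())


class MethylIndex:
    """Per-(chromosome, context) sorted-position index over a site table.

    Equivalent to :func:`region_methylation_mean` (asserted by tests) but
    O(log n) per query, for feature extraction over many genes.  Sites below
    the coverage floor are dropped at build time.
    """

    def __init__(self, sites: pd.DataFrame, min_coverage: int = 5):
        self.min_coverage = min_coverage
        keep = sites.loc[sites["n_total"] >= min_coverage]
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, context), grp in keep.groupby(["chrom", "context"]):
            order = np.argsort(grp["position"].to_numpy(), kind="stable")
            pos0 = grp["position"].to_numpy()[order] - 1
            freq = grp["frequency"].to_numpy(dtype=float)[order]
            self._index[(chrom, context)] = (pos0, freq)

    def mean(self, chrom: str, intervals, context: str) -> float:
        """Unweighted mean frequency over sites in a union of half-open
        intervals; NaN when no site qualifies."""
        entry = self._index.get((chrom, context))
        if entry is None:
            return float("nan")
        pos, freq = entry
        if isinstance(intervals, tuple) and np.isscalar(intervals[0]):
            intervals = [intervals]
        total = 0.0
        n = 0
        for s, e in merge_intervals(intervals):
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="left")
            if hi > lo:
                total += float(freq[lo:hi].sum())
                n += hi - lo
        return total / n if n else float("nan")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _covered_length(intervals: Iterable[tuple[int, int]], start: int, end: int) -> int:
    total = 0
    for s, e in merge_intervals(intervals):
        total += max(0, min(e, end) - max(s, start))
    return total


def _chrom_tes(tes: pd.DataFrame, chrom: str) -> pd.DataFrame:
    return tes.loc[tes["chrom"] == chrom]


def te_occupancy(flank: tuple[int, int], tes: pd.DataFrame, chrom: str) -> float:
    """Fraction of a half-open window covered by the union of TE intervals."""
    start, end = flank
    if end <= start:
        raise ValueError("flank has non-positive length after clipping")
    sub = _chrom_tes(tes, chrom)
    ivs = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
    return _covered_length(ivs, start, end) / (end - start)


def nearest_te_distance(gene, tes: pd.DataFrame) -> float:
    """bp gap between the gene span and the closest TE on its chromosome.

    0 when a TE overlaps the gene; NaN when the chromosome carries no TE.
    """
    sub = _chrom_tes(tes, gene.chrom)
    if sub.empty:
        return float("nan")
    s0, e0 = gene_span0(gene)
    ts = sub["start"].to_numpy(dtype=int)
    te = sub["end"].to_numpy(dtype=int)
    gap = np.maximum(ts - e0, s0 - te)  # negative or 0 => overlap/adjacency
    return float(max(0, gap.min()))


def _exonic_te_overlap(gene, merged: list[tuple[int, int]], use_introns: bool = False) -> tuple[int, int]:
    """(count of exons|introns overlapping >=1 TE, total TE-overlap bp)."""
    regions = gene.introns if use_introns else gene.exons
    n_hit = 0
    total = 0
    for s1, e1 in regions:  # 1-based inclusive -> half-open
        s0, e0 = s1 - 1, e1
        ov = _covered_length(merged, s0, e0)
        if ov > 0:
            n_hit += 1
        total += ov
    return n_hit, total


@dataclass
class _ChromTes:
    """TE intervals of one chromosome as flat arrays, merged once."""

    starts: np.ndarray
    ends: np.ndarray
    families: np.ndarray

    @classmethod
    def from_table(cls, tes: pd.DataFrame, chrom: str) -> "_ChromTes":
        sub = tes.loc[tes["chrom"] == chrom]
        return cls(
            sub["start"].to_numpy(dtype=int),
            sub["end"].to_numpy(dtype=int),
            sub["family"].to_numpy(dtype=object),
        )

    def merged(self) -> list[tuple[int, int]]:
        return merge_intervals(zip(self.starts, self.ends))

    def occupancy(self, window: tuple[int, int]) -> float:
        s, e = window
        if e <= s:
            raise ValueError("window has non-positive length after clipping")
        return _covered_length(zip(self.starts, self.ends), s, e) / (e - s)

    def family_set(self, windows: Sequence[tuple[int, int]]) -> set[str]:
        hit = np.zeros(len(self.starts), dtype=bool)
        for ws, we in windows:
            hit |= (self.starts < we) & (self.ends > ws)
        return set(self.families[hit].astype(str))

    def nearest_distance(self, span0: tuple[int, int]) -> float:
        if len(self.starts) == 0:
            return float("nan")
        s0, e0 = span0
        gap = np.maximum(self.starts - e0, s0 - self.ends)
        return float(max(0, gap.min()))


def te_pair_features(
    gene_a,
    gene_g,
    tes_a: pd.DataFrame,
    tes_g: pd.DataFrame,
    chrom_lengths_a: Optional[dict[str, int]] = None,
    chrom_lengths_g: Optional[dict[str, int]] = None,
) -> dict[str, float]:
    """The 13 TE occupancy/affinity and TE-in-gene features for one pair.

    Shared/unique TE counts are defined on TE family labels present in the
    upstream-2kb union gene-body region of each allele (haplotype coordinates
    are not directly comparable, so identity is family-level).  All
    between-allele values are absolute differences.
    """
    def clen(lengths, chrom):
        return None if lengths is None else lengths.get(chrom)

    ct_a = _ChromTes.from_table(tes_a, gene_a.chrom)
    ct_g = _ChromTes.from_table(tes_g, gene_g.chrom)
    return _te_features_impl(
        gene_a, gene_g, ct_a, ct_g,
        clen(chrom_lengths_a, gene_a.chrom), clen(chrom_lengths_g, gene_g.chrom),
    )


def _te_features_impl(
    gene_a, gene_g, ct_a: "_ChromTes", ct_g: "_ChromTes",
    clen_a: Optional[int] = None, clen_g: Optional[int] = None,
) -> dict[str, float]:
    occ = {}
    for anchor in ("upstream", "downstream"):
        for width in (2000, 5000, 10000):
            fa = gene_flank(gene_a, FlankSpec(anchor, width), clen_a)
            fg = gene_flank(gene_g, FlankSpec(anchor, width), clen_g)
            occ[f"TE_occupation_{anchor}{width // 1000}kb"] = abs(
                ct_a.occupancy(fa) - ct_g.occupancy(fg)
            )

    da = ct_a.nearest_distance(gene_span0(gene_a))
    dg = ct_g.nearest_distance(gene_span0(gene_g))
    dist = abs(da - dg) if not (np.isnan(da) or np.isnan(dg)) else float("nan")

    up2_a = gene_flank(gene_a, FlankSpec("upstream", 2000), clen_a)
    up2_g = gene_flank(gene_g, FlankSpec("upstream", 2000), clen_g)
    fams_a = ct_a.family_set([up2_a, gene_span0(gene_a)])
    fams_g = ct_g.family_set([up2_g, gene_span0(gene_g)])

    merged_a, merged_g = ct_a.merged(), ct_g.merged()
    exn_a, exl_a = _exonic_te_overlap(gene_a, merged_a, use_introns=False)
    exn_g, exl_g = _exonic_te_overlap(gene_g, merged_g, use_introns=False)
    inn_a, inl_a = _exonic_te_overlap(gene_a, merged_a, use_introns=True)
    inn_g, inl_g = _exonic_te_overlap(gene_g, merged_g, use_introns=True)

    out = {
        "TE_gene_distance": dist,
        "TE_shared_number": float(len(fams_a & fams_g)),
        "TE_unique_number": float(len(fams_a ^ fams_g)),
        "TE_number_inside_exon": float(abs(exn_a - exn_g)),
        "TE_length_inside_exon": float(abs(exl_a - exl_g)),
        "TE_number_inside_intron": float(abs(inn_a - inn_g)),
        "TE_length_inside_intron": float(abs(inl_a - inl_g)),
    }
    out.update(occ)
    return out


def tfbs_pair_features(
    gene_a,
    gene_g,
    hits_a: pd.DataFrame,
    hits_g: pd.DataFrame,
    chrom_length_a: Optional[int] = None,
    chrom_length_g: Optional[int] = None,
    width: int = 2000,
) -> tuple[int, int]:
    """(shared, unique) TFBS motif counts in the strand-aware upstream window.

    Shared is the intersection of the motif-id sets found in each allele's
    upstream ``width`` bp; unique is the symmetric difference.
    """
    def motif_set(gene, hits, clen):
        ws, we = gene_flank(gene, FlankSpec("upstream", width), clen)
        sub = hits.loc[hits["chrom"] == gene.chrom]
        keep = (sub["start"].to_numpy(dtype=int) < we) & (sub["end"].to_numpy(dtype=int) > ws)
        return set(sub.loc[keep, "motif_id"].astype(str))

    ma = motif_set(gene_a, hits_a, chrom_length_a)
    mg = motif_set(gene_g, hits_g, chrom_length_g)
    return len(ma & mg), len(ma ^ mg)


def breakpoint_te_randomization(
    breakpoints: pd.DataFrame,
    tes: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 150,
    n_perm: int = 999,
    seed: int = 0,
    superfamily: Optional[str] = None,
) -> dict:
    """Randomization test: do breakpoint windows overlap TEs more than chance?

    The observed statistic is the number of breakpoint +/- ``window`` bp
    windows overlapping at least one TE (optionally of one superfamily).  The
    null re-places each chromosome's TEs uniformly at random, preserving
    count and length (placed TEs may overlap each other); the empirical
    p-value is (1 + #{null >= observed}) / (n_perm + 1).

    ``breakpoints`` needs columns chrom, position (1-based bp).
    """
    rng = np.random.default_rng(seed)
    sub = tes if superfamily is None else tes.loc[tes["superfamily"] == superfamily]

    windows: dict[str, list[tuple[int, int]]] = {}
    for _, row in breakpoints.iterrows():
        chrom = row["chrom"]
        if chrom not in chrom_lengths:
            raise KeyError(f"breakpoint on unknown chromosome {chrom!r}")
        p0 = int(row["position"]) - 1
        if not (0 <= p0 < chrom_lengths[chrom]):
            raise ValueError(f"breakpoint {chrom}:{row['position']} outside chromosome")
        s = max(0, p0 - window)
        e = min(chrom_lengths[chrom], p0 + window + 1)
        windows.setdefault(chrom, []).append((s, e))

    def count_overlaps(te_by_chrom: dict[str, np.ndarray]) -> int:
        n = 0
        for chrom, wins in windows.items():
            ivs = te_by_chrom.get(chrom)
            if ivs is None or len(ivs) == 0:
                continue
            starts, ends = ivs[:, 0], ivs[:, 1]
            for ws, we in wins:
                if np.any((starts < we) & (ends > ws)):
                    n += 1
        return n

    obs_by_chrom = {
        chrom: grp[["start", "end"]].to_numpy(dtype=int)
        for chrom, grp in sub.groupby("chrom")
    }
    observed = count_overlaps(obs_by_chrom)

    lengths_by_chrom = {
        chrom: (ivs[:, 1] - ivs[:, 0]) for chrom, ivs in obs_by_chrom.items()
    }
    null = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        placed = {}
        for chrom, lens in lengths_by_chrom.items():
            limit = np.maximum(1, chrom_lengths[chrom] - lens)
            starts = (rng.random(len(lens)) * limit).astype(int)
            placed[chrom] = np.column_stack([starts, starts + lens])
        null[k] = count_overlaps(placed)

    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return {
        "observed": int(observed),
        "null": null,
        "p": float(p),
        "n_perm": int(n_perm),
        "n_windows": int(sum(len(v) for v in windows.values())),
        "seed": int(seed),
        "superfamily": superfamily,
    }
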