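"""One-to-one allele pairing between two haplotype gene sets.

Candidate pairs come from reciprocal best hits (RBH) on global protein
alignment of the translated CDS; pairs are then restricted to collinear
chains — maximal runs of consecutive pairs whose gene ordinals on both
haplotypes move monotonically (increasing or decreasing, so inverted blocks
survive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

from .divergence import translate_cds

__all__ = [
    "GeneModel",
    "AllelePair",
    "reciprocal_best_pairs",
    "collinearity_filter",
]


@dataclass(frozen=True)
class GeneModel:
    """One haplotype's gene: 1-based inclusive span and ordered disjoint exons.

    Introns are the gaps between consecutive exons.
    """

    gene_id: str
    haplotype: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)


@dataclass
class AllelePair:
    pair_id: str
    gene_a: str
    gene_g: str
    homology_score: float
    chain_id: Optional[str] = None


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identity(aligner: Align.PairwiseAligner, prot_a: str, prot_g: str) -> float:
    aln = aligner.align(prot_a, prot_g)[0]
    row_a, row_g = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(row_a, row_g) if x == y and x != "-")
    return matches / len(row_a) if row_a else 0.0


def _ordinals(genes: Sequence[GeneModel]) -> dict[str, int]:
    """Genome-wide ordinal rank of each gene (chromosome, then start)."""
    ranked = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    return {g.gene_id: i for i, g in enumerate(ranked)}


def _translated(genes: Sequence[GeneModel], cds_store: dict[str, str]) -> dict[str, str]:
    out = {}
    for g in genes:
        cds = cds_store.get(g.gene_id)
        if not cds:
            warnings.warn(f"{g.gene_id}: no CDS; gene skipped")
            continue
        try:
            out[g.gene_id] = translate_cds(cds, g.gene_id)
        except ValueError as exc:
            warnings.warn(f"{g.gene_id}: untranslatable CDS ({exc}); gene skipped")
    return out


def reciprocal_best_pairs(
    genes_a: Sequence[GeneModel],
    genes_g: Sequence[GeneModel],
    cds_store: dict[str, str],
    same_chrom_groups: Optional[dict[str, str]] = None,
) -> list[AllelePair]:
    """Reciprocal-best-hit allele pairs on translated-CDS similarity.

    Candidates are scored with a global protein alignment (match 1, mismatch
    0, gap open -2, gap extend -0.5); a pair is kept iff each gene is the
    other's best hit.  Ties are broken deterministically by (score, closeness
    of genome-wide ordinal ranks, lexicographic gene id).  The reported
    homology_score is the alignment identity (matches / columns).

    ``same_chrom_groups`` optionally maps chromosome name -> group label for
    both haplotypes; when given, only genes whose chromosomes share a group
    are compared (a large speedup on chromosome-matched assemblies).
    """
    if not genes_a or not genes_g:
        return []
    prot_a = _translated(genes_a, cds_store)
    prot_g = _translated(genes_g, cds_store)
    ids_a = [g.gene_id for g in genes_a if g.gene_id in prot_a]
    ids_g = [g.gene_id for g in genes_g if g.gene_id in prot_g]
    if not ids_a or not ids_g:
        return []
    chrom_of = {g.gene_id: g.chrom for g in list(genes_a) + list(genes_g)}
    rank = _ordinals(list(genes_a))
    rank.update(_ordinals(list(genes_g)))
    aligner = _aligner()

    def compatible(ga: str, gg: str) -> bool:
        if same_chrom_groups is None:
            return True
        return same_chrom_groups.get(chrom_of[ga]) == same_chrom_groups.get(chrom_of[gg])

    scores: dict[tuple[str, str], float] = {}
    for ga in ids_a:
        for gg in ids_g:
            if compatible(ga, gg):
                scores[(ga, gg)] = aligner.score(prot_a[ga], prot_g[gg])

    def best(candidates: Iterable[str], fixed: str, axis: int) -> Optional[str]:
        # higher score wins; then smaller ordinal-rank distance; then lex id
        best_id, best_key = None, None
        for other in candidates:
            key = (ga_gg := (fixed, other) if axis == 0 else (other, fixed))
            if key not in scores:
                continue
            k = (-scores[key], abs(rank[fixed] - rank[other]), other)
            if best_key is None or k < best_key:
                best_key, best_id = k, other
        return best_id

    best_for_a = {ga: best(ids_g, ga, axis=0) for ga in ids_a}
    best_for_g = {gg: best(ids_a, gg, axis=1) for gg in ids_g}

    pairs: list[AllelePair] = []
    for i, ga in enumerate(sorted(ids_a)):
        gg = best_for_a[ga]
        if gg is not None and best_for_g.get(gg) == ga:
            pairs.append(
                AllelePair(
                    pair_id=f"pair{len(pairs):05d}",
                    gene_a=ga,
                    gene_g=gg,
                    homology_score=_identity(aligner, prot_a[ga], prot_g[gg]),
                )
            )
    return pairs


def collinearity_filter(
    pairs: Sequence[AllelePair],
    genes_a: Sequence[GeneModel],
    genes_g: Sequence[GeneModel],
    min_chain: int = 3,
) -> list[AllelePair]:
    """Keep pairs lying in collinear chains of at least ``min_chain`` pairs.

    Pairs are grouped by (chrom_a, chrom_g) and ordered by the A-gene's
    per-chromosome ordinal; a chain extends while the G-ordinals stay strictly
    monotonic in one direction, so fully inverted blocks survive.  Retained
    pairs are labelled with a chain_id.
    """
    by_id_a = {g.gene_id: g for g in genes_a}
    by_id_g = {g.gene_id: g for g in genes_g}
    for p in pairs:
        if p.gene_a not in by_id_a or p.gene_g not in by_id_g:
            raise KeyError(f"pair {p.pair_id} references unknown genes")

    def per_chrom_ordinals(genes: Sequence[GeneModel]) -> dict[str, int]:
        out: dict[str, int] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            for i, g in enumerate(sorted(gs, key=lambda x: (x.start, x.gene_id))):
                out[g.gene_id] = i
        return out

    ord_a = per_chrom_ordinals(genes_a)
    ord_g = per_chrom_ordinals(genes_g)

    groups: dict[tuple[str, str], list[AllelePair]] = {}
    for p in pairs:
        key = (by_id_a[p.gene_a].chrom, by_id_g[p.gene_g].chrom)
        groups.setdefault(key, []).append(p)

    kept: list[AllelePair] = []
    chain_n = 0
    for key in sorted(groups):
        grp = sorted(groups[key], key=lambda p: ord_a[p.gene_a])
        i = 0
        while i < len(grp):
            j = i + 1
            direction = 0  # +1 increasing, -1 decreasing, 0 undecided
            while j < len(grp):
                step = ord_g[grp[j].gene_g] - ord_g[grp[j - 1].gene_g]
                if step == 0:
                    break
                d = 1 if step > 0 else -1
                if direction == 0:
                    direction = d
                elif d != direction:
                    break
                j += 1
            if j - i >= min_chain:
                chain_id = f"chain{chain_n:04d}"
                chain_n += 1
                for p in grp[i:j]:
                    kept.append(
                        AllelePair(p.pair_id, p.gene_a, p.gene_g, p.homology_score, chain_id)
                    )
            i = j
    kept.sort(key=lambda p: p.pair_id)
    return kept
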