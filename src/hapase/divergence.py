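"""Allele-pair sequence divergence: codon alignment, Ka/Ks, structural differences.

Ka and Ks (nonsynonymous/synonymous substitutions per respective site) are
estimated by Nei–Gojobori (1986) pathway counting with equal weights over all
minimal mutational pathways, followed by the Jukes–Cantor multiple-hit
correction d = -(3/4) ln(1 - 4p/3).  Synonymous site fractions come from the
standard genetic code; a substitution creating a stop codon counts as
nonsynonymous for site counting, and pathways passing through a stop codon are
excluded from pathway averaging (falling back to all pathways if every pathway
is blocked).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "DivergenceResult",
    "codon_align",
    "compute_ka_ks",
    "structure_features",
    "translate_cds",
]

_BASES = "TCAG"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _aa(codon: str) -> str:
    """Amino acid for a codon, '*' for stop."""
    codon = codon.upper().replace("U", "T")
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}


def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    Each position contributes the fraction of its three possible point
    mutations that preserve the amino acid; mutations to stop codons are
    nonsynonymous.
    """
    if _aa(codon) == "*":
        raise ValueError(f"stop codon {codon!r} has no site count")
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) != "*" and _aa(mut) == _aa(codon):
                s += 1.0 / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of the differing positions; pathways whose
    intermediate codons are stops are discarded unless every pathway is
    blocked, in which case all pathways are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                blocked = True
            if _aa(nxt) == _aa(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [(s, n) for s, n, b in paths if not b]
    if not usable:
        usable = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute per-codon synonymous sites and pairwise (Sd, Nd) tables."""
    s_sites = np.full(64, np.nan)
    for c, i in _CODON_INDEX.items():
        if _aa(c) != "*":
            s_sites[i] = _syn_sites(c)
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for c1, i in _CODON_INDEX.items():
        if _aa(c1) == "*":
            continue
        for c2, j in _CODON_INDEX.items():
            if _aa(c2) == "*" or j < i:
                continue
            s, n = _pathway_counts(c1, c2)
            sd[i, j] = sd[j, i] = s
            nd[i, j] = nd[j, i] = n
    return s_sites, sd, nd


_S_SITES, _SD, _ND = _build_tables()

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode_codons(seq: str) -> np.ndarray:
    """Codon indices (base-4 over TCAG) for a gapless in-frame sequence."""
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("non-TCAG character in coding sequence")
    codes = codes.reshape(-1, 3)
    return codes[:, 0] * 16 + codes[:, 1] * 4 + codes[:, 2]


@dataclass
class CodonAlignment:
    """A pair of aligned CDS with gaps only in codon-sized, frame-aligned runs."""

    aligned_a: str
    aligned_g: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_g):
            raise ValueError("aligned sequences differ in length")
        if len(self.aligned_a) % 3 != 0:
            raise ValueError("alignment length not a multiple of 3")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a) // 3

    def ungapped_codon_pairs(self) -> list[tuple[str, str]]:
        """Codon columns where neither sequence has a gap."""
        out = []
        for k in range(self.n_columns):
            ca = self.aligned_a[3 * k : 3 * k + 3]
            cg = self.aligned_g[3 * k : 3 * k + 3]
            if "-" not in ca and "-" not in cg:
                out.append((ca, cg))
        return out


@dataclass
class DivergenceResult:
    ka: float
    ks: float
    ratio: Optional[float]
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    saturated: bool = False


def trim_to_codons(cds: str, name: str = "sequence") -> str:
    """Trim 1-2 trailing nucleotides so the length is divisible by 3."""
    extra = len(cds) % 3
    if extra:
        warnings.warn(f"{name}: trimming {extra} trailing nt to restore frame")
        cds = cds[: len(cds) - extra]
    return cds


def translate_cds(cds: str, name: str = "sequence") -> str:
    """Translate a CDS, trimming a partial trailing codon and stripping a
    terminal stop; internal stops raise."""
    cds = trim_to_codons(cds.upper().replace("U", "T"), name)
    if not cds:
        raise ValueError(f"{name}: empty coding sequence")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if _aa(codons[-1]) == "*":
        codons = codons[:-1]
    if not codons:
        raise ValueError(f"{name}: no codons left after stop trimming")
    aas = []
    for k, c in enumerate(codons):
        a = _aa(c)
        if a == "*":
            raise ValueError(f"{name}: internal stop codon at codon {k + 1}")
        aas.append(a)
    return "".join(aas)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def codon_align(cds_a: str, cds_g: str, name_a: str = "A", name_g: str = "G") -> CodonAlignment:
    """Codon-aware alignment: globally align the proteins, then thread the
    nucleotide codons back through the protein gap pattern."""
    cds_a = trim_to_codons(cds_a.upper().replace("U", "T"), name_a)
    cds_g = trim_to_codons(cds_g.upper().replace("U", "T"), name_g)
    prot_a = translate_cds(cds_a, name_a)
    prot_g = translate_cds(cds_g, name_g)
    aln = _protein_aligner().align(prot_a, prot_g)[0]
    row_a, row_g = str(aln[0]), str(aln[1])
    out_a, out_g = [], []
    ia = ig = 0
    for pa, pg in zip(row_a, row_g):
        if pa == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if pg == "-":
            out_g.append("---")
        else:
            out_g.append(cds_g[3 * ig : 3 * ig + 3])
            ig += 1
    return CodonAlignment("".join(out_a), "".join(out_g))


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p <= 0.0:
        return 0.0, False
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def compute_ka_ks(alignment: CodonAlignment) -> DivergenceResult:
    """Nei–Gojobori Ka/Ks with Jukes–Cantor correction on an aligned CDS pair.

    Synonymous site totals are averaged over the two sequences; codon columns
    containing a gap are excluded.  The ratio is None when Ks = 0.
    """
    if "-" not in alignment.aligned_a and "-" not in alignment.aligned_g:
        ia = _encode_codons(alignment.aligned_a)
        ig = _encode_codons(alignment.aligned_g)
        n_pairs = len(ia)
        sa, sg = _S_SITES[ia], _S_SITES[ig]
        if np.isnan(sa).any() or np.isnan(sg).any():
            raise ValueError("stop codon in aligned sequence")
        s_sites = 0.5 * float(sa.sum() + sg.sum())
        sd = float(_SD[ia, ig].sum())
        nd = float(_ND[ia, ig].sum())
    else:
        pairs = alignment.ungapped_codon_pairs()
        if not pairs:
            raise ValueError("no ungapped codon pairs in alignment")
        n_pairs = len(pairs)
        s_a = s_g = sd = nd = 0.0
        for ca, cg in pairs:
            ia, ig = _CODON_INDEX[ca], _CODON_INDEX[cg]
            if np.isnan(_S_SITES[ia]) or np.isnan(_S_SITES[ig]):
                raise ValueError(f"stop codon in aligned pair ({ca}, {cg})")
            s_a += _S_SITES[ia]
            s_g += _S_SITES[ig]
            sd += _SD[ia, ig]
            nd += _ND[ia, ig]
        s_sites = 0.5 * (s_a + s_g)
    n_sites = 3.0 * n_pairs - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jukes_cantor(ps)
    ka, sat_n = _jukes_cantor(pn)
    saturated = sat_s or sat_n
    if saturated or ks == 0.0 or math.isnan(ks):
        ratio = None
    else:
        ratio = ka / ks
    return DivergenceResult(
        ka=ka, ks=ks, ratio=ratio, n_sites=n_sites, s_sites=s_sites,
        nd=nd, sd=sd, saturated=saturated,
    )


def pair_divergence(cds_a: str, cds_g: str, name_a: str = "A", name_g: str = "G") -> DivergenceResult:
    """Convenience wrapper: align two CDS and compute Ka/Ks."""
    return compute_ka_ks(codon_align(cds_a, cds_g, name_a, name_g))


def structure_features(gene_a, gene_g) -> dict[str, float]:
    """Absolute structural differences between the two alleles of a pair.

    Returns gene span length, summed exon length, summed intron length,
    exon count and intron count differences, keyed by catalog feature name.
    """
    def span_len(g):
        return g.end - g.start + 1

    def exon_len(g):
        return sum(e - s + 1 for s, e in g.exons)

    def intron_len(g):
        return span_len(g) - exon_len(g)

    return {
        "Gene_length": float(abs(span_len(gene_a) - span_len(gene_g))),
        "Exon_length": float(abs(exon_len(gene_a) - exon_len(gene_g))),
        "Intron_length": float(abs(intron_len(gene_a) - intron_len(gene_g))),
        "Exon_number": float(abs(len(gene_a.exons) - len(gene_g.exons))),
        "Intron_number": float(abs((len(gene_a.exons) - 1) - (len(gene_g.exons) - 1))),
    }
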