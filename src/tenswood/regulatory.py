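"""Differentially-regulated-gene set logic and cis-element enrichment.

DRGs (differentially regulated genes) are genes with |log2FC| >= 0.5 and
adjusted p < 0.05 in a tension-wood vs normal-wood contrast. Genes that
are DRGs in the wild type but not in the ethylene-insensitive line form
the "ET-dependent" set. Promoters are screened for degenerate IUPAC
cis-elements (the EIN3-like TEIL motif AYGWAYCT, the ERF-bound GCC-box
AGCCGCC, and the ethylene-responsive element ATTTCAAA), and motif
enrichment in a gene set against a universe is scored with a one-sided
hypergeometric test.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MOTIFS = {
    "TEIL": "AYGWAYCT",
    "GCC-box": "AGCCGCC",
    "ERE": "ATTTCAAA",
}


@dataclass
class MotifHit:
    position: int  # 1-based forward-strand start
    strand: str  # '+' or '-'


@dataclass
class EnrichmentResult:
    motif: str
    set_size: int  # n
    universe_size: int  # N
    with_motif_universe: int  # K
    with_motif_set: int  # x
    p_value: float


def classify_drgs(table: pd.DataFrame, lfc_cut: float = 0.5,
                  padj_cut: float = 0.05) -> set[str]:
    """Genes with |log2FC| >= lfc_cut and adjusted p < padj_cut.

    The fold-change bound is inclusive, the p bound strict.
    """
    required = {"gene", "log2FC", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    mask = (table["log2FC"].abs() >= lfc_cut) & (table["padj"] < padj_cut)
    return set(table.loc[mask, "gene"])


def et_dependent(wt_drgs: set[str],
                 eti_drgs: set[str]) -> tuple[set[str], dict[str, set[str]]]:
    """Ethylene-dependent genes: DRGs in the wild type only.

    Returns (wt_only, partition) where partition gives the full Venn split
    into wild-type-only, shared and insensitive-only sets.
    """
    partition = {
        "WT_only": wt_drgs - eti_drgs,
        "shared": wt_drgs & eti_drgs,
        "ETI_only": eti_drgs - wt_drgs,
    }
    return partition["WT_only"], partition


def iupac_to_regex(pattern: str) -> str:
    """Expand an IUPAC pattern to a character-class regex.

    A sequence N matches only the motif symbol N; concrete motif symbols
    never match N in the sequence.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    parts = []
    for sym in pattern.upper():
        if sym not in IUPAC:
            raise ValueError(f"illegal IUPAC symbol {sym!r}")
        opts = IUPAC[sym]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def reverse_complement(pattern: str) -> str:
    return pattern.upper().translate(COMPLEMENT)[::-1]


def scan_motif(sequence: str, motif: str,
               strand: str = "forward") -> list[MotifHit]:
    """All (possibly overlapping) motif matches, 1-based forward coordinates.

    With strand='both', reverse-complement matches are reported at the
    forward-strand position of their leftmost base, flagged strand '-'.
    """
    if strand not in ("forward", "both"):
        raise ValueError("strand must be 'forward' or 'both'")
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains non-ACGTN characters")
    hits = [MotifHit(m.start() + 1, "+")
            for m in re.finditer(f"(?=({iupac_to_regex(motif)}))", seq)]
    if strand == "both":
        rc = iupac_to_regex(reverse_complement(motif))
        hits += [MotifHit(m.start() + 1, "-")
                 for m in re.finditer(f"(?=({rc}))", seq)]
    return sorted(hits, key=lambda h: (h.position, h.strand))


def scan_promoters(promoters: dict[str, str], motif: str,
                   strand: str = "forward") -> dict[str, list[MotifHit]]:
    return {gid: scan_motif(seq, motif, strand)
            for gid, seq in promoters.items()}


def hypergeom_sf_ge(x: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n), exact tail summation.

    Terms are accumulated from log-domain binomial coefficients for
    numerical safety at genome scale.
    """
    if not (0 <= big_k <= big_n and 0 <= n <= big_n):
        raise ValueError("invalid hypergeometric parameters")
    if x <= max(0, n + big_k - big_n):
        return 1.0
    hi = min(n, big_k)
    if x > hi:
        return 0.0

    def log_comb(a: int, b: int) -> float:
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    log_denom = log_comb(big_n, n)
    total = 0.0
    for i in range(x, hi + 1):
        total += math.exp(log_comb(big_k, i) + log_comb(big_n - big_k, n - i)
                          - log_denom)
    return min(total, 1.0)


def motif_enrichment(set_genes: set[str], universe_genes: set[str],
                     has_motif: dict[str, bool],
                     motif: str = "") -> EnrichmentResult:
    """One-sided hypergeometric enrichment of motif presence in a gene set.

    The unit is gene-level presence (at least one hit in the promoter).
    ``set_genes`` must be a subset of ``universe_genes``; ``has_motif``
    indicates presence per universe gene.
    """
    if not set_genes <= universe_genes:
        raise ValueError("gene set is not a subset of the universe")
    big_n = len(universe_genes)
    n = len(set_genes)
    big_k = sum(bool(has_motif.get(g, False)) for g in universe_genes)
    x = sum(bool(has_motif.get(g, False)) for g in set_genes)
    p = hypergeom_sf_ge(x, big_n, big_k, n)
    return EnrichmentResult(motif=motif, set_size=n, universe_size=big_n,
                            with_motif_universe=big_k, with_motif_set=x,
                            p_value=p)
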