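"""Nucleotide diversity (π) for haploid population samples.

π is the unbiased mean pairwise difference per callable site,
``(n/(n-1)) * (1 - Σ p_i²)`` at each site, averaged over all callable
sites of a region (monomorphic sites included in the denominator).  When
no callable mask is supplied, every non-N reference position is assumed
callable with all samples called — the variant-filtering pipeline that
would normally produce a mask is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeneModel, VariantTable
from .siteclass import DegeneracyMap, high_impact_sites

__all__ = [
    "site_pi",
    "DiversityEstimate",
    "region_pi",
    "GeneDiversityRatio",
    "gene_pi_ratio",
    "high_impact_pi",
]


def site_pi(allele_counts, n_called: int | None = None) -> float:
    """Unbiased per-site heterozygosity for haploid samples.

    ``allele_counts`` maps alleles to called counts (or is an array of
    counts).  Sites with fewer than two called alleles are uncallable
    (ValueError): a pairwise difference needs two sequences.
    """
    if hasattr(allele_counts, "values"):
        counts = np.array(list(allele_counts.values()), dtype=float)
    else:
        counts = np.asarray(allele_counts, dtype=float)
    n = float(counts.sum()) if n_called is None else float(n_called)
    if n < 2:
        raise ValueError("site uncallable: fewer than 2 called alleles")
    p = counts / n
    return (n / (n - 1.0)) * (1.0 - float((p**2).sum()))


@dataclass
class DiversityEstimate:
    label: str
    pi: float | None
    callable_sites: int
    segregating_sites: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.pi is not None


def _callable_at(variants: VariantTable, genome, seq_id: str, pos: int) -> bool:
    if variants.callable_mask is not None:
        mask = variants.callable_mask.get(seq_id)
        return bool(mask[pos]) if mask is not None else False
    base = genome[seq_id][pos].upper() if genome is not None else "A"
    return base in "ACGT"


def region_pi(
    sites,
    variants: VariantTable,
    genome=None,
    label: str = "region",
) -> DiversityEstimate:
    """π over a position set; ``sites`` is an iterable of (seq_id, pos).

    Callable monomorphic sites count in the denominator.  Variant sites
    with fewer than two called alleles are excluded from numerator and
    denominator alike.
    """
    total = 0.0
    n_callable = 0
    n_seg = 0
    for seq_id, pos in sites:
        rec = variants.records.get((seq_id, int(pos)))
        if rec is not None:
            _, gt = rec
            called = gt[gt >= 0]
            if called.size < 2:
                continue
            counts = np.bincount(called)
            n_callable += 1
            if (counts > 0).sum() > 1:
                n_seg += 1
                total += site_pi(counts)
        else:
            if _callable_at(variants, genome, seq_id, int(pos)):
                n_callable += 1
    if n_callable == 0:
        return DiversityEstimate(label, None, 0, 0, reason="no callable sites")
    return DiversityEstimate(label, total / n_callable, n_callable, n_seg)


@dataclass
class GeneDiversityRatio:
    gene_id: str
    pi_0d: float | None
    pi_4d: float | None
    ratio: float | None
    l_0d: int
    l_4d: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def gene_pi_ratio(
    gene: GeneModel,
    degeneracy: DegeneracyMap,
    variants: VariantTable,
    genome=None,
) -> GeneDiversityRatio:
    """π0D/π4D for one gene; undefined when π4D = 0 or either L is 0.

    Undefinedness is propagated, not hidden — the coding-potential
    classifier treats undefined ratios as threshold-exceeding.
    """
    est = {}
    for fold in (0, 4):
        pos = degeneracy.positions_with_fold(fold)
        est[fold] = region_pi(
            ((gene.seq_id, p) for p in pos), variants, genome, label=f"{fold}D"
        )
    e0, e4 = est[0], est[4]
    if not e0.defined or not e4.defined:
        reason = "no callable 0D sites" if not e0.defined else "no callable 4D sites"
        return GeneDiversityRatio(
            gene.gene_id,
            e0.pi,
            e4.pi,
            None,
            e0.callable_sites,
            e4.callable_sites,
            reason,
        )
    if e4.pi == 0:
        return GeneDiversityRatio(
            gene.gene_id, e0.pi, e4.pi, None, e0.callable_sites, e4.callable_sites,
            "pi4D is zero",
        )
    return GeneDiversityRatio(
        gene.gene_id,
        e0.pi,
        e4.pi,
        e0.pi / e4.pi,
        e0.callable_sites,
        e4.callable_sites,
    )


def high_impact_pi(
    genes: list[GeneModel], variants: VariantTable, genome
) -> DiversityEstimate:
    """π over the union of high-impact sites of a gene set."""
    sites: set[tuple[str, int]] = set()
    for g in genes:
        sites |= high_impact_sites(g, genome)
    return region_pi(sorted(sites), variants, genome, label="high_impact")
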