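"""Codon usage, correspondence analysis, and an I_TE-like adaptation index.

The adaptation index follows the CAI family but adjusts for background
mutation bias: within each synonymous sub-family the weight of a codon is
its reference-set/background frequency ratio, normalised so the best codon
of the sub-family has weight 1.  Six-codon families (Leu, Ser, Arg) are by
default split into sub-families sharing their first two codon positions,
because tRNA decoding does not cross those boundaries.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .siteclass import BASES, _STOPS, _amino

__all__ = [
    "SENSE_CODONS",
    "subfamily_map",
    "codon_usage",
    "rscu",
    "correspondence_analysis",
    "select_reference_set",
    "ite_weights",
    "ite_score",
]

ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
# 59 codons with a synonymous choice: Met, Trp and stops excluded
SENSE_CODONS = [
    c for c in ALL_CODONS if c not in _STOPS and c not in ("ATG", "TGG")
]


def subfamily_map(split_families: bool = True) -> dict[str, str]:
    """codon → synonymous sub-family id.

    With ``split_families`` the six-codon families break into sub-families
    sharing their first two positions (Leu → TTR + CTN, Ser → TCN + AGY,
    Arg → CGN + AGR); otherwise families are whole amino acids.
    """
    out = {}
    for c in SENSE_CODONS:
        aa = _amino(c)
        out[c] = f"{aa}-{c[:2]}" if split_families else aa
    return out


def codon_usage(genes, genome) -> pd.DataFrame:
    """Per-gene codon counts over the spliced CDS (stop codon excluded).

    The start codon is included (it is never scored downstream anyway).
    Genes with incomplete CDS (length not a multiple of 3) are skipped
    with a warning; codons containing non-ACGT characters are ignored.
    Returns a genes × 59 count matrix.
    """
    rows = {}
    skipped = []
    for g in genes:
        cds = g.spliced_cds(genome).upper()
        if not cds or len(cds) % 3:
            skipped.append(g.gene_id)
            continue
        counts = dict.fromkeys(SENSE_CODONS, 0)
        for i in range(0, len(cds) - 3, 3):  # stop (last codon) excluded
            codon = cds[i : i + 3]
            if codon in counts:
                counts[codon] += 1
        rows[g.gene_id] = counts
    if skipped:
        warnings.warn(f"skipped {len(skipped)} gene(s) with incomplete CDS")
    return pd.DataFrame.from_dict(rows, orient="index", columns=SENSE_CODONS).fillna(0).astype(int)


def rscu(usage: pd.DataFrame, split_families: bool = True) -> pd.DataFrame:
    """Relative synonymous codon usage: count / (sub-family mean count)."""
    fam = subfamily_map(split_families)
    out = pd.DataFrame(np.nan, index=usage.index, columns=usage.columns)
    for sub in sorted(set(fam.values())):
        codons = [c for c in usage.columns if fam[c] == sub]
        block = usage[codons].astype(float)
        mean = block.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[codons] = block.div(mean, axis=0)
    return out


def correspondence_analysis(usage: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Correspondence analysis of a gene × codon count matrix.

    Standardised residuals of the independence model are decomposed by SVD
    and gene (row) principal coordinates are returned, together with the
    per-axis share of total inertia.  Zero-margin rows/columns are dropped
    with a warning.
    """
    mat = usage.astype(float)
    row_ok = mat.sum(axis=1) > 0
    col_ok = mat.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            f"dropping {(~row_ok).sum()} zero row(s), {(~col_ok).sum()} zero column(s)"
        )
        mat = mat.loc[row_ok, col_ok]
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 codons with nonzero totals")
    P = mat.to_numpy() / mat.to_numpy().sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    U, D, Vt = np.linalg.svd(S, full_matrices=False)
    # row principal coordinates
    coords = (U * D) / np.sqrt(r)[:, None]
    n_axes = min(len(D), 10)
    inertia = D**2
    share = inertia / inertia.sum() if inertia.sum() > 0 else inertia
    df = pd.DataFrame(
        coords[:, :n_axes],
        index=mat.index,
        columns=[f"axis{i + 1}" for i in range(n_axes)],
    )
    return df, share[:n_axes]


def select_reference_set(
    coords: pd.DataFrame,
    fraction: float = 0.05,
    marker_genes=None,
    pole: str | None = None,
) -> list[str]:
    """Genes at one extreme of CA axis 1, the putative high-expression set.

    The pole is the one whose extreme-set is more enriched for
    ``marker_genes`` (hypergeometric test), or is given explicitly as
    ``pole`` ('+' or '-').  Set size is ``ceil(fraction * n_genes)``.
    """
    axis = coords["axis1"]
    k = math.ceil(fraction * len(axis))
    hi = list(axis.sort_values(ascending=False).index[:k])
    lo = list(axis.sort_values(ascending=True).index[:k])
    if pole is not None:
        if pole not in ("+", "-"):
            raise ValueError("pole must be '+' or '-'")
        return hi if pole == "+" else lo
    if marker_genes is None:
        raise ValueError("no marker genes given: name the pole explicitly")
    markers = set(marker_genes) & set(axis.index)
    n, m = len(axis), len(markers)
    p_hi = hypergeom.sf(len(markers & set(hi)) - 1, n, m, k)
    p_lo = hypergeom.sf(len(markers & set(lo)) - 1, n, m, k)
    if p_hi == p_lo:
        raise ValueError(
            "marker enrichment identical at both poles: name the pole explicitly"
        )
    return hi if p_hi < p_lo else lo


@dataclass
class WeightTable:
    """Per-codon relative adaptiveness with sub-family bookkeeping."""

    weights: pd.Series  # codon -> weight in (0, 1]
    subfamily: pd.Series  # codon -> sub-family id
    unused_subfamilies: set[str]

    def optimal_codons(self) -> set[str]:
        opt = set()
        for sub in self.subfamily.unique():
            codons = self.subfamily.index[self.subfamily == sub]
            opt.add(self.weights[codons].idxmax())
        return opt


def ite_weights(
    reference_counts: pd.Series,
    background_counts: pd.Series,
    split_families: bool = True,
    pseudocount: float = 0.5,
) -> WeightTable:
    """Mutation-bias-adjusted codon weights from two codon-count vectors.

    For codon ``c`` in sub-family ``F``: ``w_c = r_c / max r``, with
    ``r_c = F_hi(c) / F_bg(c)``, the within-sub-family frequency in the
    highly expressed reference set over that in the background (a mutation
    bias proxy).  The pseudocount is applied only to sub-families with a
    zero count in either set, so weights are exactly invariant to scaling
    the reference counts whenever all codons are observed.  A sub-family
    entirely unused in the reference set gets uniform weight 1 and a flag.
    """
    fam = subfamily_map(split_families)
    codons = [c for c in SENSE_CODONS]
    ref = reference_counts.reindex(codons).fillna(0).astype(float)
    bg = background_counts.reindex(codons).fillna(0).astype(float)
    weights = pd.Series(1.0, index=codons)
    subfam = pd.Series({c: fam[c] for c in codons})
    unused = set()
    for sub in sorted(set(fam.values())):
        members = [c for c in codons if fam[c] == sub]
        if len(members) < 2:
            continue
        if ref[members].sum() == 0:
            unused.add(sub)
            warnings.warn(f"sub-family {sub} unused in reference set; weights = 1")
            continue
        pc = pseudocount if (ref[members] == 0).any() or (bg[members] == 0).any() else 0.0
        f_hi = (ref[members] + pc) / (ref[members] + pc).sum()
        f_bg = (bg[members] + pc) / (bg[members] + pc).sum()
        r = f_hi / f_bg
        weights[members] = r / r.max()
    return WeightTable(weights=weights, subfamily=subfam, unused_subfamilies=unused)


@dataclass
class CodonAdaptationScore:
    gene_id: str
    ite: float | None
    n_codons: int
    reason: str | None = None


def ite_score(gene_counts: pd.Series, table: WeightTable, gene_id: str = "") -> CodonAdaptationScore:
    """Geometric mean of codon weights over a gene's scorable codons.

    Met, Trp and stop codons are never counted (they offer no synonymous
    choice); codons of sub-families unused in the reference set are also
    excluded.  A gene with no scorable codon gets an undefined score.
    """
    total = 0.0
    n = 0
    for codon, count in gene_counts.items():
        if count == 0 or codon not in table.weights.index:
            continue
        if table.subfamily[codon] in table.unused_subfamilies:
            continue
        total += count * math.log(table.weights[codon])
        n += int(count)
    if n == 0:
        return CodonAdaptationScore(gene_id, None, 0, reason="no scorable codons")
    return CodonAdaptationScore(gene_id, math.exp(total / n), n)
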