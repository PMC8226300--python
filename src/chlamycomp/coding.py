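"""Coding-potential audit: control/test partition, score aggregation,
control-derived thresholds, and low-coding-potential classification.

The audit never recomputes the external coding-potential scorer — per-exon
and whole-CDS scores arrive as input.  Genes with neither an ortholog nor
a functional domain form the test set; thresholds on the diversity ratio
(95th control percentile) and the adaptation index (5th control
percentile) are derived from the control distribution of the same run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneEvidence",
    "ClassifierConfig",
    "CodingPotentialCall",
    "partition_genes",
    "aggregate_gene_score",
    "derive_thresholds",
    "classify",
    "audit_report",
]

MIN_EXON_BP = 45  # scorer is only trusted on exons at least this long


@dataclass
class GeneEvidence:
    gene_id: str
    has_ortholog: bool = False
    has_domain: bool = False
    exon_scores: list[tuple[int, float]] = field(default_factory=list)  # (bp, score)
    whole_cds_score: float | None = None
    pi_ratio: float | None = None  # π0D/π4D, None = undefined
    ite: float | None = None
    kozak_score: float | None = None

    @property
    def is_control(self) -> bool:
        return self.has_ortholog or self.has_domain

    @property
    def gene_score(self) -> float:
        return aggregate_gene_score(self.exon_scores, self.whole_cds_score)


def partition_genes(evidence: list[GeneEvidence]) -> tuple[list[GeneEvidence], list[GeneEvidence]]:
    """Split into (control, test): control has an ortholog and/or a domain."""
    control = [e for e in evidence if e.is_control]
    test = [e for e in evidence if not e.is_control]
    return control, test


def aggregate_gene_score(
    exon_scores: list[tuple[int, float]], whole_cds_score: float | None
) -> float:
    """Per-gene coding-potential score from per-exon scores.

    The gene score is the best exon score among exons of at least 45 bp —
    a single misaligned exon should not sink a genuine gene.  With no
    qualifying exon the whole-CDS score stands in; with no alignment at
    all the score is 0 by convention.
    """
    qualifying = [s for bp, s in exon_scores if bp >= MIN_EXON_BP]
    if qualifying:
        return max(qualifying)
    if whole_cds_score is not None:
        return whole_cds_score
    return 0.0


@dataclass
class ClassifierConfig:
    score_cutoff: float = 1.0
    ratio_percentile: float = 95.0
    ite_percentile: float = 5.0
    ratio_threshold: float | None = None
    ite_threshold: float | None = None
    provenance: str = ""


def derive_thresholds(
    control: list[GeneEvidence], config: ClassifierConfig | None = None
) -> ClassifierConfig:
    """Empirical control-set percentiles for the ratio and I_TE thresholds.

    Undefined ratios/scores are excluded from the percentile computation
    (linear interpolation).  Fewer than 20 control genes is an error —
    percentile thresholds from a handful of genes are meaningless.
    """
    config = config or ClassifierConfig()
    if len(control) < 20:
        raise ValueError(f"control set too small ({len(control)} < 20)")
    ratios = [e.pi_ratio for e in control if e.pi_ratio is not None]
    ites = [e.ite for e in control if e.ite is not None]
    if not ratios or not ites:
        raise ValueError("control set has no defined ratios or I_TE values")
    return replace(
        config,
        ratio_threshold=float(np.percentile(ratios, config.ratio_percentile)),
        ite_threshold=float(np.percentile(ites, config.ite_percentile)),
        provenance=(
            f"thresholds from {len(ratios)} control ratios "
            f"(p{config.ratio_percentile:g}) and {len(ites)} control I_TE "
            f"(p{config.ite_percentile:g})"
        ),
    )


@dataclass
class CodingPotentialCall:
    gene_id: str
    gene_set: str  # control | test
    fails: frozenset[str]  # subset of {score, ratio, ite}
    category: str  # lcp1 | lcp2 | other_fail | pass
    flags: frozenset[str] = frozenset()


def classify(
    evidence: list[GeneEvidence], config: ClassifierConfig
) -> list[CodingPotentialCall]:
    """Label every gene; only test genes can be low-coding-potential.

    Failure rules: score strictly below the cutoff (a score of exactly 1
    passes); ratio above the control threshold *or* undefined; I_TE below
    the control threshold or undefined (flagged).  lcp1 = test gene
    failing all three; lcp2 = failing score plus exactly one other.
    """
    if config.ratio_threshold is None or config.ite_threshold is None:
        raise ValueError("thresholds not derived")
    calls = []
    for e in evidence:
        fails = set()
        flags = set()
        if e.gene_score < config.score_cutoff:
            fails.add("score")
        if e.pi_ratio is None:
            fails.add("ratio")
            flags.add("ratio_undefined")
        elif e.pi_ratio > config.ratio_threshold:
            fails.add("ratio")
        if e.ite is None:
            fails.add("ite")
            flags.add("ite_undefined")
        elif e.ite < config.ite_threshold:
            fails.add("ite")
        gene_set = "control" if e.is_control else "test"
        if gene_set == "test" and fails == {"score", "ratio", "ite"}:
            category = "lcp1"
        elif gene_set == "test" and "score" in fails and len(fails) == 2:
            category = "lcp2"
        elif fails:
            category = "other_fail"
        else:
            category = "pass"
        calls.append(
            CodingPotentialCall(
                e.gene_id, gene_set, frozenset(fails), category, frozenset(flags)
            )
        )
    return calls


SUPPLEMENTARY_LABELS = {
    "lcp1": "low_coding_potential_1",
    "lcp2": "low_coding_potential_2",
}


def audit_report(
    calls: list[CodingPotentialCall],
    evidence: list[GeneEvidence],
) -> pd.DataFrame:
    """Per-category summary: counts and medians of the three statistics."""
    ev = {e.gene_id: e for e in evidence}
    rows = []
    by_cat: dict[str, list[CodingPotentialCall]] = {}
    for c in calls:
        by_cat.setdefault(c.category, []).append(c)
    for cat in ("lcp1", "lcp2", "other_fail", "pass"):
        members = by_cat.get(cat, [])
        scores = [ev[c.gene_id].gene_score for c in members]
        ratios = [
            ev[c.gene_id].pi_ratio
            for c in members
            if ev[c.gene_id].pi_ratio is not None
        ]
        ites = [ev[c.gene_id].ite for c in members if ev[c.gene_id].ite is not None]
        kozaks = [
            ev[c.gene_id].kozak_score
            for c in members
            if ev[c.gene_id].kozak_score is not None
        ]
        rows.append(
            {
                "category": cat,
                "n": len(members),
                "n_test": sum(1 for c in members if c.gene_set == "test"),
                "median_score": float(np.median(scores)) if scores else np.nan,
                "median_pi_ratio": float(np.median(ratios)) if ratios else np.nan,
                "median_ite": float(np.median(ites)) if ites else np.nan,
                "median_kozak": float(np.median(kozaks)) if kozaks else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")
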