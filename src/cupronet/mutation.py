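"""Somatic mutation filtering and mutant/wild-type survival contrast.

SNV calls are reduced to a pathogenic subset by four conjunctive rules:

1. deleterious variant classification (missense, nonsense, frame-shift
   ins/del, splice site, in-frame ins/del);
2. variant allele frequency strictly greater than 0.1, computed exactly as
   t_alt_count / t_depth with no rounding;
3. caller FILTER equal to ``PASS``;
4. REVEL ensemble pathogenicity category in the pathogenic bands.

REVEL categorisation uses configurable cut-points; the defaults follow
published clinical-calibration thresholds (supporting/moderate/strong
pathogenic at 0.644 / 0.773 / 0.932; supporting/moderate/strong benign at
0.290 / 0.183 / 0.016).  Scores in the uncategorised middle band — and
calls with no REVEL annotation — are treated as non-pathogenic.  These
cut-points are a calibration choice, not a property of the data; revisit
them for your own cohorts.

Pathogenic SNVs are combined with homozygous copy-number events (deletion
or amplification) to call each (gene, sample) mutant or wild type; a sample
is pooled-mutant when any tested gene is mutant.  Heterozygous CNV events
do not count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import GeneSet, SurvivalTable
from .signature import SurvivalComparison, logrank

__all__ = [
    "DELETERIOUS_CLASSES",
    "RevelCutpoints",
    "revel_category",
    "filter_snvs",
    "MutantStatus",
    "mutant_status",
    "mutation_survival",
]

DELETERIOUS_CLASSES = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Splice_Site",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
})

PATHOGENIC_CATEGORIES = frozenset({
    "supporting_pathogenic", "moderate_pathogenic", "strong_pathogenic",
})

HOMOZYGOUS_CNV = frozenset({"homo_del", "homo_amp"})


@dataclass(frozen=True)
class RevelCutpoints:
    """Score cut-points for the six REVEL evidence bands.

    Pathogenic thresholds are inclusive lower bounds, benign thresholds
    inclusive upper bounds; boundary scores route to the stronger band.
    """

    supporting_pathogenic: float = 0.644
    moderate_pathogenic: float = 0.773
    strong_pathogenic: float = 0.932
    supporting_benign: float = 0.290
    moderate_benign: float = 0.183
    strong_benign: float = 0.016


DEFAULT_CUTPOINTS = RevelCutpoints()


def revel_category(score: float, cuts: RevelCutpoints = DEFAULT_CUTPOINTS) -> str:
    """Map a REVEL score in [0, 1] to one of the six evidence bands.

    Scores between the benign and pathogenic bands fall in an uncategorised
    middle band (returned as ``"uncertain"``, treated as non-pathogenic).
    """
    if np.isnan(score):
        raise ValueError("REVEL score is missing")
    if score < 0 or score > 1:
        raise ValueError(f"REVEL score {score} outside [0, 1]")
    if score >= cuts.strong_pathogenic:
        return "strong_pathogenic"
    if score >= cuts.moderate_pathogenic:
        return "moderate_pathogenic"
    if score >= cuts.supporting_pathogenic:
        return "supporting_pathogenic"
    if score <= cuts.strong_benign:
        return "strong_benign"
    if score <= cuts.moderate_benign:
        return "moderate_benign"
    if score <= cuts.supporting_benign:
        return "supporting_benign"
    return "uncertain"


def filter_snvs(calls: pd.DataFrame,
                deleterious_classes: Iterable[str] = DELETERIOUS_CLASSES,
                vaf_min: float = 0.1,
                cuts: RevelCutpoints = DEFAULT_CUTPOINTS) -> pd.DataFrame:
    """Reduce SNV calls to the pathogenic subset (a pure, idempotent filter).

    Keeps calls whose classification is deleterious, whose VAF
    (t_alt_count / t_depth, exact) strictly exceeds ``vaf_min``, whose
    FILTER is PASS, and whose REVEL category is pathogenic.
    """
    deleterious = frozenset(deleterious_classes)
    vaf = calls["t_alt_count"].to_numpy(dtype=float) / calls["t_depth"].to_numpy(dtype=float)
    revel_ok = np.array([
        (not np.isnan(s)) and revel_category(float(s), cuts) in PATHOGENIC_CATEGORIES
        for s in calls["REVEL"]
    ])
    keep = (
        calls["Variant_Classification"].isin(deleterious).to_numpy()
        & (vaf > vaf_min)
        & (calls["FILTER"] == "PASS").to_numpy()
        & revel_ok
    )
    return calls[keep].reset_index(drop=True)


@dataclass
class MutantStatus:
    """Mutant/WT calls per (gene, sample) and pooled per sample."""

    per_gene: Mapping[tuple, str]
    pooled: pd.Series
    genes: frozenset

    def gene_status(self, gene: str, samples: Iterable[str]) -> pd.Series:
        return pd.Series(
            [self.per_gene.get((gene, s), "WT") for s in samples], index=list(samples)
        )


def mutant_status(snvs: pd.DataFrame, cnvs: pd.DataFrame, genes: GeneSet,
                  samples: Iterable[str] | None = None) -> MutantStatus:
    """Combine pathogenic SNVs with homozygous CNV events into mutant/WT calls.

    A (gene, sample) is mutant when a pathogenic SNV exists there (multiple
    hits count once) or its CNV class is homozygous deletion/amplification.
    The pooled per-sample call is mutant when any tested gene is mutant.
    ``samples``, if given, fixes the pooled universe (absent samples are WT).
    """
    tested = genes.genes
    mutated: set = set()
    if len(snvs):
        sub = snvs[snvs["Hugo_Symbol"].isin(tested)]
        mutated |= set(zip(sub["Hugo_Symbol"], sub["Tumor_Sample_Barcode"]))
    if len(cnvs):
        sub = cnvs[cnvs["gene"].isin(tested) & cnvs["cnv_class"].isin(HOMOZYGOUS_CNV)]
        mutated |= set(zip(sub["gene"], sub["sample_id"]))
    per_gene = {pair: "mutant" for pair in mutated}
    if samples is None:
        samples = sorted({s for _, s in mutated})
    samples = list(samples)
    mutant_samples = {s for _, s in mutated}
    pooled = pd.Series(
        ["mutant" if s in mutant_samples else "WT" for s in samples], index=samples
    )
    return MutantStatus(per_gene=per_gene, pooled=pooled, genes=frozenset(tested))


def mutation_survival(status: MutantStatus, surv: SurvivalTable,
                      per_gene: bool = False):
    """Log-rank contrast of mutant vs wild-type patients.

    Returns a pooled :class:`SurvivalComparison`, or when ``per_gene`` a
    dict gene -> comparison (genes where one group would be empty are
    skipped).  Samples in the survival table but absent from the status
    universe count as wild type.
    """
    labels = status.pooled.reindex(surv.sample_ids).fillna("WT")
    counts = labels.value_counts()
    for grp in ("mutant", "WT"):
        if counts.get(grp, 0) == 0:
            raise ValueError(f"group {grp!r} is empty")
    pooled = logrank(labels, surv)
    if not per_gene:
        return pooled
    out = {}
    for gene in sorted(status.genes):
        glab = status.gene_status(gene, surv.sample_ids)
        vc = glab.value_counts()
        if vc.get("mutant", 0) == 0 or vc.get("WT", 0) == 0:
            continue
        out[gene] = logrank(glab, surv)
    return pooled, out
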