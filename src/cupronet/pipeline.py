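"""End-to-end orchestration: expression cohort -> critical prognostic genes.

One call runs the full chain for a single cancer type: log transform,
differential expression, correlation network restricted to
database-present DEGs, FDR edge filter plus database refinement,
controllability analysis, intersection with the curated list, univariate
Cox screening, direction assignment, and (optionally) median-rule subtype
stratification with a log-rank survival contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import control as ctrl
from .diffexpr import de_test, log_transform, select_degs
from .io import ExpressionMatrix, GeneSet, InteractionDB, SurvivalTable
from .network import GeneNetwork, build_network, pairwise_pcc
from .signature import (SubtypeAssignment, SurvivalComparison, assign_direction,
                        assign_signature_subtype, logrank, median_dichotomize,
                        univariate_cox)

__all__ = ["PipelineResult", "run_pipeline", "stratify_and_test"]


@dataclass
class PipelineResult:
    de: pd.DataFrame
    degs: GeneSet
    network: GeneNetwork
    control: ctrl.ControlResult | None
    critical_curated: frozenset
    cox: pd.DataFrame                      # gene, hazard_ratio, p_value
    prognostic: frozenset                  # critical curated genes with Cox p <= alpha
    direction: dict = field(default_factory=dict)


def run_pipeline(expr: ExpressionMatrix, surv: SurvivalTable, db: InteractionDB,
                 curated: GeneSet, alpha_de: float = 0.05, lfc: float = 1.0,
                 alpha_edge: float = 0.05, alpha_cox: float = 0.05) -> PipelineResult:
    """Run the single-cancer analysis chain and return every intermediate."""
    logm = log_transform(expr) if expr.scale == "counts" else expr
    de = de_test(logm, alpha=alpha_de, lfc=lfc)
    degs = select_degs(de)
    candidates = frozenset(degs.genes) & db.genes & frozenset(logm.gene_ids)
    # correlations are estimated within the tumour cohort: pooling conditions
    # would let the planted mean shifts masquerade as co-expression
    tumour_m = logm.subset_samples(logm.samples_in("tumour"))
    net = build_network(
        pairwise_pcc(tumour_m, GeneSet("candidates", candidates)), db, alpha=alpha_edge
    ) if candidates else GeneNetwork()
    if net.n_nodes >= 2:
        cres = ctrl.critical_nodes(net)
        critical_curated = cres.critical & curated.genes
    else:
        cres = None
        critical_curated = frozenset()
    tumour = logm.subset_samples(surv.sample_ids) if critical_curated else None
    rows, keep = [], []
    for gene in sorted(critical_curated):
        fit = univariate_cox(tumour.values.loc[gene], surv)
        rows.append({"gene": gene, "hazard_ratio": fit.hazard_ratio,
                     "p_value": fit.p_value, "coef": fit.coef})
        if fit.p_value <= alpha_cox:
            keep.append(gene)
    cox = pd.DataFrame(rows, columns=["gene", "hazard_ratio", "p_value", "coef"])
    direction = {g: assign_direction([de.loc[g, "status"]] if g in de.index else [])
                 for g in keep}
    return PipelineResult(de=de, degs=degs, network=net, control=cres,
                          critical_curated=critical_curated, cox=cox,
                          prognostic=frozenset(keep), direction=direction)


def stratify_and_test(expr: ExpressionMatrix, surv: SurvivalTable,
                      up_set: GeneSet, down_set: GeneSet):
    """Median-dichotomize a signature, assign subtypes 1/2/3, run log-rank.

    Returns ``(SubtypeAssignment, SurvivalComparison)`` computed on the
    samples shared between the expression matrix and the survival table.
    """
    logm = log_transform(expr) if expr.scale == "counts" else expr
    samples = [s for s in logm.sample_ids if s in set(surv.sample_ids)]
    sub = logm.subset_samples(samples)
    genes = sorted(up_set.genes | down_set.genes)
    highlow = pd.DataFrame(
        {g: median_dichotomize(sub.values.loc[g]) for g in genes})
    subtypes = assign_signature_subtype(highlow, up_set, down_set)
    comparison = logrank(subtypes, surv.subset(samples))
    return subtypes, comparison
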