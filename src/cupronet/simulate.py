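"""Synthetic tumour/normal cohorts with planted ground truth.

The generator produces every input the pipeline consumes — expression,
condition labels, survival, somatic SNV/CNV tables, an interaction
database and a curated gene list — from one seeded configuration, together
with the planted truth needed to score recovery end to end.

Generative model
----------------
*Expression.*  Latent log2-scale deviations follow a linear structural
equation model over a planted DAG: in topological order,
``z_v = sum_parents w_uv * z_u + Normal(0, noise_sd)``; non-network genes
are independent noise.  Observed log2 expression is ``base_v + z_v`` plus
the planted differential shift for tumour samples, and the emitted matrix
is back-transformed to the count scale (``2**x - 1``).  The DAG restriction
gives exact forward sampling with no equilibrium solving while still
inducing the correlation structure the network stage estimates.

*Survival.*  Tumour patients draw event times from an exponential
proportional-hazards model, ``h = lambda0 * exp(sum_g beta_g * z_g)`` with
z-scored expression, independently censored at Uniform(0, C).

*Mutations.*  Planted pathogenic SNVs (deleterious class, VAF in a passing
range, FILTER PASS, REVEL >= 0.95) arise per (gene, sample) as Bernoulli
draws, accompanied by decoy calls each violating exactly one filter rule;
homozygous CNV events occur at a configured rate.  Optionally the pooled
mutant status feeds back into the survival linear predictor.

A single global seed governs all draws; per-table substreams are derived
deterministically, so identical configurations reproduce identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import control as ctrl
from .io import (ExpressionMatrix, GeneSet, InteractionDB, SurvivalTable,
                 write_expression, write_gmt, write_interactions, write_survival)
from .network import GeneNetwork

__all__ = [
    "SurvivalParams",
    "MutationParams",
    "SimConfig",
    "SimTruth",
    "Cohort",
    "simulate_expression",
    "simulate_survival",
    "simulate_mutations",
    "simulate_cohort",
    "config_from_yaml",
    "default_cohort_config",
    "write_cohort",
]


@dataclass
class SurvivalParams:
    baseline_hazard: float = 0.001        # events per day at eta = 0
    betas: Mapping[str, float] = field(default_factory=dict)
    censor_horizon: float = 3000.0        # days; censoring ~ Uniform(0, C)


@dataclass
class MutationParams:
    genes: list = field(default_factory=list)
    snv_rate: float = 0.0                 # pathogenic SNV prob per (gene, sample)
    cnv_rate: float = 0.0                 # homozygous CNV prob per (gene, sample)
    decoy_rate: float = 0.0               # per-rule decoy prob per (gene, sample)
    mutant_log_hr: float = 0.0            # added to eta for pooled-mutant patients


@dataclass
class SimConfig:
    n_genes: int
    n_tumour: int
    n_normal: int
    planted_network: list = field(default_factory=list)   # (u, v, weight)
    de_genes: Mapping[str, float] = field(default_factory=dict)  # gene -> log2 shift
    noise_sd: float = 0.5
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    mutation: MutationParams = field(default_factory=MutationParams)
    interaction_decoys: list = field(default_factory=list)  # extra null DB pairs
    curated_genes: list = field(default_factory=list)
    cancer_type: str = "SIM"
    seed: int = 0

    @property
    def gene_names(self) -> list:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        universe = set(self.gene_names)
        net_genes = {g for u, v, _ in self.planted_network for g in (u, v)}
        if not net_genes <= universe:
            raise ValueError("planted network refers to genes outside the universe")
        if not set(self.de_genes) <= universe:
            raise ValueError("planted DE genes outside the universe")
        g = nx.DiGraph()
        g.add_weighted_edges_from(self.planted_network)
        if g.number_of_edges() and not nx.is_directed_acyclic_graph(g):
            raise ValueError("planted network must be a DAG")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a generated cohort."""

    de_genes: frozenset
    edges: frozenset                     # unordered planted pairs
    critical_nodes: frozenset            # via the control module on the true graph
    driver_nodes: frozenset
    prognostic: dict                     # gene -> beta
    mutant_samples: frozenset = frozenset()


@dataclass
class Cohort:
    expression: ExpressionMatrix
    survival: SurvivalTable
    maf: pd.DataFrame
    cnv: pd.DataFrame
    db: InteractionDB
    curated: GeneSet
    truth: SimTruth
    config: SimConfig


def _substreams(seed: int, n: int) -> list:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _planted_graph(cfg: SimConfig) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_weighted_edges_from(cfg.planted_network)
    return g


def _truth_network(cfg: SimConfig) -> GeneNetwork:
    """The true graph under the pipeline's antiparallel edge convention."""
    return GeneNetwork.from_edges(
        [(u, v) for u, v, _ in cfg.planted_network], convention="antiparallel_pairs")


def simulate_expression(cfg: SimConfig) -> tuple:
    """Generate a count-scale expression matrix and its planted truth."""
    cfg.validate()
    rng = _substreams(cfg.seed, 4)[0]
    genes = cfg.gene_names
    n = cfg.n_tumour + cfg.n_normal
    samples = [f"S{i:04d}" for i in range(n)]
    condition = pd.Series(["tumour"] * cfg.n_tumour + ["normal"] * cfg.n_normal,
                          index=samples)
    base = rng.uniform(6.0, 10.0, size=len(genes))
    dag = _planted_graph(cfg)
    order = list(nx.topological_sort(dag)) if dag.number_of_nodes() else []
    in_net = set(dag.nodes)
    z = pd.DataFrame(0.0, index=genes, columns=samples)
    for g in genes:
        if g not in in_net:
            z.loc[g] = rng.normal(0.0, cfg.noise_sd, size=n)
    for g in order:
        eps = rng.normal(0.0, cfg.noise_sd, size=n)
        total = eps
        for u in dag.predecessors(g):
            total = total + dag[u][g]["weight"] * z.loc[u].to_numpy()
        z.loc[g] = total
    log2 = z.add(pd.Series(base, index=genes), axis=0)
    tumour_mask = (condition == "tumour").to_numpy()
    for g, shift in cfg.de_genes.items():
        log2.loc[g, tumour_mask] = log2.loc[g, tumour_mask] + shift
    counts = np.clip(np.exp2(log2.to_numpy()) - 1.0, 0.0, None)
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        scale="counts",
        condition=condition,
        cancer_type=pd.Series(cfg.cancer_type, index=samples),
    )
    truth_net = _truth_network(cfg)
    if truth_net.n_nodes >= 2:
        res = ctrl.critical_nodes(truth_net)
        critical, drivers = res.critical, res.driver_nodes
    else:
        critical, drivers = frozenset(), frozenset()
    truth = SimTruth(
        de_genes=frozenset(cfg.de_genes),
        edges=frozenset(frozenset((u, v)) for u, v, _ in cfg.planted_network),
        critical_nodes=critical,
        driver_nodes=drivers,
        prognostic=dict(cfg.survival.betas),
    )
    return expr, truth


def simulate_survival(cfg: SimConfig, expr: ExpressionMatrix,
                      extra_log_hr: pd.Series | None = None) -> SurvivalTable:
    """Exponential proportional-hazards survival for the tumour samples."""
    rng = _substreams(cfg.seed, 4)[1]
    patients = expr.samples_in("tumour")
    if not patients:
        raise ValueError("no tumour samples to assign survival to")
    vals = expr.values[patients]
    if expr.scale == "counts":
        vals = np.log2(vals + 1.0)
    eta = np.zeros(len(patients))
    for gene, beta in cfg.survival.betas.items():
        x = vals.loc[gene].to_numpy(dtype=float)
        sd = x.std()
        zx = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        eta = eta + beta * zx
    if extra_log_hr is not None:
        eta = eta + extra_log_hr.reindex(patients).fillna(0.0).to_numpy()
    rate = cfg.survival.baseline_hazard * np.exp(eta)
    event_t = rng.exponential(1.0 / rate)
    censor_t = rng.uniform(0.0, cfg.survival.censor_horizon, size=len(patients))
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    df = pd.DataFrame({
        "time": time,
        "event": event,
        "age": np.round(rng.normal(60.0, 10.0, size=len(patients)), 1),
        "sex": rng.choice(["female", "male"], size=len(patients)),
        "cancer_type": expr.cancer_type.loc[patients].to_numpy(),
    }, index=pd.Index(patients, name="sample_id"))
    return SurvivalTable(df)


_DECOY_RULES = ("class", "vaf", "filter", "revel")


def simulate_mutations(cfg: SimConfig, samples: Iterable[str]) -> tuple:
    """MAF-like SNV and CNV tables with planted pathogenic calls and decoys.

    Returns ``(maf, cnv, mutant_samples)`` where each decoy SNV violates
    exactly one of the four filter rules and every planted call passes all
    four.  Homozygous CNV events contribute to the truth mutant set;
    heterozygous decoy events do not.
    """
    rng = _substreams(cfg.seed, 4)[2]
    mp = cfg.mutation
    samples = list(samples)
    snv_rows, cnv_rows = [], []
    mutant: set = set()

    def passing_call(gene, sample):
        depth = int(rng.integers(60, 200))
        vaf = rng.uniform(0.2, 0.6)
        return {
            "Hugo_Symbol": gene, "Tumor_Sample_Barcode": sample,
            "Variant_Classification": "Missense_Mutation",
            "t_alt_count": max(int(round(vaf * depth)), 1), "t_depth": depth,
            "FILTER": "PASS", "REVEL": float(rng.uniform(0.95, 1.0)),
        }

    for gene in mp.genes:
        for sample in samples:
            if mp.snv_rate > 0 and rng.random() < mp.snv_rate:
                snv_rows.append(passing_call(gene, sample))
                mutant.add(sample)
            if mp.decoy_rate > 0:
                for rule in _DECOY_RULES:
                    if rng.random() < mp.decoy_rate:
                        row = passing_call(gene, sample)
                        if rule == "class":
                            row["Variant_Classification"] = "Silent"
                        elif rule == "vaf":
                            depth = row["t_depth"]
                            row["t_alt_count"] = max(int(0.05 * depth), 1)
                        elif rule == "filter":
                            row["FILTER"] = "germline_risk"
                        elif rule == "revel":
                            row["REVEL"] = float(rng.uniform(0.30, 0.60))
                        snv_rows.append(row)
            if mp.cnv_rate > 0 and rng.random() < mp.cnv_rate:
                cls = rng.choice(["homo_del", "homo_amp"])
                cnv_rows.append({"gene": gene, "sample_id": sample, "cnv_class": cls})
                mutant.add(sample)
            elif mp.cnv_rate > 0 and rng.random() < mp.cnv_rate:
                cnv_rows.append({"gene": gene, "sample_id": sample,
                                 "cnv_class": rng.choice(["hete_del", "hete_amp"])})
    maf_cols = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
                "t_alt_count", "t_depth", "FILTER", "REVEL"]
    maf = pd.DataFrame(snv_rows, columns=maf_cols)
    cnv = pd.DataFrame(cnv_rows, columns=["gene", "sample_id", "cnv_class"])
    cnv = cnv.drop_duplicates(["gene", "sample_id"])
    return maf, cnv, frozenset(mutant)


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a full cohort: expression, survival, mutations, DB, gene list."""
    expr, truth = simulate_expression(cfg)
    patients = expr.samples_in("tumour")
    maf, cnv, mutant = simulate_mutations(cfg, patients)
    extra = None
    if cfg.mutation.mutant_log_hr and len(mutant):
        extra = pd.Series({s: cfg.mutation.mutant_log_hr for s in mutant})
    surv = simulate_survival(cfg, expr, extra_log_hr=extra)
    truth.mutant_samples = mutant
    db_pairs = [(u, v) for u, v, _ in cfg.planted_network] + list(cfg.interaction_decoys)
    db = InteractionDB(db_pairs)
    curated = GeneSet("curated", frozenset(cfg.curated_genes)) if cfg.curated_genes \
        else GeneSet("curated", truth.critical_nodes or frozenset(cfg.gene_names[:10]))
    return Cohort(expression=expr, survival=surv, maf=maf, cnv=cnv, db=db,
                  curated=curated, truth=truth, config=cfg)


def config_from_yaml(path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML mapping.

    Top-level keys mirror the dataclass fields; ``survival`` and
    ``mutation`` are nested mappings, ``planted_network`` a list of
    ``[source, target, weight]`` triples and ``de_genes`` a mapping
    gene -> log2 shift.
    """
    import yaml
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    surv = SurvivalParams(**(raw.pop("survival", None) or {}))
    mut = MutationParams(**(raw.pop("mutation", None) or {}))
    net = [tuple(e) for e in raw.pop("planted_network", [])]
    decoys = [tuple(e) for e in raw.pop("interaction_decoys", [])]
    return SimConfig(survival=surv, mutation=mut, planted_network=net,
                     interaction_decoys=decoys, **raw)


def default_cohort_config(seed: int = 0, n_tumour: int = 550,
                          n_normal: int = 200) -> SimConfig:
    """The reference synthetic study: a cohort with known critical genes.

    The planted regulatory structure consists of three 6-gene stars (hub ->
    leaves) and three 6-gene chains, weights 0.9 — under the antiparallel
    convention the hubs and chain-internal genes are exactly the critical
    nodes of the true network.  All 36 network genes carry +/-2 log2 tumour
    shifts (so the DE screen admits them), 20 further genes carry shifts
    but no network structure, and the interaction database holds every
    planted pair plus 30 null decoy pairs.  Six critical genes are
    prognostic (beta +/-0.8 on z-scored log2 expression; tumour-up genes
    harmful, tumour-down genes protective); four independent non-network
    genes (G0036/G0038 up-harmful, G0037/G0039 down-protective) form a
    2-up/2-down median-pattern subtype signature; five genes carry planted
    pathogenic mutations with a pooled mutant log-hazard of 0.7.
    """
    genes = [f"G{i:04d}" for i in range(150)]
    edges = []
    # three stars: hub G0000/G0006/G0012 -> five leaves each
    for h in (0, 6, 12):
        for leaf in range(h + 1, h + 6):
            edges.append((genes[h], genes[leaf], 0.9))
    # three chains of six genes
    for start in (18, 24, 30):
        for i in range(start, start + 5):
            edges.append((genes[i], genes[i + 1], 0.9))
    net_genes = [genes[i] for i in range(36)]
    de = {g: (2.0 if i % 2 == 0 else -2.0) for i, g in enumerate(net_genes)}
    de.update({genes[i]: (2.0 if i % 2 == 0 else -2.0) for i in range(36, 56)})
    # prognostic critical genes, one per network component so the hazards of
    # correlated neighbours cannot cancel in the marginal Cox screen:
    # hubs G0000/G0006/G0012, one internal node per chain (G0020/G0026/G0033)
    betas = {"G0000": 0.8, "G0006": -0.8, "G0012": 0.8,
             "G0020": -0.8, "G0026": 0.8, "G0033": -0.8}
    # independent signature genes for the median-pattern subtype rule:
    # tumour-up harmful (G0036, G0038), tumour-down protective (G0037, G0039)
    betas.update({"G0036": 0.8, "G0038": 0.8, "G0037": -0.8, "G0039": -0.8})
    decoys = [(genes[36 + i], genes[40 + i]) for i in range(10)]
    decoys += [(genes[50 + (i % 6)], genes[60 + i]) for i in range(10)]
    decoys += [(genes[70 + i], genes[80 + i]) for i in range(10)]
    curated = list(betas) + [genes[i] for i in (1, 7, 13, 19, 35)] \
        + [genes[i] for i in range(90, 100)]
    return SimConfig(
        n_genes=150,
        n_tumour=n_tumour,
        n_normal=n_normal,
        planted_network=edges,
        de_genes=de,
        noise_sd=0.5,
        survival=SurvivalParams(baseline_hazard=0.001, betas=betas,
                                censor_horizon=3000.0),
        mutation=MutationParams(genes=list(betas)[:5], snv_rate=0.06,
                                cnv_rate=0.02, decoy_rate=0.02,
                                mutant_log_hr=0.7),
        interaction_decoys=decoys,
        curated_genes=curated,
        seed=seed,
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write every cohort table plus the planted truth as TSV/GMT/JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, out / "expression.tsv", out / "condition.tsv")
    write_survival(cohort.survival, out / "survival.tsv")
    cohort.maf.to_csv(out / "mutations.maf.tsv", sep="\t", index=False)
    cohort.cnv.to_csv(out / "cnv.tsv", sep="\t", index=False)
    write_interactions(cohort.db, out / "interactions.tsv")
    write_gmt([cohort.curated], out / "curated.gmt")
    truth = {
        "de_genes": sorted(cohort.truth.de_genes),
        "edges": sorted(sorted(e) for e in cohort.truth.edges),
        "critical_nodes": sorted(cohort.truth.critical_nodes),
        "driver_nodes": sorted(cohort.truth.driver_nodes),
        "prognostic": cohort.truth.prognostic,
        "mutant_samples": sorted(cohort.truth.mutant_samples),
        "seed": cohort.config.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
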