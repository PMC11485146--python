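"""Critical-gene signatures and survival stratification.

This module turns per-cancer controllability results into prognostic gene
signatures:

* intersect the critical nodes of each cancer's network with a curated gene
  list, and aggregate the hits pan-cancer with occurrence counts;
* screen candidates with univariate Cox proportional-hazards regression
  (Wald p <= 0.05);
* assign each gene an up/down regulation direction by strict majority vote
  over the cancer types in which it was identified (non-significant calls
  abstain; ties are left unclassified);
* stratify patients either by spectral clustering on a locally scaled
  similarity kernel built from squared Euclidean distances of signature
  expression, or by median-dichotomized expression patterns (the combined
  high/low rule yielding subtypes 1, 2, and 3);
* compare survival between strata with the log-rank test and Kaplan-Meier
  curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.spatial.distance import squareform, pdist
from scipy.stats import norm
from sklearn.cluster import SpectralClustering

from .control import ControlResult
from .io import ExpressionMatrix, GeneSet, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "CCGCatalog",
    "SubtypeAssignment",
    "SurvivalComparison",
    "CoxFit",
    "intersect_critical",
    "aggregate_pan_cancer",
    "univariate_cox",
    "assign_direction",
    "spectral_stratify",
    "median_dichotomize",
    "assign_signature_subtype",
    "logrank",
]


@dataclass
class CCGCatalog:
    """Critical curated genes per cancer type and pan-cancer."""

    per_cancer: Mapping[str, frozenset]
    pan_cancer: frozenset = field(init=False)
    occurrence: Mapping[str, int] = field(init=False)
    direction: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        union: set = set()
        occ: dict = {}
        for genes in self.per_cancer.values():
            for g in genes:
                occ[g] = occ.get(g, 0) + 1
            union |= set(genes)
        self.pan_cancer = frozenset(union)
        self.occurrence = occ

    @property
    def multi_cancer(self) -> frozenset:
        """Genes identified in two or more cancer types."""
        return frozenset(g for g, k in self.occurrence.items() if k >= 2)


@dataclass
class SubtypeAssignment:
    """Sample -> subtype labels plus a description of the rule that made them."""

    labels: pd.Series
    rule: str = ""

    def __post_init__(self) -> None:
        if self.labels.isna().any():
            raise ValueError("every sample must receive a subtype label")
        self.labels = self.labels.astype(int)

    def counts(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class SurvivalComparison:
    """Log-rank statistic and per-group Kaplan-Meier estimates."""

    groups: list
    chi2: float
    p_value: float
    dof: int
    km: Mapping[object, pd.DataFrame]

    def survival_at(self, group, t: float) -> float:
        """KM survival probability of one group at time t (step function)."""
        curve = self.km[group]
        past = curve[curve["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


class CoxFit(NamedTuple):
    hazard_ratio: float
    p_value: float
    coef: float
    se: float


def intersect_critical(control: ControlResult, curated: GeneSet) -> frozenset:
    """Critical network nodes that are also in the curated gene list."""
    return frozenset(control.critical) & curated.genes


def aggregate_pan_cancer(per_cancer: Mapping[str, Iterable[str]]) -> CCGCatalog:
    """Aggregate per-cancer critical curated genes into a pan-cancer catalog."""
    if not per_cancer:
        raise ValueError("need at least one cancer type")
    return CCGCatalog({c: frozenset(genes) for c, genes in per_cancer.items()})


def univariate_cox(expr_gene: pd.Series, surv: SurvivalTable) -> CoxFit:
    """Single-covariate Cox proportional-hazards fit with a Wald test.

    By convention a constant covariate is uninformative: hazard ratio 1,
    p = 1.  Requires at least 2 observed events.
    """
    common = [s for s in surv.sample_ids if s in expr_gene.index]
    df = pd.DataFrame({
        "time": surv.time.loc[common].astype(float),
        "event": surv.event.loc[common].astype(int),
        "x": expr_gene.loc[common].astype(float),
    })
    if df["event"].sum() < 2:
        raise ValueError("univariate Cox needs at least 2 observed events")
    if df["x"].std() == 0:
        return CoxFit(1.0, 1.0, 0.0, np.inf)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    row = cph.summary.loc["x"]
    return CoxFit(float(np.exp(row["coef"])), float(row["p"]),
                  float(row["coef"]), float(row["se(coef)"]))


def assign_direction(statuses: Iterable[str]) -> str:
    """Majority-vote regulation direction over a gene's cancer types.

    ``statuses`` are the DE status values (up/down/ns) of one gene in each
    cancer type where it was identified as critical.  Non-significant calls
    abstain; a strict majority of the remaining votes decides, otherwise the
    gene is left unclassified (and dropped from directional signatures).
    """
    votes = [s for s in statuses if s in ("up", "down")]
    ups = votes.count("up")
    downs = votes.count("down")
    if ups > downs:
        return "up"
    if downs > ups:
        return "down"
    return "unclassified"


def catalog_directions(catalog: CCGCatalog,
                       de_by_cancer: Mapping[str, pd.DataFrame]) -> dict:
    """Fill a catalog's direction map from per-cancer DE tables."""
    directions = {}
    for gene in catalog.pan_cancer:
        statuses = []
        for cancer, genes in catalog.per_cancer.items():
            if gene in genes and cancer in de_by_cancer:
                de = de_by_cancer[cancer]
                if gene in de.index:
                    statuses.append(de.loc[gene, "status"])
        directions[gene] = assign_direction(statuses)
    catalog.direction.update(directions)
    return directions


# ---------------------------------------------------------------------------
# patient stratification
# ---------------------------------------------------------------------------

def _local_scale_affinity(dist: np.ndarray, n_neighbors: int = 20,
                          mu: float = 0.5) -> np.ndarray:
    """Locally scaled Gaussian-density affinity from a distance matrix.

    The bandwidth for a pair (i, j) averages each sample's mean distance to
    its ``n_neighbors`` nearest neighbours with the pairwise distance
    itself, then scales by ``mu`` — the construction used by
    similarity-network-fusion toolkits for patient clustering.
    """
    d = (dist + dist.T) / 2.0
    np.fill_diagonal(d, 0.0)
    k = min(n_neighbors, d.shape[0] - 1)
    sorted_d = np.sort(d, axis=1)
    means = sorted_d[:, 1:k + 1].mean(axis=1) + np.finfo(float).eps
    sig = (means[:, None] + means[None, :] + d) / 3.0
    dens = norm.pdf(d, loc=0.0, scale=np.maximum(mu * sig, np.finfo(float).tiny))
    w = (dens + dens.T) / 2.0
    return w


def spectral_stratify(m: ExpressionMatrix, k: int = 2, seed: int = 0,
                      n_neighbors: int = 20, mu: float = 0.5) -> SubtypeAssignment:
    """Cluster patients into k groups by spectral clustering.

    Squared Euclidean distances between patients' signature-gene expression
    vectors feed a locally scaled exponential kernel; normalized-Laplacian
    spectral clustering with seeded center initialization assigns groups
    (labels 1..k, arbitrary order).
    """
    if k > m.n_samples:
        raise ValueError("more clusters than samples")
    x = m.values.to_numpy().T  # samples x genes
    sq = squareform(pdist(x, metric="sqeuclidean"))
    affinity = _local_scale_affinity(np.sqrt(sq), n_neighbors=n_neighbors, mu=mu)
    sc = SpectralClustering(n_clusters=k, affinity="precomputed",
                            random_state=seed, assign_labels="kmeans", n_init=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = sc.fit_predict(affinity)
    return SubtypeAssignment(
        pd.Series(labels + 1, index=m.sample_ids),
        rule=f"spectral(k={k}, K={n_neighbors}, mu={mu})",
    )


def median_dichotomize(expr_gene: pd.Series) -> pd.Series:
    """Label samples high/low around the cohort median (ties go low)."""
    if len(expr_gene) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    med = expr_gene.median()
    return pd.Series(np.where(expr_gene > med, "high", "low"), index=expr_gene.index)


def assign_signature_subtype(highlow: pd.DataFrame, up_set: GeneSet,
                             down_set: GeneSet) -> SubtypeAssignment:
    """Combined high/low pattern rule over a tumour-up/tumour-down signature.

    ``highlow`` is a samples x genes frame of "high"/"low" calls (one column
    per dichotomized gene).  Subtype 2 — the good-prognosis pattern — is the
    set of patients high on every tumour-down gene and low on every
    tumour-up gene; subtype 1 is the exact mirror (high on all tumour-up,
    low on all tumour-down); subtype 3 is everyone else.
    """
    if up_set.genes & down_set.genes:
        raise ValueError("up and down gene sets overlap")
    genes = sorted(up_set.genes | down_set.genes)
    missing = [g for g in genes if g not in highlow.columns]
    if missing:
        raise ValueError(f"genes not dichotomized: {', '.join(missing)}")
    up = sorted(up_set.genes)
    down = sorted(down_set.genes)
    is2 = (highlow[down] == "high").all(axis=1) & (highlow[up] == "low").all(axis=1)
    is1 = (highlow[up] == "high").all(axis=1) & (highlow[down] == "low").all(axis=1)
    labels = pd.Series(3, index=highlow.index)
    labels[is1] = 1
    labels[is2] = 2
    return SubtypeAssignment(labels, rule=f"high:{','.join(down)} low:{','.join(up)} -> 2; mirror -> 1; else 3")


def logrank(groups: pd.Series | SubtypeAssignment, surv: SurvivalTable) -> SurvivalComparison:
    """k-group log-rank test plus per-group Kaplan-Meier estimates.

    Empty groups are dropped with a warning; fewer than 2 remaining groups,
    or zero observed events overall, is an error.
    """
    labels = groups.labels if isinstance(groups, SubtypeAssignment) else groups
    common = [s for s in surv.sample_ids if s in labels.index]
    lab = labels.loc[common]
    counts = lab.value_counts()
    keep = list(counts[counts > 0].index)
    if len(keep) < len(counts):
        logger.warning("dropping empty group(s)")
    if len(keep) < 2:
        raise ValueError("log-rank needs at least 2 non-empty groups")
    time = surv.time.loc[common]
    event = surv.event.loc[common]
    if event.sum() < 1:
        raise ValueError("log-rank needs at least one observed event")
    res = multivariate_logrank_test(time, lab, event)
    km = {}
    for g in sorted(keep, key=str):
        mask = lab == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        km[g] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(),
            "at_risk": at_risk.to_numpy(dtype=float),
        })
    return SurvivalComparison(
        groups=sorted(keep, key=str),
        chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        dof=len(keep) - 1,
        km=km,
    )
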