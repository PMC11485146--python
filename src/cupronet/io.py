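"""Readers, writers and validated containers for the tabular formats the
pipeline touches.

Every stage of the analysis is file-in/file-out reproducible over a single
tabular dialect: tab-separated UTF-8 text with ``.`` as the decimal mark,
matching the genes-by-samples matrices distributed by the major cancer
expression portals.  Gene identifiers are plain symbols; no alias mapping is
attempted.

Containers
----------
:class:`ExpressionMatrix`
    genes x samples numeric matrix with per-sample condition labels
    (``tumour`` / ``normal``) and cancer-type labels.
:class:`SurvivalTable`
    per-sample follow-up time (days), event indicator and optional
    clinical covariates.
:class:`GeneSet` / :class:`InteractionDB`
    curated gene lists (GMT) and unordered interaction pairs emulating a
    protein-interaction database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("tumour", "normal")

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "GeneSet",
    "InteractionDB",
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "read_gmt",
    "write_gmt",
    "merge_gene_sets",
    "read_interactions",
    "read_maf",
    "read_cnv",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dupes = counts[counts > 1]
    if len(dupes):
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dupes.index[:10]))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with condition labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample id.  Non-negative on
        the count scale; real on the log2 scale.
    scale : str
        ``"counts"`` or ``"log2"``.  The log transform may be applied at most
        once; the tag makes double transforms a hard error.
    condition : pandas.Series
        sample id -> ``"tumour"`` or ``"normal"``.
    cancer_type : pandas.Series
        sample id -> cancer-type label.
    """

    values: pd.DataFrame
    scale: str = "counts"
    condition: pd.Series = None
    cancer_type: pd.Series = None

    def __post_init__(self) -> None:
        if self.values is None or self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("expression matrix has no data rows")
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        if self.scale not in ("counts", "log2"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(vals).any():
            bad = self.values.index[np.isnan(vals).any(axis=1)]
            raise ValueError(f"missing expression values for gene(s): {', '.join(bad[:10])}")
        if self.scale == "counts" and (vals < 0).any():
            raise ValueError("negative values on the count scale")
        if self.condition is None:
            raise ValueError("condition labels are required")
        missing = [s for s in self.values.columns if s not in self.condition.index]
        if missing:
            raise ValueError(f"sample(s) absent from condition table: {', '.join(missing[:10])}")
        bad_cond = set(self.condition.loc[list(self.values.columns)]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown condition label(s): {sorted(bad_cond)}")
        self.condition = self.condition.loc[list(self.values.columns)]
        if self.cancer_type is None:
            self.cancer_type = pd.Series("NA", index=self.values.columns)
        else:
            self.cancer_type = self.cancer_type.reindex(self.values.columns).fillna("NA")
        self.values.index.name = None
        self.values.columns.name = None

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, condition: str) -> list:
        """Sample ids carrying the given condition label."""
        return [s for s in self.values.columns if self.condition[s] == condition]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        if not keep:
            raise ValueError("gene subset does not intersect the matrix")
        return ExpressionMatrix(
            self.values.loc[keep].copy(),
            scale=self.scale,
            condition=self.condition.copy(),
            cancer_type=self.cancer_type.copy(),
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s in set(samples)]
        if not keep:
            raise ValueError("sample subset does not intersect the matrix")
        return ExpressionMatrix(
            self.values[keep].copy(),
            scale=self.scale,
            condition=self.condition.loc[keep].copy(),
            cancer_type=self.cancer_type.loc[keep].copy(),
        )


@dataclass
class SurvivalTable:
    """Per-sample follow-up table.

    ``data`` is indexed by sample id with columns ``time`` (days, >= 0),
    ``event`` (0/1, 1 = death observed), and optional ``age``, ``sex``,
    ``cancer_type``.  Samples lacking time or event are excluded at load
    time with a logged count; missing age/sex are allowed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "sample")
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if df["time"].isna().any() or df["event"].isna().any():
            raise ValueError("missing time/event after load; filter before constructing")
        if (df["time"] < 0).any():
            raise ValueError("negative follow-up time")
        if not df["event"].isin((0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        for col in ("age", "sex", "cancer_type"):
            if col not in df.columns:
                df[col] = np.nan
        df.index.name = "sample_id"
        self.data = df

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def subset(self, samples: Iterable[str]) -> "SurvivalTable":
        keep = [s for s in self.data.index if s in set(samples)]
        return SurvivalTable(self.data.loc[keep].copy())


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of gene symbols."""

    name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


class InteractionDB:
    """Unordered gene-symbol interaction pairs with optional scores.

    Self-pairs are rejected; pairs are symmetric by construction (stored as
    sorted 2-tuples).
    """

    def __init__(self, pairs: Iterable[tuple], scores: Mapping[tuple, float] | None = None):
        norm = set()
        self.scores: dict = {}
        scores = scores or {}
        for pair in pairs:
            a, b = pair
            if a == b:
                raise ValueError(f"self-interaction {a!r} not allowed")
            key = tuple(sorted((a, b)))
            norm.add(key)
            if pair in scores:
                self.scores[key] = scores[pair]
        self.pairs = frozenset(norm)

    def __len__(self) -> int:
        return len(self.pairs)

    def has_pair(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.pairs

    @property
    def genes(self) -> frozenset:
        return frozenset(g for pair in self.pairs for g in pair)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", **kw)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return df


def read_expression(path, condition_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample condition table.

    The matrix file has a header row of sample ids and gene ids in the first
    column; the condition file has columns ``sample_id``, ``condition``
    (tumour/normal) and optionally ``cancer_type``.  Values are taken to be
    on the count scale.
    """
    mat = _read_tsv(path, index_col=0)
    cond = _read_tsv(condition_path)
    if "sample_id" not in cond.columns or "condition" not in cond.columns:
        raise ValueError("condition file needs sample_id and condition columns")
    _check_unique(list(cond["sample_id"]), "sample (condition file)")
    cond = cond.set_index("sample_id")
    cancer = cond["cancer_type"] if "cancer_type" in cond.columns else None
    return ExpressionMatrix(
        mat.astype(float), scale="counts", condition=cond["condition"], cancer_type=cancer
    )


def write_expression(m: ExpressionMatrix, path, condition_path=None) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")
    if condition_path is not None:
        pd.DataFrame(
            {
                "sample_id": m.sample_ids,
                "condition": m.condition.loc[m.sample_ids].values,
                "cancer_type": m.cancer_type.loc[m.sample_ids].values,
            }
        ).to_csv(condition_path, sep="\t", index=False)


def read_survival(path) -> SurvivalTable:
    """Read a survival TSV (sample_id, time, event, age, sex, cancer_type).

    Samples with missing time or event are dropped with a logged count; this
    mirrors standard cohort curation where patients without follow-up are
    removed before analysis.
    """
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise ValueError("survival file needs a sample_id column")
    df = df.set_index("sample_id")
    n0 = len(df)
    df = df.dropna(subset=["time", "event"])
    if len(df) < n0:
        logger.info("dropped %d sample(s) lacking time/event", n0 - len(df))
    if len(df) == 0:
        raise ValueError("no samples with complete time/event")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return SurvivalTable(df)


def write_survival(t: SurvivalTable, path) -> None:
    t.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> list:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            sets.append(GeneSet(fields[0], frozenset(fields[2:])))
    if not sets:
        raise ValueError("GMT file contains no gene sets")
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na"] + sorted(gs.genes)) + "\n")


def merge_gene_sets(sets: Sequence[GeneSet], name: str = "merged") -> GeneSet:
    """Union of gene sets with duplicates removed.

    This is how a curated candidate list is assembled from several annotated
    sets: combine, then drop overlapping genes so each appears once.
    """
    if not sets:
        raise ValueError("merge_gene_sets needs at least one gene set")
    genes: set = set()
    for gs in sets:
        genes |= set(gs.genes)
    return GeneSet(name, frozenset(genes))


def read_interactions(path) -> InteractionDB:
    """Read an interaction-pair TSV (gene_a, gene_b[, score])."""
    df = _read_tsv(path)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError("interaction file needs gene_a and gene_b columns")
    pairs = list(zip(df["gene_a"], df["gene_b"]))
    scores = None
    if "score" in df.columns:
        scores = {p: s for p, s in zip(pairs, df["score"])}
    return InteractionDB(pairs, scores)


def write_interactions(db: InteractionDB, path) -> None:
    rows = [{"gene_a": a, "gene_b": b, "score": db.scores.get((a, b), np.nan)}
            for a, b in sorted(db.pairs)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


MAF_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "t_alt_count",
    "t_depth",
    "FILTER",
    "REVEL",
)


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like somatic SNV table with a precomputed REVEL column.

    Validates count sanity (t_depth > 0, t_alt_count <= t_depth).  REVEL may
    be missing per call (treated downstream as non-pathogenic).
    """
    df = _read_tsv(path)
    missing = [c for c in MAF_COLUMNS if c not in df.columns and c != "REVEL"]
    if missing:
        raise ValueError(f"MAF file missing column(s): {', '.join(missing)}")
    if "REVEL" not in df.columns:
        df["REVEL"] = np.nan
    df["t_alt_count"] = df["t_alt_count"].astype(int)
    df["t_depth"] = df["t_depth"].astype(int)
    if (df["t_depth"] <= 0).any():
        raise ValueError("t_depth must be positive")
    if (df["t_alt_count"] > df["t_depth"]).any():
        raise ValueError("t_alt_count exceeds t_depth")
    if (df["t_alt_count"] < 0).any():
        raise ValueError("negative t_alt_count")
    rev = df["REVEL"].dropna()
    if ((rev < 0) | (rev > 1)).any():
        raise ValueError("REVEL scores must lie in [0, 1]")
    return df.reset_index(drop=True)


CNV_CLASSES = ("hete_del", "homo_del", "hete_amp", "homo_amp", "neutral")


def read_cnv(path) -> pd.DataFrame:
    """Read a per-gene per-sample CNV class table (gene, sample_id, cnv_class)."""
    df = _read_tsv(path)
    if not {"gene", "sample_id", "cnv_class"} <= set(df.columns):
        raise ValueError("CNV file needs gene, sample_id, cnv_class columns")
    bad = set(df["cnv_class"]) - set(CNV_CLASSES)
    if bad:
        raise ValueError(f"unknown CNV class(es): {sorted(bad)}")
    if df.duplicated(["gene", "sample_id"]).any():
        raise ValueError("multiple CNV classes for the same (gene, sample)")
    return df.reset_index(drop=True)
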