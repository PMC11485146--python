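"""Two-condition differential-expression screen.

Expression is compared tumour vs normal per gene on the log2(count + 1)
scale with a Welch two-sample t-test, Benjamini-Hochberg correction across
all tested genes, and the conventional dual threshold: a gene is called
differentially expressed when its adjusted p-value is at most ``alpha``
(default 0.05) and |log2 fold change| is at least ``lfc`` (default 1).

The test is a deliberately transparent stand-in for moderated-t pipelines:
same contrast, same decision boundary structure, no hidden hyperparameters.
No library-size normalization is applied by default (inputs are gene-level
expected counts); an upper-quartile scaling hook is exposed for users whose
counts need it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "log_transform",
    "upper_quartile_normalize",
    "benjamini_hochberg",
    "de_test",
    "select_degs",
]


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return a log2(x + 1)-transformed copy of a count-scale matrix.

    Applying the transform twice is a hard error (the scale tag enforces
    at-most-once semantics).
    """
    if m.scale != "counts":
        raise ValueError("matrix is already log2-transformed")
    vals = m.values.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = pd.DataFrame(np.log2(vals + 1.0), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, scale="log2", condition=m.condition.copy(),
                            cancer_type=m.cancer_type.copy())


def upper_quartile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Optional upper-quartile scaling of count columns to a common quartile."""
    if m.scale != "counts":
        raise ValueError("normalization operates on the count scale")
    vals = m.values.to_numpy(dtype=float)
    uq = np.array([np.percentile(col[col > 0], 75) if (col > 0).any() else 1.0
                   for col in vals.T])
    scaled = vals / uq[None, :] * np.mean(uq)
    out = pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, scale="counts", condition=m.condition.copy(),
                            cancer_type=m.cancer_type.copy())


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Values are clipped to [0, 1] and monotone in rank; the adjustment
    depends only on ranks, so it is invariant to input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(m: ExpressionMatrix, alpha: float = 0.05, lfc: float = 1.0) -> pd.DataFrame:
    """Per-gene Welch t-test of tumour vs normal on the log2 scale.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (tumour mean
    minus normal mean), ``p_value``, ``adj_p`` (BH over all tested genes) and
    ``status`` in {up, down, ns}.

    Degenerate genes with zero variance in both groups get p = 1 when the
    group means are equal (no evidence either way) and p = 0 when they
    differ (an exact separation).
    """
    if m.scale != "log2":
        raise ValueError("de_test expects a log2-scale matrix; run log_transform first")
    tum = m.samples_in("tumour")
    nor = m.samples_in("normal")
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError("each condition needs at least 2 samples")
    a = m.values[tum].to_numpy()
    b = m.values[nor].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: Welch statistic is undefined
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p[degenerate & (np.abs(log2fc) < 1e-12)] = 1.0
    p[degenerate & (np.abs(log2fc) >= 1e-12)] = 0.0
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    adj = benjamini_hochberg(p)
    status = np.where((adj <= alpha) & (log2fc >= lfc), "up",
                      np.where((adj <= alpha) & (log2fc <= -lfc), "down", "ns"))
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "adj_p": adj, "status": status},
        index=m.values.index,
    )


def select_degs(results: pd.DataFrame, name: str = "DEGs") -> GeneSet:
    """Gene set of all genes called up or down by :func:`de_test`."""
    genes = frozenset(results.index[results["status"] != "ns"])
    if not genes:
        raise ValueError("no differentially expressed genes at these thresholds")
    return GeneSet(name, genes)
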