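"""Expression-array normalization and demethylating-agent induction screen.

Signals are scaled so that the 75th percentile of all probe-level values in
each sample equals 1.0, then averaged over the probes of a gene.  A gene is
"expressed" in the mesenchymal stem cell / osteoblast baseline when its mean
normalized signal clears a threshold in both cell types, and "induced" by
5-aza-2'-deoxycytidine when the log2 treated/mock ratio clears a fold-change
threshold (two-fold by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: normalized-signal floor applied before ratios so log2 stays finite
DEFAULT_SIGNAL_FLOOR = 0.01


@dataclass(frozen=True)
class InductionResult:
    gene: str
    mock: float
    treated: float
    log2_ratio: float
    induced: bool


def load_expression(path) -> pd.DataFrame:
    """Read a probes (or genes) x samples expression TSV, first column id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("expression matrix contains negative signals")
    return df


def normalize_75th(expr: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its 75th percentile over all probes is 1.0.

    Percentiles use linear interpolation between order statistics (numpy
    default).  Idempotent: normalizing a normalized matrix is a no-op.
    """
    q = expr.quantile(0.75, axis=0, interpolation="linear")
    if (q <= 0).any():
        zero = q.index[q <= 0].tolist()
        raise ValueError(f"samples with non-positive 75th percentile: {zero}")
    return expr / q


def aggregate_genes(expr: pd.DataFrame, probe_to_gene: pd.Series | dict) -> pd.DataFrame:
    """Gene-level matrix: mean of the member probes of each gene.

    Probes without a gene mapping are dropped; genes with no probes on the
    platform are simply absent from the result.
    """
    mapping = pd.Series(probe_to_gene)
    if mapping.empty:
        raise ValueError("empty probe-to-gene mapping")
    mapped = expr.index.intersection(mapping.index)
    genes = mapping.loc[mapped]
    out = expr.loc[mapped].groupby(genes.to_numpy()).mean()
    out.index.name = "gene"
    return out.sort_index()


def expressed_in_baseline(
    gene_expr: pd.DataFrame,
    msc_samples: list[str],
    osteoblast_samples: list[str],
    threshold: float = 0.5,
) -> set[str]:
    """Genes whose mean normalized signal clears the threshold in MSC AND OB."""
    if not msc_samples or not osteoblast_samples:
        raise ValueError("both baseline groups must be nonempty")
    msc_mean = gene_expr[list(msc_samples)].mean(axis=1)
    ob_mean = gene_expr[list(osteoblast_samples)].mean(axis=1)
    ok = (msc_mean >= threshold) & (ob_mean >= threshold)
    return set(gene_expr.index[ok])


def induction_screen(
    gene_expr: pd.DataFrame,
    mock: str | list[str],
    treated: str | list[str],
    log2_threshold: float = 1.0,
    floor: float = DEFAULT_SIGNAL_FLOOR,
) -> pd.DataFrame:
    """Per-gene log2 treated/mock ratio and induction call.

    mock/treated may be single sample ids or replicate lists (replicates are
    averaged).  Signals are floored at ``floor`` before the ratio so genes
    silent in mock produce a finite, large ratio.  Returns a DataFrame
    indexed by gene with columns mock, treated, log2_ratio, induced, sorted
    by descending log2_ratio then gene.
    """
    mock_cols = [mock] if isinstance(mock, str) else list(mock)
    treated_cols = [treated] if isinstance(treated, str) else list(treated)
    for col in mock_cols + treated_cols:
        if col not in gene_expr.columns:
            raise KeyError(f"sample {col!r} not in expression matrix")
    m = gene_expr[mock_cols].mean(axis=1).clip(lower=floor)
    t = gene_expr[treated_cols].mean(axis=1).clip(lower=floor)
    log2_ratio = np.log2(t / m)
    out = pd.DataFrame(
        {
            "mock": m,
            "treated": t,
            "log2_ratio": log2_ratio,
            "induced": log2_ratio >= log2_threshold,
        }
    )
    out.index.name = "gene"
    return out.sort_index().sort_values("log2_ratio", ascending=False, kind="stable")
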