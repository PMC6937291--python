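"""Aberrant-methylation calling and unsupervised cohort structure.

Implements the tumor-versus-normal comparison used to find promoter CpG
islands that acquire methylation in tumors: a block counts as aberrantly
methylated when it is unmethylated (beta < 0.2) in every normal sample and
methylated (beta >= 0.4 for tissues) in a minimum number of tumors.
Unsupervised hierarchical clustering over samples (Euclidean distance)
exposes CIMP-like subgroups with many methylated islands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import STATE_METH, call_states

logger = logging.getLogger(__name__)

LINKAGE_METHODS = frozenset({"complete", "average", "ward"})


@dataclass(frozen=True)
class AberrantCallConfig:
    """Thresholds for the tumor-vs-normal aberrant-methylation call.

    meth_threshold
        block beta at/above which a tissue sample counts methylated (0.4).
    unmeth_threshold
        block beta below which a sample counts unmethylated (0.2).
    min_tumor_count
        minimum number of methylated tumors for a block to qualify
        ("more than 5 of 28" -> 6).
    """

    meth_threshold: float = 0.4
    unmeth_threshold: float = 0.2
    min_tumor_count: int = 6

    def __post_init__(self) -> None:
        if not (0.0 < self.unmeth_threshold < self.meth_threshold <= 1.0):
            raise ValueError("need 0 < unmeth_threshold < meth_threshold <= 1")
        if self.min_tumor_count < 1:
            raise ValueError("min_tumor_count must be >= 1")


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples over block beta values.

    linkage is the scipy merge history (heights non-decreasing for the
    supported methods); blocks_used records the exact feature set after the
    element cap and missing-data filter, and subsample_seed the seed used
    for the cap subsample, so the tree is reproducible.
    """

    linkage: np.ndarray
    sample_ids: list[str]
    blocks_used: list[str]
    subsample_seed: int | None
    method: str

    def labels(self, k: int) -> pd.Series:
        """Cut the tree into k flat clusters (labels 1..k)."""
        lab = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.sample_ids, name=f"cluster_k{k}")

    def merge_table(self) -> pd.DataFrame:
        """Flat merge list: node, child1, child2, height, size."""
        n = len(self.sample_ids)
        return pd.DataFrame(
            {
                "node": np.arange(n, n + len(self.linkage)),
                "child1": self.linkage[:, 0].astype(int),
                "child2": self.linkage[:, 1].astype(int),
                "height": self.linkage[:, 2],
                "size": self.linkage[:, 3].astype(int),
            }
        )


def _block_annotation(blocks) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block_id": [b.block_id for b in blocks],
            "gene": [b.gene for b in blocks],
            "tss_relation": [b.tss_relation for b in blocks],
            "cgi_relation": [b.cgi_relation for b in blocks],
        }
    ).set_index("block_id")


def normally_unmethylated_cgi_blocks(
    block_beta: pd.DataFrame,
    blocks,
    normals: list[str],
    config: AberrantCallConfig = AberrantCallConfig(),
) -> list[str]:
    """CpG-island blocks unmethylated (beta < threshold) in every normal.

    These blocks are the reference set for aberrant-methylation calls and
    for the methylated-CGI fraction of a sample.
    """
    if not normals:
        raise ValueError("at least one normal sample is required")
    ann = _block_annotation(blocks)
    island_ids = ann.index[ann["cgi_relation"] == "Island"]
    island_ids = island_ids.intersection(block_beta.index)
    normal_beta = block_beta.loc[island_ids, list(normals)]
    ok = (normal_beta < config.unmeth_threshold).all(axis=1) & normal_beta.notna().all(
        axis=1
    )
    return sorted(island_ids[ok])


def call_aberrant_blocks(
    block_beta: pd.DataFrame,
    tumors: list[str],
    normals: list[str],
    config: AberrantCallConfig = AberrantCallConfig(),
    candidate_blocks: list[str] | None = None,
) -> pd.DataFrame:
    """Blocks unmethylated in all normals and methylated in enough tumors.

    Returns a DataFrame indexed by block_id with columns
    ``n_methylated_tumors`` and ``normal_max_beta``, sorted by descending
    tumor count then block_id.  ``candidate_blocks`` restricts the search
    (e.g. to normally unmethylated CpG-island blocks); by default every
    block is examined.
    """
    if not tumors:
        raise ValueError("empty tumor sample set")
    if not normals:
        raise ValueError("empty normal sample set")
    if set(tumors) & set(normals):
        raise ValueError("tumor and normal sample sets overlap")
    bb = block_beta if candidate_blocks is None else block_beta.loc[candidate_blocks]
    normal_beta = bb[list(normals)]
    tumor_beta = bb[list(tumors)]
    normal_ok = (normal_beta < config.unmeth_threshold).all(axis=1) & normal_beta.notna().all(axis=1)
    n_meth = (tumor_beta >= config.meth_threshold).sum(axis=1)
    qualifies = normal_ok & (n_meth >= config.min_tumor_count)
    out = pd.DataFrame(
        {
            "n_methylated_tumors": n_meth[qualifies].astype(int),
            "normal_max_beta": normal_beta.max(axis=1)[qualifies],
        }
    )
    out.index.name = "block_id"
    # stable sort: descending tumor count, ties broken by block_id
    out = out.sort_index().sort_values(
        "n_methylated_tumors", ascending=False, kind="stable"
    )
    return out


def select_variable_blocks(
    block_beta: pd.DataFrame, samples: list[str], n: int = 500
) -> list[str]:
    """The n most variable blocks across the given samples.

    Variability is the sample variance of the block beta values (standard
    deviation would give the same ranking).  Blocks with any missing value
    over the samples are excluded; ties are broken by block_id so the
    selection is deterministic.
    """
    sub = block_beta[list(samples)]
    complete = sub.dropna(axis=0, how="any")
    if n > len(complete):
        raise ValueError(
            f"requested {n} blocks but only {len(complete)} have complete data"
        )
    var = complete.var(axis=1, ddof=1)
    order = var.sort_index().sort_values(ascending=False, kind="stable")
    return order.index[:n].tolist()


def cluster_samples(
    block_beta: pd.DataFrame,
    block_ids: list[str],
    samples: list[str] | None = None,
    element_cap: int = 20_000,
    seed: int = 0,
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of samples with Euclidean distance.

    Hierarchical clustering over more than ``element_cap`` blocks is capped
    by a seeded uniform random subsample of the block list.  Blocks with a
    missing value in any clustered sample are dropped (Euclidean distance
    is undefined on missing cells).  Samples are put in lexicographic order
    before linkage so the tree does not depend on column order.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unsupported linkage method {method!r}")
    if samples is None:
        samples = list(block_beta.columns)
    if len(samples) < 2:
        raise ValueError("clustering requires at least 2 samples")
    samples = sorted(samples)

    block_ids = list(block_ids)
    subsample_seed = None
    if len(block_ids) > element_cap:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(block_ids), size=element_cap, replace=False)
        block_ids = [block_ids[i] for i in sorted(keep)]
        subsample_seed = seed
        logger.info("subsampled %d of %d blocks for clustering", element_cap, len(keep))

    sub = block_beta.loc[block_ids, samples]
    complete = sub.dropna(axis=0, how="any")
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.warning("dropped %d blocks with missing values before clustering", n_dropped)
    X = complete.to_numpy(dtype=float).T  # samples x blocks
    dist = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(dist, method=method)
    return ClusterResult(
        linkage=Z,
        sample_ids=samples,
        blocks_used=complete.index.tolist(),
        subsample_seed=subsample_seed,
        method=method,
    )


def methylated_fraction(
    block_beta: pd.DataFrame,
    sample: str,
    reference_blocks: list[str],
    material: str,
) -> float:
    """Fraction of reference blocks in the methylated state in one sample.

    The reference set is normally the output of
    :func:`normally_unmethylated_cgi_blocks`; the fraction is computed over
    reference blocks with a non-missing beta in the sample.
    """
    if not reference_blocks:
        raise ValueError("reference_blocks must be nonempty")
    values = block_beta.loc[list(reference_blocks), sample]
    observed = values.dropna()
    if observed.empty:
        raise ValueError(f"all reference blocks missing for sample {sample!r}")
    states = call_states(observed, material)
    return float((states == STATE_METH).sum() / len(observed))
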