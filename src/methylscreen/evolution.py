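"""Methylation-based clonal-versus-parallel evolution of tumor pairs.

Promoter CpG-island methylation is mitotically stable, so the aberrantly
methylated block set of a lesion records its clonal history.  For a
primary-metastasis pair the comparison of the two sets distinguishes:

* clonal evolution — the metastasis retains the primary's aberrant
  methylation (possibly with additional, metastasis-private events);
* parallel evolution — the metastasis shares only a fraction of the
  primary's events and carries private ones, indicating divergence from a
  common ancestor lesion rather than descent from the sampled primary.

The boundary is operationalized as a threshold on the shared fraction of
the primary's aberrant set (default 0.75); the threshold is a documented
interpretation, not a measured constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .aberrant import AberrantCallConfig

logger = logging.getLogger(__name__)

PATTERN_CLONAL = "clonal"
PATTERN_PARALLEL = "parallel"


@dataclass(frozen=True)
class MethylationProfilePair:
    """Aberrant promoter-methylation sets of a matched primary/metastasis."""

    patient_id: str
    primary_aberrant: frozenset
    met_aberrant: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        if not (self.primary_aberrant | self.met_aberrant) <= self.universe:
            raise ValueError("aberrant sets must be subsets of the universe")


@dataclass(frozen=True)
class EvolutionCall:
    patient_id: str
    pattern: str
    shared: int
    primary_private: int
    met_private: int
    shared_fraction_of_primary: float


def pair_sets(
    block_beta: pd.DataFrame,
    primary: str,
    metastasis: str,
    universe: list[str],
    config: AberrantCallConfig = AberrantCallConfig(),
    patient_id: str | None = None,
) -> MethylationProfilePair:
    """Aberrant block sets for the two lesions of one patient.

    ``universe`` is the evaluated block set — promoter (TSS200) CpG-island
    blocks unmethylated in the normal controls and belonging to genes
    expressed in the MSC/osteoblast baseline — computed upstream.  A block
    is aberrant in a lesion when its beta is at/above the tissue methylated
    threshold (0.40).
    """
    for s in (primary, metastasis):
        if s not in block_beta.columns:
            raise KeyError(f"sample {s!r} not in block beta matrix")
    sub = block_beta.loc[list(universe)]
    prim = sub[primary] >= config.meth_threshold
    met = sub[metastasis] >= config.meth_threshold
    return MethylationProfilePair(
        patient_id=patient_id or primary,
        primary_aberrant=frozenset(sub.index[prim.fillna(False)]),
        met_aberrant=frozenset(sub.index[met.fillna(False)]),
        universe=frozenset(universe),
    )


def classify_evolution(
    pair: MethylationProfilePair, shared_fraction_min: float = 0.75
) -> EvolutionCall:
    """Classify a primary-metastasis pair as clonal or parallel evolution.

    shared_fraction_of_primary = |P ∩ M| / |P|.  Clonal when the metastasis
    retains at least ``shared_fraction_min`` of the primary's aberrant set;
    parallel when it retains less and has private events of its own.  A pair
    with low shared fraction but no metastasis-private events does not fit
    either picture and is reported as clonal with a logged warning
    (methylation loss in the metastasis lineage).
    """
    P, M = pair.primary_aberrant, pair.met_aberrant
    if not P:
        raise ValueError(
            f"patient {pair.patient_id}: no aberrant methylation in the primary; "
            "classification undefined"
        )
    shared = len(P & M)
    met_private = len(M - P)
    frac = shared / len(P)
    if frac >= shared_fraction_min:
        pattern = PATTERN_CLONAL
    elif met_private > 0:
        pattern = PATTERN_PARALLEL
    else:
        pattern = PATTERN_CLONAL
        logger.warning(
            "patient %s: shared fraction %.2f below %.2f but no metastasis-private "
            "methylation; reported clonal (regression edge case)",
            pair.patient_id,
            frac,
            shared_fraction_min,
        )
    return EvolutionCall(
        patient_id=pair.patient_id,
        pattern=pattern,
        shared=shared,
        primary_private=len(P - M),
        met_private=met_private,
        shared_fraction_of_primary=frac,
    )
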