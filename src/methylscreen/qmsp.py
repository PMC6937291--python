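"""Quantitative methylation-specific PCR: percentage of methylated reference.

PMR for a sample and target CpG island is the methylated-molecule count
normalized by Alu repeat count, relative to the same ratio in a fully
(SssI-)methylated reference DNA, times 100:

    PMR = ((sample_meth / sample_alu) / (ref_meth / ref_alu)) * 100

Alu repeats normalize the DNA amount because their copy number is less
affected by cancer-associated aneuploidy than single-copy genes; PMR is
therefore invariant to rescaling both counts of a sample by a common
factor.  Values above 100 are possible with assay noise and are reported
as-is (with a warning), never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QmspMeasurement:
    """Molecule counts for one sample x target assay (replicates averaged)."""

    sample_id: str
    target_id: str
    meth_molecules: float
    alu_molecules: float

    def __post_init__(self) -> None:
        if self.meth_molecules < 0:
            raise ValueError("meth_molecules must be >= 0")
        if self.alu_molecules <= 0:
            raise ValueError("alu_molecules must be > 0")


@dataclass(frozen=True)
class PMRResult:
    sample_id: str
    target_id: str
    pmr: float


def compute_pmr(sample: QmspMeasurement, reference: QmspMeasurement) -> PMRResult:
    """PMR of a sample against the fully methylated reference for one target."""
    if sample.target_id != reference.target_id:
        raise ValueError(
            f"sample target {sample.target_id!r} != reference target "
            f"{reference.target_id!r}"
        )
    if reference.meth_molecules <= 0:
        raise ValueError("reference has zero methylated molecules; PMR undefined")
    pmr = (
        (sample.meth_molecules / sample.alu_molecules)
        / (reference.meth_molecules / reference.alu_molecules)
        * 100.0
    )
    if pmr > 100.0:
        logger.warning(
            "PMR %.1f > 100 for %s / %s (assay noise above reference)",
            pmr,
            sample.sample_id,
            sample.target_id,
        )
    return PMRResult(sample.sample_id, sample.target_id, pmr)


def load_qmsp_table(path) -> pd.DataFrame:
    """Read a qMSP CSV: sample_id, target_id, meth_molecules, alu_molecules,
    is_reference.  Replicate wells (duplicated sample x target rows) are
    averaged on the molecule-count scale."""
    df = pd.read_csv(path)
    required = {"sample_id", "target_id", "meth_molecules", "alu_molecules", "is_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qMSP table is missing columns: {sorted(missing)}")
    df["is_reference"] = df["is_reference"].astype(bool)
    return (
        df.groupby(["sample_id", "target_id", "is_reference"], as_index=False)[
            ["meth_molecules", "alu_molecules"]
        ].mean()
    )


def pmr_table(qmsp: pd.DataFrame) -> pd.DataFrame:
    """PMR per sample x target from a (replicate-averaged) qMSP table.

    Each target must have exactly one reference row (the SssI-treated fully
    methylated control).
    """
    results = []
    for target, group in qmsp.groupby("target_id"):
        refs = group[group["is_reference"]]
        if len(refs) != 1:
            raise ValueError(
                f"target {target!r} needs exactly one reference row, found {len(refs)}"
            )
        ref_row = refs.iloc[0]
        reference = QmspMeasurement(
            ref_row["sample_id"], target, ref_row["meth_molecules"], ref_row["alu_molecules"]
        )
        for row in group[~group["is_reference"]].itertuples(index=False):
            meas = QmspMeasurement(
                row.sample_id, target, row.meth_molecules, row.alu_molecules
            )
            res = compute_pmr(meas, reference)
            results.append((res.sample_id, res.target_id, res.pmr))
    out = pd.DataFrame(results, columns=["sample_id", "target_id", "pmr"])
    return out.sort_values(["target_id", "sample_id"]).reset_index(drop=True)
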