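"""Probe annotations, genomic blocks, and three-state methylation calling.

A *genomic block* groups Infinium beadarray CpG probes that share a gene,
a TSS-relative category (TSS200, TSS1500, ...) and a CpG-island relation
(Island, Shore, Shelf, OpenSea).  The methylation level of a block is the
arithmetic mean of the beta values of its member probes; averaging
emphasises densely methylated islands, which are the regions relevant for
methylation silencing.  Block-level beta values are then discretised into
three states (unmethylated / partially methylated / methylated) with
thresholds that differ between tissue samples and cancer cell lines,
because cell lines are near-clonal and show near-binary methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TSS_RELATIONS = frozenset(
    {"TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic"}
)
CGI_RELATIONS = frozenset({"Island", "Shore", "Shelf", "OpenSea"})
MATERIALS = frozenset({"tissue", "cell_line"})
SAMPLE_GROUPS = frozenset({"primary", "metastasis", "normal", "mock", "treated"})

AUTOSOMES = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
)

#: state thresholds: unmethylated [0, 0.2); partial [0.2, meth_lo); methylated
#: [meth_lo, 1].  meth_lo is 0.4 for tissues and 0.8 for cancer cell lines;
#: the methylated class is inclusive at its lower bound (beta >= 0.4).
UNMETH_UPPER = 0.2
METH_LOWER = {"tissue": 0.4, "cell_line": 0.8}

STATE_UNMETH = "unmethylated"
STATE_PARTIAL = "partial"
STATE_METH = "methylated"


@dataclass(frozen=True)
class ProbeRecord:
    """One annotated CpG probe (1-based genomic coordinate)."""

    probe_id: str
    chromosome: str
    position: int
    gene: tuple[str, ...]  # empty for intergenic probes
    tss_relation: str
    cgi_relation: str
    cgi_id: str | None  # None iff cgi_relation == OpenSea

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.probe_id}: position must be >= 1")
        if self.tss_relation not in TSS_RELATIONS:
            raise ValueError(
                f"{self.probe_id}: unknown tss_relation {self.tss_relation!r}"
            )
        if self.cgi_relation not in CGI_RELATIONS:
            raise ValueError(
                f"{self.probe_id}: unknown cgi_relation {self.cgi_relation!r}"
            )
        if self.cgi_relation == "OpenSea":
            if self.cgi_id is not None:
                raise ValueError(f"{self.probe_id}: OpenSea probe with a cgi_id")
        elif self.cgi_id is None:
            raise ValueError(
                f"{self.probe_id}: {self.cgi_relation} probe requires a cgi_id"
            )

    @property
    def is_autosomal(self) -> bool:
        return self.chromosome in AUTOSOMES


@dataclass(frozen=True)
class GenomicBlock:
    """A group of probes sharing (gene, tss_relation, cgi_relation, cgi_id).

    A probe annotated to k genes contributes to k blocks (gene-centric
    grouping for downstream per-gene screens).
    """

    block_id: str
    gene: str | None
    tss_relation: str
    cgi_relation: str
    cgi_id: str | None
    probe_ids: tuple[str, ...] = field(default=())

    @property
    def key(self) -> tuple:
        return (self.gene, self.tss_relation, self.cgi_relation, self.cgi_id)


def block_id_for_key(
    gene: str | None, tss_relation: str, cgi_relation: str, cgi_id: str | None
) -> str:
    """Deterministic, human-readable block identifier."""
    return "|".join([gene or "NA", tss_relation, cgi_relation, cgi_id or "NA"])


# ---------------------------------------------------------------------------
# I/O

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "gene",
    "tss_relation",
    "cgi_relation",
    "cgi_id",
]


def load_manifest(manifest_path, drop_non_autosomal: bool = True) -> list[ProbeRecord]:
    """Read a probe-annotation manifest CSV into validated records.

    Expected columns: probe_id, chrom, pos, gene (";"-separated symbols,
    may be empty), tss_relation, cgi_relation, cgi_id (empty for OpenSea).
    Non-autosomal probes are dropped (with a logged count) because the
    analysis is restricted to autosomes.
    """
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns: {missing}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ValueError(f"duplicate probe_id in manifest (e.g. {dups})")

    records = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        rec = ProbeRecord(
            probe_id=row.probe_id,
            chromosome=row.chrom,
            position=int(row.pos),
            gene=tuple(g for g in row.gene.split(";") if g),
            tss_relation=row.tss_relation,
            cgi_relation=row.cgi_relation,
            cgi_id=row.cgi_id or None,
        )
        if drop_non_autosomal and not rec.is_autosomal:
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        logger.info("dropped %d non-autosomal probes", n_dropped)
    return records


def write_manifest(records: list[ProbeRecord], path) -> None:
    """Write probe records in the manifest CSV dialect read by load_manifest."""
    df = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "chrom": [r.chromosome for r in records],
            "pos": [r.position for r in records],
            "gene": [";".join(r.gene) for r in records],
            "tss_relation": [r.tss_relation for r in records],
            "cgi_relation": [r.cgi_relation for r in records],
            "cgi_id": [r.cgi_id or "" for r in records],
        }
    )
    df.to_csv(path, index=False)


def load_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples beta-value TSV (first column probe_id).

    Empty cells are missing values.  All non-missing values must lie in
    [0, 1].
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    values = df.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if np.nansum(bad):
        raise ValueError("beta matrix contains values outside [0, 1]")
    return df


def load_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, material, group, patient_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "material", "group", "patient_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    bad_mat = set(df["material"]) - MATERIALS
    if bad_mat:
        raise ValueError(f"unknown material labels: {sorted(bad_mat)}")
    bad_grp = set(df["group"]) - SAMPLE_GROUPS
    if bad_grp:
        raise ValueError(f"unknown group labels: {sorted(bad_grp)}")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# Block assembly and block-level beta


def assemble_blocks(probes: list[ProbeRecord]) -> list[GenomicBlock]:
    """Group probes into genomic blocks.

    Grouping key is (gene, tss_relation, cgi_relation, cgi_id); a probe with
    no gene annotation is grouped under gene=None, and a probe annotated to
    several genes appears once per gene.  The result is sorted by block_id,
    with each block's probe list sorted, so the output is independent of
    input order.
    """
    groups: dict[tuple, list[str]] = {}
    for p in probes:
        genes = p.gene if p.gene else (None,)
        for g in genes:
            key = (g, p.tss_relation, p.cgi_relation, p.cgi_id)
            groups.setdefault(key, []).append(p.probe_id)
    blocks = [
        GenomicBlock(
            block_id=block_id_for_key(*key),
            gene=key[0],
            tss_relation=key[1],
            cgi_relation=key[2],
            cgi_id=key[3],
            probe_ids=tuple(sorted(pids)),
        )
        for key, pids in groups.items()
    ]
    blocks.sort(key=lambda b: b.block_id)
    return blocks


def block_beta(beta: pd.DataFrame, blocks: list[GenomicBlock]) -> pd.DataFrame:
    """Average probe beta values per block: blocks x samples DataFrame.

    The block value is the mean over the non-missing member probes; it is
    missing only when every member probe is missing (or absent from the
    matrix).  Blocks with no probe present in the matrix get an all-missing
    row and a logged warning.
    """
    pos = {p: i for i, p in enumerate(beta.index)}
    probe_rows: list[int] = []
    block_rows: list[int] = []
    n_empty = 0
    for bi, b in enumerate(blocks):
        present = [pos[p] for p in b.probe_ids if p in pos]
        if not present:
            n_empty += 1
            continue
        probe_rows.extend(present)
        block_rows.extend([bi] * len(present))
    if n_empty:
        logger.warning("%d blocks have no probes in the beta matrix", n_empty)

    values = beta.to_numpy(dtype=float)[probe_rows]
    observed = ~np.isnan(values)
    sums = np.zeros((len(blocks), beta.shape[1]))
    counts = np.zeros((len(blocks), beta.shape[1]))
    np.add.at(sums, block_rows, np.where(observed, values, 0.0))
    np.add.at(counts, block_rows, observed.astype(float))
    with np.errstate(invalid="ignore"):
        means = sums / counts  # NaN where no probe observed
    out = pd.DataFrame(
        means,
        index=pd.Index([b.block_id for b in blocks], name="block_id"),
        columns=beta.columns,
    )
    return out


# ---------------------------------------------------------------------------
# Three-state calling


def call_state(beta_value: float, material: str) -> str:
    """Discretise one beta value into unmethylated / partial / methylated.

    Tissues: [0, 0.2) / [0.2, 0.4) / [0.4, 1].  Cancer cell lines:
    [0, 0.2) / [0.2, 0.8) / [0.8, 1].
    """
    if material not in MATERIALS:
        raise ValueError(f"unknown material {material!r}")
    if not (0.0 <= beta_value <= 1.0):
        raise ValueError(f"beta value {beta_value} outside [0, 1]")
    if beta_value < UNMETH_UPPER:
        return STATE_UNMETH
    if beta_value < METH_LOWER[material]:
        return STATE_PARTIAL
    return STATE_METH


def call_states(beta: pd.DataFrame | pd.Series, material: str):
    """Vectorised call_state; missing values stay missing."""
    if material not in MATERIALS:
        raise ValueError(f"unknown material {material!r}")
    values = beta.to_numpy(dtype=float) if hasattr(beta, "to_numpy") else np.asarray(beta)
    with np.errstate(invalid="ignore"):
        if np.nanmin(values) < 0 or np.nanmax(values) > 1:
            raise ValueError("beta values outside [0, 1]")
    out = np.select(
        [values < UNMETH_UPPER, values < METH_LOWER[material]],
        [STATE_UNMETH, STATE_PARTIAL],
        default=STATE_METH,
    ).astype(object)
    out[np.isnan(values)] = None
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out
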