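"""Readers and writers for the pipeline's external formats, plus configuration.

Dialects: UTF-8 throughout; comma-separated CSV for batch time series,
tab-separated TSV for OTU tables and result frames, FASTA/FASTQ for probes
and reads, YAML for the analysis configuration.  Sample headers are
ISO-8601 dates.  Every loader round-trips its own writer bit-identically
for valid inputs, and loaders never alter counts or concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml
from Bio import SeqIO

from .changepoint import OtuTable
from .efish import ProbeRecord, ProbeSet
from .errors import ConfigurationError, FormatError, ValidationError
from .stoichiometry import ANALYTES, BatchTimeSeries

PathLike = Union[str, Path]


@dataclass
class AnalysisConfig:
    """Declarative configuration of one pipeline run.

    The change-point design is a fixed (n1, n2) split of the dated samples;
    ``epoch_boundary_date`` makes the same split reproducible from sample
    metadata alone.  All stochastic steps (rarefaction, simulations) draw
    from ``rng_seed``.
    """

    rarefaction_depth: int = 10_000
    rng_seed: int = 0
    changepoint_split: Tuple[int, int] = (4, 6)
    alpha_fdr: float = 0.05
    epoch_boundary_date: str = "2013-06-19"
    balance_coefficients: Dict[str, float] = field(default_factory=dict)
    universal_probe: Union[str, List[str]] = "EUB338"

    def __post_init__(self) -> None:
        if self.rarefaction_depth <= 0:
            raise ConfigurationError("rarefaction_depth must be a positive integer")
        if not 0 < self.alpha_fdr < 1:
            raise ConfigurationError("alpha_fdr must be in (0, 1)")
        n1, n2 = self.changepoint_split
        if n1 < 2 or n2 < 2:
            raise ConfigurationError("both changepoint segments need >= 2 samples")

    def validate_against(self, table: OtuTable) -> None:
        n1, n2 = self.changepoint_split
        if n1 + n2 != table.n_samples:
            raise ConfigurationError(
                f"split {self.changepoint_split} does not sum to {table.n_samples} samples"
            )
        min_depth = int(table.counts.sum(axis=0).min())
        if self.rarefaction_depth > min_depth:
            raise ConfigurationError(
                f"rarefaction_depth {self.rarefaction_depth} exceeds the minimum "
                f"sample depth {min_depth}"
            )

    @classmethod
    def from_yaml(cls, path: PathLike) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "changepoint_split" in raw:
            raw["changepoint_split"] = tuple(raw["changepoint_split"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from None


# ---------------------------------------------------------------------------
# batch time series (CSV)

_REQUIRED_TS_COLUMNS = ("time_min", "phase")


def load_batch_timeseries(path: PathLike) -> BatchTimeSeries:
    """Read one batch cycle from CSV (columns time_min, phase, analytes...)."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_TS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if not any(a in df.columns for a in ANALYTES):
        raise FormatError(f"{path}: no analyte column among {ANALYTES}")
    replicate = "r1"
    if "replicate_id" in df.columns:
        reps = df["replicate_id"].unique()
        if len(reps) > 1:
            raise ValidationError(
                f"{path}: one file holds one cycle; found replicates {list(reps)}"
            )
        replicate = str(reps[0])
        df = df.drop(columns="replicate_id")
    df = df.sort_values("time_min", kind="stable").reset_index(drop=True)
    return BatchTimeSeries(df, replicate_id=replicate)


def write_batch_timeseries(ts: BatchTimeSeries, path: PathLike) -> None:
    df = ts.data.copy()
    df["replicate_id"] = ts.replicate_id
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# OTU tables (TSV)


def load_otu_table(path: PathLike) -> OtuTable:
    """Read an OTU table: first column ids, last column taxonomy, dated samples between."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need id column, >=1 sample column and taxonomy")
    id_col, tax_col = df.columns[0], df.columns[-1]
    sample_cols = list(df.columns[1:-1])
    try:
        pd.to_datetime(sample_cols)
    except (ValueError, TypeError):
        raise FormatError(f"{path}: sample headers must be ISO dates, got {sample_cols}")
    counts = df[sample_cols].apply(pd.to_numeric, errors="raise")
    if (counts.to_numpy() % 1 != 0).any() or (counts.to_numpy() < 0).any():
        raise ValidationError(f"{path}: counts must be non-negative integers")
    counts = counts.astype("int64")
    counts.index = df[id_col]
    counts.index.name = id_col
    taxonomy = pd.Series(df[tax_col].to_numpy(), index=df[id_col])
    return OtuTable(counts=counts, taxonomy=taxonomy)


def write_otu_table(table: OtuTable, path: PathLike) -> None:
    df = table.counts.copy()
    df.insert(len(df.columns), "taxonomy", table.taxonomy)
    df.index.name = df.index.name or "otu_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# probes and reads (FASTA/FASTQ)


def load_probes(
    path: PathLike,
    universal: Union[str, Sequence[str]] = "EUB338",
    mixes: Optional[Dict[str, List[str]]] = None,
) -> ProbeSet:
    """Read a probe/primer FASTA; ``universal`` flags the reference probe(s).

    The universal designation may name several records (a probe mix); it is
    an error if none of them is present in the file.
    """
    universal_ids = [universal] if isinstance(universal, str) else list(universal)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        role = "universal" if rec.id in universal_ids else "group_probe"
        records.append(
            ProbeRecord(
                probe_id=rec.id,
                sequence=str(rec.seq),
                target_group=rec.description.split(maxsplit=1)[1]
                if " " in rec.description
                else "",
                role=role,
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if not any(r.role == "universal" for r in records):
        raise ConfigurationError(
            f"{path}: universal probe {universal_ids} not found among "
            f"{[r.probe_id for r in records]}"
        )
    return ProbeSet(records=records, mixes=mixes or {})


def write_probes(probes: ProbeSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in probes:
            desc = f" {rec.target_group}" if rec.target_group else ""
            fh.write(f">{rec.probe_id}{desc}\n{rec.sequence}\n")


def load_reads(path: PathLike) -> List[Tuple[str, str]]:
    """Read shotgun reads from FASTA or FASTQ (by extension) as (id, seq) pairs."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(p), fmt)]


def write_reads(reads: Sequence[Tuple[str, str]], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")
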