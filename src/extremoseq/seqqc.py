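"""Per-sample sequencing QC: FASTQ position profiles and pass/fail gates.

The gates mirror standard whole-exome acceptance thresholds: raw yield
>= 6 Gb, Q30 base fraction >= 80%, mean target depth >= 50x, and >= 90% of
target bases covered at 10x or deeper — all inclusive bounds.  The gate is
reported, not enforced: callers decide whether failing samples are dropped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError

BASES = ("A", "C", "G", "T", "N")


@dataclass
class QCThresholds:
    min_raw_gb: float = 6.0
    min_q30: float = 0.80
    min_depth: float = 50.0
    min_frac_10x: float = 0.90


@dataclass
class SampleQC:
    """Per-sample sequencing metrics."""

    sample_id: str
    raw_gigabases: float
    q30_fraction: float
    mean_target_depth: float
    frac_ge_10x: float
    passed: bool | None = None
    fail_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.q30_fraction <= 1.0):
            raise FormatError(f"q30_fraction {self.q30_fraction} outside [0, 1]")
        if not (0.0 <= self.frac_ge_10x <= 1.0):
            raise FormatError(f"frac_ge_10x {self.frac_ge_10x} outside [0, 1]")
        if self.mean_target_depth < 0 or self.raw_gigabases < 0:
            raise FormatError("depth and raw yield must be non-negative")


def _open_maybe_gz(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def fastq_profiles(source) -> pd.DataFrame:
    """Per-position mean quality, base fractions, and expected error rate.

    ``source`` is a FASTQ path (``.gz`` allowed) or an open text handle of
    Phred+33 records.  Reads may vary in length; each position is averaged
    over the reads that cover it.  The error rate at a position is the mean
    of 10^(-Q/10) over those reads.  A malformed record raises
    :class:`FormatError` carrying the 1-based record index.
    """
    handle = _open_maybe_gz(source) if isinstance(source, (str, Path)) else source
    qual_sum: list[float] = []
    err_sum: list[float] = []
    cover: list[int] = []
    base_counts: list[dict] = []
    n_records = 0
    try:
        for record in SeqIO.parse(handle, "fastq"):
            n_records += 1
            quals = record.letter_annotations["phred_quality"]
            seq = str(record.seq).upper()
            while len(qual_sum) < len(seq):
                qual_sum.append(0.0)
                err_sum.append(0.0)
                cover.append(0)
                base_counts.append({b: 0 for b in BASES})
            for i, (base, q) in enumerate(zip(seq, quals)):
                qual_sum[i] += q
                err_sum[i] += 10.0 ** (-q / 10.0)
                cover[i] += 1
                base_counts[i][base if base in BASES else "N"] += 1
    except ValueError as exc:
        raise FormatError(f"malformed FASTQ record {n_records + 1}: {exc}")
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    if n_records == 0:
        raise FormatError("empty FASTQ input")
    cov = np.array(cover, dtype=float)
    df = pd.DataFrame(
        {
            "position": np.arange(1, len(cover) + 1),
            "mean_quality": np.array(qual_sum) / cov,
            "error_rate": np.array(err_sum) / cov,
        }
    )
    for b in BASES:
        df[f"frac_{b}"] = np.array([c[b] for c in base_counts]) / cov
    df.attrs["n_reads"] = n_records
    return df


def qc_gate(metrics: SampleQC, thresholds: QCThresholds | None = None) -> SampleQC:
    """Apply the four inclusive QC gates; returns the metrics with ``passed``
    set and the violated gates listed in ``fail_reasons``."""
    t = thresholds or QCThresholds()
    reasons = []
    if metrics.raw_gigabases < t.min_raw_gb:
        reasons.append(f"raw yield {metrics.raw_gigabases} Gb < {t.min_raw_gb} Gb")
    if metrics.q30_fraction < t.min_q30:
        reasons.append(f"Q30 fraction {metrics.q30_fraction} < {t.min_q30}")
    if metrics.mean_target_depth < t.min_depth:
        reasons.append(f"mean depth {metrics.mean_target_depth} < {t.min_depth}")
    if metrics.frac_ge_10x < t.min_frac_10x:
        reasons.append(f"fraction >=10x {metrics.frac_ge_10x} < {t.min_frac_10x}")
    metrics.passed = not reasons
    metrics.fail_reasons = reasons
    return metrics


def read_metrics_table(path) -> list[SampleQC]:
    """Per-sample metrics TSV: sample_id, raw_gigabases, q30_fraction,
    mean_target_depth, frac_ge_10x."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "raw_gigabases", "q30_fraction",
                "mean_target_depth", "frac_ge_10x"}
    if not required <= set(df.columns):
        raise FormatError(f"metrics TSV requires columns {sorted(required)}")
    return [
        SampleQC(
            sample_id=str(r.sample_id),
            raw_gigabases=float(r.raw_gigabases),
            q30_fraction=float(r.q30_fraction),
            mean_target_depth=float(r.mean_target_depth),
            frac_ge_10x=float(r.frac_ge_10x),
        )
        for r in df.itertuples(index=False)
    ]
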