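"""Loading exon lengths and preparing them for CDF fitting.

Responsibilities:

* read exon lengths per chromosome from genome annotations (GFF3/GTF/BED,
  optionally gzipped) or plain one-integer-per-line lists;
* per-chromosome summary statistics (quartiles by linear interpolation of
  the order statistics, the convention of ``numpy.quantile``'s default and
  of R's ``quantile(type = 7)``);
* Tukey box-plot outlier removal at the fences Q1 - 1.5 IQR / Q3 + 1.5 IQR
  (strict exceedance);
* the empirical cumulative distribution with per-point binomial
  uncertainties, the fit target of the chi-square and Bayesian stages.

Every exon feature line counts once, regardless of strand or transcript
sharing; no deduplication of multi-transcript exons is attempted.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from gffutils.iterators import DataIterator

__all__ = [
    "LengthSample",
    "SummaryStats",
    "OutlierReport",
    "EmpiricalCDF",
    "read_lengths",
    "summarize",
    "iqr_filter",
    "empirical_cdf",
    "relative_difference",
    "summary_table",
]


@dataclass(frozen=True)
class LengthSample:
    """One chromosome's exon lengths (bp) with provenance labels."""

    species: str
    chromosome: str
    lengths: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths)
        if arr.size == 0:
            raise ValueError("length sample must be nonempty")
        if np.any(arr < 1):
            raise ValueError("all lengths must be >= 1 bp")
        object.__setattr__(self, "lengths", np.asarray(arr, dtype=np.int64))

    @property
    def n(self) -> int:
        return int(self.lengths.size)


@dataclass(frozen=True)
class SummaryStats:
    """Five-number summary plus mean and IQR for one sample."""

    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class OutlierReport:
    """Result of the box-plot fence rule applied to a sample."""

    lower_fence: float
    upper_fence: float
    removed: np.ndarray
    retained: LengthSample
    removed_fraction: float


@dataclass(frozen=True)
class EmpiricalCDF:
    """Empirical CDF on the sorted unique lengths, with uncertainties.

    ``probs[i]`` is the fraction of observations <= ``grid[i]`` (so the
    last value is exactly 1) and ``sigma_obs`` is the binomial standard
    error sqrt(p (1-p) / n) floored at 1/(2n) so that the p = 1 endpoint
    keeps a finite weight.
    """

    grid: np.ndarray
    probs: np.ndarray
    sigma_obs: np.ndarray
    n: int


def _open_text(path: Union[str, Path]) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r")


def _samples_from_records(
    records: Iterable[tuple[str, int]], source: str, species: str
) -> list[LengthSample]:
    by_chrom: dict[str, list[int]] = {}
    for chrom, length in records:
        by_chrom.setdefault(chrom, []).append(length)
    return [
        LengthSample(species=species, chromosome=chrom,
                     lengths=np.asarray(lens), source=source)
        for chrom, lens in by_chrom.items()
    ]


def read_lengths(
    path: Union[str, Path],
    format: str,
    species: str = "",
    feature_type: str = "exon",
) -> list[LengthSample]:
    """Read exon lengths from an annotation or plain-text file.

    Parameters
    ----------
    path:
        Input file; a ``.gz`` suffix triggers transparent decompression.
    format:
        One of ``"gff3"``, ``"gtf"``, ``"bed"``, ``"plain"`` (case
        insensitive).  GFF3/GTF coordinates are 1-based inclusive
        (length = end - start + 1); BED intervals are half-open
        (length = end - start).  ``plain`` is one positive integer per
        line and yields a single sample labelled by the file stem.
    feature_type:
        Annotation feature to keep (GFF3/GTF only); only coding segments
        (exons) are analyzed by default.

    Returns one ``LengthSample`` per chromosome that has matching
    features; chromosomes whose annotation contains none are reported via
    a warning-free empty result (they simply do not appear).
    """
    fmt = format.lower()
    path = Path(path)
    src = str(path)
    if fmt in ("gff3", "gff", "gtf"):
        records = []
        for feat in DataIterator(str(path)):
            if feat.featuretype != feature_type:
                continue
            length = feat.end - feat.start + 1
            if length < 1:
                raise ValueError(
                    f"non-positive exon length at {feat.seqid}:{feat.start}-{feat.end}"
                )
            records.append((feat.seqid, length))
        return _samples_from_records(records, src, species)
    if fmt == "bed":
        records = []
        with _open_text(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"BED line {i}: fewer than 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                length = end - start
                if length < 1:
                    raise ValueError(f"BED line {i}: non-positive length")
                records.append((chrom, length))
        return _samples_from_records(records, src, species)
    if fmt == "plain":
        with _open_text(path) as fh:
            lengths = [int(line) for line in fh if line.strip()]
        name = path.name.removesuffix(".gz")
        name = name.rsplit(".", 1)[0] if "." in name else name
        return [LengthSample(species=species, chromosome=name,
                             lengths=np.asarray(lengths), source=src)]
    raise ValueError(f"unknown format {format!r}; expected gff3/gtf/bed/plain")


def summarize(sample: LengthSample) -> SummaryStats:
    """Quartile summary with linearly interpolated order statistics."""
    x = np.asarray(sample.lengths, dtype=float)
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return SummaryStats(
        n=x.size, min=float(x.min()), q1=float(q1), median=float(med),
        q3=float(q3), max=float(x.max()), mean=float(x.mean()),
    )


def iqr_filter(sample: LengthSample) -> OutlierReport:
    """Remove points strictly outside the Tukey fences Q1/Q3 -/+ 1.5 IQR."""
    stats = summarize(sample)
    lower = stats.q1 - 1.5 * stats.iqr
    upper = stats.q3 + 1.5 * stats.iqr
    x = sample.lengths
    mask_out = (x < lower) | (x > upper)
    if mask_out.all():
        raise ValueError("degenerate sample: the fence rule removed every point")
    retained = LengthSample(
        species=sample.species, chromosome=sample.chromosome,
        lengths=x[~mask_out],
        source=f"{sample.source} [IQR-filtered]".strip(),
    )
    return OutlierReport(
        lower_fence=float(lower), upper_fence=float(upper),
        removed=np.sort(x[mask_out]), retained=retained,
        removed_fraction=float(mask_out.mean()),
    )


def empirical_cdf(sample: LengthSample) -> EmpiricalCDF:
    """Empirical CDF at the sorted unique lengths (non-strict <=)."""
    values, counts = np.unique(sample.lengths, return_counts=True)
    n = sample.n
    probs = np.cumsum(counts) / n
    sigma = np.maximum(np.sqrt(probs * (1.0 - probs) / n), 1.0 / (2.0 * n))
    return EmpiricalCDF(grid=values.astype(float), probs=probs,
                        sigma_obs=sigma, n=n)


def relative_difference(value_before: float, value_after: float) -> float:
    """|after - before| / |before|, the RD of a parameter across filtering."""
    if value_before == 0:
        raise ValueError("relative difference undefined for a zero baseline")
    return abs(value_after - value_before) / abs(value_before)


def summary_table(samples: Sequence[LengthSample]) -> pd.DataFrame:
    """Per-chromosome summary statistics as a tidy table."""
    rows = []
    for s in samples:
        st = summarize(s)
        rows.append({
            "species": s.species, "chromosome": s.chromosome, "N": st.n,
            "min": st.min, "Q1": st.q1, "median": st.median, "Q3": st.q3,
            "max": st.max, "mean": st.mean,
        })
    return pd.DataFrame(rows)
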