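"""Synthetic exon-length studies with known ground truth.

Emulates the statistical structure the analysis assumes for cucurbit
genomes: per-chromosome samples of positive integer lengths (bp) whose
bulk follows the kappa-exponential-sum law with kappa in the empirical
exon band (0.27, 0.43) and rates of 0.004-0.009 per bp, sample sizes of
order 10^3-10^4 per chromosome (20 chromosomes per species, as in
*Cucurbita*), plus a small fraction (~1%) of isolated extreme-length
outliers far beyond the fitted curve, as box-plot inspection of real
annotations shows.

Outliers are placed deliberately far in the tail — uniform in log-length
between ``outlier_scale`` times the model's 0.99-quantile and 10 times
that bound — rather than drawn from a second heavy-tailed law, so that
filter tests have unambiguous ground truth.  Continuous draws are rounded
up to integers (min 1 bp) at this boundary, since exon lengths are
integer counts.  Each chromosome gets an independent generator stream
derived from the master seed, so per-chromosome output is reproducible
under reordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .fit import FAMILIES, make_model
from .ingest import LengthSample
from .models import LengthModel

__all__ = [
    "SpeciesSpec",
    "StudyConfig",
    "generate_chromosome",
    "generate_study",
    "write_plain",
    "write_gff3",
]

#: default kappa band for exon lengths and rate band (per bp)
DEFAULT_KAPPA_BAND = (0.27, 0.43)
DEFAULT_RATE_BAND = (0.004, 0.009)


@dataclass(frozen=True)
class SpeciesSpec:
    """One synthetic species: chromosome count and per-chromosome size."""

    name: str
    n_chromosomes: int = 20
    n_per_chromosome: int = 5000
    family: str = "double"
    kappa_band: tuple[float, float] = DEFAULT_KAPPA_BAND
    rate_band: tuple[float, float] = DEFAULT_RATE_BAND


@dataclass(frozen=True)
class StudyConfig:
    """A whole synthetic study (several species) with one master seed."""

    species: tuple[SpeciesSpec, ...] = (
        SpeciesSpec("C_maxima"),
        SpeciesSpec("C_moschata"),
        SpeciesSpec("C_pepo"),
    )
    outlier_fraction: float = 0.01
    outlier_scale: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.outlier_fraction < 0.2):
            raise ValueError("outlier_fraction must lie in [0, 0.2)")
        if not self.outlier_scale > 1:
            raise ValueError("outlier_scale must exceed 1")
        for spec in self.species:
            if spec.n_per_chromosome < 10:
                raise ValueError("need at least 10 lengths per chromosome")


def generate_chromosome(
    family: str,
    params: Union[LengthModel, Sequence[float]],
    n: int,
    outlier_fraction: float = 0.01,
    outlier_scale: float = 50.0,
    seed: Union[int, np.random.Generator, None] = None,
    species: str = "synthetic",
    chromosome: str = "chr01",
) -> LengthSample:
    """One chromosome: model draws plus far-tail outliers, integerized.

    ``round(n * outlier_fraction)`` points are injected above
    ``outlier_scale`` times the model 0.99-quantile (uniform in
    log-length up to 10x that bound); the remainder are inverse-transform
    draws from the model.  All lengths are rounded up to integers >= 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= outlier_fraction < 1.0):
        raise ValueError("outlier_fraction must lie in [0, 1)")
    model = params if isinstance(params, LengthModel) else make_model(family, np.asarray(params, dtype=float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_out = int(round(n * outlier_fraction))
    n_core = n - n_out
    core = model.sample(n_core, rng) if n_core else np.empty(0)
    if n_out:
        lo = outlier_scale * model.quantile(0.99)
        out = 10.0 ** rng.uniform(np.log10(lo), np.log10(10.0 * lo), size=n_out)
        lengths = np.concatenate([core, out])
    else:
        lengths = core
    lengths = np.maximum(np.ceil(lengths), 1.0).astype(np.int64)
    lengths = rng.permutation(lengths)
    truth = {"family": family, "params": model.param_dict(),
             "n": n, "outlier_fraction": outlier_fraction,
             "outlier_scale": outlier_scale}
    return LengthSample(species=species, chromosome=chromosome,
                        lengths=lengths, source=f"synthetic:{json.dumps(truth)}")


def generate_study(config: StudyConfig) -> tuple[list[LengthSample], dict]:
    """Generate every chromosome of every species plus a truth manifest.

    Per chromosome, kappa is drawn uniformly in the species' kappa band
    and the two rates uniformly in its rate band; the manifest records
    every true parameter for recovery scoring.
    """
    samples: list[LengthSample] = []
    manifest: dict = {"seed": config.seed, "chromosomes": []}
    for si, spec in enumerate(config.species):
        for ci in range(spec.n_chromosomes):
            ss = np.random.SeedSequence([config.seed, si, ci])
            rng = np.random.default_rng(ss)
            kappa = rng.uniform(*spec.kappa_band)
            if spec.family == "double":
                g = np.sort(rng.uniform(*spec.rate_band, size=2))
                theta = [kappa, g[0], g[1]]
            elif spec.family == "single":
                theta = [kappa, 1.0 / rng.uniform(*spec.rate_band)]
            elif spec.family == "maxwell":
                theta = [kappa, 1.0 / rng.uniform(*spec.rate_band)]
            else:
                raise ValueError(f"unknown family {spec.family!r}")
            chrom = f"chr{ci + 1:02d}"
            sample = generate_chromosome(
                spec.family, np.asarray(theta), spec.n_per_chromosome,
                outlier_fraction=config.outlier_fraction,
                outlier_scale=config.outlier_scale,
                seed=rng, species=spec.name, chromosome=chrom,
            )
            samples.append(sample)
            names = FAMILIES[spec.family][1]
            manifest["chromosomes"].append({
                "species": spec.name, "chromosome": chrom,
                "family": spec.family,
                "params": dict(zip(names, (float(t) for t in theta))),
                "n": spec.n_per_chromosome,
                "outlier_fraction": config.outlier_fraction,
                "outlier_scale": config.outlier_scale,
            })
    return samples, manifest


def write_plain(sample: LengthSample, path: Union[str, Path]) -> None:
    """One integer length per line."""
    Path(path).write_text("\n".join(str(x) for x in sample.lengths) + "\n")


def write_gff3(samples: Sequence[LengthSample], path: Union[str, Path],
               gap: int = 10) -> None:
    """Minimal GFF3 rendering: consecutive exon features per contig.

    Features are laid out head-to-tail with ``gap`` bp spacing on a
    synthetic contig named after each chromosome, so annotation ingestion
    can be exercised end-to-end without real assemblies.
    """
    lines = ["##gff-version 3"]
    for s in samples:
        pos = 1
        for i, length in enumerate(s.lengths, start=1):
            end = pos + int(length) - 1
            lines.append(
                f"{s.chromosome}\tkappalen_synth\texon\t{pos}\t{end}\t.\t+\t.\t"
                f"ID=exon-{s.chromosome}-{i}"
            )
            pos = end + 1 + gap
    Path(path).write_text("\n".join(lines) + "\n")
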