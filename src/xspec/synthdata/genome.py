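"""Synthetic reference genomes and toy gene models.

The reference generator emits plain multi-FASTA with fixed line wrapping so
that downstream faidx-style indexing works. The toy gene model tiles
fixed-width genes along each chromosome; a configurable fraction of each
gene body is exonic. Gene models are written as BED6 (0-based, half-open)
with the feature type encoded in the name column (``g0001`` for a gene span,
``g0001.exon2`` for an exon).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from ..errors import ConfigError

FASTA_LINE_WIDTH = 60

#: region labels in precedence order (exon beats intron beats intergenic)
REGIONS = ("exonic", "intronic", "intergenic")

_INTERGENIC, _INTRONIC, _EXONIC = 0, 1, 2
_LABEL_NAMES = {_INTERGENIC: "intergenic", _INTRONIC: "intronic", _EXONIC: "exonic"}


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters for a synthetic reference genome."""

    n_chroms: int = 1
    chrom_length: int = 100_000
    gc_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chroms < 1:
            raise ConfigError(f"n_chroms must be >= 1, got {self.n_chroms}")
        if self.chrom_length < 1000:
            raise ConfigError(f"chrom_length must be >= 1000, got {self.chrom_length}")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ConfigError(f"gc_fraction must be in (0, 1), got {self.gc_fraction}")


def generate_reference(spec: SyntheticGenomeSpec) -> Dict[str, str]:
    """Generate random chromosome sequences with the requested GC content.

    Deterministic for a fixed ``spec.seed``: the same spec always yields the
    same sequences.
    """
    rng = np.random.default_rng(spec.seed)
    at = (1.0 - spec.gc_fraction) / 2.0
    gc = spec.gc_fraction / 2.0
    alphabet = np.array(["A", "C", "G", "T"])
    probs = np.array([at, gc, gc, at])
    seqs: Dict[str, str] = {}
    for i in range(1, spec.n_chroms + 1):
        draw = rng.choice(alphabet, size=spec.chrom_length, p=probs)
        seqs[f"chr{i}"] = "".join(draw.tolist())
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path,
                line_width: int = FASTA_LINE_WIDTH) -> Path:
    """Write sequences as FASTA with uniform line wrapping."""
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")
    return path


def gc_content(seq: str) -> float:
    """Observed G+C fraction of a sequence."""
    if not seq:
        raise ConfigError("cannot compute GC content of an empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class Gene:
    """A toy gene: a span plus exon sub-intervals, all 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str
    exons: Tuple[Tuple[int, int], ...]


@dataclass
class GeneModel:
    """A collection of toy genes with fast per-position region lookup."""

    genes: List[Gene]
    chrom_sizes: Dict[str, int] = field(default_factory=dict)

    @functools.cached_property
    def _label_arrays(self) -> Dict[str, np.ndarray]:
        arrays = {c: np.zeros(n, dtype=np.int8) for c, n in self.chrom_sizes.items()}
        for g in self.genes:
            arrays[g.chrom][g.start:g.end] = np.maximum(
                arrays[g.chrom][g.start:g.end], _INTRONIC)
        for g in self.genes:
            for s, e in g.exons:
                arrays[g.chrom][s:e] = _EXONIC
        return arrays

    def region_of(self, chrom: str, pos: int) -> str:
        """Region label at a 1-based position. Exon > intron > intergenic."""
        return _LABEL_NAMES[int(self._label_arrays[chrom][pos - 1])]

    def region_mask(self, chrom: str, region: str) -> np.ndarray:
        """Boolean mask (0-based) of positions carrying ``region`` on ``chrom``."""
        code = {v: k for k, v in _LABEL_NAMES.items()}[region]
        return self._label_arrays[chrom] == code

    def to_bed(self, path: str | Path) -> Path:
        """Write BED6: one line per gene span, one per exon."""
        path = Path(path)
        with path.open("w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t+\n")
                for i, (s, e) in enumerate(g.exons, start=1):
                    fh.write(f"{g.chrom}\t{s}\t{e}\t{g.name}.exon{i}\t0\t+\n")
        return path


def make_gene_model(chrom_sizes: Mapping[str, int],
                    gene_length: int = 2000,
                    spacing: int = 2000,
                    exon_fraction: float = 0.3,
                    n_exons: int = 3) -> GeneModel:
    """Tile fixed-width genes along each chromosome.

    Each gene carries ``n_exons`` evenly spaced exons covering
    ``exon_fraction`` of the gene body; the rest of the body is intronic and
    everything between genes is intergenic.
    """
    if not 0.0 < exon_fraction < 1.0:
        raise ConfigError(f"exon_fraction must be in (0, 1), got {exon_fraction}")
    if gene_length < n_exons or n_exons < 1:
        raise ConfigError("gene_length must accommodate at least one exon")
    exon_len = max(1, int(gene_length * exon_fraction / n_exons))
    genes: List[Gene] = []
    idx = 0
    for chrom, size in chrom_sizes.items():
        start = spacing // 2
        while start + gene_length <= size:
            idx += 1
            # exons evenly distributed across the gene body
            step = gene_length // n_exons
            exons = tuple(
                (start + k * step, start + k * step + exon_len)
                for k in range(n_exons)
            )
            genes.append(Gene(chrom, start, start + gene_length,
                              f"g{idx:04d}", exons))
            start += gene_length + spacing
    return GeneModel(genes=genes, chrom_sizes=dict(chrom_sizes))
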