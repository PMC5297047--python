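"""Simulated somatic variant callers with configurable error profiles.

Each simulated caller emits true somatic calls with probability
``sensitivity``, plus false positives drawn from the planted germline SNPs
(the dominant real-world confusion source) and from random error loci, at a
configurable per-megabase rate. Quality scores are either informative (true
calls drawn from a distribution shifted +1.5 SD above false calls) or
exchangeable between true and false calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from ..errors import ConfigError
from .variants import TruthSet

#: internal truth labels attached to every emitted record
LABEL_TRUE = "somatic-true"
LABEL_GERMLINE = "germline-contamination"
LABEL_ERROR = "error"


@dataclass(frozen=True)
class CallerModel:
    """Error and score profile of a simulated caller."""

    name: str
    sensitivity: float
    false_positive_rate_per_mb: float = 0.0
    score_informative: bool = True
    seed: int = 0
    #: fraction of false positives sourced from germline loci (rest: random error loci)
    germline_fp_fraction: float = 0.7
    score_loc: float = 25.0
    score_scale: float = 5.0
    score_shift_sd: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ConfigError(f"sensitivity must be in [0, 1], got {self.sensitivity}")
        if self.false_positive_rate_per_mb < 0:
            raise ConfigError("false_positive_rate_per_mb must be >= 0")
        if not 0.0 <= self.germline_fp_fraction <= 1.0:
            raise ConfigError("germline_fp_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    score: float
    label: str  # one of LABEL_TRUE / LABEL_GERMLINE / LABEL_ERROR

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def simulate_caller(truth: TruthSet, model: CallerModel,
                    reference: Mapping[str, str]) -> List[SimulatedCall]:
    """Emit a caller's calls against a truth set.

    The returned records carry internal truth labels partitioning the
    callset into true somatic calls, germline contamination, and random
    error calls.
    """
    rng = np.random.default_rng(model.seed)
    calls: List[SimulatedCall] = []

    # true calls
    for v in truth.somatic:
        if rng.random() < model.sensitivity:
            calls.append(SimulatedCall(v.chrom, v.pos, v.ref, v.alt, 0.0, LABEL_TRUE))

    # false positives
    genome_bp = sum(len(s) for s in reference.values())
    n_fp = int(round(model.false_positive_rate_per_mb * genome_bp / 1e6))
    n_germ = min(int(round(model.germline_fp_fraction * n_fp)), len(truth.germline))
    n_err = n_fp - n_germ
    if n_germ:
        picks = rng.choice(len(truth.germline), size=n_germ, replace=False)
        for i in picks.tolist():
            g = truth.germline[i]
            calls.append(SimulatedCall(g.chrom, g.pos, g.ref, g.alt, 0.0, LABEL_GERMLINE))
    taken = {(c.chrom, c.pos) for c in calls}
    taken |= {(v.chrom, v.pos) for v in truth.somatic + truth.germline}
    chroms = list(reference)
    while n_err > 0:
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, len(reference[chrom]) + 1))
        if (chrom, pos) in taken:
            continue
        ref = reference[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        calls.append(SimulatedCall(chrom, pos, ref, alt, 0.0, LABEL_ERROR))
        taken.add((chrom, pos))
        n_err -= 1

    # quality scores
    shift = model.score_shift_sd * model.score_scale if model.score_informative else 0.0
    scored: List[SimulatedCall] = []
    for c in calls:
        loc = model.score_loc + (shift if c.label == LABEL_TRUE else 0.0)
        score = float(max(0.01, rng.normal(loc, model.score_scale)))
        scored.append(SimulatedCall(c.chrom, c.pos, c.ref, c.alt, score, c.label))
    scored.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return scored


def write_vcf(calls: Sequence[SimulatedCall], reference: Mapping[str, str],
              path: str | Path, *, source: str = "xspec-sim",
              clonal_fraction: float = 0.5, depth: int = 40,
              seed: int = 0) -> Path:
    """Write simulated calls as VCF 4.2 with AD-style tumor/normal depths.

    Depths are drawn per record from the label-appropriate allele fraction
    (clonal for true somatic calls, heterozygous for germline contamination,
    near-zero for error calls) so the file is self-consistent, though
    downstream consensus logic only uses site, alleles and QUAL.
    """
    rng = np.random.default_rng(seed)
    path = Path(path)
    afs = {LABEL_TRUE: (clonal_fraction, 0.0),
           LABEL_GERMLINE: (0.5, 0.5),
           LABEL_ERROR: (0.02, 0.0)}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom, seq in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL\n")
        for c in calls:
            t_af, n_af = afs[c.label]
            t_alt = int(rng.binomial(depth, t_af))
            n_alt = int(rng.binomial(depth, n_af))
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.score:.2f}\tPASS\t.\t"
                f"AD:DP\t{depth - t_alt},{t_alt}:{depth}\t{depth - n_alt},{n_alt}:{depth}\n")
    return path
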