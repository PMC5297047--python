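"""Per-caller VCF ingestion, consensus, quartile stratification, panels.

Variant identity is positional + allelic only: ``(chrom, pos, ref, alt)``
with an optional ``chr`` prefix stripped from chromosome names. Quality and
depths never participate in matching.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pysam

from .errors import CapacityError, ParseError, UsageError
from .sequtils import normalize_chrom

logger = logging.getLogger(__name__)

VariantKey = Tuple[str, int, str, str]

_SNV_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantCall:
    """One called SNV from one caller."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    caller: str
    quality: float
    tumor_depths: Optional[Tuple[int, int]] = None  # (ref_count, alt_count)
    normal_depths: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise UsageError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in _SNV_BASES or self.alt not in _SNV_BASES:
            raise UsageError(f"non-SNV alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise UsageError(f"position must be >= 1, got {self.pos}")
        if not np.isfinite(self.quality):
            raise UsageError(f"non-finite quality at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)


def _sample_depths(rec: "pysam.VariantRecord", sample: str,
                   alt_index: int) -> Optional[Tuple[int, int]]:
    try:
        ad = rec.samples[sample].get("AD")
    except (KeyError, ValueError):
        return None
    if ad is None or ad[0] is None:
        return None
    try:
        return int(ad[0]), int(ad[1 + alt_index])
    except (IndexError, TypeError):
        return None


def load_calls(path: str | Path, caller_name: str) -> List[VariantCall]:
    """Load SNV calls from a VCF, splitting multi-allelic records.

    Non-SNV and symbolic-allele records are dropped; the dropped count is
    logged. Malformed VCFs raise :class:`ParseError`.
    """
    path = Path(path)
    calls: List[VariantCall] = []
    dropped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    tumor = samples[0] if samples else None
    normal = samples[1] if len(samples) > 1 else None
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if (len(rec.ref) == 1 and alt is not None and len(alt) == 1
                        and rec.ref in _SNV_BASES and alt in _SNV_BASES):
                    calls.append(VariantCall(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        caller=caller_name,
                        quality=float(rec.qual) if rec.qual is not None else 0.0,
                        tumor_depths=_sample_depths(rec, tumor, i) if tumor else None,
                        normal_depths=_sample_depths(rec, normal, i) if normal else None,
                    ))
                else:
                    dropped += 1
    if dropped:
        logger.info("%s: dropped %d non-SNV/symbolic allele(s)", path.name, dropped)
    return calls


@dataclass
class ConsensusReport:
    """Counts and keys from intersecting two or more callsets."""

    per_caller_counts: Dict[str, int]
    intersection_count: int
    union_count: int
    intersection_keys: Set[VariantKey]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "per_caller_counts": self.per_caller_counts,
            "intersection_count": self.intersection_count,
            "union_count": self.union_count,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def consensus(callsets: Mapping[str, Sequence[VariantCall]]) -> ConsensusReport:
    """Intersection/union report over per-caller callsets.

    Keys are matched exactly on (chrom, pos, ref, alt) after chromosome-name
    normalization.
    """
    if len(callsets) < 2:
        raise UsageError("consensus requires at least 2 callers")
    keysets = {name: {c.key for c in calls} for name, calls in callsets.items()}
    inter: Set[VariantKey] = set.intersection(*keysets.values())
    union: Set[VariantKey] = set.union(*keysets.values())
    return ConsensusReport(
        per_caller_counts={name: len(ks) for name, ks in keysets.items()},
        intersection_count=len(inter),
        union_count=len(union),
        intersection_keys=inter,
    )


def quartile_stratify(calls: Sequence[VariantCall]) -> Dict[int, List[VariantCall]]:
    """Bin one caller's calls into quartiles of its own quality scores.

    Cut points are the 25/50/75th percentiles; ties at a boundary go to the
    lower quartile. With fewer than 4 calls stratification is meaningless
    and raises :class:`UsageError`.
    """
    if len(calls) < 4:
        raise UsageError(f"need >= 4 calls to stratify, got {len(calls)}")
    scores = np.array([c.quality for c in calls], dtype=float)
    q25, q50, q75 = np.percentile(scores, [25, 50, 75])
    if q25 == q75:
        logger.warning("degenerate quality scores: all calls fall in one quartile bin")
    bins: Dict[int, List[VariantCall]] = {1: [], 2: [], 3: [], 4: []}
    for call, s in zip(calls, scores):
        if s <= q25:
            q = 1
        elif s <= q50:
            q = 2
        elif s <= q75:
            q = 3
        else:
            q = 4
        bins[q].append(call)
    return bins


@dataclass(frozen=True)
class PanelDesign:
    """Validation-panel draw sizes.

    ``n_unique_per_caller`` is split as evenly as possible across that
    caller's four quality quartiles; ``n_per_quartile``, when given, caps the
    per-quartile draw (the historical 48-per-quartile protocol).
    """

    n_overlap: int
    n_unique_per_caller: int
    n_per_quartile: Optional[int] = None

    def per_quartile_draws(self) -> Tuple[int, int, int, int]:
        base, rem = divmod(self.n_unique_per_caller, 4)
        draws = tuple(base + (1 if i < rem else 0) for i in range(4))
        if self.n_per_quartile is not None and max(draws) > self.n_per_quartile:
            raise UsageError(
                f"design asks {max(draws)} per quartile but caps at {self.n_per_quartile}")
        return draws


@dataclass(frozen=True)
class PanelEntry:
    key: VariantKey
    source: str  # "overlap" or "<caller>-unique"
    quality_quartile: int


@dataclass
class ValidationPanel:
    entries: List[PanelEntry]
    design: PanelDesign
    seed: int

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("chrom\tpos\tref\talt\tsource\tquality_quartile\n")
            for e in self.entries:
                c, p, r, a = e.key
                fh.write(f"{c}\t{p}\t{r}\t{a}\t{e.source}\t{e.quality_quartile}\n")
        return path


def build_panel(report: ConsensusReport,
                stratified: Mapping[str, Mapping[int, Sequence[VariantCall]]],
                design: PanelDesign,
                seed: int = 0) -> ValidationPanel:
    """Draw a validation panel: overlap entries plus per-caller unique strata.

    Sampling is without replacement, uniform within each stratum, and
    deterministic for a fixed seed. Unique strata are each caller's calls
    outside the consensus intersection, per quality quartile.
    """
    rng = np.random.default_rng(seed)
    entries: List[PanelEntry] = []

    # overlap stratum
    inter = sorted(report.intersection_keys)
    if design.n_overlap > len(inter):
        raise CapacityError(
            f"overlap stratum has {len(inter)} keys, design asks {design.n_overlap}")
    # quartile of an overlap key is taken from the first caller listing it
    key_quartile: Dict[VariantKey, int] = {}
    for caller in stratified:
        for q, calls in stratified[caller].items():
            for c in calls:
                key_quartile.setdefault(c.key, q)
    if design.n_overlap:
        picks = rng.choice(len(inter), size=design.n_overlap, replace=False)
        for i in sorted(picks.tolist()):
            key = inter[i]
            entries.append(PanelEntry(key, "overlap", key_quartile.get(key, 1)))

    # per-caller unique strata
    draws = design.per_quartile_draws()
    others = {caller: set().union(*(
        {c.key for calls in strat.values() for c in calls}
        for name, strat in stratified.items() if name != caller)) or set()
        for caller in stratified}
    for caller, strat in stratified.items():
        exclude = report.intersection_keys | others[caller]
        for q in (1, 2, 3, 4):
            pool = sorted({c.key for c in strat.get(q, ())} - exclude)
            need = draws[q - 1]
            if need == 0:
                continue
            if len(pool) < need:
                raise CapacityError(
                    f"stratum {caller} quartile {q} has {len(pool)} unique "
                    f"calls, design asks {need}")
            picks = rng.choice(len(pool), size=need, replace=False)
            for i in sorted(picks.tolist()):
                entries.append(PanelEntry(pool[i], f"{caller}-unique", q))

    seen = {e.key for e in entries}
    if len(seen) != len(entries):
        raise UsageError("panel entries are not unique by variant key")
    return ValidationPanel(entries=entries, design=design, seed=seed)
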