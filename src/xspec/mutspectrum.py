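"""Mutation burden extrapolation, substitution spectra and signatures.

Substitution spectra are pyrimidine-normalized: purine-reference changes
are reverse-complemented (G>A counted as C>T with complemented, swapped
flanks), giving 6 substitution classes and 96 trinucleotide contexts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import DomainError, ParseError
from .sequtils import CONTEXTS_96, PYR_CLASSES, normalize_chrom, normalize_substitution

logger = logging.getLogger(__name__)

#: default genome size used for per-Mb rates (zebrafish assembly denominator)
DEFAULT_GENOME_SIZE_BP = 1_412_464_843

VariantLike = Union[Tuple[str, int, str, str], object]


def _as_key(v: VariantLike) -> Tuple[str, int, str, str]:
    if hasattr(v, "key"):
        return tuple(v.key)  # type: ignore[arg-type]
    chrom, pos, ref, alt = v  # type: ignore[misc]
    return str(chrom), int(pos), str(ref), str(alt)


# ---------------------------------------------------------------------------
# burden extrapolation


@dataclass(frozen=True)
class MutationRateEstimate:
    n_called: int
    validation_rate: float
    expected_true: int
    genome_size_bp: int
    rate_per_mb: float  # full precision; use display_rate for the printed form

    @property
    def display_rate(self) -> str:
        return format_rate_per_mb(self.rate_per_mb)


def extrapolate(n_called: int, validation_rate: float) -> int:
    """Expected count of true mutations: ``floor(n_called * rate)``."""
    if n_called < 0:
        raise DomainError(f"n_called must be >= 0, got {n_called}")
    if not 0.0 <= validation_rate <= 1.0:
        raise DomainError(f"validation_rate must be in [0, 1], got {validation_rate}")
    return math.floor(n_called * validation_rate)


def rate_per_mb(expected_true: int, genome_size_bp: int) -> float:
    """Mutations per megabase, full precision."""
    if expected_true < 0:
        raise DomainError(f"expected_true must be >= 0, got {expected_true}")
    if genome_size_bp <= 0:
        raise DomainError(f"genome_size_bp must be > 0, got {genome_size_bp}")
    return expected_true * 1e6 / genome_size_bp


def format_rate_per_mb(value: float) -> str:
    """Display form: truncated (not rounded) to two decimals."""
    truncated = math.floor(value * 100 + 1e-9) / 100
    return f"{truncated:.2f}"


def estimate_mutation_rate(n_called: int, validation_rate: float,
                           genome_size_bp: int = DEFAULT_GENOME_SIZE_BP,
                           ) -> MutationRateEstimate:
    expected = extrapolate(n_called, validation_rate)
    return MutationRateEstimate(
        n_called=n_called, validation_rate=validation_rate,
        expected_true=expected, genome_size_bp=genome_size_bp,
        rate_per_mb=rate_per_mb(expected, genome_size_bp))


# ---------------------------------------------------------------------------
# substitution spectrum


@dataclass
class SubstitutionSpectrum:
    class_counts: Dict[str, int]
    context_counts: Dict[str, int]
    n_total: int
    n_context_excluded: int = 0  # variants at sequence ends, no trinucleotide

    def class_fractions(self) -> Dict[str, float]:
        if self.n_total == 0:
            raise DomainError("empty spectrum")
        return {c: self.class_counts[c] / self.n_total for c in PYR_CLASSES}

    def context_vector(self, normalized: bool = True) -> np.ndarray:
        v = np.array([self.context_counts.get(c, 0) for c in CONTEXTS_96], float)
        if normalized:
            total = v.sum()
            if total == 0:
                raise DomainError("spectrum has no context counts")
            v = v / total
        return v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "context": list(CONTEXTS_96),
            "count": [self.context_counts.get(c, 0) for c in CONTEXTS_96],
        })


def spectrum(variants: Iterable[VariantLike],
             reference: Union[str, Path, Mapping[str, str]]) -> SubstitutionSpectrum:
    """Pyrimidine-normalized 6-class / 96-context spectrum of SNVs.

    ``reference`` is a FASTA path (read via faidx) or an in-memory mapping of
    chromosome name to sequence. Every variant's ref base must match the
    reference; variants at sequence ends contribute to class counts but are
    excluded from context counts with a logged tally.
    """
    if isinstance(reference, (str, Path)):
        fasta = Fasta(str(reference))
        raw: Mapping[str, str] = {name: str(fasta[name][:]) for name in fasta.keys()}
    else:
        raw = reference
    seqs = {normalize_chrom(name): seq for name, seq in raw.items()}
    class_counts = {c: 0 for c in PYR_CLASSES}
    context_counts: Dict[str, int] = {c: 0 for c in CONTEXTS_96}
    n_total = 0
    n_excluded = 0
    mismatches: List[str] = []
    for v in variants:
        chrom, pos, ref, alt = _as_key(v)
        chrom = normalize_chrom(chrom)
        if chrom not in seqs:
            raise DomainError(f"chromosome {chrom!r} not in reference")
        seq = seqs[chrom]
        if not 1 <= pos <= len(seq):
            raise DomainError(f"position {chrom}:{pos} outside reference")
        if seq[pos - 1] != ref:
            mismatches.append(f"{chrom}:{pos} (expected {seq[pos - 1]}, got {ref})")
            continue
        n_total += 1
        if pos == 1 or pos == len(seq):
            cls = normalize_substitution(ref, alt, "A", "A")[0]
            class_counts[cls] += 1
            n_excluded += 1
            continue
        cls, ctx = normalize_substitution(ref, alt, seq[pos - 2], seq[pos])
        class_counts[cls] += 1
        context_counts[ctx] += 1
    if mismatches:
        raise DomainError("reference mismatch at: " + ", ".join(mismatches))
    if n_excluded:
        logger.info("excluded %d end-of-sequence variant(s) from context counts",
                    n_excluded)
    return SubstitutionSpectrum(class_counts=class_counts,
                                context_counts=context_counts,
                                n_total=n_total, n_context_excluded=n_excluded)


def dipyrimidine_report(spec: SubstitutionSpectrum) -> Dict[str, float]:
    """Context fractions of C>T mutations at TCA/TCG/TCC and dipyrimidines.

    Each triplet fraction is reported over two denominators: all mutations
    (``*_of_all``) and C>T mutations only (``*_of_ct``). The dipyrimidine
    fraction counts C>T mutations whose 5' neighbor is a pyrimidine.
    """
    if spec.n_total == 0:
        raise DomainError("empty spectrum")
    ct_contexts = {c: spec.context_counts.get(c, 0)
                   for c in CONTEXTS_96 if "[C>T]" in c}
    n_ct = sum(ct_contexts.values())
    out: Dict[str, float] = {}
    for trip in ("TCA", "TCG", "TCC"):
        key = f"{trip[0]}[C>T]{trip[2]}"
        count = spec.context_counts.get(key, 0)
        out[f"{trip}_of_all"] = count / spec.n_total
        out[f"{trip}_of_ct"] = count / n_ct if n_ct else 0.0
    dipyr = sum(v for c, v in ct_contexts.items() if c[0] in "CT")
    out["dipyrimidine_of_ct"] = dipyr / n_ct if n_ct else 0.0
    out["dipyrimidine_of_all"] = dipyr / spec.n_total
    return out


# ---------------------------------------------------------------------------
# genomic-region breakdown


@dataclass
class RegionBreakdown:
    counts: Dict[str, int]
    fractions: Dict[str, float]
    labels: Dict[Tuple[str, int, str, str], str] = field(default_factory=dict)


def _parse_bed_intervals(path: str | Path) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
    """BED6 gene model -> per-chrom exon and gene-span interval lists.

    Lines whose name field contains ``exon`` are exons; all other lines are
    gene spans (intronic outside exons). Intervals are 0-based half-open.
    """
    out: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has < 3 fields")
            chrom = normalize_chrom(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: end < start")
            feature = "exon" if len(fields) > 3 and "exon" in fields[3].lower() else "gene"
            out.setdefault(chrom, {"exon": [], "gene": []})[feature].append((start, end))
    return out


def _merged_arrays(intervals: List[Tuple[int, int]]) -> Tuple[np.ndarray, np.ndarray]:
    if not intervals:
        return np.array([], int), np.array([], int)
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    arr = np.array(merged, int)
    return arr[:, 0], arr[:, 1]


def region_breakdown(variants: Iterable[VariantLike],
                     gene_model_bed: str | Path) -> RegionBreakdown:
    """Classify variants as exonic / intronic / intergenic against a BED.

    BED intervals are 0-based half-open; variant positions are 1-based.
    Precedence when intervals overlap: exonic > intronic > intergenic.
    Unsorted BED input is accepted and sorted internally.
    """
    model = _parse_bed_intervals(gene_model_bed)
    lookups = {
        chrom: {feat: _merged_arrays(ivals) for feat, ivals in feats.items()}
        for chrom, feats in model.items()
    }

    def contains(chrom: str, feat: str, pos0: int) -> bool:
        starts, ends = lookups.get(chrom, {}).get(feat, (np.array([]), np.array([])))
        if len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
    labels: Dict[Tuple[str, int, str, str], str] = {}
    for v in variants:
        key = _as_key(v)
        chrom, pos = normalize_chrom(key[0]), key[1]
        pos0 = pos - 1
        if contains(chrom, "exon", pos0):
            label = "exonic"
        elif contains(chrom, "gene", pos0):
            label = "intronic"
        else:
            label = "intergenic"
        counts[label] += 1
        labels[key] = label
    total = sum(counts.values())
    fractions = {k: (c / total if total else 0.0) for k, c in counts.items()}
    return RegionBreakdown(counts=counts, fractions=fractions, labels=labels)


# ---------------------------------------------------------------------------
# signature similarity


def signature_similarity(spec: SubstitutionSpectrum,
                         signatures: pd.DataFrame) -> pd.DataFrame:
    """Cosine similarity of a spectrum against reference signature profiles.

    ``signatures`` is a 96-row matrix (indexed by context key or in
    :data:`CONTEXTS_96` order) with one nonnegative, unit-sum column per
    signature. Returns a frame ranked by descending similarity; ties keep
    column order.
    """
    if signatures.shape[0] != 96:
        raise DomainError(f"signature matrix must have 96 rows, got {signatures.shape[0]}")
    if set(signatures.index) == set(CONTEXTS_96):
        sig = signatures.loc[list(CONTEXTS_96)]
    else:
        sig = signatures.set_axis(list(CONTEXTS_96), axis=0)
    mat = sig.to_numpy(dtype=float)
    if (mat < 0).any():
        raise DomainError("signature profiles must be nonnegative")
    colsums = mat.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise DomainError("signature columns must sum to 1")
    v = spec.context_vector(normalized=True)
    vnorm = np.linalg.norm(v)
    sims = []
    for j, name in enumerate(sig.columns):
        col = mat[:, j]
        denom = vnorm * np.linalg.norm(col)
        sims.append(float(v @ col / denom) if denom > 0 else 0.0)
    out = pd.DataFrame({"signature": list(sig.columns), "cosine_similarity": sims})
    out = out.sort_values("cosine_similarity", ascending=False,
                          kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
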