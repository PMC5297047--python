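"""Planting germline SNPs and clonal somatic SNVs with known ground truth.

Somatic variants are drawn with configurable weights over the six
pyrimidine-normalized substitution classes, optional trinucleotide-context
fractions for the C>T class, and a configurable split over genomic regions
(exonic / intronic / intergenic) defined by a toy gene model. All
coordinates are 1-based inclusive, matching VCF.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from ..errors import CapacityError, ConfigError
from ..sequtils import COMPLEMENT, PYR_CLASSES, normalize_chrom, pyrimidine_class, revcomp
from .genome import GeneModel, REGIONS, make_gene_model

Locus = Tuple[str, int, str, str]  # (chrom, pos 1-based, ref, alt)


@dataclass(frozen=True)
class PlantedVariant:
    """One planted variant with its full ground-truth annotation."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    kind: str  # "somatic" or "germline"
    region: str
    pyr_class: Optional[str] = None
    context: Optional[str] = None  # pyrimidine-strand trinucleotide, e.g. "TCA"

    @property
    def key(self) -> Locus:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TruthSet:
    """Ground truth for a simulated tumor/normal pair."""

    somatic: List[PlantedVariant]
    germline: List[PlantedVariant]
    clonal_fraction: float
    gene_model: GeneModel

    def __post_init__(self) -> None:
        self._somatic_pos: Set[Tuple[str, int]] = {
            (normalize_chrom(v.chrom), v.pos) for v in self.somatic}
        self._germline_pos: Set[Tuple[str, int]] = {
            (normalize_chrom(v.chrom), v.pos) for v in self.germline}

    @property
    def somatic_loci(self) -> Set[Locus]:
        return {v.key for v in self.somatic}

    @property
    def germline_loci(self) -> Set[Locus]:
        return {v.key for v in self.germline}

    @property
    def region_labels(self) -> Dict[Locus, str]:
        return {v.key: v.region for v in self.somatic + self.germline}

    def kind_of(self, chrom: str, pos: int) -> str:
        """Truth status of a position: somatic, germline, or error.

        Chromosome names are normalized, so truth built on ``chr1`` matches
        queries phrased as ``1``.
        """
        key = (normalize_chrom(chrom), pos)
        if key in self._somatic_pos:
            return "somatic"
        if key in self._germline_pos:
            return "germline"
        return "error"


def _context_positions(arr: np.ndarray, ctx: str) -> np.ndarray:
    """0-based positions whose reference trinucleotide matches ``ctx`` on
    either strand (``ctx`` given pyrimidine-centered)."""
    hits = []
    for pat in (ctx, revcomp(ctx)):
        l, c, r = (np.bytes_(b.encode()) for b in pat)
        mask = (arr[1:-1] == c) & (arr[:-2] == l) & (arr[2:] == r)
        hits.append(np.flatnonzero(mask) + 1)
    return np.unique(np.concatenate(hits))


def plant_variants(
    reference: Mapping[str, str],
    *,
    n_somatic: int,
    germline_rate: float = 0.0,
    spectrum_weights: Sequence[float] | None = None,
    region_model: Mapping[str, float] | None = None,
    context_fractions: Mapping[str, float] | None = None,
    clonal_fraction: float = 0.5,
    gene_model: GeneModel | None = None,
    seed: int = 0,
) -> TruthSet:
    """Plant germline SNPs and exactly ``n_somatic`` clonal somatic SNVs.

    Parameters
    ----------
    spectrum_weights:
        Nonnegative weights over the six classes in :data:`PYR_CLASSES`
        order. Defaults to uniform.
    region_model:
        Fractions over ``{exonic, intronic, intergenic}`` controlling where
        somatic variants land. ``None`` places them uniformly at random.
    context_fractions:
        Optional fractions of *all* somatic variants forced to be C>T at a
        given pyrimidine-strand trinucleotide, e.g. ``{"TCA": 0.17}``.
        Remaining variants avoid the listed contexts so the planted
        fractions are recoverable.
    """
    if spectrum_weights is None:
        spectrum_weights = (1.0,) * 6
    w = np.asarray(spectrum_weights, dtype=float)
    if len(w) != 6 or (w < 0).any() or w.sum() <= 0:
        raise ConfigError("spectrum_weights must be 6 nonnegative values with positive sum")
    w = w / w.sum()
    if not 0.0 <= germline_rate < 1.0:
        raise ConfigError(f"germline_rate must be in [0, 1), got {germline_rate}")
    if not 0.0 < clonal_fraction <= 1.0:
        raise ConfigError(f"clonal_fraction must be in (0, 1], got {clonal_fraction}")
    ctx_fracs: Dict[str, float] = dict(context_fractions or {})
    for ctx in ctx_fracs:
        if len(ctx) != 3 or ctx[1] != "C" or any(b not in "ACGT" for b in ctx):
            raise ConfigError(f"context_fractions keys must be C-centered triplets, got {ctx!r}")
    if sum(ctx_fracs.values()) > 1.0 + 1e-12:
        raise ConfigError("context_fractions must sum to <= 1")

    rng = np.random.default_rng(seed)
    chrom_sizes = {c: len(s) for c, s in reference.items()}
    if gene_model is None:
        gene_model = make_gene_model(chrom_sizes)

    arrays = {c: np.frombuffer(s.encode(), dtype="S1") for c, s in reference.items()}
    chroms = list(reference)

    # --- germline SNPs: independent Bernoulli per position -----------------
    germline: List[PlantedVariant] = []
    used: Set[Tuple[str, int]] = set()  # 0-based
    if germline_rate > 0:
        for chrom in chroms:
            hits = np.flatnonzero(rng.random(chrom_sizes[chrom]) < germline_rate)
            for p0 in hits.tolist():
                ref = arrays[chrom][p0].decode()
                alt = rng.choice([b for b in "ACGT" if b != ref])
                germline.append(PlantedVariant(
                    chrom, p0 + 1, ref, str(alt), "germline",
                    gene_model.region_of(chrom, p0 + 1)))
                used.add((chrom, p0))

    # --- somatic assignment: (region, requirement) buckets -----------------
    region_names: List[Optional[str]]
    if region_model is None:
        region_names, region_probs = [None], np.array([1.0])
    else:
        missing = set(region_model) - set(REGIONS)
        if missing:
            raise ConfigError(f"unknown regions in region_model: {sorted(missing)}")
        region_names = list(region_model)
        region_probs = np.asarray([region_model[r] for r in region_names], float)
        if (region_probs < 0).any() or region_probs.sum() <= 0:
            raise ConfigError("region_model fractions must be nonnegative with positive sum")
        region_probs = region_probs / region_probs.sum()

    # requirement is ("ctx", triplet) or ("class", cls)
    ctx_names = list(ctx_fracs)
    ctx_probs = np.array([ctx_fracs[c] for c in ctx_names] + [1.0 - sum(ctx_fracs.values())])
    reqs: List[Tuple[str, str]] = []
    for _ in range(n_somatic):
        k = rng.choice(len(ctx_probs), p=ctx_probs)
        if k < len(ctx_names):
            reqs.append(("ctx", ctx_names[k]))
        else:
            reqs.append(("class", PYR_CLASSES[rng.choice(6, p=w)]))
    regions = [region_names[rng.choice(len(region_probs), p=region_probs)]
               for _ in range(n_somatic)]
    buckets = Counter(zip(regions, reqs))

    # precomputed context exclusion for the residual C>T pool
    excluded_ctx: Dict[str, np.ndarray] = {}
    if ctx_names:
        for chrom in chroms:
            ex = [_context_positions(arrays[chrom], ctx) for ctx in ctx_names]
            excluded_ctx[chrom] = np.unique(np.concatenate(ex)) if ex else np.array([], int)

    def pool_for(region: Optional[str], req: Tuple[str, str]) -> List[Tuple[str, int]]:
        out: List[Tuple[str, int]] = []
        for chrom in chroms:
            arr = arrays[chrom]
            if req[0] == "ctx":
                idx = _context_positions(arr, req[1])
            else:
                base = req[1][0]  # pyrimidine of the class
                mask = (arr == base.encode()) | (arr == COMPLEMENT[base].encode())
                idx = np.flatnonzero(mask)
                if base == "C" and ctx_names:
                    idx = np.setdiff1d(idx, excluded_ctx[chrom], assume_unique=False)
            if region is not None:
                rmask = gene_model.region_mask(chrom, region)
                idx = idx[rmask[idx]]
            out.extend((chrom, int(p)) for p in idx.tolist()
                       if (chrom, int(p)) not in used)
        return out

    somatic: List[PlantedVariant] = []
    for (region, req), count in sorted(buckets.items(), key=lambda kv: str(kv[0])):
        pool = pool_for(region, req)
        if len(pool) < count:
            raise CapacityError(
                f"need {count} positions for {req[1]} in region "
                f"{region or 'any'}, only {len(pool)} available")
        picks = rng.choice(len(pool), size=count, replace=False)
        for i in picks.tolist():
            chrom, p0 = pool[i]
            ref = arrays[chrom][p0].decode()
            cls = req[1] if req[0] == "class" else "C>T"
            pyr_ref, pyr_alt = cls.split(">")
            alt = pyr_alt if ref == pyr_ref else COMPLEMENT[pyr_alt]
            if 0 < p0 < chrom_sizes[chrom] - 1:
                tri = b"".join(arrays[chrom][p0 - 1:p0 + 2]).decode()
                ctx = tri if ref in "CT" else revcomp(tri)
            else:
                ctx = None
            somatic.append(PlantedVariant(
                chrom, p0 + 1, ref, alt, "somatic",
                gene_model.region_of(chrom, p0 + 1), cls, ctx))
            used.add((chrom, p0))

    return TruthSet(somatic=somatic, germline=germline,
                    clonal_fraction=clonal_fraction, gene_model=gene_model)
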