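"""Ortholog mapping, gene-set overlap and cohort mutation-frequency contrast.

Ortholog mapping collapses DIOPT-style multi-hits to the highest-scored
human symbol (lexicographic tie-break). Cohort frequencies count each
(cohort, sample) pair once per gene regardless of how many mutations it
carries; enrichment testing (Fisher + Benjamini-Hochberg) is supplementary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ParseError

ORTHOLOG_COLUMNS = ("fish_id", "human_symbol", "score")

#: accepted aliases for MAF-style cohort tables
_COHORT_ALIASES = {"hugo_symbol": "gene", "tumor_sample_barcode": "sample_id"}


# ---------------------------------------------------------------------------
# ortholog mapping


@dataclass
class OrthologReport:
    n_input: int
    n_mapped: int
    n_unique_human: int
    mapping: Dict[str, str]  # fish_id -> best human symbol
    unmapped: List[str]
    human_symbols: Set[str] = field(default_factory=set)


def load_ortholog_table(source: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        table = source
    else:
        table = pd.read_csv(source, sep="\t")
    missing = set(ORTHOLOG_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"ortholog table missing columns: {sorted(missing)}")
    return table[list(ORTHOLOG_COLUMNS)].copy()


def map_orthologs(fish_genes: Sequence[str],
                  table: Union[str, Path, pd.DataFrame]) -> OrthologReport:
    """Map fish gene ids to human symbols, keeping the best-scored candidate.

    Ties on score are broken by the lexicographically smallest human symbol.
    Human symbols are de-duplicated in the reported unique count.
    """
    df = load_ortholog_table(table)
    fish_genes = list(dict.fromkeys(fish_genes))  # stable de-dup
    df = df[df["fish_id"].isin(fish_genes)]
    best = (df.sort_values(["fish_id", "score", "human_symbol"],
                           ascending=[True, False, True])
              .drop_duplicates("fish_id", keep="first"))
    mapping = dict(zip(best["fish_id"], best["human_symbol"]))
    unmapped = [g for g in fish_genes if g not in mapping]
    symbols = set(mapping.values())
    return OrthologReport(
        n_input=len(fish_genes), n_mapped=len(mapping),
        n_unique_human=len(symbols), mapping=mapping,
        unmapped=unmapped, human_symbols=symbols)


# ---------------------------------------------------------------------------
# gene-set overlap


@dataclass
class OverlapResult:
    overlap: Set[str]
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    p_value: float  # one-sided enrichment (hypergeometric upper tail)


def gene_set_overlap(set_a: Sequence[str] | Set[str],
                     set_b: Sequence[str] | Set[str],
                     universe: int) -> OverlapResult:
    """Overlap of two gene sets with one-sided Fisher enrichment p-value.

    The 2x2 table is membership in A crossed with membership in B over a
    stated universe of ``universe`` genes.
    """
    a, b = set(set_a), set(set_b)
    if universe < len(a | b):
        raise DomainError(
            f"universe ({universe}) smaller than |A union B| ({len(a | b)})")
    k = len(a & b)
    table = [[k, len(a) - k], [len(b) - k, universe - len(a) - len(b) + k]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return OverlapResult(overlap=a & b, n_a=len(a), n_b=len(b),
                         n_overlap=k, universe=universe, p_value=float(p))


# ---------------------------------------------------------------------------
# cohort frequencies


def load_cohort_table(source: Union[str, Path, pd.DataFrame],
                      cohort: Optional[str] = None) -> pd.DataFrame:
    """Load a cohort mutation table; accepts MAF-like column aliases.

    Expected columns: ``cohort``, ``sample_id``, ``gene`` (``Hugo_Symbol`` /
    ``Tumor_Sample_Barcode`` accepted). A missing ``cohort`` column can be
    supplied via the ``cohort`` argument.
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source, sep="\t")
    renames = {c: _COHORT_ALIASES[c.lower()] for c in table.columns
               if c.lower() in _COHORT_ALIASES}
    table = table.rename(columns=renames)
    if "cohort" not in table.columns:
        if cohort is None:
            raise ParseError("cohort table has no 'cohort' column and no label given")
        table["cohort"] = cohort
    missing = {"cohort", "sample_id", "gene"} - set(table.columns)
    if missing:
        raise ParseError(f"cohort table missing columns: {sorted(missing)}")
    return table[["cohort", "sample_id", "gene"]]


def cohort_frequencies(table: Union[str, Path, pd.DataFrame],
                       genes: Sequence[str],
                       cohort_sizes: Optional[Mapping[str, int]] = None,
                       patient_map: Optional[Mapping[str, str]] = None,
                       ) -> pd.DataFrame:
    """Per-gene mutation frequency in each cohort.

    Each (cohort, sample) pair counts once per gene regardless of multiple
    mutations. ``cohort_sizes`` gives the denominators; when omitted they are
    inferred as the number of distinct samples observed per cohort (which
    undercounts if mutation-free samples are absent from the table).
    ``patient_map`` optionally collapses sample ids to patients so reported
    frequencies are per patient.
    """
    df = load_cohort_table(table)
    if patient_map is not None:
        df = df.assign(sample_id=df["sample_id"].map(lambda s: patient_map.get(s, s)))
    observed = dict(df.groupby("cohort")["sample_id"].nunique())
    if cohort_sizes is None:
        cohort_sizes = observed
    unknown = set(observed) - set(cohort_sizes)
    if unknown:
        raise DomainError(
            f"unknown cohort label(s) {sorted(unknown)}; valid: {sorted(cohort_sizes)}")
    df = df.drop_duplicates(["cohort", "sample_id", "gene"])
    rows = []
    for cohort, n_samples in cohort_sizes.items():
        if n_samples < 1:
            raise DomainError(f"cohort {cohort!r} has non-positive size")
        sub = df[df["cohort"] == cohort]
        counts = sub.groupby("gene")["sample_id"].nunique()
        for gene in genes:
            k = int(counts.get(gene, 0))
            if k > n_samples:
                raise DomainError(
                    f"{gene} mutated in {k} samples but cohort {cohort!r} size is {n_samples}")
            rows.append({
                "gene": gene, "cohort": cohort,
                "n_mutated_samples": k, "n_samples": n_samples,
                "frequency": k / n_samples,
                "percent": float(round(100.0 * k / n_samples)),
            })
    return pd.DataFrame(rows)


def compare_cohorts(freq_table: pd.DataFrame,
                    baseline: str, resistant: str) -> pd.DataFrame:
    """Per-gene contrast between two cohorts.

    Returns delta (percentage points), odds ratio (Haldane 0.5 correction
    when any cell is zero), one-sided Fisher p for enrichment in the
    resistant cohort, and Benjamini-Hochberg q across tested genes.
    """
    cohorts = set(freq_table["cohort"])
    for label in (baseline, resistant):
        if label not in cohorts:
            raise DomainError(f"cohort {label!r} not in table; valid: {sorted(cohorts)}")
    base = freq_table[freq_table["cohort"] == baseline].set_index("gene")
    res = freq_table[freq_table["cohort"] == resistant].set_index("gene")
    genes = [g for g in base.index if g in res.index]
    if not genes:
        raise DomainError("no genes shared between the two cohorts")
    rows = []
    for gene in genes:
        k1, n1 = int(base.loc[gene, "n_mutated_samples"]), int(base.loc[gene, "n_samples"])
        k2, n2 = int(res.loc[gene, "n_mutated_samples"]), int(res.loc[gene, "n_samples"])
        cells = (k2, n2 - k2, k1, n1 - k1)
        if 0 in cells:
            a, b, c, d = (x + 0.5 for x in cells)
        else:
            a, b, c, d = cells
        odds_ratio = (a * d) / (b * c)
        _, p = stats.fisher_exact([[k2, n2 - k2], [k1, n1 - k1]],
                                  alternative="greater")
        rows.append({
            "gene": gene,
            "baseline_frequency": k1 / n1, "resistant_frequency": k2 / n2,
            "delta_points": 100.0 * (k2 / n2 - k1 / n1),
            "odds_ratio": odds_ratio, "fisher_p": float(p),
        })
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
    return out
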