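"""Synthetic ortholog maps, mutation cohorts, DE gene lists and signatures.

These emulate the tabular inputs of the cross-species stage: a DIOPT-style
scored ortholog table with configurable 1:1 / many:1 / unmapped fractions,
two mutation cohorts (baseline vs drug-resistant) with planted per-gene
frequency enrichment, a differential-expression gene list, and a toy
mutational-signature matrix over the 96 trinucleotide contexts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from ..errors import ConfigError
from ..sequtils import CONTEXTS_96

ORTHOLOG_COLUMNS = ["fish_id", "human_symbol", "score"]
COHORT_COLUMNS = ["cohort", "sample_id", "gene"]


@dataclass
class CrossSpeciesTables:
    """Bundle of simulated cross-species inputs plus their ground truth."""

    orthologs: pd.DataFrame
    cohorts: pd.DataFrame
    de_genes: pd.DataFrame
    cohort_sizes: Dict[str, int]
    #: genes whose resistant-cohort frequency was multiplied by an enrichment factor
    enriched_genes: Dict[str, float] = field(default_factory=dict)
    #: fish_id -> intended best human symbol (None when unmapped)
    truth_mapping: Dict[str, Optional[str]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "orthologs": outdir / "orthologs.tsv",
            "cohorts": outdir / "cohorts.tsv",
            "de_genes": outdir / "de_genes.tsv",
        }
        self.orthologs.to_csv(paths["orthologs"], sep="\t", index=False)
        self.cohorts.to_csv(paths["cohorts"], sep="\t", index=False)
        self.de_genes.to_csv(paths["de_genes"], sep="\t", index=False)
        return paths


def simulate_cross_species_tables(
    *,
    n_fish_genes: int = 200,
    one_to_one_fraction: float = 0.7,
    many_to_one_fraction: float = 0.2,
    unmapped_fraction: float = 0.1,
    multi_candidate_fraction: float = 0.3,
    cohort_sizes: Mapping[str, int] | None = None,
    baseline_cohort: str = "baseline",
    resistant_cohort: str = "resistant",
    baseline_freq: float | Mapping[str, float] = 0.02,
    per_gene_enrichment: Mapping[str, float] | None = None,
    n_de_genes: int = 50,
    seed: int = 0,
) -> CrossSpeciesTables:
    """Simulate the tabular cross-species inputs with known ground truth.

    ``per_gene_enrichment`` maps human gene symbols to the factor by which
    their per-sample mutation probability is multiplied in the resistant
    cohort (expectation-level enrichment; realized counts are binomial).
    """
    fracs = (one_to_one_fraction, many_to_one_fraction, unmapped_fraction)
    if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
        raise ConfigError("mapping fractions must be nonnegative and sum to 1")
    if cohort_sizes is None:
        cohort_sizes = {baseline_cohort: 300, resistant_cohort: 100}
    if baseline_cohort not in cohort_sizes or resistant_cohort not in cohort_sizes:
        raise ConfigError("cohort_sizes must include the baseline and resistant cohorts")
    per_gene_enrichment = dict(per_gene_enrichment or {})

    rng = np.random.default_rng(seed)
    fish = [f"zfg{i:05d}" for i in range(1, n_fish_genes + 1)]
    humans = [f"HG{i:05d}" for i in range(1, n_fish_genes + 1)]

    # --- ortholog table ----------------------------------------------------
    n_unmapped = int(round(unmapped_fraction * n_fish_genes))
    n_many = int(round(many_to_one_fraction * n_fish_genes))
    order = rng.permutation(n_fish_genes)
    unmapped_ids = {fish[i] for i in order[:n_unmapped]}
    many_ids = [fish[i] for i in order[n_unmapped:n_unmapped + n_many]]

    rows: List[tuple] = []
    truth_mapping: Dict[str, Optional[str]] = {}
    hi = 0
    # many:1 — consecutive pairs of fish genes share one human symbol
    for j in range(0, len(many_ids) - 1, 2):
        sym = humans[hi]; hi += 1
        for fid in many_ids[j:j + 2]:
            rows.append((fid, sym, float(np.round(rng.uniform(7, 10), 2))))
            truth_mapping[fid] = sym
    if len(many_ids) % 2:  # odd leftover becomes 1:1
        fid = many_ids[-1]
        sym = humans[hi]; hi += 1
        rows.append((fid, sym, float(np.round(rng.uniform(7, 10), 2))))
        truth_mapping[fid] = sym
    for fid in fish:
        if fid in unmapped_ids:
            truth_mapping[fid] = None
        elif fid not in truth_mapping:
            sym = humans[hi]; hi += 1
            rows.append((fid, sym, float(np.round(rng.uniform(7, 10), 2))))
            truth_mapping[fid] = sym
    # lower-scored alternative candidates for a fraction of mapped genes
    mapped = [f for f, s in truth_mapping.items() if s is not None]
    n_multi = int(round(multi_candidate_fraction * len(mapped)))
    for fid in rng.choice(mapped, size=n_multi, replace=False).tolist():
        alt_sym = f"ALT{rng.integers(1, 10 * n_fish_genes):05d}"
        rows.append((fid, alt_sym, float(np.round(rng.uniform(1, 6), 2))))
    orthologs = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)
    orthologs = orthologs.sort_values(["fish_id", "score"],
                                      ascending=[True, False]).reset_index(drop=True)

    # --- mutation cohorts --------------------------------------------------
    gene_universe = sorted({s for s in truth_mapping.values() if s is not None}
                           | set(per_gene_enrichment))
    if isinstance(baseline_freq, Mapping):
        freq = {g: float(baseline_freq.get(g, 0.0)) for g in gene_universe}
    else:
        freq = {g: float(baseline_freq) for g in gene_universe}
    cohort_rows: List[tuple] = []
    for cohort, size in cohort_sizes.items():
        enr = cohort == resistant_cohort
        for g in gene_universe:
            p = freq[g] * (per_gene_enrichment.get(g, 1.0) if enr else 1.0)
            p = min(p, 1.0)
            if p <= 0:
                continue
            hits = np.flatnonzero(rng.random(size) < p)
            cohort_rows.extend(
                (cohort, f"{cohort}-s{k + 1:05d}", g) for k in hits.tolist())
    cohorts = pd.DataFrame(cohort_rows, columns=COHORT_COLUMNS)

    # --- DE gene list ------------------------------------------------------
    de_ids = rng.choice(fish, size=min(n_de_genes, n_fish_genes), replace=False)
    de_genes = pd.DataFrame({
        "fish_id": sorted(de_ids.tolist()),
        "log2fc": np.round(rng.normal(0, 2, size=len(de_ids)), 3),
        "fdr": np.round(rng.uniform(0, 0.05, size=len(de_ids)), 4),
    })

    return CrossSpeciesTables(
        orthologs=orthologs, cohorts=cohorts, de_genes=de_genes,
        cohort_sizes=dict(cohort_sizes), enriched_genes=dict(per_gene_enrichment),
        truth_mapping=truth_mapping)


def toy_signature_matrix(n_signatures: int = 5, seed: int = 0) -> pd.DataFrame:
    """Random signature profiles over the 96 contexts (columns sum to 1)."""
    if n_signatures < 1:
        raise ConfigError("n_signatures must be >= 1")
    rng = np.random.default_rng(seed)
    mat = rng.dirichlet(np.ones(96) * 0.5, size=n_signatures).T
    cols = [f"Signature_{i + 1}" for i in range(n_signatures)]
    return pd.DataFrame(mat, index=list(CONTEXTS_96), columns=cols)
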