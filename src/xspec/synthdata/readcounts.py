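"""Deep validation readcount simulation for candidate loci.

Emulates a pooled deep-sequencing validation run: per locus, tumor and
normal alt-read counts are binomial draws around the truth-appropriate
allele fraction (clonal for planted somatic variants, ~0.5 for germline
SNPs, the sequencing error rate for everything else).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from ..errors import ConfigError
from .variants import TruthSet

READCOUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "t_ref", "t_alt", "n_ref", "n_alt"]


def simulate_validation_reads(
    loci: Iterable[Tuple[str, int, str, str]],
    truth: TruthSet,
    *,
    depth: int = 1000,
    error_rate: float = 0.002,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-locus tumor/normal readcounts at validation depth.

    ``loci`` is any iterable of ``(chrom, pos, ref, alt)`` keys (objects with
    a ``key`` attribute are also accepted).
    """
    if depth < 1:
        raise ConfigError(f"depth must be >= 1, got {depth}")
    if not 0.0 <= error_rate < 0.5:
        raise ConfigError(f"error_rate must be in [0, 0.5), got {error_rate}")
    rng = np.random.default_rng(seed)
    rows = []
    for locus in loci:
        key = locus.key if hasattr(locus, "key") else tuple(locus)
        chrom, pos, ref, alt = key
        kind = truth.kind_of(chrom, pos)
        if kind == "somatic":
            t_p, n_p = truth.clonal_fraction, error_rate
        elif kind == "germline":
            t_p, n_p = 0.5, 0.5
        else:
            t_p, n_p = error_rate, error_rate
        t_alt = int(rng.binomial(depth, t_p))
        n_alt = int(rng.binomial(depth, n_p))
        rows.append((chrom, pos, ref, alt, depth - t_alt, t_alt, depth - n_alt, n_alt))
    return pd.DataFrame(rows, columns=READCOUNT_COLUMNS)


def write_readcounts(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_readcounts(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(READCOUNT_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigError(f"readcount table missing columns: {sorted(missing)}")
    return table
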