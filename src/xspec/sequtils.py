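"""Shared substitution-class and trinucleotide-context conventions.

All substitutions are normalized to a pyrimidine reference base: a G>A
change is counted as C>T with reverse-complemented flanks. The 96 context
classes are keyed ``"L[R>A]G"`` style strings, e.g. ``"A[C>T]G"``.
"""

from __future__ import annotations

from typing import Tuple

from .errors import ConfigError

#: the six pyrimidine-normalized substitution classes, fixed display order
PYR_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

BASES = ("A", "C", "G", "T")

#: the 96 trinucleotide-context classes in (class, 5', 3') lexicographic order
CONTEXTS_96 = tuple(
    f"{l}[{cls}]{r}" for cls in PYR_CLASSES for l in BASES for r in BASES
)


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix so mixed-dialect inputs match."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def pyrimidine_class(ref: str, alt: str) -> str:
    """Normalize a single-base substitution to its pyrimidine class."""
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        raise ConfigError(f"not a substitution: {ref}>{alt}")
    cls = f"{ref}>{alt}" if ref in "CT" else f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"
    if cls not in PYR_CLASSES:
        raise ConfigError(f"not a substitution: {ref}>{alt}")
    return cls


def normalize_substitution(ref: str, alt: str, left: str, right: str) -> Tuple[str, str]:
    """Pyrimidine-normalize a substitution with its flanking bases.

    Returns ``(class, context_key)`` where the context key is e.g.
    ``"A[C>T]G"``. Purine-reference changes have their flanks
    reverse-complemented (and swapped) along with the alleles.
    """
    cls = pyrimidine_class(ref, alt)
    if ref in "CT":
        l, r = left, right
    else:
        l, r = COMPLEMENT[right], COMPLEMENT[left]
    if l not in COMPLEMENT or r not in COMPLEMENT:
        raise ConfigError(f"non-ACGT flanking base: {left}/{right}")
    return cls, f"{l}[{cls}]{r}"


def context_key_from_triplet(triplet: str, alt_pyr: str) -> str:
    """Context key for a pyrimidine-strand triplet and pyrimidine alt base."""
    return f"{triplet[0]}[{triplet[1]}>{alt_pyr}]{triplet[2]}"
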