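"""Structural-key fingerprint analysis.

Implements the Tanimoto coefficient Tc = C / (A + B - C), where A and B are
the on-bit counts of two fingerprints and C the count of shared on-bits;
pairwise similarity matrices; per-class bit frequencies
(100 * on-count / class size); and differential-bit ranking used for
substructure-enrichment analysis between actives and inactives.

The native path consumes precomputed 166-bit tables (see
:class:`~qsarscreen.containers.FingerprintSet`); structural-key generation
from structures is a chemistry-backend concern and is not required here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import FingerprintSet, N_MACCS_BITS, ValidationError

__all__ = [
    "FingerprintSet",
    "TanimotoTerms",
    "BitFrequencyTable",
    "tanimoto",
    "tanimoto_terms",
    "pairwise_similarity",
    "bit_frequency",
    "differential_bits",
]


@dataclass(frozen=True)
class TanimotoTerms:
    """On-bit counts entering the Tanimoto coefficient: |A|, |B|, |A∩B|."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if self.c > min(self.a, self.b) or min(self.a, self.b, self.c) < 0:
            raise ValidationError(f"inconsistent Tanimoto terms: {self}")

    @property
    def tc(self) -> float:
        denom = self.a + self.b - self.c
        return self.c / denom if denom else 0.0


@dataclass
class BitFrequencyTable:
    """Per-bit on-percentage within one compound class."""

    class_label: str
    n: int
    freq: np.ndarray  # length 166, percentages in [0, 100]

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (N_MACCS_BITS,):
            raise ValidationError(f"frequency table must cover {N_MACCS_BITS} bits")
        if self.freq.size and (self.freq.min() < 0 or self.freq.max() > 100):
            raise ValidationError("frequencies must lie in [0, 100]")


def tanimoto_terms(fp_a: np.ndarray, fp_b: np.ndarray) -> TanimotoTerms:
    fp_a = np.asarray(fp_a)
    fp_b = np.asarray(fp_b)
    if fp_a.shape != (N_MACCS_BITS,) or fp_b.shape != (N_MACCS_BITS,):
        raise ValidationError(
            f"fingerprint vectors must have length {N_MACCS_BITS}; "
            f"got {fp_a.shape} and {fp_b.shape}"
        )
    a = int(fp_a.sum())
    b = int(fp_b.sum())
    c = int(np.logical_and(fp_a, fp_b).sum())
    return TanimotoTerms(a=a, b=b, c=c)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity of two 166-bit vectors; all-zero pair -> 0.0."""
    terms = tanimoto_terms(fp_a, fp_b)
    if terms.a == 0 and terms.b == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 0.0", stacklevel=2)
        return 0.0
    return terms.tc


def pairwise_similarity(set_a: FingerprintSet, set_b: FingerprintSet) -> np.ndarray:
    """All-against-all Tanimoto matrix, shape (len(set_a), len(set_b)).

    Vectorized via the bit-count identity: C = A·Bᵀ on the 0/1 matrices,
    and A + B - C from the row sums. Pairs where both fingerprints are
    all-zero get similarity 0.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValidationError("pairwise_similarity requires non-empty fingerprint sets")
    A = set_a.bits.astype(np.int64)
    B = set_b.bits.astype(np.int64)
    shared = A @ B.T
    counts_a = A.sum(axis=1)[:, None]
    counts_b = B.sum(axis=1)[None, :]
    denom = counts_a + counts_b - shared
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, shared / np.maximum(denom, 1), 0.0)
    return sim


def bit_frequency(fps: FingerprintSet, member_ids: list[str], class_label: str = "") -> BitFrequencyTable:
    """Per-bit on-percentage over the given class members."""
    if not member_ids:
        raise ValidationError("member_ids must be non-empty")
    sub = fps.subset(list(member_ids))
    freq = 100.0 * sub.bits.sum(axis=0) / len(sub)
    return BitFrequencyTable(class_label=class_label, n=len(sub), freq=freq)


def differential_bits(
    freq_active: BitFrequencyTable,
    freq_inactive: BitFrequencyTable,
    min_diff: float = 10.0,
) -> list[dict]:
    """Bits enriched in actives by at least ``min_diff`` percentage points.

    Returns records ``{bit, freq_active, freq_inactive, diff}`` sorted by
    the active-minus-inactive difference descending, ties broken by bit
    index. ``bit`` is the 1-based key index.
    """
    diff = freq_active.freq - freq_inactive.freq
    hits = [
        {
            "bit": int(i + 1),
            "freq_active": float(freq_active.freq[i]),
            "freq_inactive": float(freq_inactive.freq[i]),
            "diff": float(diff[i]),
        }
        for i in range(N_MACCS_BITS)
        if diff[i] >= min_diff
    ]
    hits.sort(key=lambda rec: (-rec["diff"], rec["bit"]))
    return hits
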