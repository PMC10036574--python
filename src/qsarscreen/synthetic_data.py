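"""Synthetic compound datasets with the statistical structure a QSAR
classification pipeline assumes.

The generator emulates a curated two-class kinase-inhibitor set: a balanced
table of actives (IC50 at or below the activity boundary) and inactives,
a descriptor block containing class-informative columns (shifted-mean
normals), pure-noise columns, and highly correlated column pairs (to
exercise redundancy pruning), plus 166-bit structural-key fingerprints with
class-enriched bits. Structure strings are opaque unique identifiers, not
chemistry: the pipeline under test consumes descriptor tables and bit
vectors, so no chemistry toolkit is needed.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64; a fixed seed yields bit-identical output across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import DescriptorMatrix, FingerprintSet, N_MACCS_BITS, ValidationError

#: target Pearson correlation for generated redundant descriptor pairs
PAIR_CORRELATION = 0.9
#: baseline on-probability for non-enriched fingerprint bits (both classes)
BASELINE_BIT_P = 0.3


class SpecError(ValueError):
    """Inconsistent synthetic-dataset specification."""


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-class compound dataset.

    Defaults describe the reference study conditions used throughout the
    test suite: 400 balanced compounds, 54 descriptors of which 5 carry a
    class signal at Cohen's d = 2, two redundant pairs at r = 0.9, and 8
    fingerprint bits enriched in actives.
    """

    n_active: int = 200
    n_inactive: int = 200
    n_informative: int = 5
    effect_size: float = 2.0
    n_noise: int = 45
    n_corr_pairs: int = 2
    n_enriched_bits: int = 8
    p_bit_active: float = 0.8
    p_bit_inactive: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_active", "n_inactive", "n_informative", "n_noise",
                     "n_corr_pairs", "n_enriched_bits"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if not (0.0 <= self.p_bit_inactive <= self.p_bit_active <= 1.0):
            raise SpecError("need 0 <= p_bit_inactive <= p_bit_active <= 1")
        if self.n_enriched_bits > N_MACCS_BITS:
            raise SpecError(f"n_enriched_bits exceeds {N_MACCS_BITS}")
        if self.n_descriptors < 1:
            raise SpecError("total descriptor count must be >= 1")

    @property
    def n_descriptors(self) -> int:
        return self.n_informative + self.n_noise + 2 * self.n_corr_pairs

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Output bundle of :func:`generate_dataset`.

    ``compounds`` is the raw compound table (id, structure, ic50_um, label);
    ``labels`` is an int vector (1 = active) aligned with ``descriptors``
    rows. Ground-truth bookkeeping (which descriptors were planted as
    informative, which bits enriched) is kept for recovery studies.
    """

    compounds: pd.DataFrame
    descriptors: DescriptorMatrix
    fingerprints: FingerprintSet
    labels: np.ndarray
    informative_names: list[str] = field(default_factory=list)
    noise_names: list[str] = field(default_factory=list)
    corr_pair_names: list[tuple[str, str]] = field(default_factory=list)
    enriched_bit_indices: list[int] = field(default_factory=list)


def _ic50_values(rng: np.random.Generator, n_active: int, n_inactive: int) -> np.ndarray:
    """Log-uniform IC50s: actives in (0.001, 1] uM, inactives in (1, 100] uM."""
    act = 10.0 ** rng.uniform(-3.0, 0.0, size=n_active)
    inact = 10.0 ** rng.uniform(0.0, 2.0, size=n_inactive)
    # keep inactives strictly above the 1 uM boundary
    inact = np.maximum(inact, np.nextafter(1.0, 2.0))
    act = np.minimum(act, 1.0)
    return np.concatenate([act, inact])


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a labeled compound set with descriptors and fingerprints.

    Descriptor construction (per compound class):

    * informative: N(effect_size, 1) for actives, N(0, 1) for inactives;
    * noise: N(0, 1) independent of class;
    * correlated pairs: ``x2 = rho * x1 + sqrt(1 - rho^2) * eps`` with
      rho = 0.9, both members class-independent and unit-variance.

    Fingerprint bits are Bernoulli: enriched bits use ``p_bit_active`` /
    ``p_bit_inactive`` per class, the remainder a shared baseline.
    """
    if spec.n_active == 0 or spec.n_inactive == 0:
        raise SpecError("both classes need at least one compound")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_active + spec.n_inactive
    labels = np.concatenate(
        [np.ones(spec.n_active, dtype=int), np.zeros(spec.n_inactive, dtype=int)]
    )

    cols: dict[str, np.ndarray] = {}
    informative = [f"inf_{i + 1}" for i in range(spec.n_informative)]
    for name in informative:
        cols[name] = rng.normal(0.0, 1.0, n) + spec.effect_size * labels
    noise = [f"noise_{i + 1}" for i in range(spec.n_noise)]
    for name in noise:
        cols[name] = rng.normal(0.0, 1.0, n)
    pairs: list[tuple[str, str]] = []
    rho = PAIR_CORRELATION
    for i in range(spec.n_corr_pairs):
        a, b = f"corr_{i + 1}a", f"corr_{i + 1}b"
        x1 = rng.normal(0.0, 1.0, n)
        x2 = rho * x1 + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, n)
        cols[a], cols[b] = x1, x2
        pairs.append((a, b))

    ids = [f"CPD-{i + 1:06d}" for i in range(n)]
    frame = pd.DataFrame(cols, index=ids)
    descriptors = DescriptorMatrix(frame, provenance=["synthetic: generate_dataset"])

    enriched = list(range(spec.n_enriched_bits))
    p = np.full((n, N_MACCS_BITS), BASELINE_BIT_P)
    if enriched:
        p[labels == 1, : spec.n_enriched_bits] = spec.p_bit_active
        p[labels == 0, : spec.n_enriched_bits] = spec.p_bit_inactive
    bits = (rng.random((n, N_MACCS_BITS)) < p).astype(np.uint8)
    fingerprints = FingerprintSet(ids, bits)

    compounds = pd.DataFrame(
        {
            "compound_id": ids,
            "structure": [f"SYN[{cid}]" for cid in ids],
            "ic50_um": _ic50_values(rng, spec.n_active, spec.n_inactive),
            "label": np.where(labels == 1, "active", "inactive"),
        }
    )
    return SyntheticDataset(
        compounds=compounds,
        descriptors=descriptors,
        fingerprints=fingerprints,
        labels=labels,
        informative_names=informative,
        noise_names=noise,
        corr_pair_names=pairs,
        enriched_bit_indices=enriched,
    )


def generate_screening_library(
    n: int,
    frac_shifted: float = 0.0,
    shift: float = 10.0,
    seed: int = 0,
    descriptor_names: list[str] | None = None,
    n_descriptors: int = 54,
) -> tuple[DescriptorMatrix, FingerprintSet]:
    """Generate an unlabeled screening library.

    ``round(n * frac_shifted)`` compounds are offset by ``shift`` standard
    deviations on every descriptor (decoys intended to fall outside a
    training-data applicability domain); the remainder are drawn from the
    training marginal N(0, 1). Fingerprint bits are baseline Bernoulli.
    """
    if n <= 0:
        raise SpecError("screening library must contain at least one compound")
    if not (0.0 <= frac_shifted <= 1.0):
        raise SpecError("frac_shifted must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if descriptor_names is None:
        descriptor_names = [f"d_{i + 1}" for i in range(n_descriptors)]
    d = len(descriptor_names)
    n_shifted = int(round(n * frac_shifted))
    X = rng.normal(0.0, 1.0, (n, d))
    X[:n_shifted] += shift
    ids = [f"LIB-{i + 1:06d}" for i in range(n)]
    frame = pd.DataFrame(X, index=ids, columns=descriptor_names)
    descriptors = DescriptorMatrix(
        frame, provenance=[f"synthetic: screening library, {n_shifted}/{n} shifted by {shift}"]
    )
    bits = (rng.random((n, N_MACCS_BITS)) < BASELINE_BIT_P).astype(np.uint8)
    return descriptors, FingerprintSet(ids, bits)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write compound table, descriptors and fingerprints as CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.compounds.to_csv(outdir / "compounds.csv", index=False)
    ds.descriptors.to_csv(outdir / "descriptors.csv")
    ds.fingerprints.to_csv(outdir / "fingerprints.csv")
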