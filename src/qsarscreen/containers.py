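"""Core in-memory containers: descriptor matrices and structural-key fingerprints.

Both containers are thin, validated wrappers around :class:`pandas.DataFrame` /
:class:`numpy.ndarray` with strict CSV round-tripping (UTF-8, header row,
first column ``compound_id``) so tables interchange bit-exactly with external
descriptor tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_MACCS_BITS = 166


class ValidationError(ValueError):
    """Raised when a container or record fails its invariants."""


@dataclass
class DescriptorMatrix:
    """Compounds x named numeric descriptors.

    Parameters
    ----------
    frame
        DataFrame indexed by compound id with one numeric column per
        descriptor. All entries must be finite; descriptor names unique.
    provenance
        Free-form log of selection/transformation steps applied so far.
    """

    frame: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            dups = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate descriptor names: {dups}")
        if self.frame.index.duplicated().any():
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValidationError(f"duplicate compound ids: {dups}")
        values = self.frame.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            bad = self.frame.index[~np.isfinite(values).all(axis=1)].tolist()
            raise ValidationError(f"non-finite descriptor values for compounds: {bad[:10]}")

    @property
    def compound_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def select(self, names: list[str], note: str | None = None) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise ValidationError(f"unknown descriptors: {missing}")
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return DescriptorMatrix(self.frame[names].copy(), prov)

    def subset_rows(self, ids: list[str]) -> "DescriptorMatrix":
        missing = [i for i in ids if i not in self.frame.index]
        if missing:
            raise ValidationError(f"unknown compound ids: {missing}")
        return DescriptorMatrix(self.frame.loc[ids].copy(), list(self.provenance))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "compound_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DescriptorMatrix":
        frame = pd.read_csv(path)
        if frame.columns[0] != "compound_id":
            raise ValidationError("descriptor CSV must have 'compound_id' as its first column")
        frame = frame.set_index("compound_id")
        frame.index = frame.index.astype(str)
        return cls(frame)


@dataclass
class FingerprintSet:
    """Per-compound 166-bit structural-key (MACCS-style) fingerprints."""

    compound_ids: list[str]
    bits: np.ndarray  # (n_compounds, 166) of {0, 1}

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[1] != N_MACCS_BITS:
            raise ValidationError(
                f"fingerprint matrix must be (n, {N_MACCS_BITS}); got {self.bits.shape}"
            )
        if len(self.compound_ids) != self.bits.shape[0]:
            raise ValidationError("compound_ids length does not match bit matrix")
        if self.bits.size and not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("fingerprint entries must be 0 or 1")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValidationError("duplicate compound ids in fingerprint set")

    def __len__(self) -> int:
        return self.bits.shape[0]

    def get(self, compound_id: str) -> np.ndarray:
        try:
            idx = self.compound_ids.index(compound_id)
        except ValueError:
            raise ValidationError(f"unknown compound id: {compound_id}") from None
        return self.bits[idx]

    def subset(self, ids: list[str]) -> "FingerprintSet":
        index = {cid: i for i, cid in enumerate(self.compound_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValidationError(f"unknown compound ids: {missing}")
        rows = [index[i] for i in ids]
        return FingerprintSet(list(ids), self.bits[rows].copy())

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(
            self.bits, columns=[f"bit_{i + 1}" for i in range(N_MACCS_BITS)]
        )
        frame.insert(0, "compound_id", self.compound_ids)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FingerprintSet":
        frame = pd.read_csv(path)
        if frame.columns[0] != "compound_id":
            raise ValidationError("fingerprint CSV must have 'compound_id' as its first column")
        ids = frame["compound_id"].astype(str).tolist()
        return cls(ids, frame.iloc[:, 1:].to_numpy())

    def to_hex(self) -> dict[str, str]:
        """Hex-string encoding, 21 bytes per fingerprint (166 bits zero-padded to 168)."""
        out = {}
        for cid, row in zip(self.compound_ids, self.bits):
            out[cid] = np.packbits(np.concatenate([row, np.zeros(2, dtype=np.uint8)])).tobytes().hex()
        return out

    @classmethod
    def from_hex(cls, mapping: dict[str, str]) -> "FingerprintSet":
        ids, rows = [], []
        for cid, hx in mapping.items():
            raw = np.frombuffer(bytes.fromhex(hx), dtype=np.uint8)
            rows.append(np.unpackbits(raw)[:N_MACCS_BITS])
            ids.append(cid)
        return cls(ids, np.array(rows, dtype=np.uint8))
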