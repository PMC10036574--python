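"""Activity-record curation: deduplication and binary labeling.

Raw compound tables (id, structure line notation, IC50 in micromolar) are
reduced to one record per canonical structure and labeled against an
activity decision boundary — active when IC50 <= 1 uM by default. Duplicate
groups are resolved to the median IC50 (robust to outlier assays) or,
optionally, keep-first. A pluggable canonicalizer hook stands in for
structure-validity / organic-element filtering; records it rejects are
dropped with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .containers import ValidationError

ACTIVITY_BOUNDARY_UM = 1.0


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    structure: str
    ic50_um: float | None = None
    label: Literal["active", "inactive"] | None = None


def _default_canonicalizer(structure: str) -> str:
    """Identity canonical key: stripped structure string; rejects blanks."""
    key = structure.strip()
    if not key:
        raise ValidationError("empty structure string")
    return key


def assign_labels(
    records: list[CompoundRecord],
    boundary_um: float = ACTIVITY_BOUNDARY_UM,
    exclude_range_um: tuple[float, float] | None = None,
) -> tuple[list[CompoundRecord], dict]:
    """Label records active iff IC50 <= boundary (inclusive), else inactive.

    ``exclude_range_um = (lo, hi)`` optionally discards records with
    boundary-zone potency (lo < IC50 < hi), e.g. ``(1.0, 10.0)``; by default
    everything above the boundary is kept as inactive.

    Returns the labeled records and a summary with per-class counts.
    Records with missing or non-positive IC50 raise a single validation
    error listing every offending id.
    """
    if boundary_um <= 0:
        raise ValidationError("boundary_um must be positive")
    bad = [r.compound_id for r in records if r.ic50_um is None or r.ic50_um <= 0]
    if bad:
        raise ValidationError(f"missing or non-positive ic50_um for: {bad}")
    out: list[CompoundRecord] = []
    excluded: list[str] = []
    for r in records:
        if exclude_range_um is not None:
            lo, hi = exclude_range_um
            if lo < r.ic50_um < hi:
                excluded.append(r.compound_id)
                continue
        label = "active" if r.ic50_um <= boundary_um else "inactive"
        out.append(replace(r, label=label))
    summary = {
        "n_active": sum(r.label == "active" for r in out),
        "n_inactive": sum(r.label == "inactive" for r in out),
        "n_excluded": len(excluded),
        "excluded_ids": excluded,
        "boundary_um": boundary_um,
    }
    return out, summary


def deduplicate(
    records: list[CompoundRecord],
    aggregate: Literal["median", "first"] = "median",
    canonicalizer: Callable[[str], str] = _default_canonicalizer,
) -> tuple[list[CompoundRecord], list[dict]]:
    """Collapse records sharing a canonical structure key.

    Each duplicate group is resolved to a single record carrying the median
    IC50 of the group (or the first record's, with ``aggregate='first'``).
    Records whose structure the canonicalizer rejects are dropped. Returns
    the deduplicated records plus a removal log in which every input id
    that is not in the output appears with a reason.
    """
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    log: list[dict] = []
    for r in records:
        try:
            key = canonicalizer(r.structure)
        except Exception as exc:  # invalid / "inorganic" structures
            log.append({"compound_id": r.compound_id, "reason": f"unparseable structure: {exc}"})
            continue
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    out: list[CompoundRecord] = []
    for key in order:
        grp = groups[key]
        keep = grp[0]
        if len(grp) > 1:
            if aggregate == "median":
                vals = [g.ic50_um for g in grp if g.ic50_um is not None]
                if vals:
                    keep = replace(keep, ic50_um=float(np.median(vals)))
            for dup in grp[1:]:
                log.append(
                    {"compound_id": dup.compound_id,
                     "reason": f"duplicate of {keep.compound_id} (structure key match)"}
                )
        out.append(keep)
    return out, log


def records_from_frame(frame: pd.DataFrame) -> list[CompoundRecord]:
    """Build records from a compound table (compound_id, structure, ic50_um)."""
    required = {"compound_id", "structure", "ic50_um"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"compound table missing columns: {sorted(missing)}")
    return [
        CompoundRecord(
            compound_id=str(row.compound_id),
            structure=str(row.structure),
            ic50_um=float(row.ic50_um) if pd.notna(row.ic50_um) else None,
        )
        for row in frame.itertuples(index=False)
    ]


def records_to_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "structure": [r.structure for r in records],
            "ic50_um": [r.ic50_um for r in records],
            "label": [r.label for r in records],
        }
    )
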