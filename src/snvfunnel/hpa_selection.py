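"""Differential-staining candidate selection from an HPA-style table.

Antibody-based tissue staining is scored on the ordinal scale
none < weak < moderate < strong, per protein, per patient, separately in
normal glandular tissue and in tumor tissue.  A protein is a candidate
when its staining clearly separates the two tissues: either absent in
normal tissue and strong in enough tumor patients (up-regulated), or the
mirror image (down-regulated).  Literature-derived proteins can then be
merged in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger("snvfunnel")

LEVELS = ("none", "weak", "moderate", "strong")
LEVEL_RANK = {lvl: i for i, lvl in enumerate(LEVELS)}
TISSUES = ("normal_glandular", "tumor")


@dataclass(frozen=True)
class StainingRecord:
    """One staining observation (protein, tissue, patient)."""

    protein_id: str
    tissue: str
    patient_id: str
    level: str
    validation_score: int = 0
    transmembrane: bool = False
    signal_peptide: bool = False

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown staining level {self.level!r}")


@dataclass(frozen=True)
class SelectionCriteria:
    """One differential-staining search.

    ``up_in_tumor`` asks for normal tissue at ``normal_level_required``
    (default: all normal records at 'none') and at least
    ``tumor_min_patients`` tumor patients staining in ``tumor_level_set``.
    ``down_in_tumor`` is the complementary search.
    """

    direction: str = "up_in_tumor"
    normal_level_required: str = "none"
    tumor_min_patients: int = 5
    tumor_level_set: frozenset = frozenset({"strong"})

    def __post_init__(self) -> None:
        if self.direction not in ("up_in_tumor", "down_in_tumor"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.tumor_min_patients < 1:
            raise ValueError("tumor_min_patients must be >= 1")
        bad = set(self.tumor_level_set) - set(LEVELS)
        if bad:
            raise ValueError(f"unknown tumor levels {sorted(bad)}")


UP_IN_TUMOR = SelectionCriteria("up_in_tumor", "none", 5, frozenset({"strong"}))
DOWN_IN_TUMOR = SelectionCriteria("down_in_tumor", "strong", 10,
                                  frozenset({"none", "weak"}))


def select_candidates(records: Sequence[StainingRecord],
                      criteria: SelectionCriteria,
                      normal_mode: str = "all",
                      min_validation_score: int | None = None,
                      ) -> list[str]:
    """Return the lexicographically sorted protein ids passing ``criteria``.

    ``normal_mode`` controls whether ALL normal-tissue records (default)
    or ANY of them must sit at the required normal level.  Proteins with
    tumor records but no normal records cannot be judged and are excluded
    with a warning.  ``min_validation_score`` optionally screens on assay
    quality (soft criterion, off by default).
    """
    if not records:
        raise ValueError("empty staining record list")
    if normal_mode not in ("all", "any"):
        raise ValueError(f"normal_mode must be 'all' or 'any', got {normal_mode!r}")

    by_protein: dict[str, list[StainingRecord]] = {}
    for rec in records:
        by_protein.setdefault(rec.protein_id, []).append(rec)

    selected = []
    for pid, recs in by_protein.items():
        normal = [r for r in recs if r.tissue == "normal_glandular"]
        tumor = [r for r in recs if r.tissue == "tumor"]
        if tumor and not normal:
            logger.warning("protein %s has tumor records but no normal "
                           "records; excluded from selection", pid)
            continue
        if not normal:
            continue
        if min_validation_score is not None and any(
                r.validation_score < min_validation_score for r in recs):
            continue
        check = all if normal_mode == "all" else any
        normal_ok = check(r.level == criteria.normal_level_required for r in normal)
        n_tumor = len({r.patient_id for r in tumor
                       if r.level in criteria.tumor_level_set})
        if normal_ok and n_tumor >= criteria.tumor_min_patients:
            selected.append(pid)
    return sorted(selected)


def merge_with_literature(selected: Sequence[str],
                          literature: Sequence[str]) -> list[str]:
    """Union keeping input order: selected first, then novel literature ids."""
    out = list(selected)
    seen = set(selected)
    for pid in literature:
        if pid not in seen:
            out.append(pid)
            seen.add(pid)
    return out


# -- TSV I/O ----------------------------------------------------------------

_COLUMNS = ["protein_id", "tissue", "patient_id", "level", "validation_score",
            "transmembrane", "signal_peptide"]


def read_staining_table(path: str | Path) -> list[StainingRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(StainingRecord(
            protein_id=row.protein_id, tissue=row.tissue,
            patient_id=row.patient_id, level=row.level,
            validation_score=int(row.validation_score),
            transmembrane=getattr(row, "transmembrane", "0") in ("1", "True", "true"),
            signal_peptide=getattr(row, "signal_peptide", "0") in ("1", "True", "true"),
        ))
    return records


def write_staining_table(path: str | Path,
                         records: Sequence[StainingRecord]) -> None:
    df = pd.DataFrame([{
        "protein_id": r.protein_id, "tissue": r.tissue,
        "patient_id": r.patient_id, "level": r.level,
        "validation_score": r.validation_score,
        "transmembrane": int(r.transmembrane),
        "signal_peptide": int(r.signal_peptide),
    } for r in records], columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_selection(path: str | Path, selected: Sequence[str],
                    records: Sequence[StainingRecord],
                    criteria: SelectionCriteria) -> None:
    """Selection output: one row per selected protein with its criterion hit
    and pass-through annotation flags."""
    flags = {}
    for r in records:
        tm, sp = flags.get(r.protein_id, (False, False))
        flags[r.protein_id] = (tm or r.transmembrane, sp or r.signal_peptide)
    df = pd.DataFrame([{
        "protein_id": pid,
        "criterion": criteria.direction,
        "transmembrane": int(flags.get(pid, (False, False))[0]),
        "signal_peptide": int(flags.get(pid, (False, False))[1]),
    } for pid in selected])
    df.to_csv(path, sep="\t", index=False)
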