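"""Curation of ChEMBL-style bioactivity exports into a non-redundant pIC50 table.

The filter chain mirrors the standard large-scale QSAR curation recipe:

1. keep a single endpoint type (IC50 by default),
2. drop records with missing values or inequality qualifiers (<, >, <=, >=),
3. keep a single unit (nM by default; other units are dropped, not converted),
4. collapse replicate measurements per compound, discarding compounds whose
   replicate spread exceeds a threshold,
5. drop compounds without a SMILES structure.

The response is pIC50 = 9 - log10(IC50 [nM]), i.e. -log10 of the molar IC50.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QUALIFIERS_DROPPED = frozenset({"<", ">", "<=", ">="})

#: Activity-class boundaries on the pIC50 scale.  Active means IC50 < 1 uM
#: (pIC50 strictly above 6); inactive means IC50 > 10 uM (pIC50 strictly
#: below 5); everything else, boundaries included, is intermediate.
ACTIVE_BOUND = 6.0
INACTIVE_BOUND = 5.0

#: Column-name dialects: canonical field -> column header in the input file.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {
        "compound_id": "compound_id",
        "smiles": "smiles",
        "endpoint": "endpoint",
        "qualifier": "qualifier",
        "value": "value",
        "unit": "unit",
    },
    "chembl": {
        "compound_id": "CMPD_CHEMBLID",
        "smiles": "CANONICAL_SMILES",
        "endpoint": "STANDARD_TYPE",
        "qualifier": "RELATION",
        "value": "STANDARD_VALUE",
        "unit": "STANDARD_UNITS",
    },
}

REQUIRED_FIELDS = ("compound_id", "smiles", "endpoint", "qualifier", "value", "unit")


class CurationConfigError(ValueError):
    """Raised when an input table does not match the declared dialect."""


@dataclass(frozen=True)
class ActivityRecord:
    """One bioactivity measurement row from an activity export."""

    compound_id: str
    smiles: str
    endpoint: str
    qualifier: str
    value: float  # NaN when the cell was blank or malformed
    unit: str

    @property
    def value_missing(self) -> bool:
        return not math.isfinite(self.value)


@dataclass(frozen=True)
class CompoundRecord:
    """A curated, non-redundant compound with aggregated potency."""

    compound_id: str
    smiles: str
    ic50_nM: float
    pic50: float
    activity_class: str


@dataclass
class CurationLog:
    """Ordered record of the filter chain: stage, records in/out, compounds out."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, stage: str, records_in: int, records_out: int, compounds_out: int) -> None:
        if records_out > records_in:
            raise ValueError(f"stage {stage!r}: records_out > records_in")
        self.stages.append((stage, records_in, records_out, compounds_out))

    def compound_counts(self) -> dict[str, int]:
        return {s[0]: s[3] for s in self.stages}

    def to_json(self, path) -> None:
        payload = [
            {"stage": s, "records_in": ri, "records_out": ro, "compounds_out": co}
            for s, ri, ro, co in self.stages
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def n_compounds(records: Sequence[ActivityRecord]) -> int:
    return len({r.compound_id for r in records})


def read_activity_table(path, dialect: str | dict[str, str] = "generic") -> list[ActivityRecord]:
    """Read a CSV/TSV activity table into :class:`ActivityRecord` rows.

    ``dialect`` is either a preset name (``"generic"``, ``"chembl"``) or a
    mapping from canonical field names to the file's column headers.  Malformed
    numeric cells become missing values rather than errors; row order is
    preserved.
    """
    colmap = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    for fld in REQUIRED_FIELDS:
        if fld not in colmap:
            raise CurationConfigError(f"dialect does not map required field {fld!r}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [colmap[f] for f in REQUIRED_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise CurationConfigError(f"input table is missing required column(s): {missing}")
    values = pd.to_numeric(df[colmap["value"]].str.strip(), errors="coerce")
    records = [
        ActivityRecord(
            compound_id=cid.strip(),
            smiles=smi.strip(),
            endpoint=ep.strip(),
            qualifier=q.strip(),
            value=float(v) if pd.notna(v) else math.nan,
            unit=u.strip(),
        )
        for cid, smi, ep, q, v, u in zip(
            df[colmap["compound_id"]],
            df[colmap["smiles"]],
            df[colmap["endpoint"]],
            df[colmap["qualifier"]],
            values,
            df[colmap["unit"]],
        )
    ]
    return records


def records_from_frame(df: pd.DataFrame) -> list[ActivityRecord]:
    """ActivityRecords from an in-memory raw table (generic column names)."""
    out = []
    for r in df.itertuples():
        raw = r.value
        try:
            value = float(raw) if raw not in ("", None) else math.nan
        except (TypeError, ValueError):
            value = math.nan
        out.append(
            ActivityRecord(str(r.compound_id), str(r.smiles), str(r.endpoint),
                           str(r.qualifier), value, str(r.unit))
        )
    return out


def filter_endpoint(records: Iterable[ActivityRecord], endpoint: str = "IC50") -> list[ActivityRecord]:
    """Keep only records whose endpoint label equals ``endpoint`` exactly."""
    endpoint = endpoint.strip()
    return [r for r in records if r.endpoint == endpoint]


def drop_qualified_or_missing(records: Iterable[ActivityRecord]) -> list[ActivityRecord]:
    """Drop records with a missing value or an inequality qualifier.

    ``=`` and blank qualifiers are kept: both denote an exact measurement in
    ChEMBL exports.
    """
    return [r for r in records if not r.value_missing and r.qualifier not in QUALIFIERS_DROPPED]


def filter_units(records: Iterable[ActivityRecord], unit: str = "nM") -> list[ActivityRecord]:
    """Keep only records in the requested unit.  No conversion is attempted."""
    unit = unit.strip()
    return [r for r in records if r.unit == unit]


def to_pic50(ic50_nM: float) -> float:
    """pIC50 from an IC50 in nM: 9 - log10(IC50)."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM!r}")
    return 9.0 - math.log10(ic50_nM)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`: IC50 in nM."""
    return 10.0 ** (9.0 - pic50)


def assign_activity_class(
    pic50: float,
    active_gt: float = ACTIVE_BOUND,
    inactive_lt: float = INACTIVE_BOUND,
) -> str:
    """Three-way potency class: active / intermediate / inactive.

    Active requires pIC50 strictly above ``active_gt`` (IC50 < 1 uM by
    default); inactive requires pIC50 strictly below ``inactive_lt``; the
    boundaries themselves fall into the intermediate class.
    """
    if not math.isfinite(pic50):
        raise ValueError("pIC50 must be finite")
    if pic50 > active_gt:
        return "active"
    if pic50 < inactive_lt:
        return "inactive"
    return "intermediate"


def deduplicate_replicates(
    records: Sequence[ActivityRecord],
    sd_threshold: float = 2.0,
    sd_scale: str = "pic50",
) -> list[CompoundRecord]:
    """Collapse replicate measurements to one record per compound.

    Compounds measured once are kept as-is.  Replicate groups are kept only if
    the sample standard deviation of their measurements is strictly below
    ``sd_threshold``; surviving groups are aggregated by the arithmetic mean of
    their pIC50 values.  ``sd_scale`` selects the scale the threshold is
    applied on: ``"pic50"`` (log molar units, the default) or ``"nM"``.

    Non-positive IC50 values cannot be log-transformed and are rejected with a
    warning before grouping.
    """
    if sd_scale not in ("pic50", "nM"):
        raise ValueError(f"sd_scale must be 'pic50' or 'nM', got {sd_scale!r}")
    clean: list[ActivityRecord] = []
    for r in records:
        if r.value_missing or r.value <= 0:
            logger.warning("rejecting non-positive IC50 for compound %s: %r", r.compound_id, r.value)
            continue
        clean.append(r)
    groups: dict[str, list[ActivityRecord]] = {}
    order: list[str] = []
    for r in clean:
        if r.compound_id not in groups:
            groups[r.compound_id] = []
            order.append(r.compound_id)
        groups[r.compound_id].append(r)

    out: list[CompoundRecord] = []
    for cid in order:
        grp = groups[cid]
        pic50s = np.array([to_pic50(r.value) for r in grp])
        if len(grp) > 1:
            spread = np.std(pic50s if sd_scale == "pic50" else np.array([r.value for r in grp]), ddof=1)
            if not spread < sd_threshold:
                continue
        pic50 = float(np.mean(pic50s))
        smiles = next((r.smiles for r in grp if r.smiles), "")
        out.append(
            CompoundRecord(
                compound_id=cid,
                smiles=smiles,
                ic50_nM=from_pic50(pic50),
                pic50=pic50,
                activity_class=assign_activity_class(pic50),
            )
        )
    return out


def drop_missing_smiles(compounds: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Remove curated compounds that carry no SMILES structure."""
    return [c for c in compounds if c.smiles]


def standardize_structure(smiles: str, canonical_tautomer: bool = True) -> str:
    """Standardize a SMILES string: strip salts, neutralize, canonicalize.

    Keeps the largest organic fragment, neutralizes charges where chemically
    valid, optionally emits the canonical tautomer, and returns canonical
    SMILES.  Deterministic for a fixed toolkit version.  Raises ``ValueError``
    on unparseable input.
    """
    from rdkit import Chem
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.FragmentParent(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    if canonical_tautomer:
        enumerator = rdMolStandardize.TautomerEnumerator()
        mol = enumerator.Canonicalize(mol)
    return Chem.MolToSmiles(mol)


def curate(
    records: Sequence[ActivityRecord],
    endpoint: str = "IC50",
    unit: str = "nM",
    sd_threshold: float = 2.0,
    sd_scale: str = "pic50",
) -> tuple[pd.DataFrame, CurationLog]:
    """Run the full filter chain and return the curated table plus its log.

    The returned frame has columns ``compound_id, smiles, ic50_nM, pic50,
    activity_class`` in first-appearance order.
    """
    log = CurationLog()
    log.add("read", len(records), len(records), n_compounds(records))

    stage = filter_endpoint(records, endpoint)
    log.add("endpoint", len(records), len(stage), n_compounds(stage))

    prev = stage
    stage = drop_qualified_or_missing(prev)
    log.add("qualifier_missing", len(prev), len(stage), n_compounds(stage))

    prev = stage
    stage = filter_units(prev, unit)
    log.add("unit", len(prev), len(stage), n_compounds(stage))

    compounds = deduplicate_replicates(stage, sd_threshold=sd_threshold, sd_scale=sd_scale)
    log.add("replicate_sd", len(stage), len(compounds), len(compounds))

    final = drop_missing_smiles(compounds)
    log.add("smiles", len(compounds), len(final), len(final))

    df = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in final],
            "smiles": [c.smiles for c in final],
            "ic50_nM": [c.ic50_nM for c in final],
            "pic50": [c.pic50 for c in final],
            "activity_class": [c.activity_class for c in final],
        }
    )
    return df, log
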