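"""CSV readers and writers for the pipeline's interchange tables.

All tables are UTF-8, comma-separated CSV with a header row and "." as
the decimal mark.  Units are fixed in the column names (``_mm``, ``_g``,
``_pct``, ``_ml``) to prevent silent unit drift.  Readers validate the
schema case-insensitively, retain row numbers for error messages (row 1 is
the header), and pass unknown columns through untouched.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .records import (
    Cohort,
    CompositionRecord,
    FemaleRecord,
    FollicleRecord,
    OvaryRecord,
)

FOLLICLE_COLUMNS = ["female_id", "ovary_side", "follicle_id", "diameter_mm", "atretic"]
FOLLICLE_OPTIONAL = ["dry_mass_g", "type"]
OVARY_COLUMNS = ["female_id", "ovary_side", "scar_count", "mass_g", "volume_ml", "measured"]
OVARY_OPTIONAL = ["oviduct_egg_count"]
COMPOSITION_COLUMNS = [
    "female_id", "follicle_id", "type",
    "water_pct", "om_pct", "mineral_pct", "lipid_pct", "n_pct", "p_pct",
]

_FLOAT_FORMAT = "%.6g"


class SchemaError(ValueError):
    """Raised when an input table does not match its schema."""


def _read_table(path, required: list[str], numeric: list[str],
                optional_numeric: Iterable[str] = ()) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}' in {path}")
    to_parse = list(numeric) + [c for c in optional_numeric if c in df.columns]
    for col in to_parse:
        raw = df[col].str.strip()
        blank = raw == ""
        parsed = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SchemaError(
                f"non-numeric value '{raw.iloc[row - 2]}' in column '{col}' "
                f"at row {row} of {path}"
            )
        df[col] = parsed
    return df


def read_follicles(path) -> pd.DataFrame:
    """Read and validate a follicles table."""
    df = _read_table(
        path,
        required=FOLLICLE_COLUMNS,
        numeric=["diameter_mm", "atretic"],
        optional_numeric=["dry_mass_g"],
    )
    if (df["diameter_mm"] <= 0).any():
        row = int(np.flatnonzero((df["diameter_mm"] <= 0).to_numpy())[0]) + 2
        raise SchemaError(f"non-positive diameter_mm at row {row} of {path}")
    return df


def read_ovaries(path) -> pd.DataFrame:
    df = _read_table(
        path,
        required=OVARY_COLUMNS,
        numeric=["scar_count", "measured"],
        optional_numeric=["mass_g", "volume_ml", "oviduct_egg_count"],
    )
    if (df["scar_count"] < 0).any():
        row = int(np.flatnonzero((df["scar_count"] < 0).to_numpy())[0]) + 2
        raise SchemaError(f"negative scar_count at row {row} of {path}")
    return df


def read_composition(path) -> pd.DataFrame:
    return _read_table(
        path,
        required=COMPOSITION_COLUMNS,
        numeric=["water_pct", "om_pct", "mineral_pct", "lipid_pct", "n_pct", "p_pct"],
    )


def build_cohort(
    follicles: pd.DataFrame,
    ovaries: pd.DataFrame,
    composition: Optional[pd.DataFrame] = None,
) -> Cohort:
    """Assemble typed records from validated tables."""
    females: dict[str, FemaleRecord] = {}
    for _, row in ovaries.iterrows():
        fid = str(row["female_id"])
        female = females.setdefault(fid, FemaleRecord(female_id=fid))
        ovi = row.get("oviduct_egg_count")
        mass = row.get("mass_g")
        vol = row.get("volume_ml")
        female.ovaries.append(
            OvaryRecord(
                female_id=fid,
                side=str(row["ovary_side"]).lower(),
                scar_count=int(row["scar_count"]),
                mass_g=None if pd.isna(mass) else float(mass),
                volume_ml=None if pd.isna(vol) else float(vol),
                oviduct_egg_count=None if ovi is None or pd.isna(ovi) else int(ovi),
                measured=bool(int(row["measured"])),
                follicles=[],
            )
        )
    for _, row in follicles.iterrows():
        fid = str(row["female_id"])
        side = str(row["ovary_side"]).lower()
        if fid not in females:
            raise SchemaError(f"follicle {row['follicle_id']} references unknown female {fid}")
        ovary = next((o for o in females[fid].ovaries if o.side == side), None)
        if ovary is None:
            raise SchemaError(
                f"follicle {row['follicle_id']} references unknown ovary {fid}/{side}"
            )
        dm = row.get("dry_mass_g")
        ftype = str(row.get("type") or "").strip() or None
        ovary.follicles.append(
            FollicleRecord(
                follicle_id=str(row["follicle_id"]),
                female_id=fid,
                ovary_side=side,
                diameter_mm=float(row["diameter_mm"]),
                atretic=bool(int(row["atretic"])),
                dry_mass_g=None if dm is None or pd.isna(dm) else float(dm),
                follicle_type=ftype,
            )
        )
    comp_records: list[CompositionRecord] = []
    if composition is not None:
        for _, row in composition.iterrows():
            comp_records.append(
                CompositionRecord(
                    female_id=str(row["female_id"]),
                    follicle_id=str(row["follicle_id"]),
                    follicle_type=str(row["type"]).upper(),
                    water_pct=float(row["water_pct"]),
                    om_pct=float(row["om_pct"]),
                    mineral_pct=float(row["mineral_pct"]),
                    lipid_pct=float(row["lipid_pct"]),
                    n_pct=float(row["n_pct"]),
                    p_pct=float(row["p_pct"]),
                )
            )
    ordered = [females[k] for k in sorted(females)]
    return Cohort(females=ordered, composition=comp_records)


def read_cohort(follicles_path, ovaries_path, composition_path=None) -> Cohort:
    comp = read_composition(composition_path) if composition_path else None
    return build_cohort(read_follicles(follicles_path), read_ovaries(ovaries_path), comp)


# ---------------------------------------------------------------------------
# writers


def cohort_frames(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Flatten a cohort into its CSV-shaped tables."""
    foll_rows, ovary_rows, female_rows = [], [], []
    for fem in cohort.females:
        female_rows.append(
            {
                "female_id": fem.female_id,
                "n_ovaries_measured": len(fem.measured_ovaries()),
                "has_composition": int(
                    any(c.female_id == fem.female_id for c in cohort.composition)
                ),
            }
        )
        for ov in fem.ovaries:
            ovary_rows.append(
                {
                    "female_id": ov.female_id,
                    "ovary_side": ov.side,
                    "scar_count": ov.scar_count,
                    "mass_g": ov.mass_g,
                    "volume_ml": ov.volume_ml,
                    "oviduct_egg_count": ov.oviduct_egg_count,
                    "measured": int(ov.measured),
                }
            )
            for f in ov.follicles:
                foll_rows.append(
                    {
                        "female_id": f.female_id,
                        "ovary_side": f.ovary_side,
                        "follicle_id": f.follicle_id,
                        "diameter_mm": f.diameter_mm,
                        "atretic": int(f.atretic),
                        "dry_mass_g": f.dry_mass_g,
                        "type": f.follicle_type or "",
                    }
                )
    comp_rows = [
        {
            "female_id": c.female_id,
            "follicle_id": c.follicle_id,
            "type": c.follicle_type,
            "water_pct": c.water_pct,
            "om_pct": c.om_pct,
            "mineral_pct": c.mineral_pct,
            "lipid_pct": c.lipid_pct,
            "n_pct": c.n_pct,
            "p_pct": c.p_pct,
        }
        for c in cohort.composition
    ]
    return {
        "follicles": pd.DataFrame(foll_rows),
        "ovaries": pd.DataFrame(ovary_rows),
        "females": pd.DataFrame(female_rows),
        "composition": pd.DataFrame(
            comp_rows, columns=COMPOSITION_COLUMNS if not comp_rows else None
        ),
    }


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    frames = cohort_frames(cohort)
    paths = {}
    for name, frame in frames.items():
        path = os.path.join(outdir, f"{name}.csv")
        frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
        paths[name] = path
    return paths


def write_table(frame: pd.DataFrame, path) -> str:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return str(path)
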