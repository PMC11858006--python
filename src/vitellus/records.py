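"""Core record types shared across the pipeline.

A cohort is a collection of females; each female carries one or two ovary
records (only ovaries that were actually measured appear), and each ovary
carries its follicles.  Yolk-composition measurements of the subsampled
follicles live in a separate flat table keyed by female and follicle id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SIDES = ("left", "right")
FOLLICLE_TYPES = ("AF", "SF", "LF")

#: Composition variables: water is % of wet mass, the rest % of dry mass.
COMPOSITION_VARIABLES = ("water_pct", "om_pct", "mineral_pct", "lipid_pct", "n_pct", "p_pct")


@dataclass
class FollicleRecord:
    """One measured vitellogenic follicle."""

    follicle_id: str
    female_id: str
    ovary_side: str
    diameter_mm: float
    atretic: bool = False
    dry_mass_g: Optional[float] = None
    follicle_type: Optional[str] = None  # AF/SF/LF for subsampled follicles


@dataclass
class OvaryRecord:
    """One measured ovary: ovulatory scars, bulk size, and its follicles."""

    female_id: str
    side: str
    scar_count: int
    mass_g: Optional[float] = None  # scale resolution 500 g
    volume_ml: Optional[float] = None  # water displacement, resolution 50 ml
    oviduct_egg_count: Optional[int] = None
    measured: bool = True
    follicles: list[FollicleRecord] = field(default_factory=list)

    def diameters(self) -> list[float]:
        return [f.diameter_mm for f in self.follicles]


@dataclass
class FemaleRecord:
    """A female turtle with her measured ovaries."""

    female_id: str
    ovaries: list[OvaryRecord] = field(default_factory=list)

    def measured_ovaries(self) -> list[OvaryRecord]:
        return [o for o in self.ovaries if o.measured]


@dataclass
class CompositionRecord:
    """Yolk composition of one subsampled follicle (percentages)."""

    female_id: str
    follicle_id: str
    follicle_type: str  # AF, SF or LF
    water_pct: float
    om_pct: float
    mineral_pct: float
    lipid_pct: float
    n_pct: float
    p_pct: float


@dataclass
class Cohort:
    females: list[FemaleRecord] = field(default_factory=list)
    composition: list[CompositionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.females)

    def all_follicles(self) -> list[FollicleRecord]:
        return [f for fem in self.females for ov in fem.ovaries for f in ov.follicles]

    def pooled_diameters(self) -> list[float]:
        return [f.diameter_mm for f in self.all_follicles()]
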