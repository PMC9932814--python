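"""Deterministic calculators for dual-luciferase and electroporation readouts.

Dual-luciferase wells: technical repeats per channel are averaged, firefly
is normalized by Renilla per well, and each pathway-stimulated (DVL2+) well
is expressed as fold change over the mean ratio of the unstimulated (DVL2-)
wells of the same plate and condition — plates hold cells from different
passages, so normalization never crosses plates.  Abnormally low Renilla
wells (transfection failures) are flagged, never silently excluded.

Electroporated retinas: every GFP+ cell is classified into the outer nuclear
layer (ONL), the outer half of the inner nuclear layer, or the inner half of
the INL — the amacrine cell layer (ACL) — and the ACL count is expressed as
a percentage of all GFP+ cells, summed over sections.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import ValidationError

CONDITIONS = ("control", "full_length", "truncated", "missense")

#: Renilla flagging: a well is suspect when its Renilla mean is more than
#: k-fold below the plate median.  Advisory only; exclusion is a caller call.
DEFAULT_RENILLA_K = 10.0


@dataclass
class LuciferaseWell:
    plate: str
    condition: str
    dvl2: bool
    firefly_reads: list[float]
    renilla_reads: list[float]
    well: str = ""

    def __post_init__(self) -> None:
        if not self.firefly_reads or not self.renilla_reads:
            raise ValidationError("each channel needs >=1 read")
        if any(r < 0 for r in self.firefly_reads + self.renilla_reads):
            raise ValidationError("luminosity reads must be >= 0")

    @property
    def firefly_mean(self) -> float:
        return float(np.mean(self.firefly_reads))

    @property
    def renilla_mean(self) -> float:
        return float(np.mean(self.renilla_reads))

    @property
    def ratio(self) -> float:
        if self.renilla_mean == 0:
            raise ValidationError(
                f"plate {self.plate} {self.condition}: Renilla mean is 0"
            )
        return self.firefly_mean / self.renilla_mean


@dataclass
class FoldChange:
    plate: str
    condition: str
    well: str
    fold: float


def luciferase_fold_change(wells: Sequence[LuciferaseWell]) -> list[FoldChange]:
    """Per-well fold change of DVL2+ wells over the DVL2- baseline.

    Baseline = mean firefly/Renilla ratio over DVL2- wells of the same plate
    and condition; every (plate, condition) group must contain at least one
    DVL2- well.
    """
    groups: dict[tuple[str, str], list[LuciferaseWell]] = defaultdict(list)
    for w in wells:
        groups[(w.plate, w.condition)].append(w)
    out: list[FoldChange] = []
    for (plate, condition), members in groups.items():
        baseline_wells = [w for w in members if not w.dvl2]
        if not baseline_wells:
            raise ValidationError(
                f"plate {plate} {condition}: no DVL2- baseline well"
            )
        baseline = float(np.mean([w.ratio for w in baseline_wells]))
        if baseline == 0:
            raise ValidationError(
                f"plate {plate} {condition}: baseline ratio is 0"
            )
        for w in members:
            if w.dvl2:
                out.append(FoldChange(plate, condition, w.well, w.ratio / baseline))
    return out


def flag_low_renilla(
    wells: Sequence[LuciferaseWell], k: float = DEFAULT_RENILLA_K
) -> list[LuciferaseWell]:
    """Flag wells whose Renilla mean is k-fold below the plate median.

    Returns the flagged wells; requires >=4 wells per plate for the median
    to be meaningful.
    """
    by_plate: dict[str, list[LuciferaseWell]] = defaultdict(list)
    for w in wells:
        by_plate[w.plate].append(w)
    flagged = []
    for plate, members in by_plate.items():
        if len(members) < 4:
            raise ValidationError(f"plate {plate}: need >=4 wells to flag outliers")
        med = float(np.median([w.renilla_mean for w in members]))
        for w in members:
            if w.renilla_mean < med / k:
                flagged.append(w)
    return flagged


# ---------------------------------------------------------------------------
# Electroporation ACL fraction
# ---------------------------------------------------------------------------


@dataclass
class SectionCounts:
    onl: int
    inl_outer: int
    acl: int

    def __post_init__(self) -> None:
        if min(self.onl, self.inl_outer, self.acl) < 0:
            raise ValidationError("section counts must be >= 0")


@dataclass
class ElectroporatedRetina:
    retina: str
    condition: str  # control | dtx4
    sections: list[SectionCounts] = field(default_factory=list)


def acl_fraction(retina: ElectroporatedRetina) -> float:
    """ACL cells as a percentage of all GFP+ cells, summed over sections."""
    onl = sum(s.onl for s in retina.sections)
    inl_outer = sum(s.inl_outer for s in retina.sections)
    acl = sum(s.acl for s in retina.sections)
    total = onl + inl_outer + acl
    if total == 0:
        raise ValidationError(f"retina {retina.retina}: no counted cells")
    return 100.0 * acl / total


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------


def read_luciferase_csv(path: str | os.PathLike) -> list[LuciferaseWell]:
    """Read a luciferase CSV with columns plate, well, condition, dvl2, channel, read."""
    frame = pd.read_csv(os.fspath(path))
    frame.columns = [c.strip().lower() for c in frame.columns]
    keyed: dict[tuple, dict[str, list[float]]] = defaultdict(
        lambda: {"firefly": [], "renilla": []}
    )
    dvl2_map = {"true": True, "false": False, "1": True, "0": False}
    for row in frame.itertuples(index=False):
        key = (str(row.plate), str(row.well), str(row.condition),
               dvl2_map[str(row.dvl2).strip().lower()])
        keyed[key][str(row.channel).strip().lower()].append(float(row.read))
    return [
        LuciferaseWell(
            plate=plate,
            condition=condition,
            dvl2=dvl2,
            firefly_reads=chans["firefly"],
            renilla_reads=chans["renilla"],
            well=well,
        )
        for (plate, well, condition, dvl2), chans in keyed.items()
    ]


def read_electroporation_csv(path: str | os.PathLike) -> list[ElectroporatedRetina]:
    """Read an electroporation CSV: retina, condition, section, onl, inl_outer, acl."""
    frame = pd.read_csv(os.fspath(path))
    frame.columns = [c.strip().lower() for c in frame.columns]
    retinas: dict[tuple[str, str], list[SectionCounts]] = defaultdict(list)
    for row in frame.itertuples(index=False):
        retinas[(str(row.retina), str(row.condition))].append(
            SectionCounts(int(row.onl), int(row.inl_outer), int(row.acl))
        )
    return [
        ElectroporatedRetina(retina, condition, sections)
        for (retina, condition), sections in retinas.items()
    ]
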