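"""Lipid-mediator panel data model and the default 8-group enrichment scheme.

A *panel* is the registry of lipid species a targeted LC-MS/MS assay
quantifies: eicosanoids, docosanoids, octadecanoids, endocannabinoids (eCB)
and N-acyl ethanolamines (NAE).  Each species carries its precursor PUFA
(AA, EPA, DHA, ...), a biosynthetic pathway label, the reporting unit and
the analytical limit of detection (LOD).  A *group scheme* clusters species
into named sets sharing common features (e.g. all HEPEs); these sets are
the units scored by iterative group analysis (:mod:`lipidiga.iga`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PRECURSORS = frozenset(
    {"AA", "EPA", "DHA", "LA", "DGLA", "ALA", "saturated/monounsaturated", "other"}
)
PATHWAYS = frozenset(
    {
        "COX",
        "LOX",
        "CYP450-epoxide",
        "CYP450-diol",
        "eCB",
        "NAE",
        "nonenzymatic",
        "hybrid-monohydroxy",
    }
)
UNITS = frozenset({"pg/mg-protein", "pg/ml"})
COMPARTMENTS = frozenset({"skin", "plasma"})

#: CSV columns required by :func:`load_panel`.
PANEL_COLUMNS = ("name", "precursor", "pathway", "unit", "lod")


class PanelValidationError(ValueError):
    """Raised when a panel file or in-memory panel violates an invariant."""


@dataclass(frozen=True)
class LipidSpecies:
    """A single lipid mediator.

    ``compartments`` records where the assay measures the species
    ("skin", "plasma" or both); skin concentrations are reported in
    pg/mg protein and plasma concentrations in pg/ml.
    """

    name: str
    precursor: str
    pathway: str
    unit: str
    lod: float
    compartments: tuple[str, ...] = ("skin", "plasma")

    def __post_init__(self) -> None:
        if self.precursor not in PRECURSORS:
            raise PanelValidationError(
                f"unknown precursor {self.precursor!r} for species {self.name!r}"
            )
        if self.pathway not in PATHWAYS:
            raise PanelValidationError(
                f"unknown pathway {self.pathway!r} for species {self.name!r}"
            )
        if self.unit not in UNITS:
            raise PanelValidationError(
                f"unknown unit {self.unit!r} for species {self.name!r}"
            )
        if not self.lod > 0:
            raise PanelValidationError(
                f"LOD must be positive, got {self.lod!r} for species {self.name!r}"
            )
        bad = set(self.compartments) - COMPARTMENTS
        if bad or not self.compartments:
            raise PanelValidationError(
                f"invalid compartments {self.compartments!r} for species {self.name!r}"
            )


class MediatorPanel:
    """Ordered, validated collection of :class:`LipidSpecies`."""

    def __init__(self, species: Iterable[LipidSpecies]):
        species = list(species)
        if not species:
            raise PanelValidationError("panel must contain at least one species")
        seen: set[str] = set()
        for sp in species:
            if sp.name in seen:
                raise PanelValidationError(f"duplicate species name {sp.name!r}")
            seen.add(sp.name)
        self.species: tuple[LipidSpecies, ...] = tuple(species)
        self._by_name = {sp.name: sp for sp in self.species}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self) -> Iterator[LipidSpecies]:
        return iter(self.species)

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> LipidSpecies:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [sp.name for sp in self.species]

    def species_in(self, compartment: str) -> list[str]:
        """Names of species measured in ``compartment`` ('skin' or 'plasma')."""
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        return [sp.name for sp in self.species if compartment in sp.compartments]

    def lods(self, names: Sequence[str] | None = None) -> pd.Series:
        names = list(names) if names is not None else self.names
        return pd.Series({n: self._by_name[n].lod for n in names}, name="lod").loc[names]

    def subset(self, names: Sequence[str]) -> "MediatorPanel":
        return MediatorPanel(self._by_name[n] for n in names)

    # -- (de)serialisation ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [sp.name for sp in self.species],
                "precursor": [sp.precursor for sp in self.species],
                "pathway": [sp.pathway for sp in self.species],
                "unit": [sp.unit for sp in self.species],
                "lod": [sp.lod for sp in self.species],
                "compartments": [";".join(sp.compartments) for sp in self.species],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MediatorPanel":
        missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
        if missing:
            raise PanelValidationError(f"panel table lacks columns {missing}")
        species = []
        for row in frame.itertuples(index=False):
            comp = getattr(row, "compartments", None)
            if comp is None or (isinstance(comp, float) and pd.isna(comp)):
                compartments: tuple[str, ...] = ("skin", "plasma")
            else:
                compartments = tuple(str(comp).split(";"))
            species.append(
                LipidSpecies(
                    name=str(row.name),
                    precursor=str(row.precursor),
                    pathway=str(row.pathway),
                    unit=str(row.unit),
                    lod=float(row.lod),
                    compartments=compartments,
                )
            )
        return cls(species)


def load_panel(path: str | Path) -> MediatorPanel:
    """Read a panel CSV (columns: name, precursor, pathway, unit, lod[, compartments])."""
    frame = pd.read_csv(path, dtype={"name": str})
    return MediatorPanel.from_frame(frame)


def write_panel(panel: MediatorPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)


def load_default_panel() -> MediatorPanel:
    """The packaged fixture panel: 89 skin-measured species, 66 of them in plasma."""
    ref = resources.files("lipidiga.data").joinpath("panel.csv")
    with resources.as_file(ref) as path:
        return load_panel(path)


# ---------------------------------------------------------------------------
# Group scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupScheme:
    """Named species groups used for rank-based enrichment scoring."""

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for label, members in self.groups.items():
            if not members:
                raise PanelValidationError(f"group {label!r} is empty")

    def __len__(self) -> int:
        return len(self.groups)

    def validate_against(self, panel: MediatorPanel) -> None:
        for label, members in self.groups.items():
            unknown = [m for m in members if m not in panel]
            if unknown:
                raise PanelValidationError(
                    f"group {label!r} references species not in panel: {unknown}"
                )

    def restrict(self, names: Sequence[str]) -> dict[str, tuple[str, ...]]:
        """Intersect every group with ``names``; empty intersections are dropped."""
        universe = set(names)
        out = {}
        for label, members in self.groups.items():
            kept = tuple(m for m in members if m in universe)
            if kept:
                out[label] = kept
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {label: list(members) for label, members in self.groups.items()},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroupScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({label: tuple(members) for label, members in raw.items()})


# Default grouping: precursor x pathway rules applied in order; each species
# joins the first matching group only, so the default scheme never overlaps.
_MONOHYDROXY = frozenset({"LOX", "hybrid-monohydroxy"})
_DEFAULT_GROUP_RULES: tuple[tuple[str, object], ...] = (
    ("AA COX prostanoids", lambda s: s.precursor == "AA" and s.pathway == "COX"),
    ("HETEs + hepoxilins", lambda s: s.precursor == "AA" and s.pathway in _MONOHYDROXY),
    (
        "HEPEs + E-series prostanoids",
        lambda s: s.precursor == "EPA" and s.pathway in (_MONOHYDROXY | {"COX"}),
    ),
    ("HDHAs", lambda s: s.precursor == "DHA" and s.pathway in _MONOHYDROXY),
    (
        "octadecanoid hydroxy acids",
        lambda s: s.precursor in {"LA", "DGLA", "ALA"}
        and s.pathway in (_MONOHYDROXY | {"nonenzymatic"}),
    ),
    ("CYP450 epoxides", lambda s: s.pathway == "CYP450-epoxide"),
    ("CYP450 diols", lambda s: s.pathway == "CYP450-diol"),
    ("eCBs + NAEs", lambda s: s.pathway in {"eCB", "NAE"}),
)


def default_group_scheme(panel: MediatorPanel) -> GroupScheme:
    """Cluster panel species into the default 8 groups by precursor and pathway.

    Species matching no rule (e.g. nonenzymatic AA isoprostanes) are left
    ungrouped and reported via a warning; they still take part in per-species
    testing and count toward the ranked universe in iGA.
    """
    assigned: dict[str, list[str]] = {label: [] for label, _ in _DEFAULT_GROUP_RULES}
    orphans: list[str] = []
    for sp in panel:
        for label, rule in _DEFAULT_GROUP_RULES:
            if rule(sp):
                assigned[label].append(sp.name)
                break
        else:
            orphans.append(sp.name)
    if orphans:
        logger.warning(
            "species assigned to no default group: %s", ", ".join(orphans)
        )
    groups = {
        label: tuple(members) for label, members in assigned.items() if members
    }
    if len(groups) < len(_DEFAULT_GROUP_RULES):
        empty = [label for label, _ in _DEFAULT_GROUP_RULES if label not in groups]
        logger.warning("default groups with no members on this panel: %s", empty)
    return GroupScheme(groups)
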