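"""Antibody/reagent panel: marker <-> metal isotope <-> mass channel registry.

A panel maps each stain (metal-conjugated antibody or element-containing
reagent) to the mass channel it is detected on, together with a functional
role tag.  Roles drive downstream processing: ``stromal`` and ``epithelial``
channels feed the region classifier, ``nuclear`` channels feed nucleus
segmentation, the ``drug`` channel (platinum) is the quantification target,
and the ``background`` channel (the xenon plasma impurity) is the
sensitivity monitor used for normalization.

Channel names are canonicalised to mass-then-element form ("195Pt",
"169Tm"); common variants ("Pt195", "Pt-195") are accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import yaml

from .errors import PanelError

#: Recognised role tags.
ROLES = (
    "nuclear",
    "epithelial",
    "stromal",
    "proliferation",
    "hypoxia",
    "damage",
    "drug",
    "background",
    "other",
)

_CHANNEL_RE = re.compile(r"^\s*(?:(\d{2,3})[-_ ]?([A-Za-z]{1,2})|([A-Za-z]{1,2})[-_ ]?(\d{2,3}))\s*$")


def normalize_channel_name(name: str) -> str:
    """Return the canonical ``<mass><Element>`` form of a channel name.

    Accepts "195Pt", "Pt195", "Pt-195", "pt 195" and the like.  Names that
    do not look like an isotope label are returned stripped but otherwise
    unchanged (the raw reader tolerates arbitrary column names).
    """
    m = _CHANNEL_RE.match(name)
    if not m:
        return name.strip()
    if m.group(1):
        mass, elem = m.group(1), m.group(2)
    else:
        elem, mass = m.group(3), m.group(4)
    return f"{int(mass)}{elem.capitalize()}"


def split_channel_name(name: str) -> tuple[Optional[str], Optional[int]]:
    """Split a canonical channel name into (element, mass); (None, None) if not isotope-like."""
    m = _CHANNEL_RE.match(name)
    if not m:
        return None, None
    if m.group(1):
        return m.group(2).capitalize(), int(m.group(1))
    return m.group(3).capitalize(), int(m.group(4))


def _normalize_marker(marker: str) -> str:
    """Fold a marker name to a lookup key (case, spaces, dashes, Greek letters)."""
    s = marker.strip().lower()
    s = s.replace("γ", "g").replace("α", "a").replace("β", "b")
    s = re.sub(r"[\s\-_/]", "", s)
    return s


@dataclass(frozen=True)
class PanelEntry:
    marker: str
    metal_isotope: str
    channel_name: str
    role: str
    final_concentration: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PanelError(f"unknown role {self.role!r} for marker {self.marker!r}; "
                             f"expected one of {ROLES}")
        object.__setattr__(self, "channel_name", normalize_channel_name(self.channel_name))
        object.__setattr__(self, "metal_isotope", normalize_channel_name(self.metal_isotope))


@dataclass
class Panel:
    """Ordered registry of panel entries with unique channel names."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.channel_name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate channel names in panel: {sorted(dupes)}")

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def channels(self) -> list[str]:
        return [e.channel_name for e in self.entries]

    def by_role(self, role: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.role == role]

    def entry_for_channel(self, channel: str) -> PanelEntry:
        key = normalize_channel_name(channel)
        for e in self.entries:
            if e.channel_name == key:
                return e
        raise PanelError(f"channel {channel!r} not in panel")

    def entry_for_marker(self, marker: str) -> PanelEntry:
        key = _normalize_marker(marker)
        for e in self.entries:
            if _normalize_marker(e.marker) == key:
                return e
        raise PanelError(f"marker {marker!r} not in panel")

    def channel_for_marker(self, marker: str) -> str:
        return self.entry_for_marker(marker).channel_name

    def require_roles(self, roles: Iterable[str]) -> None:
        """Raise PanelError naming every role in *roles* that has no entry."""
        missing = [r for r in roles if not self.by_role(r)]
        if missing:
            raise PanelError(f"panel is missing required roles: {missing}")

    def require_markers(self, markers: Iterable[str]) -> None:
        missing = []
        for m in markers:
            try:
                self.entry_for_marker(m)
            except PanelError:
                missing.append(m)
        if missing:
            raise PanelError(f"panel is missing required markers: {missing}")

    # -- serialisation ----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = [
            {
                "marker": e.marker,
                "metal_isotope": e.metal_isotope,
                "channel_name": e.channel_name,
                "role": e.role,
                "final_concentration": e.final_concentration,
            }
            for e in self.entries
        ]
        with open(path, "w") as fh:
            yaml.safe_dump({"panel": data}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Panel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        entries = [PanelEntry(**row) for row in data["panel"]]
        return cls(entries)


def default_panel() -> Panel:
    """The default xenograft staining panel.

    Lineage markers for epithelium (Pan-Keratin, E-cadherin) and stroma
    (Collagen I, aSMA), nuclear stains (Ir intercalator, Histone H3),
    proliferation (IdU via 127I, Ki-67), hypoxia (EF5), DNA damage (gH2AX),
    the platinum drug channel (195Pt) and the xenon sensitivity monitor
    (134Xe).
    """
    return Panel([
        PanelEntry("gH2AX", "147Sm", "147Sm", "damage", "5 ug/mL"),
        PanelEntry("E-cadherin", "158Gd", "158Gd", "epithelial", "5 ug/mL"),
        PanelEntry("EF5", "159Tb", "159Tb", "hypoxia", "10 ug/mL"),
        PanelEntry("Pan-Keratin", "162Dy", "162Dy", "epithelial", "5 ug/mL"),
        PanelEntry("Ki-67", "168Er", "168Er", "proliferation", "5 ug/mL"),
        PanelEntry("Collagen I", "169Tm", "169Tm", "stromal", "5 ug/mL"),
        PanelEntry("aSMA", "175Lu", "175Lu", "stromal", "5 ug/mL"),
        PanelEntry("Histone H3", "176Yb", "176Yb", "nuclear", "5 ug/mL"),
        PanelEntry("Ir-Intercalator", "191Ir", "191Ir", "nuclear", "25 uM"),
        PanelEntry("IdU", "127I", "127I", "proliferation", "60 mg/kg"),
        PanelEntry("Cisplatin", "195Pt", "195Pt", "drug", None),
        PanelEntry("Xenon", "134Xe", "134Xe", "background", None),
    ])


#: Marker keys the simulator and classifier rely on.
REQUIRED_MARKERS = (
    "Collagen I", "aSMA", "Pan-Keratin", "E-cadherin", "Histone H3",
    "Ir-Intercalator", "IdU", "EF5", "gH2AX", "Ki-67",
)
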