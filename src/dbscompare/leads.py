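"""Parametric DBS lead geometry and stimulation-setting representation.

The catalog covers the ring ("standard") and segmented ("steerable") leads used
in the experimental cohort: Medtronic 3387/3389, Boston Scientific Vercise
(2201) and Cartesia (2202), and Abbott 6172.  Geometry is vendor-nominal and
lives in ``data/leads.yaml``; individual dimensions can be overridden at build
time.

Conventions
-----------
* World frame is RAS millimetres.
* The lead frame is right-handed with +z pointing from the tip toward the
  shaft; contact angular sectors are measured about +z from the lead-frame +x
  axis.
* A :class:`LeadPlacement` is the rigid map lead-frame -> world: rotation
  taking +z to ``axis`` composed with a roll about the axis, then translation
  by ``tip_position``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Contact",
    "LeadModel",
    "LeadPlacement",
    "StimSetting",
    "CatalogError",
    "available_leads",
    "build_lead",
    "placement_rotation",
    "contact_positions",
    "enumerate_settings",
    "load_experiment_table",
]


class CatalogError(KeyError):
    """Unknown lead name."""


@dataclass(frozen=True)
class Contact:
    """A single electrode contact in the lead frame.

    ``angular_span`` is ``None`` for a full ring, else ``(start_deg, end_deg)``
    with ``end > start`` and span < 360.  ``center`` is the centroid of the
    contact surface in lead-frame mm (on the axis for rings, on the shaft
    surface for segments).
    """

    index: int
    level: int
    angular_span: tuple[float, float] | None
    center: tuple[float, float, float]

    @property
    def full_ring(self) -> bool:
        return self.angular_span is None

    @property
    def z(self) -> float:
        return self.center[2]


@dataclass(frozen=True)
class LeadModel:
    name: str
    vendor: str
    lead_type: str  # "standard" | "steerable"
    shaft_radius: float  # mm
    tip_length: float  # mm
    contact_height: float  # mm
    contact_gap: float  # mm
    contacts: tuple[Contact, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for v in (self.shaft_radius, self.tip_length, self.contact_height, self.contact_gap):
            if v <= 0:
                raise ValueError(f"lead dimensions must be positive, got {v}")
        # contacts at one level must span disjoint sectors summing to < 360 deg
        by_level: dict[int, list[Contact]] = {}
        for c in self.contacts:
            by_level.setdefault(c.level, []).append(c)
        for level, cs in by_level.items():
            segs = [c for c in cs if not c.full_ring]
            if segs and len(segs) != len(cs):
                raise ValueError(f"level {level} mixes ring and segmented contacts")
            spans = sorted(c.angular_span for c in segs)
            total = sum(e - s for s, e in spans)
            if segs and total >= 360.0:
                raise ValueError(f"level {level} sectors sum to {total} >= 360 deg")
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                if e0 > s1:
                    raise ValueError(f"level {level} sectors overlap")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def n_levels(self) -> int:
        return 1 + max(c.level for c in self.contacts)

    def level_z(self, level: int) -> float:
        """Axial position (mm above tip) of a contact level's centroid."""
        return self.tip_length + level * (self.contact_height + self.contact_gap) + self.contact_height / 2.0

    def is_segmented(self, index: int) -> bool:
        return not self.contacts[index].full_ring

    def contacts_at_level(self, level: int) -> tuple[Contact, ...]:
        return tuple(c for c in self.contacts if c.level == level)

    @property
    def top_z(self) -> float:
        """Axial position of the top edge of the most proximal contact."""
        return self.level_z(self.n_levels - 1) + self.contact_height / 2.0


@dataclass(frozen=True)
class LeadPlacement:
    """Rigid pose of a lead in world (RAS mm) coordinates."""

    tip_position: tuple[float, float, float]
    axis: tuple[float, float, float]
    roll_deg: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, float)
        if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-6):
            raise ValueError(f"placement axis must be a unit vector, |axis|={np.linalg.norm(a):.4f}")


@dataclass(frozen=True)
class StimSetting:
    """One stimulation setting.

    ``anodes == ()`` means the return is at the implanted-pulse-generator case
    (monopolar, cathodic).  The waveform is carried as metadata; the linear
    field model uses the cathodic-phase amplitude only.
    """

    cathodes: tuple[int, ...]
    anodes: tuple[int, ...]  # empty tuple == case return (monopolar)
    amplitude_mA: float
    pulse_width_us: float = 60.0
    frequency_hz: float = 10.0
    interphase_gap_us: float = 70.0
    directional: bool = False
    setting_id: str = ""

    def __post_init__(self) -> None:
        if not self.cathodes:
            raise ValueError("a setting needs at least one cathode")
        if self.amplitude_mA <= 0:
            raise ValueError("amplitude must be positive")
        if set(self.cathodes) & set(self.anodes):
            raise ValueError("cathodes and anodes must be disjoint")

    @property
    def monopolar(self) -> bool:
        return len(self.anodes) == 0

    @property
    def active_contacts(self) -> tuple[int, ...]:
        return tuple(self.cathodes) + tuple(self.anodes)

    @property
    def contact_currents_mA(self) -> dict[int, float]:
        """Signed current per active contact (cathodes negative); case return
        carries the balance for monopolar settings."""
        out = {c: -self.amplitude_mA / len(self.cathodes) for c in self.cathodes}
        for a in self.anodes:
            out[a] = self.amplitude_mA / len(self.anodes)
        return out


def _load_catalog() -> dict:
    with resources.files("dbscompare.data").joinpath("leads.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def available_leads() -> tuple[str, ...]:
    return tuple(sorted(_load_catalog()))


def build_lead(name: str, overrides: Mapping[str, float] | None = None) -> LeadModel:
    """Build a lead model from the catalog.

    Parameters
    ----------
    name
        Catalog key, e.g. ``"MDT3389"``.
    overrides
        Optional replacements for scalar dimensions
        (``shaft_radius``, ``tip_length``, ``contact_height``, ``contact_gap``).
    """
    catalog = _load_catalog()
    if name not in catalog:
        raise CatalogError(f"unknown lead {name!r}; valid: {', '.join(sorted(catalog))}")
    entry = dict(catalog[name])
    if overrides:
        entry.update(overrides)
    shaft_radius = float(entry["shaft_radius"])
    tip_length = float(entry["tip_length"])
    height = float(entry["contact_height"])
    gap = float(entry["contact_gap"])

    contacts: list[Contact] = []
    idx = 0
    for level, sectors in enumerate(entry["levels"]):
        z = tip_length + level * (height + gap) + height / 2.0
        for sector in sectors:
            if sector == "ring":
                contacts.append(Contact(idx, level, None, (0.0, 0.0, z)))
            else:
                s, e = float(sector[0]), float(sector[1])
                mid = np.deg2rad((s + e) / 2.0)
                center = (shaft_radius * np.cos(mid), shaft_radius * np.sin(mid), z)
                contacts.append(Contact(idx, level, (s, e), center))
            idx += 1
    return LeadModel(
        name=name,
        vendor=str(entry.get("vendor", "")),
        lead_type=str(entry["type"]),
        shaft_radius=shaft_radius,
        tip_length=tip_length,
        contact_height=height,
        contact_gap=gap,
        contacts=tuple(contacts),
    )


def placement_rotation(placement: LeadPlacement) -> np.ndarray:
    """3x3 rotation whose columns are the world directions of the lead-frame
    x, y, z axes (roll included).

    The lead-frame x axis is constructed deterministically by Gram-Schmidt of
    the world +x (or +y when the lead axis is nearly parallel to +x) against
    the lead axis, then rotated about the axis by ``roll_deg``.
    """
    z = np.asarray(placement.axis, float)
    z = z / np.linalg.norm(z)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, z)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - np.dot(ref, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    roll = np.deg2rad(placement.roll_deg)
    xr = np.cos(roll) * x + np.sin(roll) * y
    yr = np.cross(z, xr)
    return np.column_stack([xr, yr, z])


def lead_to_world(points_lead: np.ndarray, placement: LeadPlacement) -> np.ndarray:
    R = placement_rotation(placement)
    return np.asarray(points_lead, float) @ R.T + np.asarray(placement.tip_position, float)


def world_to_lead(points_world: np.ndarray, placement: LeadPlacement) -> np.ndarray:
    R = placement_rotation(placement)
    return (np.asarray(points_world, float) - np.asarray(placement.tip_position, float)) @ R


def contact_positions(lead: LeadModel, placement: LeadPlacement) -> np.ndarray:
    """World-frame contact surface centroids, shape (n_contacts, 3)."""
    centers = np.array([c.center for c in lead.contacts], float)
    return lead_to_world(centers, placement)


def _as_config(entry: Sequence[int] | Mapping) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Normalize a settings-menu entry to (cathodes, anodes)."""
    if isinstance(entry, Mapping):
        return tuple(entry["cathodes"]), tuple(entry.get("anodes", ()))
    return tuple(entry), ()


def enumerate_settings(
    lead: LeadModel,
    menu: Mapping,
) -> list[StimSetting]:
    """Expand a settings menu into the cartesian product of contact
    configurations and amplitudes.

    Menu schema (YAML-friendly)::

        monopolar: [[0], [1], [2], [3], [1, 2, 3]]   # each entry: cathode list
        bipolar: [{cathodes: [0], anodes: [3]}]
        amplitudes_mA: [1, 2, 3, 4, 5]
        pulse_width_us: 60
        frequency_hz: 10
        interphase_gap_us: 70

    A multi-cathode monopolar entry covering all segments of one level is a
    "pseudo ring" and is classified non-directional; the directional flag is
    true iff any active contact is a single segmented sector (i.e. the setting
    breaks ring symmetry).
    """
    amplitudes = list(menu.get("amplitudes_mA", []))
    mono = [(_as_config(e)) for e in menu.get("monopolar", [])]
    bi = [(_as_config(e)) for e in menu.get("bipolar", [])]
    configs = mono + bi
    if not configs or not amplitudes:
        raise ValueError("settings menu must list at least one configuration and one amplitude")
    pw = float(menu.get("pulse_width_us", 60.0))
    freq = float(menu.get("frequency_hz", 10.0))
    ipg = float(menu.get("interphase_gap_us", 70.0))

    settings: list[StimSetting] = []
    for (cathodes, anodes), amp in itertools.product(configs, amplitudes):
        active = tuple(cathodes) + tuple(anodes)
        for c in active:
            if c < 0 or c >= lead.n_contacts:
                raise ValueError(f"contact {c} out of range for {lead.name}")
        directional = _is_directional(lead, cathodes, anodes)
        sid = _setting_id(cathodes, anodes, amp)
        settings.append(
            StimSetting(
                cathodes=tuple(cathodes),
                anodes=tuple(anodes),
                amplitude_mA=float(amp),
                pulse_width_us=pw,
                frequency_hz=freq,
                interphase_gap_us=ipg,
                directional=directional,
                setting_id=sid,
            )
        )
    return settings


def _is_directional(lead: LeadModel, cathodes: Iterable[int], anodes: Iterable[int]) -> bool:
    """A setting is directional iff its active segmented contacts do not form
    complete levels (pseudo rings count as non-directional)."""
    active = set(cathodes) | set(anodes)
    seg_active = {i for i in active if lead.is_segmented(i)}
    if not seg_active:
        return False
    for level in {lead.contacts[i].level for i in seg_active}:
        level_ids = {c.index for c in lead.contacts_at_level(level)}
        if not level_ids <= active:
            return True
    return False


def _setting_id(cathodes: Sequence[int], anodes: Sequence[int], amp: float) -> str:
    c = "+".join(str(i) for i in cathodes)
    a = "+".join(str(i) for i in anodes) if anodes else "case"
    return f"c{c}_a{a}_{amp:g}mA"


def load_experiment_table() -> pd.DataFrame:
    """Experimental-cohort bookkeeping table (per-patient setting counts, lead
    models, and bottom-contact mid-commissural-point coordinates)."""
    with resources.files("dbscompare.data").joinpath("experiment_table.csv").open("r") as fh:
        df = pd.read_csv(fh)
    df["n_settings"] = df["n_monopolar"] + df["n_bipolar"]
    return df
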