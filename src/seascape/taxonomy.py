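"""Three-level sound-source taxonomy.

The label hierarchy follows the standard soundscape partition: Level 1
separates biophony (biological sources), geophony (wind-driven waves, rain)
and anthrophony (vessels, construction, active acoustics); Level 2 groups
sources within a category (fish vs. marine mammals, vessels vs. construction);
Level 3 is the most detailed class (species, call type, vessel type).  A
distinguished *background* class represents ambient noise with no identifiable
event and sits outside the three sound categories.

The default library holds 52 classes (51 sound classes plus background),
shipped as a JSON file so that every class's synthesis archetype and its
acoustic parameters are fixed data, not code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

NYQUIST_HZ = 22_050.0

LEVEL1_CATEGORIES = ("biophony", "geophony", "anthrophony")
BACKGROUND_LEVEL1 = "background"

ARCHETYPES = (
    "tonal_fm",
    "pulse_train",
    "harmonic_stack",
    "noise_band",
    "background_noise",
)


@dataclass(frozen=True)
class SoundClassSpec:
    """One Level-3 class: identity, hierarchy position and synthesis recipe."""

    class_id: int
    name: str
    level1: str
    level2: str
    archetype: str
    archetype_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError(f"class_id must be >= 0, got {self.class_id}")
        valid_level1 = LEVEL1_CATEGORIES + (BACKGROUND_LEVEL1,)
        if self.level1 not in valid_level1:
            raise ValueError(f"level1 must be one of {valid_level1}, got {self.level1!r}")
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if (self.level1 == BACKGROUND_LEVEL1) != (self.archetype == "background_noise"):
            raise ValueError("background level1 and background_noise archetype must coincide")
        for key, value in self.archetype_params.items():
            if not value > 0:
                raise ValueError(f"archetype_params[{key!r}] must be positive, got {value}")
            if key.endswith("_hz") and value > NYQUIST_HZ:
                raise ValueError(
                    f"archetype_params[{key!r}]={value} exceeds Nyquist ({NYQUIST_HZ} Hz)"
                )

    @property
    def is_background(self) -> bool:
        return self.level1 == BACKGROUND_LEVEL1


class SoundTaxonomy:
    """Immutable collection of :class:`SoundClassSpec` with hierarchy lookups."""

    def __init__(self, classes: list[SoundClassSpec]):
        ids = [c.class_id for c in classes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate class_id in taxonomy")
        self._by_id: dict[int, SoundClassSpec] = {
            c.class_id: c for c in sorted(classes, key=lambda c: c.class_id)
        }

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[SoundClassSpec]:
        return iter(self._by_id.values())

    def __contains__(self, class_id: int) -> bool:
        return class_id in self._by_id

    def __getitem__(self, class_id: int) -> SoundClassSpec:
        try:
            return self._by_id[class_id]
        except KeyError:
            raise KeyError(f"unknown class_id {class_id}") from None

    # -- lookups ------------------------------------------------------------
    @property
    def class_ids(self) -> tuple[int, ...]:
        """All class ids in ascending order (the canonical class order)."""
        return tuple(self._by_id)

    @property
    def background_id(self) -> int:
        for c in self:
            if c.is_background:
                return c.class_id
        raise ValueError("taxonomy has no background class")

    @property
    def sound_class_ids(self) -> tuple[int, ...]:
        return tuple(c.class_id for c in self if not c.is_background)

    def level_label(self, class_id: int, level: int) -> str:
        """Map a Level-3 class id to its label at the requested level.

        Background maps to ``"background"`` at every level.
        """
        spec = self[class_id]
        if level == 3:
            return spec.name
        if level == 2:
            return spec.level2
        if level == 1:
            return spec.level1
        raise ValueError(f"level must be 1, 2 or 3, got {level}")

    def level_labels(self, level: int) -> tuple[str, ...]:
        """Distinct labels at a level, in canonical (ascending class id) order."""
        seen: dict[str, None] = {}
        for c in self:
            seen.setdefault(self.level_label(c.class_id, level), None)
        return tuple(seen)

    def id_for_name(self, name: str) -> int:
        for c in self:
            if c.name == name:
                return c.class_id
        raise KeyError(f"unknown class name {name!r}")

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        records = [
            {
                "class_id": c.class_id,
                "name": c.name,
                "level1": c.level1,
                "level2": c.level2,
                "archetype": c.archetype,
                "archetype_params": dict(c.archetype_params),
            }
            for c in self
        ]
        return json.dumps(records, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SoundTaxonomy":
        records = json.loads(text)
        return cls([SoundClassSpec(**r) for r in records])


def build_default_taxonomy() -> SoundTaxonomy:
    """Load the shipped 52-class library (51 sound classes + background)."""
    text = resources.files("seascape.data").joinpath("default_taxonomy.json").read_text()
    return SoundTaxonomy.from_json(text)
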