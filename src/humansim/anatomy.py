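"""Functional anatomy: the body as a tree of blocks.

Injuries are localised to anatomical blocks (head, neck, trunk segments,
limb segments).  Each block carries its share of resting cardiac output,
its share of skin surface (rule-of-nines allocation) and the spinal
segments passing through it, which lets a cervical lesion be translated
into the set of motor effectors lost below it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

# Vertebral levels in rostro-caudal order.  C0 denotes the
# atlanto-occipital junction.
VERTEBRAL_LEVELS = (
    [f"C{i}" for i in range(0, 8)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
)
_LEVEL_INDEX = {name: i for i, name in enumerate(VERTEBRAL_LEVELS)}


@dataclass(frozen=True)
class FunctionalBlock:
    id: str
    parent: Optional[str]
    blood_flow_fraction: float  # share of cardiac output at rest
    skin_fraction: float  # share of total body surface area
    spinal_segments: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpinalLesion:
    """A cord lesion at a vertebral level with fractional completeness."""

    level: str
    completeness: float = 1.0

    def __post_init__(self):
        if self.level not in _LEVEL_INDEX:
            raise ValueError(f"unknown vertebral level {self.level!r}")
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError("completeness must be in [0, 1]")

    @property
    def level_index(self) -> int:
        return _LEVEL_INDEX[self.level]


@dataclass
class AnatomyGraph:
    blocks: dict[str, FunctionalBlock] = field(default_factory=dict)

    @property
    def root(self) -> FunctionalBlock:
        roots = [b for b in self.blocks.values() if b.parent is None]
        if len(roots) != 1:
            raise ValueError(f"anatomy must have exactly one root, got {len(roots)}")
        return roots[0]

    def validate(self) -> None:
        root = self.root
        for b in self.blocks.values():
            if b.parent is not None and b.parent not in self.blocks:
                raise ValueError(f"block {b.id} has unknown parent {b.parent}")
            if not (0.0 <= b.blood_flow_fraction <= 1.0):
                raise ValueError(f"block {b.id} flow fraction out of [0,1]")
            if not (0.0 <= b.skin_fraction <= 1.0):
                raise ValueError(f"block {b.id} skin fraction out of [0,1]")
        # acyclicity: walking up from any block must reach the root
        for b in self.blocks.values():
            seen = set()
            cur: Optional[str] = b.id
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle through block {cur}")
                seen.add(cur)
                cur = self.blocks[cur].parent
        flow = sum(b.blood_flow_fraction for b in self.blocks.values())
        skin = sum(b.skin_fraction for b in self.blocks.values())
        if abs(flow - 1.0) > 1e-9:
            raise ValueError(f"blood flow fractions sum to {flow}, not 1")
        if abs(skin - 1.0) > 1e-9:
            raise ValueError(f"skin fractions sum to {skin}, not 1")

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            [
                {
                    "id": b.id,
                    "parent": b.parent,
                    "blood_flow_fraction": b.blood_flow_fraction,
                    "skin_fraction": b.skin_fraction,
                    "spinal_segments": list(b.spinal_segments),
                }
                for b in self.blocks.values()
            ],
            **kwargs,
        )

    @classmethod
    def from_json(cls, text: str) -> "AnatomyGraph":
        graph = cls()
        for item in json.loads(text):
            block = FunctionalBlock(
                id=item["id"],
                parent=item["parent"],
                blood_flow_fraction=item["blood_flow_fraction"],
                skin_fraction=item["skin_fraction"],
                spinal_segments=tuple(item.get("spinal_segments", ())),
            )
            graph.blocks[block.id] = block
        graph.validate()
        return graph

    @classmethod
    def from_file(cls, path: str | Path) -> "AnatomyGraph":
        return cls.from_json(Path(path).read_text())


def _seg(lo: str, hi: str) -> tuple[str, ...]:
    return tuple(VERTEBRAL_LEVELS[_LEVEL_INDEX[lo] : _LEVEL_INDEX[hi] + 1])


# (id, parent, flow fraction, skin fraction, spinal segments)
# Flow fractions follow the textbook resting distribution of cardiac output
# (brain ~14%, splanchnic+renal ~40%, ...); skin follows the rule of nines
# with the trunk's 36% split thorax/abdomen/pelvis and head+neck's 9%+1%
# allocated 9% head, 1% neck.
_DEFAULT_BLOCKS = [
    ("thorax", None, 0.09, 0.18, _seg("T1", "T12")),
    ("head", "neck", 0.14, 0.09, ("C0",)),
    ("neck", "thorax", 0.03, 0.01, _seg("C1", "C7")),
    ("abdomen", "thorax", 0.40, 0.09, _seg("L1", "L3")),
    ("pelvis", "abdomen", 0.08, 0.09, _seg("L4", "L5")),
    ("arm_l", "thorax", 0.02, 0.045, ()),
    ("arm_r", "thorax", 0.02, 0.045, ()),
    ("forearm_l", "arm_l", 0.02, 0.045, ()),
    ("forearm_r", "arm_r", 0.02, 0.045, ()),
    ("thigh_l", "pelvis", 0.05, 0.09, ()),
    ("thigh_r", "pelvis", 0.05, 0.09, ()),
    ("leg_l", "thigh_l", 0.04, 0.09, ()),
    ("leg_r", "thigh_r", 0.04, 0.09, ()),
]


def build_default_anatomy() -> AnatomyGraph:
    """The default body tree rooted at the thorax."""
    graph = AnatomyGraph(
        blocks={
            bid: FunctionalBlock(bid, parent, flow, skin, segs)
            for bid, parent, flow, skin, segs in _DEFAULT_BLOCKS
        }
    )
    graph.validate()
    return graph


@dataclass(frozen=True)
class EffectorStatus:
    """Motor/respiratory effectors preserved below a cord lesion.

    Capacities are in [0, 1]; the boolean views threshold at 0.5 so that a
    complete lesion gives crisp flags while partial lesions scale linearly.
    """

    diaphragm: float = 1.0
    intercostals: float = 1.0
    arms_motor: float = 1.0
    legs_motor: float = 1.0

    @property
    def diaphragm_intact(self) -> bool:
        return self.diaphragm > 0.5

    @property
    def intercostals_intact(self) -> bool:
        return self.intercostals > 0.5

    @property
    def arms_motor_intact(self) -> bool:
        return self.arms_motor > 0.5

    @property
    def legs_motor_intact(self) -> bool:
        return self.legs_motor > 0.5


# Highest (most caudal) level whose lesion still removes the effector:
# phrenic roots are C3-C5 so lesions at/above C3 abolish diaphragmatic
# breathing; intercostals run T1-T12; leg innervation arises caudal to L2.
_EFFECTOR_CUTOFF = {
    "diaphragm": _LEVEL_INDEX["C3"],
    "intercostals": _LEVEL_INDEX["T11"],
    "legs_motor": _LEVEL_INDEX["L2"],
}

#: brachial-plexus roots; arm capacity scales with the share rostral to
#: the lesion, so a low cervical lesion spares part of the arms
_ARM_ROOTS = ("C5", "C6", "C7", "T1")


def effectors_below_lesion(lesion: Optional[SpinalLesion]) -> EffectorStatus:
    """Effector capacities remaining distal to a cord lesion.

    ``None`` means no lesion (everything intact).  A complete lesion at or
    above C3 stops the diaphragm (apnea); a complete C5-C7 lesion spares the
    diaphragm but takes the intercostals, the legs, and part of the arms.
    """
    if lesion is None:
        return EffectorStatus()
    idx = lesion.level_index
    caps = {}
    for name, cutoff in _EFFECTOR_CUTOFF.items():
        caps[name] = 1.0 - lesion.completeness if idx <= cutoff else 1.0
    spared = sum(1 for r in _ARM_ROOTS if _LEVEL_INDEX[r] < idx) / len(_ARM_ROOTS)
    caps["arms_motor"] = 1.0 - lesion.completeness * (1.0 - spared)
    return EffectorStatus(**caps)
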