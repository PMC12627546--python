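"""Skeleton definitions: the full tracked joint set and the model subset.

The tracked upper body is described by 17 joint rotations.  The networks only
see 10 of them: both arms (hand, forearm, upper arm, shoulder), head and
sternum.  Every joint has a mirror partner (midline joints mirror to
themselves), which supports the left/right mirroring used to train a single
left-arm network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "JointSet",
    "FULL_SKELETON",
    "MODEL_JOINTS",
    "ARM_CHAIN",
    "FOCAL_ARM_JOINTS",
]

_MIDLINE = (
    "pelvis",
    "spine_lower",
    "spine_mid",
    "spine_upper",
    "sternum",
    "neck",
    "head",
)
_BILATERAL = ("clavicle", "shoulder", "upper_arm", "forearm", "hand")


def _mirror_name(name: str) -> str:
    if name.startswith("left_"):
        return "right_" + name[5:]
    if name.startswith("right_"):
        return "left_" + name[6:]
    return name


@dataclass(frozen=True)
class JointSet:
    """Ordered collection of named joints with a left/right mirror map."""

    names: tuple[str, ...]
    mirror: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate joint names")
        mirror = {n: _mirror_name(n) for n in self.names}
        missing = [m for m in mirror.values() if m not in self.names]
        if missing:
            raise ValueError(f"mirror partners missing from joint set: {missing}")
        object.__setattr__(self, "mirror", mirror)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)

    def mirror_permutation(self) -> list[int]:
        """Index permutation mapping each joint to its mirror partner."""
        return [self.names.index(self.mirror[n]) for n in self.names]

    def subset(self, names: tuple[str, ...]) -> "JointSet":
        unknown = [n for n in names if n not in self.names]
        if unknown:
            raise ValueError(f"joints not in set: {unknown}")
        return JointSet(tuple(names))


FULL_SKELETON = JointSet(
    _MIDLINE
    + tuple(f"left_{b}" for b in _BILATERAL)
    + tuple(f"right_{b}" for b in _BILATERAL)
)

#: The 10 joints the networks consume: both arms plus head and sternum.
MODEL_JOINTS = FULL_SKELETON.subset(
    (
        "left_hand",
        "left_forearm",
        "left_upper_arm",
        "left_shoulder",
        "right_hand",
        "right_forearm",
        "right_upper_arm",
        "right_shoulder",
        "head",
        "sternum",
    )
)

#: Kinematic chain (proximal to distal) used for hand forward kinematics.
ARM_CHAIN = ("shoulder", "upper_arm", "forearm", "hand")

#: Focal arm joints of the sensitivity analysis, distal to proximal:
#: hand, lower arm, upper arm, shoulder of the (left) active arm.
FOCAL_ARM_JOINTS = ("left_hand", "left_forearm", "left_upper_arm", "left_shoulder")
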