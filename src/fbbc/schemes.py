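"""Keypoint schemes: the mapping between numeric keypoint ids and anatomy.

A scheme names the landmarks a pose-estimation backend reports so that
feature recipes can refer to keypoints by stable integer ids.  The built-in
:data:`HALPE26_UPPER_BODY` subset covers the upper-body landmarks of the
Halpe-26 convention used by RTMPose-style detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = ["KeypointScheme", "HALPE26_UPPER_BODY", "get_scheme"]


@dataclass(frozen=True)
class KeypointScheme:
    """An ordered set of (id, label) keypoints with an optional skeleton.

    Parameters
    ----------
    name:
        Scheme identifier, e.g. ``"halpe26_upper_body"``.
    keypoints:
        Ordered ``(id, label)`` pairs.  Ids must be unique non-negative
        integers; labels must be unique.
    skeleton:
        Optional id pairs describing limb connectivity (cosmetic only).
    """

    name: str
    keypoints: tuple[tuple[int, str], ...]
    skeleton: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        ids = [kid for kid, _ in self.keypoints]
        if any(kid < 0 for kid in ids):
            raise ValidationError(f"scheme '{self.name}': negative keypoint id")
        if len(set(ids)) != len(ids):
            raise ValidationError(f"scheme '{self.name}': duplicate keypoint ids")
        labels = [lab for _, lab in self.keypoints]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"scheme '{self.name}': duplicate labels")
        for a, b in self.skeleton:
            if a not in set(ids) or b not in set(ids):
                raise ValidationError(
                    f"scheme '{self.name}': skeleton edge ({a}, {b}) references unknown id"
                )

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(kid for kid, _ in self.keypoints)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, lab in self.keypoints)

    def __contains__(self, keypoint_id: int) -> bool:
        return keypoint_id in self.ids

    def label_of(self, keypoint_id: int) -> str:
        for kid, lab in self.keypoints:
            if kid == keypoint_id:
                return lab
        raise KeyError(keypoint_id)

    def id_of(self, label: str) -> int:
        for kid, lab in self.keypoints:
            if lab == label:
                return kid
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "keypoints": [list(kp) for kp in self.keypoints],
            "skeleton": [list(e) for e in self.skeleton],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KeypointScheme":
        return cls(
            name=d["name"],
            keypoints=tuple((int(k), str(v)) for k, v in d["keypoints"]),
            skeleton=tuple((int(a), int(b)) for a, b in d.get("skeleton", [])),
        )


#: Upper-body subset of the Halpe-26 whole-body landmark convention.
#: Ids follow Halpe numbering: 5/6 shoulders, 8 right elbow, 9/10 hands
#: (wrist landmarks, conventionally read as hand position), 18 neck.
HALPE26_UPPER_BODY = KeypointScheme(
    name="halpe26_upper_body",
    keypoints=(
        (5, "left_shoulder"),
        (6, "right_shoulder"),
        (8, "right_elbow"),
        (9, "left_hand"),
        (10, "right_hand"),
        (18, "neck"),
    ),
    skeleton=((18, 5), (18, 6), (6, 8), (8, 10)),
)

_REGISTRY = {HALPE26_UPPER_BODY.name: HALPE26_UPPER_BODY}


def get_scheme(name: str) -> KeypointScheme:
    """Look up a built-in scheme by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme '{name}'; built-in schemes: {sorted(_REGISTRY)}"
        ) from None
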