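"""Stimulus scene geometry for the five-object face pop-out display.

A scene is one 20-s display: five rectangular areas of interest (one face
and four non-face competitors — a face-matched noise patch, a mobile phone,
a bird and a car) laid out around the screen centre, with the face location
counterbalanced across the six stimuli.  The exact published layout is not
part of the data contract, so the default here is a stand-in: five equal
rectangles on a ring around the centre, leaving the centre free for the
gaze-contingent trial start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

AOI_LABELS = ("face", "noise", "phone", "bird", "car")


@dataclass(frozen=True)
class GazeScene:
    """One stimulus display: screen size and five labelled AOI rectangles.

    Rectangles are (x0, y0, x1, y1) in pixels with half-open containment
    [x0, x1) x [y0, y1); they must be pairwise non-overlapping and lie
    within the screen.
    """

    stimulus_id: int
    screen: tuple[int, int] = (1920, 1080)
    aois: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.aois) != set(AOI_LABELS):
            raise ValueError(f"scene must define exactly the AOIs {AOI_LABELS}")
        w, h = self.screen
        rects = list(self.aois.items())
        for label, (x0, y0, x1, y1) in rects:
            if not (x1 > x0 and y1 > y0):
                raise ValueError(f"degenerate AOI rectangle {label!r}")
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                raise ValueError(f"AOI {label!r} exceeds the screen")
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                la, a = rects[i]
                lb, b = rects[j]
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise ValueError(f"AOIs {la!r} and {lb!r} overlap")

    @property
    def face_position_index(self) -> int:
        order = sorted(self.aois, key=lambda l: self.aois[l][:2])
        return order.index("face")

    def centre(self) -> tuple[float, float]:
        return self.screen[0] / 2.0, self.screen[1] / 2.0

    def aoi_centre(self, label: str) -> tuple[float, float]:
        x0, y0, x1, y1 = self.aois[label]
        return (x0 + x1) / 2.0, (y0 + y1) / 2.0


def default_scenes(
    n_stimuli: int = 6,
    screen: tuple[int, int] = (1920, 1080),
    aoi_size: tuple[int, int] = (340, 340),
    ring_radius: float = 380.0,
) -> list[GazeScene]:
    """Six stand-in displays with the face location rotating over the five
    ring positions (counterbalanced; stimulus 6 reuses position 1)."""
    scenes = []
    w, h = screen
    aw, ah = aoi_size
    for stim in range(1, n_stimuli + 1):
        centres = []
        for p in range(5):
            ang = -math.pi / 2 + 2 * math.pi * p / 5
            centres.append((w / 2 + ring_radius * math.cos(ang),
                            h / 2 + ring_radius * math.sin(ang) * 0.85))
        face_pos = (stim - 1) % 5
        labels = list(AOI_LABELS[1:])
        aois = {}
        for p, (cx, cy) in enumerate(centres):
            label = "face" if p == face_pos else labels.pop(0)
            aois[label] = (cx - aw / 2, cy - ah / 2, cx + aw / 2, cy + ah / 2)
        scenes.append(GazeScene(stimulus_id=stim, screen=screen, aois=aois))
    return scenes


def scenes_to_yaml(scenes: list[GazeScene], path) -> None:
    payload = [
        {
            "stimulus_id": s.stimulus_id,
            "screen": list(s.screen),
            "aois": [
                {"label": lab, "x0": r[0], "y0": r[1], "x1": r[2], "y1": r[3]}
                for lab, r in s.aois.items()
            ],
        }
        for s in scenes
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def scenes_from_yaml(path) -> list[GazeScene]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        GazeScene(
            stimulus_id=int(item["stimulus_id"]),
            screen=tuple(item["screen"]),
            aois={a["label"]: (a["x0"], a["y0"], a["x1"], a["y1"])
                  for a in item["aois"]},
        )
        for item in payload
    ]
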