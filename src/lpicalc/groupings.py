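"""Bundled grouping presets and JSON loading for grouping schemes.

Two presets are bundled:

``merged-5realm`` (default)
    The grouping used by the weighted index: Australasia and Indo-Malayan
    are merged into the Indo-Pacific realm and reptiles and amphibians
    into herptiles, giving 5 realms / 3 taxa for the terrestrial
    ecosystem, 5 / 4 for freshwater and 6 / 4 for marine.

``full-6realm``
    The unmerged alternative: 6 terrestrial/freshwater realms with
    reptiles and amphibians kept apart.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

from .model import GroupingScheme, LpiError

_TERRESTRIAL_REALMS_MERGED = (
    "Afrotropical",
    "Palearctic",
    "Nearctic",
    "Neotropical",
    "Indo-Pacific",
)
_TERRESTRIAL_REALMS_FULL = (
    "Afrotropical",
    "Palearctic",
    "Nearctic",
    "Neotropical",
    "Australasia",
    "Indo-Malayan",
)
_MARINE_REALMS = (
    "Arctic",
    "Atlantic North Temperate",
    "Atlantic Tropical and Subtropical",
    "Pacific North Temperate",
    "Tropical and Subtropical Indo-Pacific",
    "South Temperate and Antarctic",
)

MERGED_5REALM = GroupingScheme(
    name="merged-5realm",
    realms={
        "terrestrial": _TERRESTRIAL_REALMS_MERGED,
        "freshwater": _TERRESTRIAL_REALMS_MERGED,
        "marine": _MARINE_REALMS,
    },
    taxa={
        "terrestrial": ("birds", "mammals", "herptiles"),
        "freshwater": ("birds", "mammals", "herptiles", "fish"),
        "marine": ("birds", "mammals", "herptiles", "fish"),
    },
    merge={
        "Australasia": "Indo-Pacific",
        "Indo-Malayan": "Indo-Pacific",
        "reptiles": "herptiles",
        "amphibians": "herptiles",
    },
)

FULL_6REALM = GroupingScheme(
    name="full-6realm",
    realms={
        "terrestrial": _TERRESTRIAL_REALMS_FULL,
        "freshwater": _TERRESTRIAL_REALMS_FULL,
        "marine": _MARINE_REALMS,
    },
    taxa={
        "terrestrial": ("birds", "mammals", "reptiles", "amphibians"),
        "freshwater": ("birds", "mammals", "reptiles", "amphibians", "fish"),
        "marine": ("birds", "mammals", "reptiles", "amphibians", "fish"),
    },
    merge={},
)

PRESETS = {g.name: g for g in (MERGED_5REALM, FULL_6REALM)}


def get_grouping(name_or_path: Union[str, Path, GroupingScheme]) -> GroupingScheme:
    """Resolve a preset name, a JSON file path, or pass a scheme through."""
    if isinstance(name_or_path, GroupingScheme):
        return name_or_path
    name = str(name_or_path)
    if name in PRESETS:
        return PRESETS[name]
    path = Path(name)
    if path.exists():
        return load_grouping_json(path)
    raise LpiError(
        f"unknown grouping {name!r}: not a preset "
        f"({', '.join(PRESETS)}) and not an existing file"
    )


def load_grouping_json(path: Union[str, Path]) -> GroupingScheme:
    """Load a grouping scheme from a JSON file.

    Expected keys: ``name``, ``realms`` (ecosystem -> list of realm labels),
    ``taxa`` (ecosystem -> list of taxon labels), optional ``merge``
    (raw label -> merged label).
    """
    with open(path) as fh:
        raw = json.load(fh)
    try:
        scheme = GroupingScheme(
            name=raw.get("name", Path(path).stem),
            realms={k: tuple(v) for k, v in raw["realms"].items()},
            taxa={k: tuple(v) for k, v in raw["taxa"].items()},
            merge=raw.get("merge", {}),
        )
    except KeyError as exc:
        raise LpiError(f"grouping file {path}: missing key {exc}") from exc
    for raw_label, merged in scheme.merge.items():
        reachable = any(
            merged in labels
            for labels in list(scheme.realms.values()) + list(scheme.taxa.values())
        )
        if not reachable:
            raise LpiError(
                f"grouping file {path}: merge target {merged!r} (from "
                f"{raw_label!r}) is not a recognised label"
            )
    return scheme


def save_grouping_json(scheme: GroupingScheme, path: Union[str, Path]) -> None:
    payload = {
        "name": scheme.name,
        "realms": {k: list(v) for k, v in scheme.realms.items()},
        "taxa": {k: list(v) for k, v in scheme.taxa.items()},
        "merge": dict(scheme.merge),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
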