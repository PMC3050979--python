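"""The B-cell activation miRNA signature and its container type.

When resting human B cells are acutely activated through Toll-like
receptor 9 (CpG oligonucleotides), a small set of miRNAs changes
expression: five go up and seven go down. This module packages that
signature as the default gene-set pair used by the enrichment analysis,
together with a minimal :class:`MiRNASignature` container and GMT
read/write helpers (one line per direction, ``<NAME>_UP`` and
``<NAME>_DOWN``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "ACTIVATION_UP",
    "ACTIVATION_DOWN",
    "MiRNASignature",
    "activation_signature",
    "read_gmt",
    "write_gmt",
]

#: miRNAs upregulated after acute CpG activation of resting B cells.
ACTIVATION_UP = (
    "miR-34a",
    "miR-198",
    "miR-155",
    "miR-337-3p",
    "miR-342-3p",
)

#: miRNAs downregulated after acute CpG activation of resting B cells.
ACTIVATION_DOWN = (
    "let-7c",
    "miR-15b",
    "miR-20b",
    "miR-103",
    "miR-181a",
    "miR-181b",
    "miR-331-3p",
)


@dataclass(frozen=True)
class MiRNASignature:
    """A named pair of disjoint feature sets (up- and down-regulated).

    Parameters
    ----------
    name : str
        Signature name; GMT set names are ``<name>_UP`` / ``<name>_DOWN``.
    up, down : frozenset of str
        Disjoint miRNA identifier sets.
    """

    name: str
    up: frozenset = field(default_factory=frozenset)
    down: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        up = frozenset(self.up)
        down = frozenset(self.down)
        if up & down:
            raise ValueError(
                f"up and down sets overlap: {sorted(up & down)}"
            )
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)

    @property
    def is_empty(self) -> bool:
        return not (self.up or self.down)


def activation_signature() -> MiRNASignature:
    """Return the packaged B-cell activation signature (5 up, 7 down)."""
    return MiRNASignature(
        name="B_CELL_ACTIVATION",
        up=frozenset(ACTIVATION_UP),
        down=frozenset(ACTIVATION_DOWN),
    )


def write_gmt(signature: MiRNASignature, path) -> None:
    """Write a signature as a two-line GMT file (UP set then DOWN set)."""
    lines = []
    for suffix, members in (("UP", signature.up), ("DOWN", signature.down)):
        cols = [f"{signature.name}_{suffix}", "na", *sorted(members)]
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path) -> dict:
    """Read a GMT file into ``{set_name: frozenset(members)}``."""
    sets: dict[str, frozenset] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs >=3 columns): {line!r}")
        sets[fields[0]] = frozenset(f for f in fields[2:] if f)
    return sets


def signature_from_gmt(path, name: str | None = None) -> MiRNASignature:
    """Reassemble a :class:`MiRNASignature` from a GMT written by
    :func:`write_gmt` (or any GMT with ``*_UP`` / ``*_DOWN`` set names)."""
    sets = read_gmt(path)
    ups = {k: v for k, v in sets.items() if k.endswith("_UP")}
    downs = {k: v for k, v in sets.items() if k.endswith("_DOWN")}
    if not ups and not downs:
        raise ValueError(f"no *_UP or *_DOWN sets found in {path}")
    if name is None:
        key = next(iter(ups or downs))
        name = key.rsplit("_", 1)[0]
    up = ups.get(f"{name}_UP", frozenset())
    down = downs.get(f"{name}_DOWN", frozenset())
    if not up and not down:
        warnings.warn(f"signature {name!r} has no members in {path}")
    return MiRNASignature(name=name, up=up, down=down)


def strip_species_prefix(feature_id: str) -> str:
    """Drop a leading species prefix such as ``hsa-`` from a miRNA id."""
    parts = feature_id.split("-", 1)
    if (
        len(parts) == 2
        and len(parts[0]) == 3
        and parts[0].islower()
        and parts[1].lower().startswith(("mir", "let"))
    ):
        return parts[1]
    return feature_id


def ids_match(a: str, b: str) -> bool:
    """Case-insensitive miRNA id equality, tolerant of species prefixes,
    so that e.g. ``hsa-miR-146b-5p`` matches ``miR-146b-5p``."""
    return strip_species_prefix(a).lower() == strip_species_prefix(b).lower()


def matching_ids(candidates: Iterable[str], targets: Iterable[str]) -> list:
    """Return the elements of *candidates* that match any id in *targets*."""
    targets = list(targets)
    return [c for c in candidates if any(ids_match(c, t) for t in targets)]
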