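"""Brain region sets used for current-density (CD) representations.

The default set covers the deep and cortical structures implicated in
slow-oscillation dynamics: neocortex, hippocampus, nucleus accumbens,
amygdala, caudate, putamen, pallidum and thalamus (each split into left
and right hemisphere components) plus the unpaired brainstem — 17 regions
in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_PAIRED = (
    "cortex",
    "hippocampus",
    "nucleus-accumbens",
    "amygdala",
    "caudate",
    "putamen",
    "pallidum",
    "thalamus",
)


def _default_names() -> tuple[str, ...]:
    names: list[str] = []
    for base in _PAIRED:
        names.append(f"{base}-L")
        names.append(f"{base}-R")
    names.append("brainstem")
    return tuple(names)


@dataclass(frozen=True)
class RegionSet:
    """Ordered, unique region labels defining the columns of a CD matrix."""

    names: tuple[str, ...] = field(default_factory=_default_names)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("region names must be unique")
        if len(self.names) == 0:
            raise ValueError("region set must be non-empty")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_REGIONS = RegionSet()
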