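"""Stimulation electrode montages and full paradigms.

A montage is four scalp pad electrodes, one per scalp quartile
(left-anterior, right-anterior, left-posterior, right-posterior), two
driven anodal (+1) and two cathodal (−1) so the voltages sum to zero.
A paradigm couples a montage with a stimulation waveform and the time
bin width Δt of the current-density representation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .waveforms import VALID_DT_MS, Waveform

QUARTILES = (
    "left-anterior",
    "right-anterior",
    "left-posterior",
    "right-posterior",
)

#: anterior pair anodal, posterior pair cathodal
DEFAULT_POLARITY = (1, 1, -1, -1)

#: all sign assignments of (+1, +1, −1, −1) over four electrodes
ALL_POLARITIES = tuple(sorted(set(itertools.permutations((1, 1, -1, -1)))))


@dataclass(frozen=True)
class Montage:
    """Four stimulation electrodes, one per quartile, with ±1 polarities."""

    electrodes: tuple[str, str, str, str]
    polarities: tuple[int, int, int, int] = DEFAULT_POLARITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        object.__setattr__(self, "polarities", tuple(int(p) for p in self.polarities))
        if len(self.electrodes) != 4:
            raise ValueError("a montage needs exactly 4 electrodes")
        if len(set(self.electrodes)) != 4:
            raise ValueError("montage electrodes must be distinct")
        if sorted(self.polarities) != [-1, -1, 1, 1]:
            raise ValueError("polarities must be two +1 and two -1 (zero sum)")

    @property
    def key(self) -> str:
        """Stable string key, e.g. ``F3+|F4+|P3-|P4-``."""
        return "|".join(
            f"{e}{'+' if p > 0 else '-'}"
            for e, p in zip(self.electrodes, self.polarities)
        )

    def flipped(self) -> "Montage":
        """Montage with anodes and cathodes swapped."""
        return Montage(self.electrodes, tuple(-p for p in self.polarities))


@dataclass(frozen=True)
class Paradigm:
    """A candidate stimulation protocol: montage + waveform + Δt."""

    montage: Montage
    waveform: Waveform
    dt: int

    def __post_init__(self) -> None:
        if self.dt not in VALID_DT_MS:
            raise ValueError(f"dt must be one of {VALID_DT_MS}, got {self.dt}")

    @property
    def key(self) -> str:
        return f"{self.montage.key}/{self.waveform.kind}/dt{self.dt}"


def enumerate_montages(
    candidates: dict[str, list[str]] | list[list[str]],
    polarity: str = "fixed",
) -> list[Montage]:
    """All one-electrode-per-quartile montages from per-quartile candidates.

    Parameters
    ----------
    candidates : mapping quartile name → electrode labels, or a 4-list in
        :data:`QUARTILES` order.
    polarity : ``"fixed"`` keeps the default anterior-anodal assignment;
        ``"all"`` expands every zero-sum sign pattern (6 per electrode set).
    """
    if isinstance(candidates, dict):
        missing = [q for q in QUARTILES if q not in candidates]
        if missing:
            raise ValueError(f"missing quartile candidate lists: {missing}")
        lists = [list(candidates[q]) for q in QUARTILES]
    else:
        lists = [list(c) for c in candidates]
        if len(lists) != 4:
            raise ValueError("need one candidate list per scalp quartile (4)")
    for q, lst in zip(QUARTILES, lists):
        if not lst:
            raise ValueError(f"empty candidate list for quartile {q}")
    seen: dict[str, str] = {}
    for q, lst in zip(QUARTILES, lists):
        for e in lst:
            if e in seen and seen[e] != q:
                raise ValueError(f"electrode {e} listed in two quartiles")
            seen[e] = q
    pol_sets = (DEFAULT_POLARITY,) if polarity == "fixed" else ALL_POLARITIES
    out = []
    for combo in itertools.product(*lists):
        if len(set(combo)) != 4:
            continue
        for pols in pol_sets:
            out.append(Montage(tuple(combo), pols))
    return out
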