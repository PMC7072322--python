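"""Microsatellite-instability classification from Bethesda marker panels.

A sample is typed from per-marker instability flags over the five standard
Bethesda loci (BAT25, BAT26, D2S123, D5S346, D17S250): MSI-high when more
than 30% of markers are unstable, MSI-low when some but at most 30% are,
and microsatellite-stable (MSS) when none are. With five markers the 30%
boundary is unreachable (2/5 = 40% > 30% > 1/5 = 20%); the generic-panel
variant fixes the convention that exactly 30% is MSI-L, since MSI-high
requires strictly more than 30%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

BETHESDA_MARKERS = ("BAT25", "BAT26", "D2S123", "D5S346", "D17S250")
MSI_H_THRESHOLD = 0.30

MSI_CLASSES = ("MSS", "MSI-L", "MSI-H")


class MSIError(ValueError):
    """Invalid marker panel input."""


def classify_msi_fraction(unstable: int, n_markers: int) -> str:
    """Bethesda class from an unstable-marker count over any panel size."""
    if n_markers < 1:
        raise MSIError("panel must contain at least one marker")
    if not 0 <= unstable <= n_markers:
        raise MSIError(f"unstable count {unstable} outside [0, {n_markers}]")
    fraction = unstable / n_markers
    if fraction > MSI_H_THRESHOLD:
        return "MSI-H"
    if fraction > 0:
        return "MSI-L"
    return "MSS"


def classify_msi(flags: Sequence[bool]) -> str:
    """Bethesda class from exactly five per-marker instability flags."""
    if len(flags) != len(BETHESDA_MARKERS):
        raise MSIError(
            f"expected {len(BETHESDA_MARKERS)} marker flags "
            f"({', '.join(BETHESDA_MARKERS)}), got {len(flags)}"
        )
    return classify_msi_fraction(sum(bool(f) for f in flags), len(flags))


@dataclass(frozen=True)
class MSIPanelResult:
    """Per-sample 5-marker instability flags and Bethesda class."""

    sample_id: str
    flags: tuple[bool, ...]
    unstable_fraction: float
    msi_class: str

    @property
    def markers(self) -> tuple[str, ...]:
        return BETHESDA_MARKERS


def classify_panel(sample_id: str, flags: Sequence[bool]) -> MSIPanelResult:
    flags = tuple(bool(f) for f in flags)
    return MSIPanelResult(
        sample_id=sample_id,
        flags=flags,
        unstable_fraction=sum(flags) / len(BETHESDA_MARKERS),
        msi_class=classify_msi(flags),
    )
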