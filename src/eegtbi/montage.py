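"""Electrode montage bookkeeping for the 64-channel WaveGuard cap.

The cap places 64 electrodes on 10-10 system sites.  CPz is wired as an
electrooculography channel during acquisition and is dropped before any
analysis, leaving 63 scalp channels.  Channel order everywhere in this
package is the cap's default arrangement, never re-sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MontageError

#: Default channel arrangement of the 64-channel WaveGuard cap (10-10 names).
WAVEGUARD_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "M1", "T7", "C3", "Cz",
    "C4", "T8", "M2", "CP5", "CP1", "CP2", "CP6", "P7",
    "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FC3", "FCz", "FC4", "C5", "C1", "C2", "C6", "CP3",
    "CPz", "CP4", "P5", "P1", "P2", "P6", "PO5", "PO3",
    "PO4", "PO6", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
)

#: Channels that downstream feature pipelines rely on; any reduced montage
#: must retain them (AF7/AF8/Fpz for frontal derivations, CPz as the EOG
#: channel that gets excluded).
REQUIRED_CHANNELS: tuple[str, ...] = ("Fpz", "AF7", "AF8", "CPz")

#: The EOG channel excluded from analysis.
EOG_CHANNEL = "CPz"


@dataclass(frozen=True)
class Montage:
    """A channel layout plus the set of channels excluded before analysis.

    Parameters
    ----------
    all_labels : ordered channel names as stored in the recording.
    excluded_labels : channels removed before analysis (default: CPz).
    reference_description : free-text provenance of the reference scheme.
    """

    all_labels: tuple[str, ...] = WAVEGUARD_64
    excluded_labels: frozenset[str] = frozenset({EOG_CHANNEL})
    reference_description: str = "linked earlobes"

    def __post_init__(self):
        object.__setattr__(self, "all_labels", tuple(self.all_labels))
        object.__setattr__(self, "excluded_labels", frozenset(self.excluded_labels))
        missing = self.excluded_labels - set(self.all_labels)
        if missing:
            raise MontageError(f"excluded labels not in montage: {sorted(missing)}")

    @property
    def retained_labels(self) -> tuple[str, ...]:
        return tuple(c for c in self.all_labels if c not in self.excluded_labels)

    @property
    def n_retained(self) -> int:
        return len(self.retained_labels)


def select_channels(n_channels: int) -> tuple[str, ...]:
    """Deterministic subset of the WaveGuard layout with ``n_channels`` sites.

    Reduced montages (used for desk-scale synthetic cohorts) always keep
    :data:`REQUIRED_CHANNELS` and preserve the cap's default order.
    """
    if not 4 <= n_channels <= len(WAVEGUARD_64):
        raise MontageError(
            f"n_channels must be in [4, {len(WAVEGUARD_64)}], got {n_channels}"
        )
    if n_channels == len(WAVEGUARD_64):
        return WAVEGUARD_64
    keep = set(REQUIRED_CHANNELS)
    for name in WAVEGUARD_64:
        if len(keep) == n_channels:
            break
        keep.add(name)
    return tuple(c for c in WAVEGUARD_64 if c in keep)
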