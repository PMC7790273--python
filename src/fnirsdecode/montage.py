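"""Optode montage: source-detector channels and their scalp region labels.

The default layout mirrors a fronto-occipital band: nine sources and nine
detectors across the forehead and temples (sensor 1 near T7, sensor 9 near
T8, channel 5-5 centred on Fpz) plus three sources and three detectors over
the occiput (channel 11-11 centred on Oz).  All adjacent source-detector
pairs are 30 mm apart and measured at 760 and 850 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

REGIONS = ("frontopolar", "anterofrontal", "frontal", "temporal", "occipital")

#: channels that carry the default planted affective effects (all HbR)
EFFECT_CHANNELS = ("6-7", "5-4", "4-4")


def channel_name(source: int, detector: int) -> str:
    return f"{source}-{detector}"


@dataclass(frozen=True)
class Montage:
    """A list of source-detector channels with per-channel region labels.

    Parameters
    ----------
    channels
        ``(source_id, detector_id)`` pairs, ids in 1..12.  Order here fixes
        the channel order everywhere downstream (recordings, features,
        weight maps).
    regions
        One region label per channel, drawn from :data:`REGIONS`.
    distance_mm
        Source-detector separation, identical for all channels.
    wavelengths_nm
        The two measurement wavelengths, low first.
    """

    channels: tuple[tuple[int, int], ...]
    regions: tuple[str, ...]
    distance_mm: float = 30.0
    wavelengths_nm: tuple[int, int] = (760, 850)

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.regions):
            raise ValidationError(
                f"{len(self.channels)} channels but {len(self.regions)} region labels"
            )
        for s, d in self.channels:
            if not (1 <= s <= 12 and 1 <= d <= 12):
                raise ValidationError(f"optode ids out of range in channel {s}-{d}")
        for r in self.regions:
            if r not in REGIONS:
                raise ValidationError(f"unknown region label {r!r}")
        if self.distance_mm <= 0:
            raise ValidationError("distance_mm must be > 0")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(channel_name(s, d) for s, d in self.channels)

    def region_of(self, name: str) -> str:
        return self.regions[self.names.index(name)]


def _band_region(source: int, detector: int) -> str:
    # Position along the forehead band is indexed by the mean optode id;
    # 5 sits over Fpz, 1 and 9 over the temples.
    m = 0.5 * (source + detector)
    if 4.0 <= m <= 6.0:
        return "frontopolar"
    if 3.0 <= m <= 7.0:
        return "anterofrontal"
    if 2.0 <= m <= 8.0:
        return "frontal"
    return "temporal"


def default_montage() -> Montage:
    """The 32-channel fronto-occipital montage used throughout.

    25 channels chain sources/detectors 1..9 along the forehead band
    (pairs ``(i, i)``, ``(i, i+1)``, ``(i+1, i)``) and 7 channels connect
    sources/detectors 10..12 over the occiput.
    """
    channels: list[tuple[int, int]] = []
    for i in range(1, 10):
        channels.append((i, i))
        if i < 9:
            channels.append((i, i + 1))
            channels.append((i + 1, i))
    # keep deterministic reading order: sort band channels by (source, detector)
    channels.sort()
    occipital = [(10, 10), (10, 11), (11, 10), (11, 11), (11, 12), (12, 11), (12, 12)]
    regions = [_band_region(s, d) for s, d in channels] + ["occipital"] * len(occipital)
    return Montage(tuple(channels + occipital), tuple(regions))
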