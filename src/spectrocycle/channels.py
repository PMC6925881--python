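"""Excitation/emission channel descriptors.

A *spectral channel* is one excitation-wavelength / emission-band combination
in which an image is acquired.  The instrument this pipeline models combines
18 narrow-band excitation lines (band half-width 5 nm) with four emission
filter cubes (bandpass half-width 20 nm, or long-pass cut-on) to give 34
channels; the ordered :class:`ChannelSet` defines the column index of every
image stack and endmember matrix in the pipeline.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import yaml

__all__ = [
    "Channel",
    "ChannelSet",
    "ChannelParseError",
    "parse_channel_list",
    "render_channel_list",
    "builtin_channels",
    "distinct_excitations",
    "EXCITATION_HALF_WIDTH_NM",
    "EMISSION_HALF_WIDTH_NM",
]

#: Excitation band half-width (nm), a fixed property of the channel set.
EXCITATION_HALF_WIDTH_NM = 5.0
#: Bandpass emission filter half-width (nm).
EMISSION_HALF_WIDTH_NM = 20.0

_WAVELENGTH_RANGE = (200.0, 900.0)


class ChannelParseError(ValueError):
    """Raised when a channel-list string cannot be parsed."""


@dataclass(frozen=True, order=True)
class Channel:
    """One excitation/emission acquisition band.

    ``emission_nm`` is the band centre for bandpass filters and the cut-on
    wavelength for long-pass filters.
    """

    excitation_nm: float
    emission_nm: float
    kind: str = "bandpass"  # "bandpass" | "longpass"

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "longpass"):
            raise ValueError(f"unknown emission kind {self.kind!r}")
        for name, value in (("excitation_nm", self.excitation_nm),
                            ("emission_nm", self.emission_nm)):
            if not (_WAVELENGTH_RANGE[0] <= value <= _WAVELENGTH_RANGE[1]):
                raise ValueError(
                    f"{name}={value} outside plausible range {_WAVELENGTH_RANGE}")
        if self.kind == "bandpass" and not self.excitation_nm < self.emission_nm:
            raise ValueError(
                f"bandpass channel requires Stokes shift: "
                f"{self.excitation_nm}/{self.emission_nm}")
        if self.excitation_nm == self.emission_nm:
            raise ValueError("excitation and emission wavelengths coincide")

    @property
    def longpass(self) -> bool:
        return self.kind == "longpass"

    def render(self) -> str:
        token = f"{self.excitation_nm:g}/{self.emission_nm:g}"
        if self.longpass:
            token += " (long-pass)"
        return token


@dataclass(frozen=True)
class ChannelSet:
    """Ordered, duplicate-free list of channels; the spectral axis."""

    channels: tuple[Channel, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        seen = set()
        for ch in self.channels:
            key = (ch.excitation_nm, ch.emission_nm, ch.kind)
            if key in seen:
                raise ValueError(f"duplicate channel {ch.render()}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self) -> Iterator[Channel]:
        return iter(self.channels)

    def __getitem__(self, i: int) -> Channel:
        return self.channels[i]

    def distinct_excitations(self) -> list[float]:
        """Sorted unique excitation wavelengths."""
        return sorted({ch.excitation_nm for ch in self.channels})

    def distinct_emissions(self) -> list[float]:
        """Sorted unique emission band centres / cut-ons."""
        return sorted({ch.emission_nm for ch in self.channels})

    def render(self) -> str:
        return ", ".join(ch.render() for ch in self.channels)

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "channels": [
                {"ex": ch.excitation_nm, "em": ch.emission_nm, "kind": ch.kind}
                for ch in self.channels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSet":
        chans = tuple(
            Channel(float(c["ex"]), float(c["em"]), c.get("kind", "bandpass"))
            for c in d["channels"]
        )
        return cls(chans, name=d.get("name", ""))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ChannelSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["index", "excitation_nm", "emission_nm", "kind"])
            for i, ch in enumerate(self.channels):
                writer.writerow([i, ch.excitation_nm, ch.emission_nm, ch.kind])


_TOKEN_RE = re.compile(
    r"^(\d+(?:\.\d+)?)/(\d+(?:\.\d+)?)(\s*\(long-pass\))?$")


def parse_channel_list(text: str, name: str = "") -> ChannelSet:
    """Parse a free-text list of ``ex/em`` tokens into a :class:`ChannelSet`.

    Tokens are separated by commas; an optional ``(long-pass)`` suffix marks a
    long-pass emission filter whose ``em`` value is the cut-on wavelength.
    """
    if not text or not text.strip():
        raise ChannelParseError("empty channel list")
    channels = []
    for raw in text.split(","):
        token = raw.strip()
        if not token:
            continue
        m = _TOKEN_RE.match(token)
        if m is None:
            raise ChannelParseError(f"malformed channel token {token!r}")
        ex, em, lp = float(m.group(1)), float(m.group(2)), m.group(3)
        channels.append(Channel(ex, em, "longpass" if lp else "bandpass"))
    if not channels:
        raise ChannelParseError("no channel tokens found")
    return ChannelSet(tuple(channels), name=name)


def render_channel_list(cs: ChannelSet) -> str:
    """Inverse of :func:`parse_channel_list` (up to the set name)."""
    return cs.render()


# The instrument's 34-channel layout: 18 excitation lines x 4 filter cubes
# (440/475/593 bandpass, 715 long-pass).
_BUILTIN_LIST = (
    "340/440, 368/440, 373/440, 378/440, "
    "340/475, 368/475, 373/475, 378/475, 382/475, 388/475, 391/475, "
    "394/475, 405/475, 413/475, "
    "340/593, 368/593, 373/593, 378/593, 382/593, 388/593, 391/593, "
    "394/593, 405/593, 413/593, 432/593, 441/593, 455/593, 460/593, "
    "470/593, 491/593, 510/593, "
    "413/715 (long-pass), 455/715 (long-pass), 660/715 (long-pass)"
)


def builtin_channels() -> ChannelSet:
    """The 34-channel multispectral autofluorescence acquisition layout.

    Eighteen distinct narrow-band excitation wavelengths (340-660 nm) combined
    with four emission bands (440, 475, 593 nm bandpass and a 715 nm
    long-pass), in fixed acquisition order.
    """
    return parse_channel_list(_BUILTIN_LIST, name="autofluorescence-34")


def distinct_excitations(cs: ChannelSet) -> list[float]:
    """Sorted unique excitation wavelengths of a channel set."""
    if len(cs) == 0:
        raise ValueError("empty channel set")
    return cs.distinct_excitations()
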