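"""Autofluorophore endmember spectra and the channel-response forward model.

The four endogenous fluorophores tracked by the pipeline are free NAD(P)H,
protein-bound NAD(P)H, FAD and protoporphyrin IX (PPIX).  Each is described
by Gaussian excitation/emission peak mixtures; combining a spectrum with a
:class:`~spectrocycle.channels.Channel` through :func:`channel_response`
yields one entry of the channel x fluorophore endmember matrix used both by
the scene renderer (forward model) and by NNLS unmixing (inverse model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .channels import (
    Channel,
    ChannelSet,
    EXCITATION_HALF_WIDTH_NM,
    EMISSION_HALF_WIDTH_NM,
)

__all__ = [
    "FLUOROPHORES",
    "EndmemberSpectrum",
    "EndmemberMatrix",
    "default_endmembers",
    "channel_response",
    "build_endmember_matrix",
]

#: Fixed fluorophore order used by every abundance vector in the package.
FLUOROPHORES = ("NADPH_free", "NADPH_bound", "FAD", "PPIX")

# Instrument band Gaussians: sigma chosen so the stated half-width is the
# half-width at half-maximum.
_HWHM_TO_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))
_EX_BAND_SIGMA = EXCITATION_HALF_WIDTH_NM * _HWHM_TO_SIGMA
_EM_BAND_SIGMA = EMISSION_HALF_WIDTH_NM * _HWHM_TO_SIGMA


@dataclass(frozen=True)
class EndmemberSpectrum:
    """Gaussian-mixture excitation and emission profile of one fluorophore.

    Peaks are ``(centre_nm, sigma_nm, weight)`` triples; weights of each peak
    list sum to one, so ``brightness`` carries the relative quantal yield.
    """

    fluorophore: str
    excitation_peaks: tuple[tuple[float, float, float], ...]
    emission_peaks: tuple[tuple[float, float, float], ...]
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")
        for peaks in (self.excitation_peaks, self.emission_peaks):
            if not peaks:
                raise ValueError("peak list must be nonempty")
            if any(w[1] <= 0 for w in peaks):
                raise ValueError("peak widths must be positive")
            total = sum(w[2] for w in peaks)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"peak weights sum to {total}, expected 1")


def default_endmembers() -> list[EndmemberSpectrum]:
    """Reference spectra of the four autofluorophores.

    Free NAD(P)H: excitation maxima 290/351 nm, emission maxima 440/460 nm.
    Bound NAD(P)H: same excitation, emission blue-shifted by 15 nm and twice
    the quantal yield of the free form (binding both shifts and brightens the
    nicotinamide emission).  FAD: excitation maximum 450 nm, emission 535 nm.
    PPIX: Soret excitation at 405 nm with weak visible Q-bands, red emission
    at 635 nm with a 705 nm shoulder.
    """
    return [
        EndmemberSpectrum(
            "NADPH_free",
            excitation_peaks=((290.0, 12.0, 0.5), (351.0, 14.0, 0.5)),
            emission_peaks=((440.0, 18.0, 0.5), (460.0, 20.0, 0.5)),
            brightness=1.0,
        ),
        EndmemberSpectrum(
            "NADPH_bound",
            excitation_peaks=((290.0, 12.0, 0.5), (351.0, 14.0, 0.5)),
            emission_peaks=((425.0, 18.0, 0.5), (445.0, 20.0, 0.5)),
            brightness=2.0,
        ),
        EndmemberSpectrum(
            "FAD",
            excitation_peaks=((450.0, 18.0, 1.0),),
            emission_peaks=((535.0, 25.0, 1.0),),
            brightness=0.9,
        ),
        EndmemberSpectrum(
            "PPIX",
            excitation_peaks=(
                (405.0, 20.0, 0.85),
                (505.0, 25.0, 0.05),
                (540.0, 25.0, 0.04),
                (575.0, 25.0, 0.03),
                (630.0, 25.0, 0.03),
            ),
            emission_peaks=((635.0, 20.0, 0.9), (705.0, 25.0, 0.1)),
            brightness=0.7,
        ),
    ]


def _norm_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def channel_response(spectrum: EndmemberSpectrum, channel: Channel) -> float:
    """Expected relative signal of a fluorophore in one channel.

    Excitation factor: each excitation peak Gaussian convolved with the
    narrow excitation band Gaussian, evaluated at the channel's excitation
    centre.  Emission factor: for bandpass filters the overlap integral of
    the (unit-mass) emission peak with the Gaussian transmission profile; for
    long-pass filters the emission mass above the cut-on wavelength.
    Deterministic and nonnegative.
    """
    ex = 0.0
    for centre, sigma, weight in spectrum.excitation_peaks:
        var = sigma * sigma + _EX_BAND_SIGMA * _EX_BAND_SIGMA
        ex += weight * math.exp(-((channel.excitation_nm - centre) ** 2) / (2.0 * var))

    em = 0.0
    for centre, sigma, weight in spectrum.emission_peaks:
        if channel.longpass:
            em += weight * _norm_cdf((centre - channel.emission_nm) / sigma)
        else:
            var = sigma * sigma + _EM_BAND_SIGMA * _EM_BAND_SIGMA
            amp = _EM_BAND_SIGMA / math.sqrt(var)
            em += weight * amp * math.exp(
                -((channel.emission_nm - centre) ** 2) / (2.0 * var))

    return spectrum.brightness * ex * em


@dataclass(frozen=True)
class EndmemberMatrix:
    """Channels x fluorophores mixing matrix with unit-norm columns.

    ``matrix`` columns are scaled to unit Euclidean norm; ``scales`` holds the
    original column norms so physical responses can be recovered via
    :meth:`physical`.
    """

    matrix: np.ndarray  # (C, K), unit-norm columns
    fluorophores: tuple[str, ...]
    scales: np.ndarray  # (K,)
    channelset: ChannelSet

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.fluorophores):
            raise ValueError("matrix shape inconsistent with fluorophore list")
        if np.any(np.linalg.norm(m, axis=0) < 1e-12):
            raise ValueError("fluorophore invisible to channel set")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def physical(self) -> np.ndarray:
        """Un-normalised response matrix (columns times their stored scales)."""
        return self.matrix * self.scales

    def to_dict(self) -> dict:
        return {
            "fluorophores": list(self.fluorophores),
            "matrix": self.matrix.tolist(),
            "scales": self.scales.tolist(),
            "channels": self.channelset.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EndmemberMatrix":
        return cls(
            matrix=np.asarray(d["matrix"], dtype=float),
            fluorophores=tuple(d["fluorophores"]),
            scales=np.asarray(d["scales"], dtype=float),
            channelset=ChannelSet.from_dict(d["channels"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EndmemberMatrix":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_endmember_matrix(
    endmembers: list[EndmemberSpectrum], cs: ChannelSet
) -> EndmemberMatrix:
    """Evaluate every (channel, fluorophore) response and column-normalise.

    Raises if any fluorophore is invisible to the channel set or if there are
    fewer channels than fluorophores.
    """
    if len(cs) < len(endmembers):
        raise ValueError(
            f"need at least {len(endmembers)} channels, got {len(cs)}")
    raw = np.array(
        [[channel_response(s, ch) for s in endmembers] for ch in cs],
        dtype=float,
    )
    norms = np.linalg.norm(raw, axis=0)
    if np.any(norms < 1e-12):
        bad = [s.fluorophore for s, n in zip(endmembers, norms) if n < 1e-12]
        raise ValueError(f"fluorophore invisible to channel set: {bad}")
    return EndmemberMatrix(
        matrix=raw / norms,
        fluorophores=tuple(s.fluorophore for s in endmembers),
        scales=norms,
        channelset=cs,
    )
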