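"""Synthetic multispectral scene generator with known ground truth.

Emulates fields of view of plated cancer cells (HeLa, MIA-PaCa-2, PANC1)
imaged in the 34-channel autofluorescence layout.  Each cell is an ellipse
whose noiseless signal follows the linear mixing model
``photon_scale * (M @ a) * texture(p)`` for a per-cell abundance vector *a*
over the four fluorophores, plus background fluorescence, multiplied by a
smooth illumination (vignette) field, Poisson-sampled, and corrupted with
dead and saturated sensor pixels -- exactly the four artefact classes the
preprocessing module treats.

Between-line abundance differences are strong (2-4x) while between-phase
differences within a line are weak multiplicative effects, so cell-origin
structure dominates cell-cycle structure, and phase-dependent texture
granularity (smooth G1 through granular M) gives texture features some class
signal.  M-phase cells are generated for phase-wise abundance comparisons
but are merged with G2 for classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .channels import ChannelSet, builtin_channels
from .endmembers import (
    FLUOROPHORES,
    EndmemberMatrix,
    EndmemberSpectrum,
    build_endmember_matrix,
    default_endmembers,
)
from .stack import MultispectralStack

logger = logging.getLogger(__name__)

__all__ = [
    "LINES",
    "PHASES",
    "PhaseEffectSpec",
    "Artefacts",
    "CellSpec",
    "ScenePlan",
    "DatasetConfig",
    "SyntheticDataset",
    "default_phase_effects",
    "sample_scene",
    "render_stack",
    "make_dataset",
    "sample_true_abundances",
    "save_dataset",
]

LINES = ("HeLa", "MIA_PaCa_2", "PANC1")
PHASES = ("G1", "S", "G2", "M")


@dataclass(frozen=True)
class PhaseEffectSpec:
    """Ground-truth abundance distribution for one (line, phase) group.

    ``abundance_mean`` is the mean relative concentration of
    (NADPH_free, NADPH_bound, FAD, PPIX); per-cell abundances are drawn
    lognormally around it with coefficient of variation ``abundance_cv``.
    """

    line: str
    phase: str
    abundance_mean: tuple[float, float, float, float]
    abundance_cv: float = 0.18

    def __post_init__(self) -> None:
        if len(self.abundance_mean) != len(FLUOROPHORES):
            raise ValueError("abundance_mean needs one entry per fluorophore")
        if any(m < 0 for m in self.abundance_mean):
            raise ValueError("abundance means must be nonnegative")
        if self.abundance_cv < 0:
            raise ValueError("abundance_cv must be nonnegative")


# Line baselines: strong (2-4x) between-line differences in both overall
# autofluorescence and fluorophore composition.
_LINE_BASELINES: dict[str, tuple[float, float, float, float]] = {
    "HeLa": (1.0, 0.45, 0.6, 0.08),
    "MIA_PaCa_2": (3.4, 1.05, 2.5, 0.05),
    "PANC1": (0.6, 1.9, 0.22, 0.18),
}

# Weak multiplicative phase effects relative to G1, per fluorophore
# (free NAD(P)H, bound NAD(P)H, FAD, PPIX).  Encoded directions: bound
# NAD(P)H S > G1 in MIA-PaCa-2 and PANC1; PPIX M > G1 in HeLa and PANC1;
# redox ratio (FAD/free) and bound/free ratio G1 > M in HeLa and PANC1.
_PHASE_MULTIPLIERS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "HeLa": {
        "G1": (1.00, 1.00, 1.00, 1.00),
        "S": (1.10, 1.10, 1.05, 1.00),
        "G2": (1.15, 1.15, 1.10, 1.10),
        "M": (1.35, 1.12, 0.92, 1.40),
    },
    "MIA_PaCa_2": {
        "G1": (1.00, 1.00, 1.00, 1.00),
        "S": (1.05, 1.35, 1.05, 1.00),
        "G2": (1.10, 1.25, 1.10, 1.05),
        "M": (1.20, 1.20, 1.05, 1.10),
    },
    "PANC1": {
        "G1": (1.00, 1.00, 1.00, 1.00),
        "S": (1.05, 1.40, 1.05, 1.00),
        "G2": (1.10, 1.30, 1.10, 1.15),
        "M": (1.30, 1.20, 0.90, 1.40),
    },
}

#: Texture-field correlation length (px) per phase: G1 smooth -> M granular.
#: The contrast is deliberately mild so texture carries some class signal
#: without making any stage's clusters fully separable.
TEXTURE_CORRELATION_PX = {"G1": 2.2, "S": 2.0, "G2": 1.8, "M": 1.5}


def default_phase_effects(
    abundance_cv: float = 0.18, null: bool = False
) -> dict[tuple[str, str], PhaseEffectSpec]:
    """Ground-truth abundance table for every (line, phase) group.

    With ``null=True`` all phase multipliers are 1 (no phase effect), which
    is the configuration used for type-I-error calibration.
    """
    effects = {}
    for line in LINES:
        base = _LINE_BASELINES[line]
        for phase in PHASES:
            mult = (1.0,) * 4 if null else _PHASE_MULTIPLIERS[line][phase]
            mean = tuple(b * m for b, m in zip(base, mult))
            effects[(line, phase)] = PhaseEffectSpec(
                line, phase, mean, abundance_cv)
    return effects


@dataclass(frozen=True)
class Artefacts:
    """Artefact injection parameters for one rendered field of view."""

    background_level: float = 25.0
    vignette_coeffs: tuple[float, ...] = (1.0, 0.02, -0.03, -0.12, 0.01, -0.10)
    dead_pixel_rate: float = 1e-4
    saturated_pixel_rate: float = 5e-5
    photon_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if not (0 <= self.dead_pixel_rate < 1):
            raise ValueError("dead_pixel_rate must be in [0, 1)")
        if not (0 <= self.saturated_pixel_rate < 1):
            raise ValueError("saturated_pixel_rate must be in [0, 1)")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")


def _vignette_field(shape: tuple[int, int], coeffs) -> np.ndarray:
    """Low-order 2-D polynomial illumination field, normalised to unit mean."""
    h, w = shape
    v, u = np.meshgrid(
        np.linspace(-1.0, 1.0, h), np.linspace(-1.0, 1.0, w), indexing="ij")
    terms = [np.ones_like(u), u, v, u * u, u * v, v * v]
    field_ = sum(c * t for c, t in zip(coeffs, terms))
    field_ = np.clip(field_, 0.05, None)
    return field_ / field_.mean()


@dataclass(frozen=True)
class CellSpec:
    cell_id: int
    centre: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]
    orientation: float  # radians
    line: str
    phase: str
    abundance: tuple[float, float, float, float]  # raw, relative units
    texture_seed: int


@dataclass(frozen=True)
class ScenePlan:
    cells: tuple[CellSpec, ...]
    image_shape: tuple[int, int]
    artefacts: Artefacts


class PackingError(RuntimeError):
    """Rejection sampling could not place all requested cells."""


def _draw_abundance(rng: np.random.Generator, spec: PhaseEffectSpec) -> tuple:
    mean = np.asarray(spec.abundance_mean, dtype=float)
    if spec.abundance_cv == 0:
        return tuple(mean)
    sigma = math.sqrt(math.log(1.0 + spec.abundance_cv**2))
    z = rng.standard_normal(len(mean))
    return tuple(mean * np.exp(sigma * z - 0.5 * sigma * sigma))


def sample_scene(
    counts: dict[tuple[str, str], int],
    image_shape: tuple[int, int],
    effects: dict[tuple[str, str], PhaseEffectSpec],
    seed: int | np.random.SeedSequence = 0,
    artefacts: Artefacts | None = None,
    semi_axis_range: tuple[float, float] = (6.0, 11.0),
    id_start: int = 1,
    max_rejections: int = 10_000,
) -> ScenePlan:
    """Place non-overlapping elliptical cells and draw their ground truth.

    Reproducible for a fixed seed.  Raises :class:`PackingError` after
    ``max_rejections`` rejected placements.
    """
    rng = np.random.default_rng(seed)
    artefacts = artefacts or Artefacts()
    h, w = image_shape
    cells: list[CellSpec] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    rejections = 0
    cell_id = id_start
    for (line, phase), n in counts.items():
        spec = effects[(line, phase)]
        for _ in range(n):
            semi = tuple(sorted(rng.uniform(*semi_axis_range, size=2))[::-1])
            radius = semi[0] + 1.5
            while True:
                if rejections > max_rejections:
                    raise PackingError(
                        "could not place all cells without overlap; "
                        "use a larger image or fewer cells")
                r = rng.uniform(radius, h - radius)
                c = rng.uniform(radius, w - radius)
                ok = all(
                    (r - pr) ** 2 + (c - pc) ** 2 >= (radius + prad) ** 2
                    for pr, pc, prad in placed
                )
                if ok:
                    break
                rejections += 1
            placed.append((r, c, radius))
            cells.append(
                CellSpec(
                    cell_id=cell_id,
                    centre=(r, c),
                    semi_axes=semi,
                    orientation=float(rng.uniform(0, math.pi)),
                    line=line,
                    phase=phase,
                    abundance=_draw_abundance(rng, spec),
                    texture_seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            cell_id += 1
    return ScenePlan(tuple(cells), tuple(image_shape), artefacts)


def _cell_mask(cell: CellSpec, shape) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = draw_ellipse(
        cell.centre[0],
        cell.centre[1],
        cell.semi_axes[0],
        cell.semi_axes[1],
        shape=shape,
        rotation=cell.orientation,
    )
    return rr, cc


def _texture_values(
    cell: CellSpec, rr: np.ndarray, cc: np.ndarray, strength: float
) -> np.ndarray:
    """Positive, unit-mean multiplicative texture over the cell's pixels.

    A Gaussian random field with phase-dependent correlation length,
    exponentiated and renormalised so the cell-mean signal still follows the
    linear mixing model exactly.
    """
    if strength == 0 or len(rr) == 0:
        return np.ones(len(rr))
    rng = np.random.default_rng(cell.texture_seed)
    corr = TEXTURE_CORRELATION_PX[cell.phase]
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    pad = int(math.ceil(3 * corr))
    g = rng.standard_normal((r1 - r0 + 2 * pad, c1 - c0 + 2 * pad))
    g = gaussian_filter(g, corr, mode="wrap")
    sd = g.std()
    if sd > 0:
        g = g / sd
    vals = np.exp(strength * g[rr - r0 + pad, cc - c0 + pad])
    return vals / vals.mean()


def render_stack(
    plan: ScenePlan,
    cs: ChannelSet,
    seed: int | np.random.SeedSequence = 0,
    endmembers: list[EndmemberSpectrum] | None = None,
    matrix: EndmemberMatrix | None = None,
    texture_strength: float = 0.25,
    poisson: bool = True,
) -> tuple[MultispectralStack, np.ndarray, pd.DataFrame]:
    """Render a scene plan into (stack, label mask, ground-truth table).

    Bit-identical for a fixed (plan, seed).  With ``poisson=False`` the
    expected (noiseless) photon rate is returned as real values (the
    shot-noise-free limit); dead/saturated pixel injection still applies at
    the configured rates.
    """
    if matrix is None:
        matrix = build_endmember_matrix(endmembers or default_endmembers(), cs)
    m_phys = matrix.physical()  # (C, K)
    h, w = plan.image_shape
    n_chan = len(cs)
    art = plan.artefacts

    expected = np.zeros((h, w, n_chan), dtype=float)
    labels = np.zeros((h, w), dtype=np.int32)
    truth_rows = []
    for cell in plan.cells:
        rr, cc = _cell_mask(cell, (h, w))
        tex = _texture_values(cell, rr, cc, texture_strength)
        spectrum = m_phys @ np.asarray(cell.abundance)  # (C,)
        expected[rr, cc, :] += art.photon_scale * tex[:, None] * spectrum[None, :]
        labels[rr, cc] = cell.cell_id
        raw = np.asarray(cell.abundance, dtype=float)
        frac = raw / raw.sum()
        row = {"cell_id": cell.cell_id, "line": cell.line, "phase": cell.phase}
        row.update({f"a_{f}": v for f, v in zip(FLUOROPHORES, raw)})
        row.update({f"frac_{f}": v for f, v in zip(FLUOROPHORES, frac)})
        truth_rows.append(row)

    expected += art.background_level
    expected *= _vignette_field((h, w), art.vignette_coeffs)[:, :, None]

    rng = np.random.default_rng(seed)
    if poisson:
        pixels = rng.poisson(expected).astype(np.int64)
    else:
        pixels = expected

    max_value = 2**16 - 1
    n_natural_sat = int((pixels > max_value).sum())
    if n_natural_sat > 0.01 * pixels.size:
        logger.warning(
            "photon_scale saturates %.2f%% of pixels",
            100.0 * n_natural_sat / pixels.size)
    pixels = np.clip(pixels, 0, max_value)

    n_dead = rng.binomial(h * w, art.dead_pixel_rate)
    n_sat = rng.binomial(h * w, art.saturated_pixel_rate)
    flat = rng.choice(h * w, size=n_dead + n_sat, replace=False)
    dead_idx, sat_idx = flat[:n_dead], flat[n_dead:]
    pixels.reshape(-1, n_chan)[dead_idx, :] = 0
    pixels.reshape(-1, n_chan)[sat_idx, :] = max_value

    stack = MultispectralStack(
        pixels.astype(np.uint16) if poisson else pixels, cs)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["defects"] = {
        "dead_pixels": int(n_dead), "saturated_pixels": int(n_sat)}
    return stack, labels, truth


@dataclass(frozen=True)
class DatasetConfig:
    """Study-condition defaults for :func:`make_dataset`.

    One field of view is rendered per (line, phase) group with
    ``n_per_group`` cells each: 3 lines x 4 phases x 50 cells by default.
    """

    n_per_group: int = 50
    lines: tuple[str, ...] = LINES
    phases: tuple[str, ...] = PHASES
    image_shape: tuple[int, int] = (384, 384)
    artefacts: Artefacts = field(default_factory=Artefacts)
    abundance_cv: float = 0.18
    null_phase_effects: bool = False
    semi_axis_range: tuple[float, float] = (6.0, 11.0)
    texture_strength: float = 0.25
    poisson: bool = True

    def effects(self) -> dict[tuple[str, str], PhaseEffectSpec]:
        return default_phase_effects(self.abundance_cv, self.null_phase_effects)

    def small(self, n_per_group: int = 4) -> "DatasetConfig":
        """A reduced copy for quick tests."""
        return replace(self, n_per_group=n_per_group, image_shape=(160, 160))


@dataclass
class SyntheticDataset:
    stacks: list[MultispectralStack]
    masks: list[np.ndarray]
    truth: pd.DataFrame
    channels: ChannelSet
    endmember_matrix: EndmemberMatrix
    config: DatasetConfig
    defects: list[dict]
    plans: list[ScenePlan]

    def expected_cell_spectrum(self, cell_id: int) -> np.ndarray:
        """Noiseless in-cell mean spectrum: photon_scale * (M @ a)."""
        row = self.truth.loc[self.truth.cell_id == cell_id].iloc[0]
        a = np.array([row[f"a_{f}"] for f in FLUOROPHORES])
        return self.config.artefacts.photon_scale * (
            self.endmember_matrix.physical() @ a)


def make_dataset(
    config: DatasetConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> SyntheticDataset:
    """Generate the full multi-line, multi-phase synthetic dataset.

    Cell ids are globally unique across fields of view; label masks carry
    the global ids, and the concatenated ground-truth table covers every
    cell of every field of view.
    """
    config = config or DatasetConfig()
    if config.n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    effects = config.effects()
    cs = builtin_channels()
    matrix = build_endmember_matrix(default_endmembers(), cs)

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    groups = [(line, phase) for line in config.lines for phase in config.phases]
    children = ss.spawn(2 * len(groups))

    stacks, masks, plans, defects, truths = [], [], [], [], []
    id_start = 1
    for i, (line, phase) in enumerate(groups):
        plan = sample_scene(
            {(line, phase): config.n_per_group},
            config.image_shape,
            effects,
            seed=children[2 * i],
            artefacts=config.artefacts,
            semi_axis_range=config.semi_axis_range,
            id_start=id_start,
        )
        stack, labels, truth = render_stack(
            plan,
            cs,
            seed=children[2 * i + 1],
            matrix=matrix,
            texture_strength=config.texture_strength,
            poisson=config.poisson,
        )
        id_start += config.n_per_group
        stacks.append(stack)
        masks.append(labels)
        plans.append(plan)
        truths.append(truth)
        defects.append(truth.attrs["defects"])

    truth = pd.concat(truths, ignore_index=True)
    return SyntheticDataset(
        stacks, masks, truth, cs, matrix, config, defects, plans)


def sample_true_abundances(
    n_per_phase: int,
    lines: tuple[str, ...] = LINES,
    phases: tuple[str, ...] = PHASES,
    abundance_cv: float = 0.18,
    null: bool = False,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Draw ground-truth abundance fractions directly (no imaging).

    Used for statistical calibration of the phase-comparison pipeline:
    rows carry fractions plus redox and bound/free ratios computed from the
    generator's own truth.
    """
    effects = default_phase_effects(abundance_cv, null)
    rng = np.random.default_rng(seed)
    rows = []
    cell_id = 1
    for line in lines:
        for phase in phases:
            spec = effects[(line, phase)]
            for _ in range(n_per_phase):
                raw = np.asarray(_draw_abundance(rng, spec))
                frac = raw / raw.sum()
                row = {"cell_id": cell_id, "line": line, "phase": phase}
                row.update(
                    {f"frac_{f}": v for f, v in zip(FLUOROPHORES, frac)})
                row["redox_ratio"] = frac[2] / max(frac[0], 1e-9)
                row["bound_free_ratio"] = frac[1] / max(frac[0], 1e-9)
                rows.append(row)
                cell_id += 1
    return pd.DataFrame(rows)


def save_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write stacks, masks, truth table and channel metadata to a directory."""
    import pathlib

    import tifffile

    from .stack import write_stack

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (stack, mask) in enumerate(zip(dataset.stacks, dataset.masks)):
        write_stack(stack, out / f"fov_{i:03d}.tif")
        tifffile.imwrite(out / f"fov_{i:03d}_mask.tif", mask)
    dataset.truth.to_csv(out / "truth.csv", index=False)
    dataset.channels.to_yaml(out / "channels.yaml")
    dataset.endmember_matrix.to_yaml(out / "endmembers.yaml")
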