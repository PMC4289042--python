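"""Synthetic phantoms with known geometry, and a two-group cohort simulator.

The estimator-validation phantoms are deterministic voxel sets whose
fractal dimension is known analytically: a solid block (D = 3), a flat
slab (D = 2), a straight line (D = 1) and the Menger sponge
(D = log 20 / log 3 ≈ 2.7268).

The folded-ribbon phantom stands in for a cortical grey-matter ribbon:
a doubly-sinusoidal sheet

    z(x, y) = mid + A · sin(2π f x / L + φx) · sin(2π f y / L + φy)

thickened by ``thickness`` voxels along its local normal, with small
seeded phase jitter (φx, φy) providing subject-to-subject variability.
``fold_frequency`` f is the complexity knob — more folds per grid width
raise the measured FD — while ``thickness`` scales volume with little
effect on FD, decoupling the two the way cortical volume and
gyrification are decoupled in real brains.

The cohort simulator draws per-subject ribbon parameters from per-group
distributions and measures every phantom with the full FD/morphometry
stack, emulating a sex-stratified adolescent-vs-adult design (default
cell sizes 11/7 female and 6/7 male).  All randomness flows from the
single spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fractal import compute_fd
from .morphometry import measure_mask
from .volumes import BinaryMask

__all__ = [
    "MENGER_DIMENSION",
    "PhantomSpec",
    "GroupEffect",
    "CohortSpec",
    "make_solid_block",
    "make_slab",
    "make_line",
    "make_menger_sponge",
    "make_folded_ribbon",
    "make_phantom",
    "simulate_cohort",
]

#: analytic fractal dimension of the Menger sponge
MENGER_DIMENSION = math.log(20) / math.log(3)

#: half-width of the uniform phase jitter (radians) in the folded ribbon
PHASE_JITTER = math.pi / 8


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description (used by the CLI and config files)."""

    kind: str
    size: int = 64
    params: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = ("solid_block", "slab", "line", "menger_sponge", "folded_ribbon")
        if self.kind not in kinds:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {kinds}")
        if self.kind != "menger_sponge" and self.size < 8:
            raise ValueError(f"grid edge must be >= 8 voxels, got {self.size}")


def make_solid_block(size: int) -> BinaryMask:
    """Fully occupied size³ cube (D = 3 reference)."""
    if size < 8:
        raise ValueError(f"size must be >= 8, got {size}")
    return BinaryMask(np.ones((size, size, size), dtype=bool))


def make_slab(size: int, thickness: int = 1) -> BinaryMask:
    """size × size × thickness sheet centered in a size³ grid (D = 2 reference)."""
    if size < 8:
        raise ValueError(f"size must be >= 8, got {size}")
    if not 1 <= thickness < size:
        raise ValueError(f"need 1 <= thickness < size, got thickness {thickness}")
    grid = np.zeros((size, size, size), dtype=bool)
    start = (size - thickness) // 2
    grid[:, :, start:start + thickness] = True
    return BinaryMask(grid)


def make_line(size: int) -> BinaryMask:
    """Straight 1-voxel-wide line through the grid center (D = 1 reference)."""
    if size < 8:
        raise ValueError(f"size must be >= 8, got {size}")
    grid = np.zeros((size, size, size), dtype=bool)
    mid = size // 2
    grid[:, mid, mid] = True
    return BinaryMask(grid)


def make_menger_sponge(level: int) -> BinaryMask:
    """Level-n Menger sponge on a (3^n)³ grid; voxel count is exactly 20^n.

    Each 3×3×3 subdivision keeps the 20 subcubes that do not touch the
    center of a face or the body center (i.e. drops subcubes with two or
    more middle coordinates).  Levels above 4 are refused as a memory
    guard (3^5 = 243³ ≈ 14M voxels).
    """
    if not 1 <= level <= 4:
        raise ValueError(f"level must be in 1..4, got {level}")
    grid = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        n = grid.shape[0]
        nxt = np.zeros((3 * n, 3 * n, 3 * n), dtype=bool)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if (i == 1) + (j == 1) + (k == 1) >= 2:
                        continue
                    nxt[i * n:(i + 1) * n, j * n:(j + 1) * n, k * n:(k + 1) * n] = grid
        grid = nxt
    return BinaryMask(grid)


def make_folded_ribbon(
    size: int,
    fold_frequency: float,
    amplitude: float,
    thickness: float,
    seed: int = 0,
    phase_jitter: float = PHASE_JITTER,
) -> BinaryMask:
    """Doubly-sinusoidal sheet of given normal thickness in a size³ grid.

    With ``fold_frequency = 0`` (flat sheet, no jitter applied) the result
    is exactly ``make_slab(size, thickness)``.  Deterministic given seed.
    """
    if size < 8:
        raise ValueError(f"size must be >= 8, got {size}")
    if thickness < 1:
        raise ValueError(f"thickness must be >= 1 voxel, got {thickness}")
    if fold_frequency < 0:
        raise ValueError(f"fold_frequency must be >= 0, got {fold_frequency}")
    if amplitude + thickness >= size / 2:
        raise ValueError(
            f"amplitude + thickness ({amplitude + thickness}) must stay below "
            f"size/2 ({size / 2}); the sheet would leave the grid"
        )
    rng = np.random.default_rng(seed)
    if fold_frequency > 0 and phase_jitter > 0:
        phi_x, phi_y = rng.uniform(-phase_jitter, phase_jitter, size=2)
    else:
        phi_x = phi_y = 0.0

    x, y = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    mid = (size - 1) / 2.0
    k = 2.0 * math.pi * fold_frequency / size
    ax = k * x + phi_x
    ay = k * y + phi_y
    sheet = mid + amplitude * np.sin(ax) * np.sin(ay)
    # analytic surface gradient -> cosine of the normal's angle to the z axis
    gx = amplitude * k * np.cos(ax) * np.sin(ay)
    gy = amplitude * k * np.sin(ax) * np.cos(ay)
    cos_tilt = 1.0 / np.sqrt(1.0 + gx**2 + gy**2)

    z = np.arange(size)[None, None, :]
    normal_dist = (z - sheet[:, :, None]) * cos_tilt[:, :, None]
    half = thickness / 2.0
    grid = (normal_dist >= -half) & (normal_dist < half)
    return BinaryMask(grid)


def make_phantom(spec: PhantomSpec) -> BinaryMask:
    """Build a phantom from a :class:`PhantomSpec`."""
    p = dict(spec.params)
    if spec.kind == "solid_block":
        return make_solid_block(spec.size)
    if spec.kind == "slab":
        return make_slab(spec.size, int(p.get("thickness", 1)))
    if spec.kind == "line":
        return make_line(spec.size)
    if spec.kind == "menger_sponge":
        return make_menger_sponge(int(p.get("level", 3)))
    return make_folded_ribbon(
        spec.size,
        fold_frequency=float(p.get("fold_frequency", 6.0)),
        amplitude=float(p.get("amplitude", spec.size / 12.0)),
        thickness=float(p.get("thickness", 2.0)),
        seed=spec.seed,
    )


@dataclass(frozen=True)
class GroupEffect:
    """(mean, sd) of each folded-ribbon parameter for one group."""

    fold_frequency: tuple[float, float] = (5.0, 0.5)
    thickness: tuple[float, float] = (2.0, 0.1)
    size: tuple[float, float] = (48.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("fold_frequency", "thickness", "size"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0, got {sd}")
            if mean <= 0:
                raise ValueError(f"{name}: mean must be > 0, got {mean}")


#: study-design cell sizes: 11 girls / 7 women, 6 boys / 7 men
DEFAULT_CELLS: dict[tuple[str, str], int] = {
    ("adolescent", "female"): 11,
    ("adult", "female"): 7,
    ("adolescent", "male"): 6,
    ("adult", "male"): 7,
}

#: adolescents fold more tightly than adults (higher FD, and through the
#: larger sheet area also higher volume), mirroring the direction and
#: magnitude of the reported group differences: FD gap ~0.02-0.05 with
#: within-group sd ~0.01-0.04 at the default calibration grid of 48³
DEFAULT_EFFECTS: dict[str, GroupEffect] = {
    "adolescent": GroupEffect(fold_frequency=(6.0, 0.5), thickness=(2.0, 0.1),
                              size=(48.0, 0.0)),
    "adult": GroupEffect(fold_frequency=(5.0, 0.5), thickness=(2.0, 0.1),
                         size=(48.0, 0.0)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated two-group, sex-stratified cohort."""

    n_per_cell: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_CELLS)
    )
    effect: Mapping[str, GroupEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for (group, sex), n in self.n_per_cell.items():
            if n < 2:
                raise ValueError(
                    f"cell ({group}, {sex}): need >= 2 subjects per compared cell, got {n}"
                )
            if group not in self.effect:
                raise ValueError(f"no effect distribution given for group {group!r}")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def _sample_positive(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    return max(lo, float(rng.normal(mean, sd)))


def simulate_cohort(
    spec: CohortSpec,
    methods: Sequence[str] = ("BC", "MB"),
    region_name: str = "WB",
    return_masks: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, BinaryMask]]:
    """Simulate a cohort of folded-ribbon phantoms and measure each one.

    Each subject is a single whole-brain surrogate phantom (one region
    row per subject).  Returns a tidy cohort table with columns
    ``subject_id, group, sex, region, fd_bc, fd_mb, volume_mm3,
    surface_mm2`` plus the sampled generator parameters; identical seeds
    give bit-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    masks: dict[str, BinaryMask] = {}
    for (group, sex), n in sorted(spec.n_per_cell.items()):
        eff = spec.effect[group]
        for i in range(n):
            sid = f"{group[:4]}_{sex[0]}{i + 1:02d}"
            f = _sample_positive(rng, *eff.fold_frequency, lo=0.0)
            t = _sample_positive(rng, *eff.thickness, lo=1.0)
            size = int(round(_sample_positive(rng, *eff.size, lo=24.0)))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            mask = make_folded_ribbon(
                size, fold_frequency=f, amplitude=size / 12.0,
                thickness=t, seed=sub_seed,
            )
            row: dict[str, object] = {
                "subject_id": sid,
                "group": group,
                "sex": sex,
                "region": region_name,
                "fold_frequency": f,
                "thickness": t,
                "grid_size": size,
            }
            for method in methods:
                est = compute_fd(mask, method, "whole_brain")
                row[f"fd_{method.lower()}"] = est.D
            morpho = measure_mask(mask)
            row["volume_mm3"] = morpho.volume_mm3
            row["surface_mm2"] = morpho.surface_mm2
            rows.append(row)
            if return_masks:
                masks[sid] = mask
    table = pd.DataFrame(rows)
    return (table, masks) if return_masks else table
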