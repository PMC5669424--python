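"""Synthesis of abstract triangle-grid patterns with controlled mirror symmetry.

Patterns live on an 8x8 grid of cells; each cell is empty, one of four
half-square triangles (split along a cell diagonal and filled toward the
named corner), or a full black square.  A full cell counts as two black
triangular elements, a triangle as one; generated patterns carry 36-44
elements on a white background.

Symmetric patterns are produced by a simulated-annealing search whose
moves resample whole orbits of cells under the reflection group of the
target axes, so the declared symmetry is exact by construction and the
annealing only has to satisfy the element-count range (and keep
non-target axes visibly asymmetric).  Just-not-symmetric ("broken")
variants are created by re-randomising a small 3x3 window of a symmetric
pattern.

Rasterisation fills each cell with a ``px_per_cell`` square tile.  The
four triangle tiles map onto each other exactly under horizontal and
vertical flips, transposition and anti-transposition, which is what makes
grid-level symmetry equivalent to exact pixel-level symmetry of the
rendered image.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .symmetry import AXES, axis_symmetry

EMPTY, TRI_NE, TRI_NW, TRI_SE, TRI_SW, FULL = range(6)
N_STATES = 6
#: black triangular elements contributed by each cell state
STATE_ELEMENTS = np.array([0, 1, 1, 1, 1, 2])
GRID = 8

SYMMETRY_CLASSES = {
    "asymmetric": (),
    "1-orthogonal": ("vertical",),
    "2-orthogonal": ("vertical", "horizontal"),
    "1-diagonal": ("main-diagonal",),
    "2-diagonal": ("main-diagonal", "secondary-diagonal"),
    "4-axes": AXES,
}

# state permutations under the four reflections
_STATE_PERMS = {
    "vertical": np.array([EMPTY, TRI_NW, TRI_NE, TRI_SW, TRI_SE, FULL]),
    "horizontal": np.array([EMPTY, TRI_SE, TRI_SW, TRI_NE, TRI_NW, FULL]),
    "main-diagonal": np.array([EMPTY, TRI_SW, TRI_NW, TRI_SE, TRI_NE, FULL]),
    "secondary-diagonal": np.array([EMPTY, TRI_NE, TRI_SE, TRI_NW, TRI_SW, FULL]),
}


def _coord_map(axis: str):
    if axis == "vertical":
        return lambda i, j: (i, GRID - 1 - j)
    if axis == "horizontal":
        return lambda i, j: (GRID - 1 - i, j)
    if axis == "main-diagonal":
        return lambda i, j: (j, i)
    return lambda i, j: (GRID - 1 - j, GRID - 1 - i)


class PatternError(ValueError):
    """Invalid pattern-simulator input or degenerate operation."""


class ConvergenceError(RuntimeError):
    """Annealing failed to reach zero energy within the step budget."""

    def __init__(self, residual: float, steps: int):
        self.residual = residual
        super().__init__(
            f"annealing did not reach zero energy in {steps} steps "
            f"(residual energy {residual:.4g})"
        )


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric cooling schedule for the pattern search."""

    initial_temperature: float = 1.0
    cooling_factor: float = 0.95
    steps_per_temperature: int = 200
    min_temperature: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.cooling_factor < 1:
            raise PatternError("cooling_factor must lie in (0, 1)")
        if self.steps_per_temperature < 1 or self.initial_temperature <= 0:
            raise PatternError("annealing counts must be positive")


@dataclass(frozen=True)
class SimSpec:
    """Target for one generated pattern.

    ``target_axes`` is the (possibly empty) set of axes on which the
    pattern must be exactly mirror-symmetric; an empty set requests an
    asymmetric pattern whose every axis scores below
    ``asymmetry_threshold``.
    """

    target_axes: tuple[str, ...] = ()
    n_elements_range: tuple[int, int] = (36, 44)
    seed: int = 0
    annealing: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    asymmetry_threshold: float = 0.98

    def __post_init__(self) -> None:
        for ax in self.target_axes:
            if ax not in AXES:
                raise PatternError(f"unknown axis {ax!r}; expected one of {AXES}")
        lo, hi = self.n_elements_range
        if not 0 < lo <= hi:
            raise PatternError("n_elements_range must be positive and ordered")


@dataclass(frozen=True, eq=False)
class GridPattern:
    """An 8x8 triangle-grid pattern with its symmetry ground truth."""

    cells: np.ndarray
    symmetry_class: str
    seed: int

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int8)
        if cells.shape != (GRID, GRID):
            raise PatternError(f"grid must be {GRID}x{GRID}, got {cells.shape}")
        if cells.min() < 0 or cells.max() >= N_STATES:
            raise PatternError("invalid cell state")
        object.__setattr__(self, "cells", cells)

    @property
    def n_elements(self) -> int:
        return int(STATE_ELEMENTS[self.cells].sum())

    @property
    def declared_axes(self) -> tuple[str, ...]:
        return tuple(SYMMETRY_CLASSES.get(self.symmetry_class, ()))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GridPattern)
            and np.array_equal(self.cells, other.cells)
            and self.symmetry_class == other.symmetry_class
            and self.seed == other.seed
        )


def _tiles(px: int) -> np.ndarray:
    """Black(0)/white(1) tile for each cell state at ``px`` pixels per cell."""
    r, c = np.indices((px, px))
    tiles = np.ones((N_STATES, px, px), dtype=np.uint8)
    tiles[TRI_NE][c > r] = 0
    tiles[TRI_NW][r + c < px - 1] = 0
    tiles[TRI_SE][r + c > px - 1] = 0
    tiles[TRI_SW][c < r] = 0
    tiles[FULL][:] = 0
    return tiles


def render(pattern: GridPattern, px_per_cell: int = 74) -> np.ndarray:
    """Rasterise a pattern to a square binary image (black=0, white=1).

    ``px_per_cell`` must be even and at least 2: an odd tile size would
    leave the cell diagonals without an exact mirror partner pixel.  The
    default of 74 px per cell gives a 592x592 image, the closest even
    tile size to the conventional ~600x600 presentation format.
    """
    return _render_cells(pattern.cells, px_per_cell)


def _render_cells(cells: np.ndarray, px_per_cell: int) -> np.ndarray:
    if px_per_cell < 2 or px_per_cell % 2 != 0:
        raise PatternError(
            "px_per_cell must be an even integer >= 2 "
            "(odd sizes break exact mirror symmetry of rasterised triangles)"
        )
    tiles = _tiles(px_per_cell)
    img = tiles[cells]  # (8, 8, px, px)
    return img.transpose(0, 2, 1, 3).reshape(GRID * px_per_cell, GRID * px_per_cell)


def _group(axes: tuple[str, ...]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Closure of the reflection group generated by ``axes``.

    Each element is a pair ``(perm, sperm)`` acting on a flattened grid as
    ``g(cells)[k] = sperm[cells[perm[k]]]`` (``perm[k]`` is the source
    cell whose reflected content lands at position ``k``).
    """
    identity = (tuple(range(GRID * GRID)), tuple(range(N_STATES)))
    idx = np.arange(GRID * GRID).reshape(GRID, GRID)
    gens = []
    for ax in axes:
        cmap = _coord_map(ax)
        src = np.empty((GRID, GRID), dtype=int)
        for i, j in itertools.product(range(GRID), range(GRID)):
            src[cmap(i, j)] = idx[i, j]
        gens.append((tuple(src.ravel()), tuple(_STATE_PERMS[ax])))
    elements = {identity, *gens}
    frontier = list(elements)
    while frontier:
        new = []
        for p1, s1 in frontier:
            for p2, s2 in gens:
                p1a, s1a = np.asarray(p1), np.asarray(s1)
                p2a, s2a = np.asarray(p2), np.asarray(s2)
                # (g2∘g1): first reflect by g1, then g2
                comp = (tuple(p1a[p2a]), tuple(s2a[s1a]))
                if comp not in elements:
                    elements.add(comp)
                    new.append(comp)
        frontier = new
    return [(np.array(p), np.array(s)) for p, s in sorted(elements)]


def _orbit_assign(cells_flat: np.ndarray, group, cell: int, state: int) -> None:
    # setting `cell` to `state` and propagating through every group element
    # keeps the grid exactly symmetric under the whole group
    for perm, sperm in group:
        target = int(np.flatnonzero(perm == cell)[0])
        cells_flat[target] = sperm[state]


def _allowed_states(group, cell: int) -> np.ndarray:
    """States of ``cell`` compatible with its stabiliser in the group."""
    ok = np.ones(N_STATES, dtype=bool)
    states = np.arange(N_STATES)
    for perm, sperm in group:
        if perm[cell] == cell:
            ok &= sperm[states] == states
    return np.flatnonzero(ok)


def grid_axis_exact(cells: np.ndarray, axis: str) -> bool:
    """True iff the grid (hence any even-px render) is exactly symmetric."""
    cmap = _coord_map(axis)
    sperm = _STATE_PERMS[axis]
    mapped = np.empty_like(cells)
    for i, j in itertools.product(range(GRID), range(GRID)):
        mapped[cmap(i, j)] = sperm[cells[i, j]]
    return bool(np.array_equal(mapped, cells))


def _count_granularity(group) -> int:
    """gcd of orbit sizes: achievable element counts are its multiples."""
    n = GRID * GRID
    seen = np.zeros(n, dtype=bool)
    g = 0
    for cell in range(n):
        if seen[cell]:
            continue
        orbit = {int(np.flatnonzero(perm == cell)[0]) for perm, _ in group}
        for c in orbit:
            seen[c] = True
        g = int(np.gcd(g, len(orbit)))
    return g


def _count_penalty(cells: np.ndarray, target: int) -> float:
    return float(abs(int(STATE_ELEMENTS[cells].sum()) - target))


def _asym_penalty(cells: np.ndarray, spec: SimSpec) -> float:
    others = [ax for ax in AXES if ax not in spec.target_axes]
    if not others:
        return 0.0
    img = _render_cells(cells, 2)
    pen = 0.0
    for ax in others:
        s = axis_symmetry(img, ax)
        if s >= spec.asymmetry_threshold:
            pen += 1.0 + (s - spec.asymmetry_threshold)
    return pen


def _energy(cells: np.ndarray, spec: SimSpec, target: int) -> float:
    return _count_penalty(cells, target) + _asym_penalty(cells, spec)


def generate_pattern(spec: SimSpec) -> GridPattern:
    """Generate one pattern satisfying ``spec`` by simulated annealing.

    The energy is zero iff the element count lies in range and every
    non-target axis scores below the asymmetry threshold; target-axis
    symmetry is exact by construction of the orbit moves.  The same seed
    always yields the identical pattern.

    Raises
    ------
    ConvergenceError
        If zero energy is not reached within the cooling schedule,
        reporting the best residual energy seen.
    """
    rng = np.random.default_rng(spec.seed)
    group = _group(tuple(spec.target_axes))
    allowed = [_allowed_states(group, c) for c in range(GRID * GRID)]
    # orbit moves change the element count in multiples of the orbit
    # sizes, so only some counts are reachable for a given axis group;
    # a feasible target is drawn per pattern so counts vary across runs
    lo, hi = spec.n_elements_range
    gran = _count_granularity(group)
    feasible = [c for c in range(lo, hi + 1) if c % gran == 0]
    if not feasible:
        raise PatternError(
            f"no element count in [{lo}, {hi}] is reachable for axes "
            f"{spec.target_axes} (counts must be multiples of {gran})"
        )
    target = int(rng.choice(feasible))
    cells = np.zeros(GRID * GRID, dtype=np.int8)
    # randomised symmetric start
    for _ in range(2 * GRID * GRID):
        c = int(rng.integers(GRID * GRID))
        s = int(rng.choice(allowed[c]))
        _orbit_assign(cells, group, c, s)

    sched = spec.annealing
    energy = _energy(cells.reshape(GRID, GRID), spec, target)
    temp = sched.initial_temperature
    steps = 0
    best = energy
    while temp > sched.min_temperature and energy > 0:
        for _ in range(sched.steps_per_temperature):
            if energy == 0:
                break
            steps += 1
            c = int(rng.integers(GRID * GRID))
            s = int(rng.choice(allowed[c]))
            cand = cells.copy()
            _orbit_assign(cand, group, c, s)
            cand_energy = _energy(cand.reshape(GRID, GRID), spec, target)
            delta = cand_energy - energy
            if delta <= 0 or rng.random() < np.exp(-delta / temp):
                cells, energy = cand, cand_energy
        best = min(best, energy)
        temp *= sched.cooling_factor
    if energy > 0:
        raise ConvergenceError(best, steps)

    klass = _class_of_axes(tuple(spec.target_axes))
    return GridPattern(cells.reshape(GRID, GRID), klass, spec.seed)


def _class_of_axes(axes: tuple[str, ...]) -> str:
    key = tuple(sorted(axes))
    for name, ax in SYMMETRY_CLASSES.items():
        if tuple(sorted(ax)) == key:
            return name
    return "custom"


def generate_class(symmetry_class: str, seed: int, **spec_kwargs) -> GridPattern:
    """Generate a pattern of a named symmetry class (see SYMMETRY_CLASSES)."""
    if symmetry_class not in SYMMETRY_CLASSES:
        raise PatternError(
            f"unknown symmetry class {symmetry_class!r}; "
            f"expected one of {sorted(SYMMETRY_CLASSES)}"
        )
    spec = SimSpec(
        target_axes=tuple(SYMMETRY_CLASSES[symmetry_class]), seed=seed, **spec_kwargs
    )
    return generate_pattern(spec)


def break_symmetry(
    pattern: GridPattern,
    window_origin: tuple[int, int],
    seed: int,
    max_tries: int = 100,
) -> GridPattern:
    """Perturb a 3x3 cell window to produce a just-not-symmetric pattern.

    The nine window cells are re-randomised until (a) every axis that was
    exactly symmetric before is broken (per-axis score strictly below 1,
    hence aggregate MS strictly below 100), (b) the element count stays
    within 36-44, and (c) the pattern actually changed.  Only cells inside
    the window differ from the input.
    """
    if pattern.symmetry_class in ("asymmetric", "broken"):
        raise PatternError("break_symmetry requires a symmetric pattern")
    r0, c0 = window_origin
    if not (0 <= r0 <= GRID - 3 and 0 <= c0 <= GRID - 3):
        raise PatternError("3x3 window must lie fully inside the 8x8 grid")
    exact_before = [ax for ax in AXES if grid_axis_exact(pattern.cells, ax)]
    if not exact_before:
        raise PatternError("pattern has no exactly symmetric axis to break")
    lo, hi = 36, 44
    rng = np.random.default_rng(seed)
    rest = int(STATE_ELEMENTS[pattern.cells].sum()) - int(
        STATE_ELEMENTS[pattern.cells[r0 : r0 + 3, c0 : c0 + 3]].sum()
    )
    for _ in range(max_tries):
        cand = pattern.cells.copy()
        window = rng.integers(0, N_STATES, size=9, dtype=np.int8)
        # repair the draw toward the admissible element budget: a uniform
        # window averages ~9 elements, which would often leave the range
        for _ in range(64):
            total = rest + int(STATE_ELEMENTS[window].sum())
            if total > hi:
                nz = np.flatnonzero(STATE_ELEMENTS[window] > 0)
                k = int(rng.choice(nz))
                window[k] = EMPTY if window[k] != FULL else int(rng.integers(1, 5))
            elif total < lo:
                low = np.flatnonzero(STATE_ELEMENTS[window] < 2)
                k = int(rng.choice(low))
                window[k] = FULL if window[k] != EMPTY else int(rng.integers(1, 5))
            else:
                break
        cand[r0 : r0 + 3, c0 : c0 + 3] = window.reshape(3, 3)
        if np.array_equal(cand, pattern.cells):
            continue
        if not lo <= int(STATE_ELEMENTS[cand].sum()) <= hi:
            continue
        if any(grid_axis_exact(cand, ax) for ax in exact_before):
            continue
        return GridPattern(cand, "broken", seed)
    raise PatternError(
        "no admissible perturbation of the 3x3 window found "
        f"in {max_tries} tries (degenerate window or count range)"
    )
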