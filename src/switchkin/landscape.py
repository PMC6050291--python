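"""Production-count potential landscape: 2D histogram, U = -ln P,
interpolation, basins, saddles and minimax barriers.

The potential is the negative natural logarithm of the per-bin frame
probability (with a pseudocount keeping empty bins finite), shifted so its
minimum is zero. Basins are strict local minima of the (optionally
interpolated) surface surviving a persistence filter; the barrier between
two basins is the minimax path statistic over the 8-connected grid graph:
min over paths of the max U along the path, minus the starting basin's U.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline


@dataclass
class ProductionHistogram2D:
    """Probability per unit-width integer (cro, ci) bin; axis 0 = cro."""

    probabilities: np.ndarray
    n_frames: int
    max_count: int

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be >= 0")
        if self.n_frames > 0 and not np.isclose(
            self.probabilities.sum(), 1.0, atol=1e-9
        ):
            raise ValueError("probabilities must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(self.max_count + 1)


@dataclass
class Basin:
    location: tuple  # (cro, ci) grid coordinates (interpolated units)
    depth: float  # U at the minimum


@dataclass
class Saddle:
    location: tuple
    height: float


@dataclass
class PotentialLandscape:
    potential: np.ndarray  # U grid, axis 0 = cro
    probabilities: np.ndarray
    pseudocount: float
    n_frames: int
    coords: tuple | None = None  # (cro_coords, ci_coords) in molecule units
    basins: list = field(default_factory=list)
    saddles: list = field(default_factory=list)
    barriers: np.ndarray | None = None

    def grid_coords(self):
        if self.coords is not None:
            return self.coords
        n0, n1 = self.potential.shape
        return np.arange(n0, dtype=float), np.arange(n1, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        cro, ci = self.grid_coords()
        cc, ii = np.meshgrid(cro, ci, indexing="ij")
        return pd.DataFrame(
            {
                "cro_bin": cc.ravel(),
                "ci_bin": ii.ravel(),
                "P": self.probabilities.ravel()
                if self.probabilities.shape == self.potential.shape
                else np.full(self.potential.size, np.nan),
                "U": self.potential.ravel(),
            }
        )


def histogram2d(traces, max_count: int | None = None) -> ProductionHistogram2D:
    """Normalized 2D histogram of per-frame (cro, ci) production counts.

    Unit-width integer bins from 0 to ``max_count``; counts above the top
    bin are pooled into it.
    """
    if not traces:
        raise ValueError("empty trace collection")
    counts = np.vstack([t.counts for t in traces])
    if counts.size == 0:
        raise ValueError("no frames in traces")
    if max_count is None:
        max_count = int(counts.max())
    c = np.clip(counts, 0, max_count)
    M = max_count + 1
    flat = c[:, 0] * M + c[:, 1]
    hist = np.bincount(flat, minlength=M * M).reshape(M, M).astype(float)
    n = counts.shape[0]
    return ProductionHistogram2D(
        probabilities=hist / n, n_frames=n, max_count=max_count
    )


def potential(
    hist: ProductionHistogram2D, pseudocount: float = 0.5
) -> PotentialLandscape:
    """U = -ln(P + pseudocount/n_frames), shifted so min U = 0."""
    P = hist.probabilities
    if pseudocount <= 0:
        if np.any(P == 0):
            raise ValueError(
                "pseudocount must be > 0 when empty bins are present"
            )
        U = -np.log(P)
    else:
        n = max(hist.n_frames, 1)
        U = -np.log(P + pseudocount / n)
    U = U - U.min()
    return PotentialLandscape(
        potential=U,
        probabilities=P,
        pseudocount=pseudocount,
        n_frames=hist.n_frames,
    )


def interpolate(landscape: PotentialLandscape, factor: int) -> PotentialLandscape:
    """Bicubic-spline refinement of the potential surface by an integer
    factor; values at the original nodes are preserved exactly."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 1")
    if factor == 1:
        return landscape
    U = landscape.potential
    n0, n1 = U.shape
    x0, x1 = landscape.grid_coords()
    kx = min(3, n0 - 1)
    ky = min(3, n1 - 1)
    spline = RectBivariateSpline(x0, x1, U, kx=kx, ky=ky, s=0)
    f0 = np.linspace(x0[0], x0[-1], (n0 - 1) * factor + 1)
    f1 = np.linspace(x1[0], x1[-1], (n1 - 1) * factor + 1)
    # pin original nodes exactly onto the refined grid
    f0[::factor] = x0
    f1[::factor] = x1
    refined = spline(f0, f1)
    return PotentialLandscape(
        potential=refined,
        probabilities=landscape.probabilities,
        pseudocount=landscape.pseudocount,
        n_frames=landscape.n_frames,
        coords=(f0, f1),
    )


# ---------------------------------------------------------------------------
# Basins, saddles, minimax barriers
# ---------------------------------------------------------------------------

def _neighbors(i, j, n0, n1):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < n0 and 0 <= b < n1:
                yield a, b


def local_minima(U: np.ndarray) -> list[tuple]:
    """Strict local minima under 8-connectivity."""
    n0, n1 = U.shape
    out = []
    for i in range(n0):
        for j in range(n1):
            if all(U[i, j] < U[a, b] for a, b in _neighbors(i, j, n0, n1)):
                out.append((i, j))
    return out


def minimax_level(U: np.ndarray, src: tuple, dst: tuple, return_saddle=False):
    """Minimax path value: min over 8-connected grid paths from src to dst
    of the maximum U along the path (Dijkstra with max-cost relaxation).

    With ``return_saddle`` also returns the highest node on an optimal path
    (the saddle location)."""
    n0, n1 = U.shape
    best = np.full((n0, n1), np.inf)
    best[src] = U[src]
    prev = {}
    heap = [(U[src], src)]
    while heap:
        lvl, (i, j) = heapq.heappop(heap)
        if (i, j) == dst:
            break
        if lvl > best[i, j]:
            continue
        for a, b in _neighbors(i, j, n0, n1):
            cand = max(lvl, U[a, b])
            if cand < best[a, b]:
                best[a, b] = cand
                prev[(a, b)] = (i, j)
                heapq.heappush(heap, (cand, (a, b)))
    lvl = float(best[dst])
    if not return_saddle:
        return lvl
    node = dst
    saddle = dst
    while node != src:
        if U[node] > U[saddle]:
            saddle = node
        node = prev.get(node, src)
    if U[src] > U[saddle]:
        saddle = src
    return lvl, saddle


def merge_levels(U: np.ndarray, minima: list[tuple]) -> dict:
    """All pairwise minimax path levels between the given minima.

    Single sweep: nodes are activated in ascending U order and joined by
    union-find; the first time two minima's components connect, the level
    of the activating node is their minimax level. Returns
    {(m_a, m_b): level} with each unordered pair keyed both ways.
    """
    n0, n1 = U.shape
    order = np.argsort(U, axis=None, kind="stable")
    parent = np.arange(n0 * n1)

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    active = np.zeros(n0 * n1, dtype=bool)
    members: dict[int, list] = {}
    min_set = {m[0] * n1 + m[1] for m in minima}
    levels: dict = {}
    for flat in order:
        i, j = divmod(int(flat), n1)
        active[flat] = True
        if flat in min_set:
            members[flat] = [flat]
        for a, b in _neighbors(i, j, n0, n1):
            nb = a * n1 + b
            if not active[nb]:
                continue
            ra, rb = find(int(flat)), find(nb)
            if ra == rb:
                continue
            ma, mb = members.get(ra, []), members.get(rb, [])
            lvl = float(U[i, j])
            for x in ma:
                for y in mb:
                    ka = (divmod(x, n1), divmod(y, n1))
                    levels[ka] = lvl
                    levels[(ka[1], ka[0])] = lvl
            parent[ra] = rb
            members[rb] = ma + mb
            members.pop(ra, None)
    return levels


def find_basins_and_saddles(
    landscape: PotentialLandscape,
    min_depth: float = 0.5,
    min_mass: float = 15.0,
):
    """Identify basins, saddles and the pairwise minimax barrier matrix.

    Two noise filters: minima whose histogram bin carries fewer than
    ``min_mass`` expected frames are discarded (isolated low-count tail
    bins form wells of depth ~ln(3) regardless of sample size), and minima
    whose persistence (minimax merge level with a deeper basin minus their
    own depth) falls below ``min_depth`` are absorbed into their parent
    basin. barriers[i, j] is the minimax path level between basins i and j
    minus U(basin i); a flat landscape yields zero basins (no exception).
    Results are stored on the landscape and also returned as
    (basins, saddles, barriers).
    """
    U = landscape.potential
    minima = local_minima(U)
    if not minima:
        landscape.basins, landscape.saddles, landscape.barriers = [], [], None
        return [], [], None

    coords = landscape.grid_coords()

    # mass filter against the original (non-interpolated) histogram
    if landscape.n_frames > 0 and landscape.probabilities is not None:
        P = landscape.probabilities
        kept = []
        for m in minima:
            c0 = int(round(coords[0][m[0]]))
            c1 = int(round(coords[1][m[1]]))
            c0 = min(max(c0, 0), P.shape[0] - 1)
            c1 = min(max(c1, 0), P.shape[1] - 1)
            if P[c0, c1] * landscape.n_frames >= min_mass:
                kept.append(m)
        minima = kept
    if not minima:
        landscape.basins, landscape.saddles, landscape.barriers = [], [], None
        return [], [], None

    pair_levels = merge_levels(U, minima)

    # persistence filter: repeatedly drop the shallowest minimum whose
    # merge level with a deeper-or-equal survivor is within min_depth
    survivors = sorted(minima, key=lambda m: U[m])
    changed = True
    while changed and len(survivors) > 1:
        changed = False
        for m in reversed(survivors[1:]):  # shallowest first
            lv = [
                pair_levels[(m, other)]
                for other in survivors
                if other != m and U[other] <= U[m]
            ]
            if lv and (min(lv) - U[m]) < min_depth:
                survivors.remove(m)
                changed = True
                break
    basins = [
        Basin(location=(coords[0][m[0]], coords[1][m[1]]), depth=float(U[m]))
        for m in survivors
    ]
    nb = len(survivors)
    saddles = []
    if nb < 2:
        barriers = np.zeros((0, 0))
    else:
        barriers = np.zeros((nb, nb))
        for a in range(nb):
            for b in range(a + 1, nb):
                lvl, sad = minimax_level(
                    U, survivors[a], survivors[b], return_saddle=True
                )
                barriers[a, b] = lvl - U[survivors[a]]
                barriers[b, a] = lvl - U[survivors[b]]
                saddles.append(
                    Saddle(
                        location=(coords[0][sad[0]], coords[1][sad[1]]),
                        height=float(lvl),
                    )
                )
    landscape.basins = basins
    landscape.saddles = saddles
    landscape.barriers = barriers
    return basins, saddles, barriers


def direct_saddle_level(
    landscape: PotentialLandscape, a: tuple, b: tuple, n_samples: int = 200
) -> float:
    """Maximum potential along the straight segment between two points
    (molecule-unit coordinates), sampled on the spline surface.

    Minimax path levels between basins form an ultrametric, so a barrier
    between opposite basins can never strictly exceed all barriers of the
    adjacent pairs covering the same triangle: the switching-difficulty
    ordering of *direct* transitions is instead measured along the straight
    inter-basin path (the central peak for opposite pairs, the side saddles
    for adjacent pairs).
    """
    U = landscape.potential
    c0, c1 = landscape.grid_coords()
    kx = min(3, len(c0) - 1)
    ky = min(3, len(c1) - 1)
    sp = RectBivariateSpline(c0, c1, U, kx=kx, ky=ky, s=0)
    ts = np.linspace(0.0, 1.0, n_samples)
    xs = a[0] + (b[0] - a[0]) * ts
    ys = a[1] + (b[1] - a[1]) * ts
    return float(sp.ev(xs, ys).max())


def direct_barriers(landscape: PotentialLandscape, basins=None) -> np.ndarray:
    """Pairwise direct-path barrier matrix: direct saddle level between
    basins i and j minus U(basin i)."""
    if basins is None:
        basins = landscape.basins
    nb = len(basins)
    out = np.zeros((nb, nb))
    for i in range(nb):
        for j in range(i + 1, nb):
            lvl = direct_saddle_level(landscape, basins[i].location, basins[j].location)
            out[i, j] = lvl - basins[i].depth
            out[j, i] = lvl - basins[j].depth
    return out
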