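"""Lattice embodiment of the two-step dendrite-formation mechanism.

Dendritic peptide microstructures can form in two stages: (1) pre-nucleation
of fractal clusters by diffusion-limited aggregation (DLA), which fixes the
dendritic geometry, and (2) coalescence, in which further molecules deposit
on the cluster surface and fill concave sites, turning the interrupted
dendrite into a continuous structure.  This module is an illustrative,
quantitatively generic embodiment of that mechanism on a 2D square lattice:
no parameter here maps onto a physical concentration or rate.

Stage 1 is classic on-lattice DLA: random walkers launched from a circle
around the cluster stick (with a given probability) when they touch it.
Stage 2 deposits particles preferentially at perimeter sites with two or
more occupied neighbours, which never increases the perimeter-to-area ratio.
The box-counting fractal dimension of stage-1 clusters is the classic DLA
value (~1.7).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import ParameterError, PrecisionError

NEIGHBORS4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
NEIGHBORS8 = NEIGHBORS4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))

PRENUCLEATED = "PRENUCLEATED"
FILL = "FILL"


@dataclass
class LatticeCluster:
    """Connected set of occupied 2D lattice sites with per-site stage tags."""

    occupied: set = field(default_factory=set)
    stage: dict = field(default_factory=dict)  # site -> PRENUCLEATED | FILL
    neighborhood: int = 4

    @property
    def seed_sites(self) -> set:
        return {s for s, t in self.stage.items() if t == PRENUCLEATED}

    @property
    def fill_sites(self) -> set:
        return {s for s, t in self.stage.items() if t == FILL}

    @property
    def offsets(self):
        return NEIGHBORS4 if self.neighborhood == 4 else NEIGHBORS8

    def is_connected(self) -> bool:
        if not self.occupied:
            return True
        start = next(iter(self.occupied))
        seen = {start}
        stack = [start]
        offs = self.offsets
        while stack:
            x, y = stack.pop()
            for dx, dy in offs:
                s = (x + dx, y + dy)
                if s in self.occupied and s not in seen:
                    seen.add(s)
                    stack.append(s)
        return len(seen) == len(self.occupied)

    def perimeter(self) -> int:
        """Number of occupied-to-empty 4-neighbour adjacencies."""
        p = 0
        for x, y in self.occupied:
            for dx, dy in NEIGHBORS4:
                if (x + dx, y + dy) not in self.occupied:
                    p += 1
        return p

    @property
    def area(self) -> int:
        return len(self.occupied)

    def copy(self) -> "LatticeCluster":
        return LatticeCluster(
            occupied=set(self.occupied),
            stage=dict(self.stage),
            neighborhood=self.neighborhood,
        )


def dla_grow(
    n_particles: int,
    stickiness: float = 1.0,
    seed: int = 0,
    neighborhood: int = 4,
) -> LatticeCluster:
    """Grow a diffusion-limited aggregate of ``n_particles`` sites.

    Walkers are launched on a circle of radius (cluster radius + 5), walk on
    the lattice, are discarded beyond three launch radii, and stick to a
    cluster neighbour with probability ``stickiness``.  Far from the cluster
    the walk takes long radial jumps (a standard exact speed-up for
    nearest-neighbour DLA).  Deterministic per seed.
    """
    if n_particles < 1:
        raise ParameterError("n_particles must be >= 1")
    if not 0.0 < stickiness <= 1.0:
        raise ParameterError("stickiness must be in (0, 1]")
    rng = random.Random(seed)
    cluster = LatticeCluster(neighborhood=neighborhood)
    cluster.occupied.add((0, 0))
    cluster.stage[(0, 0)] = PRENUCLEATED
    offs = cluster.offsets
    occupied = cluster.occupied
    r_max = 0.0
    while len(occupied) < n_particles:
        launch = r_max + 5.0
        kill = 3.0 * launch
        th = rng.random() * 2.0 * math.pi
        x = int(round(launch * math.cos(th)))
        y = int(round(launch * math.sin(th)))
        while True:
            d = math.hypot(x, y)
            if d > kill:
                break  # walker lost; relaunch
            if d > r_max + 4.0:
                # long jump toward/around the cluster, length d - r_max - 3
                step = d - r_max - 3.0
                th = rng.random() * 2.0 * math.pi
                x += int(round(step * math.cos(th)))
                y += int(round(step * math.sin(th)))
                continue
            dx, dy = NEIGHBORS4[rng.randrange(4)]
            x += dx
            y += dy
            if (x, y) in occupied:
                # stepped onto the cluster: retreat and treat as contact
                x -= dx
                y -= dy
            touching = any((x + ox, y + oy) in occupied for ox, oy in offs)
            if touching:
                if stickiness >= 1.0 or rng.random() < stickiness:
                    occupied.add((x, y))
                    cluster.stage[(x, y)] = PRENUCLEATED
                    r_max = max(r_max, math.hypot(x, y))
                    break
    return cluster


def coalesce_fill(cluster: LatticeCluster, n_fill: int, seed: int = 0) -> LatticeCluster:
    """Deposit ``n_fill`` particles on the cluster surface, preferring
    concave perimeter sites (>= 2 occupied neighbours); tags them FILL.

    Connectivity is preserved and the perimeter-to-area ratio never
    increases.  Returns a new cluster; the input is untouched.
    """
    if not cluster.occupied:
        raise ParameterError("cluster must be non-empty")
    if n_fill < 0:
        raise ParameterError("n_fill must be >= 0")
    out = cluster.copy()
    if n_fill == 0:
        return out
    rng = random.Random(seed)
    occupied = out.occupied

    def neighbor_count(site):
        x, y = site
        return sum((x + dx, y + dy) in occupied for dx, dy in NEIGHBORS4)

    # perimeter candidates keyed by occupied-neighbour count
    candidates: dict[tuple, int] = {}
    for x, y in occupied:
        for dx, dy in NEIGHBORS4:
            s = (x + dx, y + dy)
            if s not in occupied and s not in candidates:
                candidates[s] = neighbor_count(s)
    for _ in range(n_fill):
        if not candidates:
            break
        best = max(candidates.values())
        pool = sorted(s for s, c in candidates.items() if c == best)
        site = pool[rng.randrange(len(pool))]
        occupied.add(site)
        out.stage[site] = FILL
        del candidates[site]
        x, y = site
        for dx, dy in NEIGHBORS4:
            s = (x + dx, y + dy)
            if s in occupied:
                continue
            candidates[s] = neighbor_count(s)
    return out


class DimensionEstimate(NamedTuple):
    dimension: float
    stderr: float


def _min_cover_count(sites, b: int, n_offsets: int = 4) -> int:
    """Smallest number of b-by-b boxes covering the sites over a grid-offset
    scan (the box-counting definition asks for a minimal cover)."""
    step = max(1, b // n_offsets)
    best = None
    for ox in range(0, b, step):
        for oy in range(0, b, step):
            n = len({((x + ox) // b, (y + oy) // b) for x, y in sites})
            if best is None or n < best:
                best = n
    return best


def fractal_dimension(cluster, min_sites: int = 100) -> DimensionEstimate:
    """Box-counting dimension: least-squares slope of log N(b) vs log(1/b)
    over dyadic box sizes b, with its standard error.

    N(b) is the minimal cover over a grid-offset scan.  Scales below the
    saturation regime (where boxes hold fewer than ~10 sites on average and
    N(b) simply tracks the site count rather than the geometry) and above
    half the cluster span are excluded from the fit; at least four dyadic
    scales must remain.  Accepts a LatticeCluster or a bare set of (x, y)
    sites.
    """
    from scipy.stats import linregress

    sites = cluster.occupied if isinstance(cluster, LatticeCluster) else set(cluster)
    n_sites = len(sites)
    if n_sites < min_sites:
        raise PrecisionError(f"need >= {min_sites} occupied sites, got {n_sites}")
    xs = [s[0] for s in sites]
    ys = [s[1] for s in sites]
    span = max(max(xs) - min(xs), max(ys) - min(ys)) + 1
    log_inv_b, log_n = [], []
    b = 1
    while b <= span / 2:
        n = _min_cover_count(sites, b)
        if n_sites / n >= 10.0 and n >= 2:
            log_inv_b.append(-math.log(b))
            log_n.append(math.log(n))
        b *= 2
    if len(log_n) < 4:
        raise PrecisionError("cluster spans too few dyadic scales (need >= 4)")
    fit = linregress(log_inv_b, log_n)
    return DimensionEstimate(dimension=float(fit.slope), stderr=float(fit.stderr))


def cluster_to_csv(cluster: LatticeCluster, path) -> None:
    """x, y, stage rows; deterministic ordering."""
    with open(path, "w") as fh:
        fh.write("x\ty\tstage\n")
        for x, y in sorted(cluster.occupied):
            fh.write(f"{x}\t{y}\t{cluster.stage.get((x, y), PRENUCLEATED)}\n")


def cluster_to_png(cluster: LatticeCluster, path) -> None:
    """Render the cluster (pre-nucleated sites dark, fill sites light)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for tag, color in ((PRENUCLEATED, "#1f3b73"), (FILL, "#e08a3c")):
        pts = [s for s, t in cluster.stage.items() if t == tag]
        if pts:
            ax.scatter([p[0] for p in pts], [p[1] for p in pts], s=1, c=color,
                       label=tag.lower())
    ax.set_aspect("equal")
    ax.legend(markerscale=8, frameon=False)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
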