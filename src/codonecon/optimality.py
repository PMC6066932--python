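"""Cost-efficiency Pareto frontier and transcript optimality score.

For a fixed amino-acid sequence, every synonymous encoding maps to a point
(mean per-codon relative biosynthetic cost, mean per-codon relative
translational efficiency). The Pareto frontier is the boundary of this
achievable region where no encoding can be made cheaper without becoming
less efficient; the anti-frontier is the opposite (most expensive, least
efficient) boundary. A transcript's optimality is its relative position
between the two boundaries,

    score = 100 * d4 / (d1 + d4)

with d1 the distance from the transcript's point to the Pareto frontier
and d4 its distance to the anti-frontier, both measured along the fixed
trade-off direction (-1, +1)/sqrt(2) (simultaneously cheaper and more
efficient). 100% means the transcript lies on the Pareto frontier.

Because per-position choices are independent and coordinates are means,
the achievable region is (1/L times) a Minkowski sum of per-position
option sets; its convex frontier is constructed exactly by merging the
edges of per-position convex chains in slope order — the exact limit of a
scalarization sweep over trade-off weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .code import STOP, GeneticCode, split_codons
from .costs import CostTable, relative_cost
from .tai import TAITable

#: unit vector towards "cheaper and more efficient"
_TRADE_DIR = (-1.0 / math.sqrt(2.0), 1.0 / math.sqrt(2.0))


@dataclass(frozen=True)
class PointCE:
    cost: float
    eff: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.cost, self.eff)


@dataclass(frozen=True)
class FrontierPair:
    """Pareto (cheap/efficient) and anti (expensive/inefficient) polylines.

    Vertices are sorted by increasing cost; along either polyline both
    coordinates increase (a non-dominated boundary of a 2-D region with a
    minimized x and maximized y objective is monotone).
    """

    pareto: tuple[tuple[float, float], ...]
    anti: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class OptimalityResult:
    point: PointCE
    d1: float
    d4: float
    score: float


def per_codon_options(
    aa: str, table: CostTable, tai: TAITable, code: GeneticCode
) -> list[tuple[str, float, float]]:
    """(codon, relative cost, relative efficiency) for one amino acid."""
    if aa not in code.families:
        raise KeyError(f"unknown amino acid {aa!r}")
    return [
        (c, relative_cost(c, table, code), tai.rel[c])
        for c in sorted(code.families[aa])
    ]


def _chain(points: list[tuple[float, float]], anti: bool) -> list[tuple[float, float]]:
    """Convex non-dominated chain of a finite point set.

    ``anti=False``: minimize x, maximize y (upper-left concave chain).
    ``anti=True``: maximize x, minimize y (lower-right convex chain),
    computed as the mirrored problem on negated coordinates.
    """
    if anti:
        return [(-x, -y) for x, y in reversed(_chain([(-x, -y) for x, y in points], False))]
    # non-dominated points: sort by (x asc, y desc); keep strictly rising y
    pts = sorted(set(points), key=lambda p: (p[0], -p[1]))
    nd = []
    best_y = -math.inf
    for x, y in pts:
        if y > best_y:
            nd.append((x, y))
            best_y = y
    # upper (concave) hull of the non-dominated staircase
    hull: list[tuple[float, float]] = []
    for p in nd:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            # drop hull[-1] if it lies on or below segment hull[-2]->p
            if (x2 - x1) * (p[1] - y1) - (y2 - y1) * (p[0] - x1) >= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    return hull


def _merge_chains(
    chains: list[tuple[list[tuple[float, float]], int]], concave: bool
) -> list[tuple[float, float]]:
    """Minkowski sum of monotone convex chains (with multiplicities),
    divided by the total multiplicity, via slope-ordered edge merging."""
    total = sum(mult for _, mult in chains)
    x0 = sum(ch[0][0] * m for ch, m in chains)
    y0 = sum(ch[0][1] * m for ch, m in chains)
    edges = []
    for ch, m in chains:
        for (xa, ya), (xb, yb) in zip(ch, ch[1:]):
            dx, dy = (xb - xa) * m, (yb - ya) * m
            edges.append((dy / dx, dx, dy))
    # concave chains stack steepest-first, convex chains shallowest-first
    edges.sort(key=lambda e: e[0], reverse=concave)
    verts = [(x0 / total, y0 / total)]
    x, y = x0, y0
    prev_slope = None
    for slope, dx, dy in edges:
        if prev_slope is not None and math.isclose(slope, prev_slope, rel_tol=1e-12, abs_tol=1e-12):
            x, y = x + dx, y + dy
            verts[-1] = (x / total, y / total)
        else:
            x, y = x + dx, y + dy
            verts.append((x / total, y / total))
        prev_slope = slope
    return verts


def frontiers_from_composition(
    aa_counts: dict[str, int],
    table: CostTable,
    tai: TAITable,
    code: GeneticCode,
) -> FrontierPair:
    """Frontiers for an amino-acid composition (order is irrelevant because
    the coordinates are per-position means)."""
    if not aa_counts or sum(aa_counts.values()) == 0:
        raise ValueError("empty amino-acid sequence")
    par_chains, anti_chains = [], []
    for aa, mult in aa_counts.items():
        if mult == 0:
            continue
        opts = [(c, e) for _, c, e in per_codon_options(aa, table, tai, code)]
        par_chains.append((_chain(opts, anti=False), mult))
        anti_chains.append((_chain(opts, anti=True), mult))
    pareto = _merge_chains(par_chains, concave=True)
    anti = _merge_chains(anti_chains, concave=False)
    return FrontierPair(pareto=tuple(pareto), anti=tuple(anti))


def frontiers(
    aa_seq: str, table: CostTable, tai: TAITable, code: GeneticCode
) -> FrontierPair:
    """Cost-efficiency frontier pair for an amino-acid sequence."""
    counts: dict[str, int] = {}
    for aa in aa_seq:
        counts[aa] = counts.get(aa, 0) + 1
    return frontiers_from_composition(counts, table, tai, code)


def _ray_polyline_distance(
    point: tuple[float, float],
    direction: tuple[float, float],
    polyline: tuple[tuple[float, float], ...],
) -> float:
    """Distance from ``point`` along ``direction`` to a monotone polyline.

    Returns the non-negative parameter t of the first intersection of the
    ray point + t*direction with the polyline; if the ray misses, clamps
    to the Euclidean distance to the nearest polyline endpoint.
    """
    px, py = point
    ux, uy = direction
    best = None
    for (ax, ay), (bx, by) in zip(polyline, polyline[1:]):
        sx, sy = bx - ax, by - ay
        denom = ux * sy - uy * sx
        if abs(denom) < 1e-15:
            continue
        # solve p + t u = a + r s
        t = ((ax - px) * sy - (ay - py) * sx) / denom
        r = ((ax - px) * uy - (ay - py) * ux) / denom
        if -1e-12 <= r <= 1 + 1e-12 and t >= -1e-9:
            t = max(t, 0.0)
            best = t if best is None else min(best, t)
    if len(polyline) == 1:
        ax, ay = polyline[0]
        # on-ray single point
        t = (ax - px) * ux + (ay - py) * uy
        cross = (ax - px) * uy - (ay - py) * ux
        if abs(cross) < 1e-12 and t >= -1e-9:
            return max(t, 0.0)
    if best is not None:
        return best
    # ray misses: clamp to nearest endpoint
    ends = [polyline[0], polyline[-1]]
    return min(math.hypot(ex - px, ey - py) for ex, ey in ends)


def gene_point(
    cds: str, table: CostTable, tai: TAITable, code: GeneticCode
) -> PointCE:
    """Mean per-codon (relative cost, relative efficiency) of a CDS."""
    codons = split_codons(cds)
    if codons and code.translate_codon(codons[-1]) == STOP:
        codons = codons[:-1]
    if not codons:
        raise ValueError("no sense codons")
    costs, effs = [], []
    for i, c in enumerate(codons):
        if code.translate_codon(c) == STOP:
            raise ValueError(f"internal stop codon at codon {i}")
        costs.append(relative_cost(c, table, code))
        effs.append(tai.rel[c])
    return PointCE(cost=float(np.mean(costs)), eff=float(np.mean(effs)))


def optimality(
    cds: str, table: CostTable, tai: TAITable, code: GeneticCode
) -> OptimalityResult:
    """Transcript cost-efficiency optimality score (0-100)."""
    codons = split_codons(cds)
    if codons and code.translate_codon(codons[-1]) == STOP:
        codons = codons[:-1]
    aa_seq = "".join(code.translate_codon(c) for c in codons)
    if STOP in aa_seq:
        raise ValueError("internal stop codon")
    fronts = frontiers(aa_seq, table, tai, code)
    point = gene_point(cds, table, tai, code)
    return score_point(point, fronts)


def score_point(point: PointCE, fronts: FrontierPair) -> OptimalityResult:
    """Score a precomputed (cost, eff) point against a frontier pair."""
    p = point.as_tuple()
    d1 = _ray_polyline_distance(p, _TRADE_DIR, fronts.pareto)
    d4 = _ray_polyline_distance(p, (-_TRADE_DIR[0], -_TRADE_DIR[1]), fronts.anti)
    if d1 <= 1e-12:
        score = 100.0
    elif d1 + d4 <= 1e-12:
        score = 100.0
    else:
        score = 100.0 * d4 / (d1 + d4)
    return OptimalityResult(point=point, d1=d1, d4=d4, score=float(np.clip(score, 0.0, 100.0)))
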