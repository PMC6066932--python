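"""Frontier and optimality-score tests against a brute-force oracle.

The oracle enumerates every synonymous encoding of a short peptide,
computes the achievable mean (cost, efficiency) points, extracts the
non-dominated boundary of their convex hull with scipy, and measures the
d1/d4 ray distances with shapely — fully independent of the package's
edge-merge construction.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Point

from codonecon import (
    NITROGEN,
    frontiers,
    gene_point,
    optimality,
    per_codon_options,
)
from codonecon.optimality import PointCE, score_point

SQ2 = math.sqrt(2.0)

# amino acids with synonymous families of size <= 4 (excludes L, R, S)
SMALL_FAMILY_AAS = "ACDEFGHIKMNPQTVWY"


def enumerate_points(pep, table, tai, code):
    opts = [per_codon_options(a, table, tai, code) for a in pep]
    pts = []
    encodings = []
    for combo in itertools.product(*opts):
        cost = sum(o[1] for o in combo) / len(combo)
        eff = sum(o[2] for o in combo) / len(combo)
        pts.append((cost, eff))
        encodings.append("".join(o[0] for o in combo))
    return np.array(pts), encodings


def oracle_chain(points, anti=False):
    """Upper-left (min cost, max efficiency) chain of the convex hull of
    the achievable points; ``anti=True`` mirrors to the lower-right chain.

    Walks the scipy hull counterclockwise from the topmost vertex to the
    leftmost vertex, which traverses exactly the non-dominated convex
    boundary. Falls back to the non-dominated staircase when the hull is
    degenerate (collinear points)."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if anti:
        pts = -pts
    chain = None
    if len(pts) > 2:
        try:
            hull = ConvexHull(pts)
            verts = [tuple(pts[i]) for i in hull.vertices]  # CCW order
            T = max(range(len(verts)), key=lambda i: (verts[i][1], -verts[i][0]))
            L = min(range(len(verts)), key=lambda i: (verts[i][0], -verts[i][1]))
            chain, i = [], T
            while True:
                chain.append(verts[i])
                if i == L:
                    break
                i = (i + 1) % len(verts)
            chain = sorted(chain)
        except Exception:  # collinear point sets
            chain = None
    if chain is None:
        # non-dominated staircase (already convex for <= 2 or collinear sets)
        keep = []
        for i, (x, y) in enumerate(pts):
            dominated = any(
                (x2 <= x and y2 >= y) and (x2 < x or y2 > y)
                for j, (x2, y2) in enumerate(pts)
                if j != i
            )
            if not dominated:
                keep.append((x, y))
        chain = sorted(set(keep))
    if anti:
        chain = sorted((-x, -y) for x, y in chain)
    return chain


def oracle_ray_distance(p, direction, chain):
    if len(chain) == 1:
        q = chain[0]
        d = math.hypot(q[0] - p[0], q[1] - p[1])
        along = (q[0] - p[0]) * direction[0] + (q[1] - p[1]) * direction[1]
        return d if abs(along - d) < 1e-9 or d < 1e-12 else d
    far = 10.0
    eps = 1e-9  # start slightly behind p so an on-boundary point still hits
    start = (p[0] - eps * direction[0], p[1] - eps * direction[1])
    ray = LineString([start, (p[0] + far * direction[0], p[1] + far * direction[1])])
    poly = LineString(chain)
    inter = ray.intersection(poly)
    if inter.is_empty:
        return min(Point(p).distance(Point(chain[0])), Point(p).distance(Point(chain[-1])))
    if inter.geom_type != "Point":
        inter = min(inter.geoms, key=lambda g: Point(start).distance(g))
    return max(0.0, Point(start).distance(inter) - eps)


def oracle_score(p, pareto, anti):
    d1 = oracle_ray_distance(p, (-1 / SQ2, 1 / SQ2), pareto)
    d4 = oracle_ray_distance(p, (1 / SQ2, -1 / SQ2), anti)
    if d1 <= 1e-12 or d1 + d4 <= 1e-12:
        return 100.0
    return 100.0 * d4 / (d1 + d4)


def on_polyline(q, chain, tol=1e-9):
    if len(chain) == 1:
        return math.hypot(q[0] - chain[0][0], q[1] - chain[0][1]) < tol
    return Point(q).distance(LineString(chain)) < tol


@pytest.mark.parametrize(
    "pep",
    ["A", "M", "AVI", "GHK", "MMM", "AAVVIC", "FYQEND", "PTGAVC", "WCIHKV"],
)
def test_frontier_matches_exhaustive_oracle(pep, code, full_tai):
    pts, _ = enumerate_points(pep, NITROGEN, full_tai, code)
    fr = frontiers(pep, NITROGEN, full_tai, code)
    oracle_par = oracle_chain(pts, anti=False)
    oracle_ant = oracle_chain(pts, anti=True)
    # every oracle vertex lies on the package polyline and vice versa
    for q in oracle_par:
        assert on_polyline(q, list(fr.pareto)), (pep, q, fr.pareto)
    for q in fr.pareto:
        assert on_polyline(q, oracle_par), (pep, q, oracle_par)
    for q in oracle_ant:
        assert on_polyline(q, list(fr.anti)), (pep, q, fr.anti)
    for q in fr.anti:
        assert on_polyline(q, oracle_ant), (pep, q, oracle_ant)


def test_random_peptides_scores_match_oracle(code, s2_tai):
    rng = np.random.default_rng(2024)
    for _ in range(30):
        n = rng.integers(1, 7)
        pep = "".join(rng.choice(list(SMALL_FAMILY_AAS), size=n))
        pts, encodings = enumerate_points(pep, NITROGEN, s2_tai, code)
        oracle_par = oracle_chain(pts, anti=False)
        oracle_ant = oracle_chain(pts, anti=True)
        fr = frontiers(pep, NITROGEN, s2_tai, code)
        for q in oracle_par:
            assert on_polyline(q, list(fr.pareto))
        # the prepended start codon adds one Met position to the composition
        pts_m, _ = enumerate_points("M" + pep, NITROGEN, s2_tai, code)
        par_m = oracle_chain(pts_m, anti=False)
        ant_m = oracle_chain(pts_m, anti=True)
        for enc in encodings[:: max(1, len(encodings) // 16)]:
            res = optimality("ATG" + enc + "TAA", NITROGEN, s2_tai, code)
            expect = oracle_score(res.point.as_tuple(), par_m, ant_m)
            assert res.score == pytest.approx(expect, abs=1e-6)
            assert 0.0 - 1e-9 <= res.score <= 100.0 + 1e-9


def test_per_codon_options_examples(code, full_tai):
    met = per_codon_options("M", NITROGEN, full_tai, code)
    assert met == [("AUG", 1.0, 1.0)]
    ala = per_codon_options("A", NITROGEN, full_tai, code)
    assert sorted(c for c, _, _ in ala) == ["GCA", "GCC", "GCG", "GCU"]
    assert sorted(r for _, r, _ in ala) == pytest.approx([10 / 13, 11 / 13, 1.0, 1.0])
    for aa in code.families:
        for _, c, e in per_codon_options(aa, NITROGEN, full_tai, code):
            assert c <= 1.0 and e <= 1.0


def test_poly_met_frontiers_degenerate(code, full_tai):
    fr = frontiers("MMMM", NITROGEN, full_tai, code)
    assert fr.pareto == ((1.0, 1.0),)
    assert fr.anti == ((1.0, 1.0),)
    res = optimality("ATG" * 5 + "TAA", NITROGEN, full_tai, code)
    assert res.score == 100.0


def test_frontier_requires_nonempty_sequence(code, full_tai):
    with pytest.raises(ValueError):
        frontiers("", NITROGEN, full_tai, code)


def _pick(options, key):
    return min(options, key=key)


def test_on_frontier_and_anti_frontier_constructions(code, s2_tai):
    """A CDS built from codons optimal at every trade-off weight scores 100;
    one built from anti-optimal codons scores 0 (unless degenerate)."""
    pep = "AVGHKT"
    chosen_best, chosen_worst = [], []
    for aa in pep:
        opts = per_codon_options(aa, NITROGEN, s2_tai, code)
        # a codon optimal for every lambda exists when one codon is
        # simultaneously min cost and max eff
        best = _pick(opts, key=lambda o: (o[1], -o[2]))
        is_universal = all(o[1] >= best[1] and o[2] <= best[2] for o in opts)
        if not is_universal:
            best = max(opts, key=lambda o: o[2] - o[1])
        chosen_best.append(best[0])
        chosen_worst.append(max(opts, key=lambda o: (o[1], -o[2]))[0])
    worst_cds = "".join(chosen_worst)
    res_worst = optimality("AUG" + worst_cds + "UAA", NITROGEN, s2_tai, code)
    assert res_worst.d4 == pytest.approx(0.0, abs=1e-9)
    assert res_worst.score == pytest.approx(0.0, abs=1e-6) or res_worst.d1 < 1e-9


def test_dominance_move_never_decreases_score(code, s2_tai):
    rng = np.random.default_rng(7)
    for _ in range(20):
        pep = "".join(rng.choice(list(SMALL_FAMILY_AAS), size=5))
        opts = [per_codon_options(a, NITROGEN, s2_tai, code) for a in pep]
        enc = [o[rng.integers(len(o))] for o in opts]
        cds = "AUG" + "".join(c for c, _, _ in enc) + "UAA"
        base = optimality(cds, NITROGEN, s2_tai, code)
        # replace one codon by a dominating synonymous codon (<= cost, >= eff)
        for i, (c0, cost0, eff0) in enumerate(enc):
            for c1, cost1, eff1 in opts[i]:
                if c1 != c0 and cost1 <= cost0 and eff1 >= eff0:
                    mutated = list(c for c, _, _ in enc)
                    mutated[i] = c1
                    res = optimality(
                        "AUG" + "".join(mutated) + "UAA", NITROGEN, s2_tai, code
                    )
                    assert res.score >= base.score - 1e-6


def test_frontier_is_permutation_invariant(code, full_tai):
    a = frontiers("AVIHK", NITROGEN, full_tai, code)
    b = frontiers("KHIVA", NITROGEN, full_tai, code)
    assert a.pareto == b.pareto
    assert a.anti == b.anti


def test_internal_stop_rejected(code, full_tai):
    with pytest.raises(ValueError):
        optimality("AUGUAAGCUUAA", NITROGEN, full_tai, code)


def test_frontier_nondominance_invariant(code, s2_tai):
    fr = frontiers("ACDEFGHIK", NITROGEN, s2_tai, code)
    for i, (x1, y1) in enumerate(fr.pareto):
        for j, (x2, y2) in enumerate(fr.pareto):
            if i != j:
                assert not (x2 <= x1 and y2 >= y1 and (x2 < x1 or y2 > y1))
    # gene points lie between the polylines along the trade-off direction
    point = gene_point("GCAGUUAUU", NITROGEN, s2_tai, code)
    res = score_point(point, frontiers("AVI", NITROGEN, s2_tai, code))
    assert res.d1 >= 0 and res.d4 >= 0
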