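"""The SK log-linear model of synonymous codon choice.

Within each synonymous family F, the probability of observing codon c is a
softmax over three linear codon features:

    P(c | F) = exp(GC_b * n_gc(c) + S_c * cost(c) + S_t * eff(c))
               / sum_{c' in F} exp(GC_b * n_gc(c') + S_c * cost(c') + S_t * eff(c'))

where n_gc is the number of G/C nucleotides in the codon (all three
positions by default), cost its absolute biosynthetic cost and eff its
global tAI weight w. Negative S_c means selection to reduce biosynthetic
cost; positive S_t means selection for translational efficiency; positive
GC_b means bias towards GC. Parameters are estimated by maximizing the
multinomial log-likelihood of observed codon counts; models are compared
by AIC over all non-empty subsets of {GC_b, S_c, S_t}.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .code import STOP, GeneticCode, split_codons
from .costs import CostTable, codon_cost, relative_cost
from .tai import TAITable

logger = logging.getLogger(__name__)

PARAM_NAMES = ("GCb", "Sc", "St")


class FitError(RuntimeError):
    """Optimizer failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SKParams:
    GCb: float = 0.0
    Sc: float = 0.0
    St: float = 0.0

    def __post_init__(self):
        for name in PARAM_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} is not finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.GCb, self.Sc, self.St], dtype=float)


@dataclass(frozen=True)
class CodonFeatures:
    """Per-sense-codon model features in a fixed codon order.

    ``relative`` switches cost/efficiency to within-family relative values
    and ``gc_third_position_only`` restricts the GC feature to the wobble
    position, so alternative published conventions can be matched.
    """

    codons: tuple[str, ...]
    n_gc: np.ndarray
    cost: np.ndarray
    eff: np.ndarray
    family_index: np.ndarray  # integer family label per codon
    family_slices: tuple[tuple[int, ...], ...] = field(repr=False, default=())


def build_features(
    table: CostTable,
    tai: TAITable,
    code: GeneticCode,
    relative: bool = False,
    gc_third_position_only: bool = False,
) -> CodonFeatures:
    codons = tuple(code.sense_codons)
    idx = {c: i for i, c in enumerate(codons)}
    if gc_third_position_only:
        n_gc = np.array([1.0 if c[2] in "GC" else 0.0 for c in codons])
    else:
        n_gc = np.array([sum(b in "GC" for b in c) for c in codons], dtype=float)
    if relative:
        cost = np.array([relative_cost(c, table, code) for c in codons])
        eff = np.array([tai.rel[c] for c in codons])
    else:
        cost = np.array([codon_cost(c, table) for c in codons])
        eff = np.array([tai.w[c] for c in codons])
    fam_index = np.empty(len(codons), dtype=int)
    slices = []
    for k, (aa, fam) in enumerate(sorted(code.families.items())):
        members = tuple(idx[c] for c in sorted(fam))
        slices.append(members)
        for i in members:
            fam_index[i] = k
    return CodonFeatures(
        codons=codons,
        n_gc=n_gc,
        cost=cost,
        eff=eff,
        family_index=fam_index,
        family_slices=tuple(slices),
    )


@dataclass(frozen=True)
class FitResult:
    params: SKParams
    included: frozenset[str]
    loglik: float
    aic: float
    fit_r2: float
    n_codons: int
    converged: bool = True

    def __post_init__(self):
        if not math.isclose(
            self.aic, 2 * len(self.included) - 2 * self.loglik, rel_tol=1e-9, abs_tol=1e-9
        ):
            raise ValueError("AIC inconsistent with loglik and parameter count")


def _probabilities(theta: np.ndarray, features: CodonFeatures) -> np.ndarray:
    """Within-family softmax probabilities for all sense codons."""
    eta = (
        theta[0] * features.n_gc + theta[1] * features.cost + theta[2] * features.eff
    )
    probs = np.empty_like(eta)
    for members in features.family_slices:
        m = list(members)
        e = eta[m]
        e = np.exp(e - e.max())
        probs[m] = e / e.sum()
    return probs


def codon_probability(
    codon: str, params: SKParams, features: CodonFeatures, code: GeneticCode
) -> float:
    """P(codon | its synonymous family) under the SK model."""
    c = codon.upper().replace("T", "U")
    if code.translate_codon(c) == STOP:
        raise ValueError(f"{codon!r} is a stop codon")
    probs = _probabilities(params.as_array(), features)
    return float(probs[features.codons.index(c)])


def count_codons(cds_set, code: GeneticCode) -> dict[str, int]:
    """Codon counts over all sense positions of a set of CDS (stops excluded)."""
    counts = {c: 0 for c in code.sense_codons}
    for cds in cds_set:
        for codon in split_codons(cds):
            if code.translate_codon(codon) != STOP:
                counts[codon] += 1
    return counts


def _counts_array(counts: dict[str, int], features: CodonFeatures) -> np.ndarray:
    return np.array([counts.get(c, 0) for c in features.codons], dtype=float)


def _loglik(theta: np.ndarray, n: np.ndarray, features: CodonFeatures) -> float:
    probs = _probabilities(theta, features)
    mask = n > 0
    return float(np.sum(n[mask] * np.log(probs[mask])))


def _fit_r2(n: np.ndarray, probs: np.ndarray, features: CodonFeatures) -> float:
    """Squared Pearson r between observed within-family frequencies and
    fitted probabilities, across sense codons of families of size >= 2."""
    obs, fitted = [], []
    for members in features.family_slices:
        m = list(members)
        if len(m) < 2:
            continue
        tot = n[m].sum()
        if tot == 0:
            continue
        obs.extend(n[m] / tot)
        fitted.extend(probs[m])
    if len(obs) < 2 or np.std(obs) == 0 or np.std(fitted) == 0:
        return 1.0 if np.allclose(obs, fitted) else 0.0
    r = np.corrcoef(obs, fitted)[0, 1]
    return float(r**2)


def fit(
    counts: dict[str, int],
    features: CodonFeatures,
    spec: set[str] | frozenset[str] = frozenset(PARAM_NAMES),
    fixed: SKParams | None = None,
    seed: int = 0,
    n_starts: int = 5,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood fit of the SK model.

    ``spec`` names the free parameters; the others are held at 0 unless
    supplied in ``fixed``. Optimization is a derivative-free simplex with
    seeded multi-starts from the origin and random points in [-2, 2]^k.
    """
    spec = frozenset(spec)
    unknown = spec - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameters {sorted(unknown)}")
    n = _counts_array(counts, features)
    if n.sum() <= 0:
        raise ValueError("total codon count is zero; nothing to fit")

    base = (fixed.as_array() if fixed is not None else np.zeros(3))
    free_idx = [i for i, name in enumerate(PARAM_NAMES) if name in spec]
    k = len(free_idx)

    def negll(x: np.ndarray) -> float:
        theta = base.copy()
        theta[free_idx] = x
        return -_loglik(theta, n, features)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)] + [rng.uniform(-2, 2, size=k) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negll,
            x0,
            method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-8, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("optimizer failed on all starts", best=best)
    if not best.success:
        logger.warning("simplex did not report convergence: %s", best.message)

    theta = base.copy()
    theta[free_idx] = best.x
    loglik = -best.fun
    probs = _probabilities(theta, features)
    params = SKParams(*theta)
    return FitResult(
        params=params,
        included=spec,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        fit_r2=_fit_r2(n, probs, features),
        n_codons=int(n.sum()),
        converged=bool(best.success),
    )


def select_model(
    counts: dict[str, int],
    features: CodonFeatures,
    seed: int = 0,
) -> FitResult:
    """Fit all 7 non-empty parameter subsets and return the AIC-minimal fit.

    Ties (within 1e-9) are broken towards fewer parameters.
    """
    fits = []
    for r in (1, 2, 3):
        for combo in itertools.combinations(PARAM_NAMES, r):
            fits.append(fit(counts, features, spec=set(combo), seed=seed))
    return min(fits, key=lambda f: (f.aic, len(f.included)))


def fit_genes(
    cds_set,
    genome_fit: FitResult,
    features: CodonFeatures,
    code: GeneticCode,
    ids=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene S_c/S_t fits with GC_b fixed at the genome-wide estimate.

    Genes without any synonymous information (all observed families are
    effectively singletons) are flagged ``estimable=False`` rather than
    raising; identical sequences yield identical rows.
    """
    gcb = genome_fit.params.GCb
    ids = list(ids) if ids is not None else [f"gene_{i}" for i in range(len(cds_set))]
    rows = []
    for gene_id, cds in zip(ids, cds_set):
        counts = count_codons([cds], code)
        n = _counts_array(counts, features)
        informative = any(
            n[list(m)].sum() > 0 and len(m) >= 2 for m in features.family_slices
        )
        if not informative:
            rows.append(
                dict(gene=gene_id, Sc=np.nan, St=np.nan, loglik=np.nan, estimable=False)
            )
            continue
        res = fit(
            counts,
            features,
            spec={"Sc", "St"},
            fixed=SKParams(GCb=gcb),
            seed=seed,
        )
        rows.append(
            dict(
                gene=gene_id,
                Sc=res.params.Sc,
                St=res.params.St,
                loglik=res.loglik,
                estimable=True,
            )
        )
    df = pd.DataFrame(rows)
    n_bad = int((~df["estimable"]).sum())
    if n_bad:
        logger.info("%d gene(s) flagged not-estimable", n_bad)
    return df
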