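"""Seeded synthetic-data generators with known ground truth.

The genome generator inverts the SK model: for each gene an amino-acid
sequence is drawn (uniform over the 20 amino acids by default, or from a
supplied composition), then each codon is sampled from the within-family
softmax at the gene's true (GC_b, S_c, S_t); a start codon is prepended
and a stop appended. Per-gene selection strengths can be coupled to a
log-normal latent "abundance" to emulate expression-dependent selection.
Rate tables are generated as linear functions of optimality plus Gaussian
noise, truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .code import GeneticCode, dna
from .io import GeneRecord
from .skmodel import CodonFeatures, SKParams, _probabilities


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for a synthetic genome.

    ``abundance_coupling`` (kc, kt) makes per-gene selection strengths
    Sc_g = Sc * (1 + kc*z_g), St_g = St * (1 + kt*z_g) with z_g the gene's
    standardized log-abundance, so highly expressed genes are under
    stronger selection.
    """

    n_genes: int = 500
    codons_per_gene: int = 300
    params: SKParams = field(default_factory=SKParams)
    inventory_kind: str = "full"
    seed: int = 0
    aa_weights: dict[str, float] | None = None
    abundance_coupling: tuple[float, float] = (0.0, 0.0)
    abundance_sigma: float = 1.0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def simulate_genome(
    spec: SimulationSpec, features: CodonFeatures, code: GeneticCode
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Sample a synthetic CDS set plus its per-gene ground-truth table.

    Returns (records, truth) where truth has columns gene, Sc, St,
    abundance. Deterministic for a given spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    aas = sorted(code.families)
    if spec.aa_weights is None:
        aa_p = np.full(len(aas), 1.0 / len(aas))
    else:
        aa_p = np.array([spec.aa_weights.get(a, 0.0) for a in aas], dtype=float)
        aa_p = aa_p / aa_p.sum()

    fam_members = {
        aa: [features.codons.index(c) for c in sorted(code.families[aa])] for aa in aas
    }
    kc, kt = spec.abundance_coupling
    log_ab = rng.normal(0.0, spec.abundance_sigma, size=spec.n_genes)
    z = (log_ab - log_ab.mean()) / (log_ab.std() or 1.0)

    stops = sorted(code.stop_codons)
    records, truth_rows = [], []
    for g in range(spec.n_genes):
        sc_g = spec.params.Sc * (1.0 + kc * z[g])
        st_g = spec.params.St * (1.0 + kt * z[g])
        theta = np.array([spec.params.GCb, sc_g, st_g])
        probs = _probabilities(theta, features)
        aa_seq = rng.choice(aas, size=spec.codons_per_gene, p=aa_p)
        codons = np.empty(spec.codons_per_gene, dtype=object)
        for aa in fam_members:
            where = np.flatnonzero(aa_seq == aa)
            if where.size == 0:
                continue
            members = fam_members[aa]
            p = probs[members]
            draws = rng.choice(len(members), size=where.size, p=p / p.sum())
            for pos, d in zip(where, draws):
                codons[pos] = features.codons[members[d]]
        seq = "AUG" + "".join(codons) + stops[rng.integers(len(stops))]
        gene_id = f"gene_{g:05d}"
        records.append(GeneRecord(id=gene_id, seq=dna(seq)))
        truth_rows.append(
            dict(gene=gene_id, Sc=sc_g, St=st_g, abundance=float(np.exp(log_ab[g])))
        )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["seed"] = spec.seed
    return records, truth


def simulate_rates(
    truth: pd.DataFrame,
    a: float = 1.0,
    b: float = 0.005,
    a_prime: float = 0.5,
    b_prime: float = 0.003,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic Ka/Ks rates linear in optimality: Ks = a - b*optimality + e.

    ``truth`` must carry gene and optimality columns. Rates are truncated
    at zero. Returns columns gene, Ka, Ks, optimality.
    """
    if "optimality" not in truth.columns:
        raise ValueError("truth table must carry an 'optimality' column")
    rng = np.random.default_rng(seed)
    opt = truth["optimality"].to_numpy(dtype=float)
    ks = np.maximum(0.0, a - b * opt + rng.normal(0.0, noise_sd, size=len(opt)))
    ka = np.maximum(0.0, a_prime - b_prime * opt + rng.normal(0.0, noise_sd, size=len(opt)))
    return pd.DataFrame(
        {"gene": truth["gene"], "Ka": ka, "Ks": ks, "optimality": opt}
    )
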