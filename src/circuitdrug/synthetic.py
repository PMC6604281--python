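"""Synthetic cohort generators with known ground truth.

Three designs, mirroring the data the pipeline consumes:

* a *regulator cohort*: unit-scale expression for a panel of candidate
  drug-target (KDT) genes plus the pathway genes, where a small planted set
  of KDT genes statistically drives pathway-gene expression — the training
  design for the relevance model;
* a *case/control cohort* with an expression shift planted on the genes of
  chosen circuits — the differential-testing design;
* a *count matrix* with negative-binomial noise, variable sequencing depth
  and an optional composition bias — the input to the normalization chain.

Every generator is a pure function of its parameters and seed; each returns
a ``SimulationTruth`` that fully describes what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .knowledge_base import PathwayGraph
from .mechanistic import extract_circuits
from .preprocess import ExpressionMatrix


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    seed: int
    regulator_genes: tuple[str, ...] = ()
    weights: pd.DataFrame | None = None  # pathway genes x regulators
    shifted_circuits: tuple[str, ...] = ()
    shift: float = 0.0

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "regulator_genes": list(self.regulator_genes),
            "shifted_circuits": list(self.shifted_circuits),
            "shift": self.shift,
            "weights": None if self.weights is None else self.weights.to_dict(),
        }


def _pathway_gene_order(graph: PathwayGraph) -> list[str]:
    return sorted(graph.gene_symbols)


def simulate_regulator_cohort(
    n_samples: int,
    n_kdt: int,
    n_regulators: int,
    effect_size: float,
    noise_sd: float,
    graph: PathwayGraph,
    seed: int,
    baseline_low: float = 0.1,
    baseline_high: float = 0.3,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Multi-tissue-like cohort where planted KDT genes drive pathway genes.

    KDT expression is i.i.d. Beta(2, 2).  Each pathway gene j gets

        g_j = clip_[0,1]( alpha_j + effect_size * sum_k w_jk r_k + eps ),

    with eps ~ Normal(0, noise_sd), baseline alpha_j ~ U(baseline_low,
    baseline_high), and w_jk nonzero only for the ``n_regulators`` planted
    KDT genes.  Regulation is sparse — each pathway gene is assigned one
    regulator (w_jk = 1 for it, 0 elsewhere), the usual structure of
    transcriptional control and the one under which the planted signal
    survives the propagation model at realistic noise.  The returned matrix
    stacks KDT genes and pathway genes.
    """
    if n_regulators > n_kdt:
        raise ValueError("n_regulators cannot exceed n_kdt")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    kdt_genes = [f"KDT{i:04d}" for i in range(1, n_kdt + 1)]
    pathway_genes = _pathway_gene_order(graph)
    overlap = set(kdt_genes) & set(pathway_genes)
    if overlap:
        raise ValueError(f"KDT symbols collide with pathway genes: {overlap}")
    regulators = tuple(sorted(rng.choice(kdt_genes, size=n_regulators, replace=False)))
    r = rng.beta(2.0, 2.0, size=(n_kdt, n_samples))
    kdt_df = pd.DataFrame(r, index=kdt_genes)
    alpha = rng.uniform(baseline_low, baseline_high, size=len(pathway_genes))
    assignment = rng.integers(n_regulators, size=len(pathway_genes))
    w = np.zeros((len(pathway_genes), n_regulators))
    w[np.arange(len(pathway_genes)), assignment] = 1.0
    reg_expr = kdt_df.loc[list(regulators)].to_numpy()
    drive = effect_size * (w @ reg_expr)
    eps = rng.normal(0.0, noise_sd, size=(len(pathway_genes), n_samples))
    g = np.clip(alpha[:, None] + drive + eps, 0.0, 1.0)
    values = pd.DataFrame(
        np.vstack([r, g]),
        index=kdt_genes + pathway_genes,
        columns=[f"S{j:04d}" for j in range(1, n_samples + 1)],
    )
    truth = SimulationTruth(
        seed=seed,
        regulator_genes=regulators,
        weights=pd.DataFrame(w, index=pathway_genes, columns=list(regulators)),
    )
    return ExpressionMatrix(values, scale="unit"), truth


def simulate_case_control(
    n_per_group: int,
    graph: PathwayGraph,
    shifted_circuits: tuple[str, ...] | list[str],
    shift: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    exclusive: bool = True,
) -> tuple[ExpressionMatrix, pd.Series, SimulationTruth]:
    """Two-group cohort with an expression shift planted on circuit genes.

    Controls draw every pathway gene from Beta(2, 2); cases add ``shift``
    (clipped to [0, 1]) to the genes belonging to the nodes of the chosen
    circuits, plus optional Gaussian noise.  Returns (expression, labels,
    truth) with labels 'case'/'control'.

    With ``exclusive=True`` (the default) the shift touches only genes that
    belong to *no* unshifted circuit, so the planted signal is genuinely
    circuit-specific: circuits in a pathway share their upstream segment
    (here the FA core machinery), and shifting shared genes would move every
    circuit at once rather than the planted one.  ``exclusive=False`` shifts
    every gene of the shifted circuits' nodes.
    """
    shifted_circuits = tuple(shifted_circuits)
    circuit_ids = {c.circuit_id for c in extract_circuits(graph)}
    unknown = set(shifted_circuits) - circuit_ids
    if unknown:
        raise ValueError(f"unknown circuits: {sorted(unknown)}")
    if shift != 0.0 and not shifted_circuits:
        raise ValueError("nonzero shift requires at least one shifted circuit")
    if abs(shift) > 1:
        raise ValueError("|shift| must be <= 1")
    rng = np.random.default_rng(seed)
    genes = _pathway_gene_order(graph)
    n_total = 2 * n_per_group
    base = rng.beta(2.0, 2.0, size=(len(genes), n_total))
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    shifted_genes: set[str] = set()
    unshifted_genes: set[str] = set()
    for c in extract_circuits(graph):
        circuit_genes = {g for nid in c.node_ids for g in graph.nodes[nid].genes}
        if c.circuit_id in shifted_circuits:
            shifted_genes |= circuit_genes
        else:
            unshifted_genes |= circuit_genes
    if exclusive:
        shifted_genes -= unshifted_genes
        if shift != 0.0 and shifted_circuits and not shifted_genes:
            raise ValueError(
                "shifted circuits have no exclusive genes; use exclusive=False"
            )
    gene_mask = np.array([g in shifted_genes for g in genes])
    case_cols = np.arange(n_per_group, n_total)
    base[np.ix_(gene_mask, case_cols)] += shift
    values = pd.DataFrame(
        np.clip(base, 0.0, 1.0),
        index=genes,
        columns=[f"S{j:04d}" for j in range(1, n_total + 1)],
    )
    labels = pd.Series(
        ["control"] * n_per_group + ["case"] * n_per_group, index=values.columns
    )
    truth = SimulationTruth(
        seed=seed, shifted_circuits=shifted_circuits, shift=shift
    )
    return ExpressionMatrix(values, scale="unit"), labels, truth


def simulate_counts(
    n_genes: int,
    n_samples: int,
    frac_biased: float = 0.0,
    fold: float = 1.0,
    depth_range: tuple[float, float] = (1e6, 3e6),
    dispersion: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Negative-binomial count matrix with depth variation and composition bias.

    Per-gene relative abundances are log-normal; per-sample depths are drawn
    uniformly from ``depth_range``; a ``frac_biased`` fraction of genes is
    multiplied by ``fold`` in the second half of the samples (the classic
    asymmetric composition bias TMM is designed to absorb).  Counts are
    gamma-Poisson with the given dispersion.
    """
    if not (0 <= frac_biased < 1):
        raise ValueError("frac_biased must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rel = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    rel /= rel.sum()
    depths = rng.uniform(depth_range[0], depth_range[1], size=n_samples)
    mu = np.outer(rel, depths)
    n_biased = int(round(frac_biased * n_genes))
    if n_biased > 0 and fold != 1.0:
        biased_genes = rng.choice(n_genes, size=n_biased, replace=False)
        half = n_samples // 2
        mu[np.ix_(biased_genes, np.arange(half, n_samples))] *= fold
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)
    values = pd.DataFrame(
        counts,
        index=[f"G{i:05d}" for i in range(1, n_genes + 1)],
        columns=[f"S{j:04d}" for j in range(1, n_samples + 1)],
    )
    return ExpressionMatrix(values, scale="counts")
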