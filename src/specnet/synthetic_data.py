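"""Seeded generators for synthetic inputs with the structure the analysis assumes.

Counts follow a negative-binomial model with protein-size-dependent means,
per-sample library factors and a planted differentially-expressed subset;
the network is a stochastic block model whose score distributions make a
0.4 threshold retain module structure; annotations concentrate one term per
planted module; the transcript table carries a controlled overlap against
the planted up-regulated proteins.

A single global seed feeds independent per-operation streams so each stage
can be regenerated in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io_tables import MEAN_RESIDUE_MASS, WATER_MASS, SpectralCountTable

logger = logging.getLogger(__name__)

# substream ids: keep stable so stages regenerate independently
_STREAM_COUNTS = 0
_STREAM_NETWORK = 1
_STREAM_ANNOTATIONS = 2
_STREAM_TRANSCRIPTS = 3


@dataclass
class SimConfig:
    """Parameters of the synthetic 2-group spectral-counting experiment."""

    n_proteins: int = 500
    n_per_group: int = 3
    baseline_scale: float = 0.05
    length_exponent: float = 1.0
    abundance_sigma: float = 1.0
    dispersion: float = 0.2
    library_factors: list[float] | None = None
    de_fraction: float = 0.1
    lfc_mean: float = 1.5
    lfc_sd: float = 0.5
    n_modules: int = 4
    module_size: int = 15
    p_in: float = 0.9
    p_out: float = 0.02
    term_coverage: float = 0.9
    background_fraction: float = 0.05
    transcript_overlap: float = 0.5
    n_transcript_noise: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 for any differential design")
        for name in ("baseline_scale", "abundance_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("de_fraction", "transcript_overlap", "p_in", "p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.term_coverage <= 1.0:
            raise ValueError("term_coverage must be in (0, 1]")
        if self.background_fraction < 0:
            raise ValueError("background_fraction must be >= 0")
        if self.n_modules * self.module_size > self.n_proteins:
            raise ValueError("n_modules * module_size must be <= n_proteins")
        n_samples = 2 * self.n_per_group
        if self.library_factors is not None:
            if len(self.library_factors) != n_samples:
                raise ValueError(
                    f"library_factors must have length {n_samples}, got {len(self.library_factors)}"
                )
            if any(f <= 0 for f in self.library_factors):
                raise ValueError("library_factors must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SimTruth:
    """Ground truth planted by the generators."""

    de_log2fc: dict[str, float]            # accession -> signed true log2 FC
    gene_of: dict[str, str]                # accession -> gene symbol
    module_labels: dict[str, int]          # gene symbol -> module index
    module_terms: dict[int, str]           # module index -> planted term id
    transcript_overlap: set[str] = field(default_factory=set)  # gene symbols
    expected_mean: pd.DataFrame | None = None  # mu_ij of the count model

    @property
    def de_up_genes(self) -> set[str]:
        return {self.gene_of[a] for a, b in self.de_log2fc.items() if b > 0}

    @property
    def de_down_genes(self) -> set[str]:
        return {self.gene_of[a] for a, b in self.de_log2fc.items() if b < 0}


def _accessions(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def _genes(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def gen_counts(config: SimConfig) -> tuple[SpectralCountTable, pd.DataFrame, SimTruth]:
    """Simulate the count table, protein metadata and ground truth.

    Mean model per protein i, sample j:
        mu_ij = baseline_scale * L_i**alpha * a_i * lib_j * 2**(beta_i * g_j)
    with a_i lognormal(0, abundance_sigma), L_i the simulated length,
    beta_i the planted signed log2 fold change (0 outside the DE set) and
    g_j = 1 for the case group.  Counts are negative binomial with
    variance mu + dispersion * mu**2 (Poisson when dispersion == 0).
    """
    rng = config.rng(_STREAM_COUNTS)
    n = config.n_proteins
    acc = _accessions(n)
    genes = _genes(n)

    lengths = np.maximum(50, rng.lognormal(mean=6.0, sigma=0.6, size=n)).astype(int)
    mass_kda = (lengths * MEAN_RESIDUE_MASS + WATER_MASS) / 1000.0
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)

    n_de = round(config.de_fraction * n)
    de_idx = np.sort(rng.choice(n, size=n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    beta = np.zeros(n)
    beta[de_idx] = signs * np.abs(rng.normal(config.lfc_mean, config.lfc_sd, size=n_de))

    n_samples = 2 * config.n_per_group
    samples = [f"C{j + 1}" for j in range(config.n_per_group)] + [
        f"I{j + 1}" for j in range(config.n_per_group)
    ]
    groups = {s: ("control" if s.startswith("C") else "injured") for s in samples}
    g = np.array([0] * config.n_per_group + [1] * config.n_per_group)
    lib = (
        np.asarray(config.library_factors, dtype=float)
        if config.library_factors is not None
        else np.ones(n_samples)
    )

    base = config.baseline_scale * lengths ** config.length_exponent * abundance
    mu = base[:, None] * lib[None, :] * 2.0 ** (beta[:, None] * g[None, :])
    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        p = 1.0 / (1.0 + config.dispersion * mu)
        counts = rng.negative_binomial(r, p)

    unique = np.where(counts > 0, np.maximum(1, np.ceil(counts / 5)), 0).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=acc, columns=samples, dtype=np.int64)
    unique_df = pd.DataFrame(unique, index=acc, columns=samples)
    table = SpectralCountTable(counts=counts_df, groups=groups, unique_peptides=unique_df)

    meta = pd.DataFrame(
        {
            "gene_symbol": genes,
            "description": [f"simulated protein {a}" for a in acc],
            "mass_kda": mass_kda,
            "ecm_category": "other",
        },
        index=pd.Index(acc, name="accession"),
    )

    module_labels = {
        genes[m * config.module_size + j]: m
        for m in range(config.n_modules)
        for j in range(config.module_size)
    }
    truth = SimTruth(
        de_log2fc={acc[i]: float(beta[i]) for i in de_idx},
        gene_of=dict(zip(acc, genes)),
        module_labels=module_labels,
        module_terms={m: f"TERM{m:03d}" for m in range(config.n_modules)},
        expected_mean=pd.DataFrame(mu, index=acc, columns=samples),
    )
    # overlap subset of up-regulated DE genes, drawn on the counts stream so
    # truth is complete after gen_counts
    up_genes = sorted(truth.de_up_genes)
    k = round(config.transcript_overlap * len(up_genes))
    truth.transcript_overlap = set(
        rng.choice(up_genes, size=k, replace=False)
    ) if k else set()
    return table, meta, truth


def gen_network(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Stochastic-block-model edge table over the planted module members.

    Within-module pairs connect with probability p_in and score
    Uniform(0.6, 1.0); cross-module pairs with p_out and Uniform(0.15, 0.5),
    so a 0.4 threshold preferentially keeps module structure.
    """
    if config.p_in <= config.p_out:
        logger.warning("p_in <= p_out: module recovery is not guaranteed")
    rng = config.rng(_STREAM_NETWORK)
    nodes = sorted(truth.module_labels)
    rows = []
    for a, b in combinations(nodes, 2):
        same = truth.module_labels[a] == truth.module_labels[b]
        p = config.p_in if same else config.p_out
        if rng.random() < p:
            lo, hi = (0.6, 1.0) if same else (0.15, 0.5)
            rows.append((a, b, float(rng.uniform(lo, hi))))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "score"])


def gen_annotations(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """One term per planted module covering ``term_coverage`` of its members,
    plus uniformly drawn background genes."""
    rng = config.rng(_STREAM_ANNOTATIONS)
    all_genes = sorted(set(truth.gene_of.values()))
    rows = []
    for m, term in sorted(truth.module_terms.items()):
        members = sorted(g for g, lab in truth.module_labels.items() if lab == m)
        k = round(config.term_coverage * len(members))
        chosen = sorted(rng.choice(members, size=k, replace=False)) if k else []
        outside = sorted(set(all_genes) - set(members))
        n_bg = round(config.background_fraction * len(members))
        bg = sorted(rng.choice(outside, size=min(n_bg, len(outside)), replace=False)) if n_bg else []
        for gsym in chosen + bg:
            rows.append((term, f"planted term {m}", "BP", gsym))
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace", "gene_symbol"])
    return df.drop_duplicates(subset=["term_id", "gene_symbol"]).reset_index(drop=True)


def gen_transcripts(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Transcript DE table: the planted overlap genes marked up (p <= 0.05,
    FC = 2**|beta|) plus noise entries under invented symbols absent from the
    proteome (unmatched probes)."""
    rng = config.rng(_STREAM_TRANSCRIPTS)
    gene_beta = {truth.gene_of[a]: b for a, b in truth.de_log2fc.items()}
    rows = []
    for gsym in sorted(truth.transcript_overlap):
        fc = float(2.0 ** abs(gene_beta.get(gsym, 1.0)))
        rows.append((gsym, fc, float(rng.uniform(0.001, 0.05)), "up"))
    for i in range(config.n_transcript_noise):
        up = bool(rng.random() < 0.5)
        fc = float(2.0 ** rng.uniform(0.3, 2.5))
        if not up:
            fc = 1.0 / fc
        rows.append(
            (f"PROBE{i:04d}", fc, float(rng.uniform(0.0, 1.0)), "up" if up else "down")
        )
    return pd.DataFrame(rows, columns=["gene_symbol", "fold_change", "p_value", "direction"])
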