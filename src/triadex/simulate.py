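"""Synthetic triad data with planted ground truth.

Generates everything the downstream pipeline consumes — negative-binomial
count matrices for a (female parent, male parent, hybrid) triad, phenotype
replicates with a planted mid-parent heterosis, gene→term annotation maps
with an optionally enriched term, and qPCR CT tables derived from counts —
together with a truth table recording each gene's planted inheritance mode
and expected group means.

Counts for gene g in sample s are drawn NB(mean μ_g,group · L_s, var
μ + αμ²), where L_s is a per-sample library-size factor (log-uniform) and
α the NB dispersion; α = 0 degenerates to Poisson.  Hybrid means are set
from the planted mode:

==========  =======================================================
conserved   μ_H = μ_F = μ_M
additive    parents differ by ``effect_log2``; μ_H = (μ_F + μ_M)/2
eldF        parents differ; μ_H = μ_F
eldM        parents differ; μ_H = μ_M
od_up       μ_H = max(μ_F, μ_M) · 2^effect_log2
od_down     μ_H = min(μ_F, μ_M) · 2^−effect_log2
==========  =======================================================

Within additive/ELD modes the parent order (F>M or F<M) is drawn
uniformly; overdominant modes additionally allow equal parents.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .patterns import classify_gene, relations_from_means

MODES = ("conserved", "additive", "eldF", "eldM", "od_up", "od_down")

DEFAULT_PROPORTIONS: Dict[str, float] = {
    "conserved": 0.5,
    "additive": 0.1,
    "eldF": 0.1,
    "eldM": 0.1,
    "od_up": 0.1,
    "od_down": 0.1,
}

DEFAULT_GROUPS: Tuple[Tuple[str, str], ...] = (
    ("F", "female_parent"),
    ("M", "male_parent"),
    ("FO", "hybrid"),
)


@dataclasses.dataclass
class SimConfig:
    """Parameters of a simulated triad experiment.

    Defaults mirror a three-replicate, two-time-point seedling design with
    a two-fold-per-unit effect size (``effect_log2 = 2`` means planted
    parent contrasts and overdominance offsets of 4-fold).
    """

    n_genes: int = 2000
    n_replicates: int = 3
    groups: Tuple[Tuple[str, str], ...] = DEFAULT_GROUPS
    time_points: int = 2
    baseline_mean_log2: float = 7.0
    baseline_sd_log2: float = 2.0
    dispersion: float = 0.05
    libsize_factor_range: Tuple[float, float] = (0.7, 1.4)
    class_proportions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    effect_log2: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.time_points < 1:
            raise ValueError("time_points must be >= 1")
        lo, hi = self.libsize_factor_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_factor_range must be a positive interval")
        props = dict(self.class_proportions)
        unknown = set(props) - set(MODES)
        if unknown:
            raise ValueError(f"unknown inheritance modes: {sorted(unknown)}")
        vals = np.array([props.get(m, 0.0) for m in MODES], dtype=float)
        if (vals < 0).any():
            raise ValueError("class proportions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        roles = [r for _, r in self.groups]
        for role in ("female_parent", "male_parent", "hybrid"):
            if roles.count(role) != 1:
                raise ValueError(f"groups must contain exactly one {role}")

    def role_genotype(self, role: str) -> str:
        for g, r in self.groups:
            if r == role:
                return g
        raise KeyError(role)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws parameterised by (mean, dispersion): Var = μ + αμ²."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha  # NB shape; p = size / (size + mean)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _plant_means(
    rng: np.random.Generator, config: SimConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-gene modes and expected (μ_F, μ_M, μ_H) on the count scale."""
    n = config.n_genes
    props = np.array(
        [dict(config.class_proportions).get(m, 0.0) for m in MODES], dtype=float
    )
    modes = rng.choice(len(MODES), size=n, p=props)
    base = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n)
    half = config.effect_log2 / 2.0
    # parent sub-pattern: 0 -> F high, 1 -> M high, 2 -> equal (OD only)
    sub2 = rng.integers(0, 2, size=n)
    sub3 = rng.integers(0, 3, size=n)

    mu_f = np.empty(n)
    mu_m = np.empty(n)
    mu_h = np.empty(n)
    for i in range(n):
        mode = MODES[modes[i]]
        b = base[i]
        if mode == "conserved":
            f = m = 2.0 ** b
            h = f
        elif mode in ("additive", "eldF", "eldM"):
            hi, lo = 2.0 ** (b + half), 2.0 ** (b - half)
            f, m = (hi, lo) if sub2[i] == 0 else (lo, hi)
            if mode == "additive":
                h = 0.5 * (f + m)
            elif mode == "eldF":
                h = f
            else:
                h = m
        else:  # overdominant: parents may also be equal
            if sub3[i] == 2:
                f = m = 2.0 ** b
            else:
                hi, lo = 2.0 ** (b + half), 2.0 ** (b - half)
                f, m = (hi, lo) if sub3[i] == 0 else (lo, hi)
            if mode == "od_up":
                h = max(f, m) * 2.0 ** config.effect_log2
            else:
                h = min(f, m) * 2.0 ** (-config.effect_log2)
        mu_f[i], mu_m[i], mu_h[i] = f, m, h
    return modes, mu_f, mu_m, mu_h


def simulate_triad_counts(
    config: SimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a triad count matrix with planted inheritance modes.

    Returns
    -------
    counts : DataFrame
        Genes × samples integer matrix, gene ids in the index.
    samples : DataFrame
        Sample sheet with columns sample_id, genotype, role, time_point,
        replicate (one row per sample; triad means are constant across
        time points).
    truth : DataFrame
        Per-gene planted mode, planted class (rule table applied to the
        true means) and expected normalised means μ_F, μ_M, μ_H.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    modes, mu_f, mu_m, mu_h = _plant_means(rng, config)

    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    role_mu = {"female_parent": mu_f, "male_parent": mu_m, "hybrid": mu_h}

    rows: List[dict] = []
    columns: Dict[str, np.ndarray] = {}
    lo, hi = config.libsize_factor_range
    for t in range(1, config.time_points + 1):
        for genotype, role in config.groups:
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{genotype}_T{t}_r{rep}"
                lib = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                counts = _nb_draw(rng, role_mu[role] * lib, config.dispersion)
                columns[sample_id] = counts.astype(np.int64)
                rows.append(
                    dict(
                        sample_id=sample_id,
                        genotype=genotype,
                        role=role,
                        time_point=f"T{t}",
                        replicate=rep,
                    )
                )

    counts_df = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    samples_df = pd.DataFrame(rows)

    planted_class = []
    for i in range(config.n_genes):
        cls = classify_gene(*relations_from_means(mu_f[i], mu_m[i], mu_h[i]))
        planted_class.append(str(cls))
    truth_df = pd.DataFrame(
        {
            "planted_mode": [MODES[m] for m in modes],
            "planted_class": planted_class,
            "mu_F": mu_f,
            "mu_M": mu_m,
            "mu_H": mu_h,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return counts_df, samples_df, truth_df


def simulate_phenotypes(
    trait_means: Mapping[str, float],
    trait_sd: float,
    n_plants: int,
    seed: int,
    trait: str = "root_length",
    time_point: str = "T1",
) -> pd.DataFrame:
    """Normal per-plant trait draws for each genotype.

    ``trait_means`` maps genotype label → true mean.  The planted
    mid-parent heterosis of a triad (F, M, H) is
    ``(μ_H − (μ_F+μ_M)/2) / ((μ_F+μ_M)/2) · 100``.
    """
    if trait_sd < 0:
        raise ValueError("trait_sd must be >= 0")
    if n_plants < 2:
        raise ValueError("n_plants must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, mu in trait_means.items():
        values = rng.normal(mu, trait_sd, size=n_plants)
        for rep, v in enumerate(values, start=1):
            rows.append(
                dict(
                    genotype=genotype,
                    trait=trait,
                    time_point=time_point,
                    replicate=rep,
                    value=float(v),
                )
            )
    return pd.DataFrame(rows)


def simulate_annotation(
    genes: Sequence[str],
    n_terms: int,
    term_size_range: Tuple[int, int],
    enriched_term: Optional[Tuple[str, Sequence[str]]] = None,
    seed: int = 0,
) -> Dict[str, set]:
    """Random gene→term map, optionally with one planted enriched term.

    Term sizes are uniform over ``term_size_range``; members are sampled
    without replacement from ``genes``.  If ``enriched_term`` is given as
    ``(term_id, gene_subset)``, that term contains exactly that subset.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be non-empty")
    lo, hi = term_size_range
    if hi > len(genes):
        raise ValueError("term sizes cannot exceed the number of genes")
    rng = np.random.default_rng(seed)
    annotation: Dict[str, set] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        annotation[f"TERM{i:04d}"] = {genes[j] for j in members}
    if enriched_term is not None:
        term_id, subset = enriched_term
        subset = set(subset)
        if not subset <= set(genes):
            raise ValueError("enriched term subset must be drawn from genes")
        annotation[term_id] = subset
    return annotation


def simulate_ct_table(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genes: Sequence[str],
    reference_gene: str = "Actin",
    ct_offset: float = 35.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Derive a qPCR CT table from simulated counts.

    CT cycles fall by one per doubling of template, so each target gene's
    CT is ``ct_offset − log2(normalised count + 1)`` plus Gaussian noise;
    the reference gene gets a constant CT (equal expression everywhere).
    Used to test RNA-seq/qPCR concordance by construction.
    """
    rng = np.random.default_rng(seed)
    lib = counts.sum(axis=0) / counts.sum(axis=0).mean()
    rows = []
    for _, s in samples.iterrows():
        sid = s["sample_id"]
        for gene in genes:
            norm = counts.at[gene, sid] / lib[sid]
            ct = ct_offset - np.log2(norm + 1.0) + rng.normal(0, noise_sd)
            rows.append(
                dict(
                    sample_id=sid,
                    genotype=s["genotype"],
                    gene=gene,
                    replicate=s["replicate"],
                    CT=float(ct),
                )
            )
        rows.append(
            dict(
                sample_id=sid,
                genotype=s["genotype"],
                gene=reference_gene,
                replicate=s["replicate"],
                CT=float(20.0 + rng.normal(0, noise_sd)),
            )
        )
    return pd.DataFrame(rows)
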