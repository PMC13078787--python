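"""Synthetic data generator for the Raman-proteome correspondence pipeline.

Emulates the structure of a study in which bulk proteomes of a microbe are
quantified under ``m`` growth conditions with known growth rates, while
single-cell Raman spectra are measured under the same conditions. The
generated proteome plants a stoichiometry-conserving architecture:

* a large *homeostatic core* whose members all follow the growth law
  (abundance proportional to growth rate, one shared pattern),
* several condition-specific groups, each sharing one pattern (the first
  grows exponentially with growth rate; the others peak in one condition),
* background proteins with independent random condition profiles.

Spectra are built from the proteome through a fixed linear protein-to-
spectrum map (sparse Gaussian-peak signatures), so the linear Raman-omics
correspondence holds by construction up to the configured noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SpectraSet

__all__ = [
    "GeneratorConfig",
    "make_conditions",
    "make_proteome",
    "make_spectra",
    "make_annotations",
    "simulate_dataset",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    The defaults mirror the scale of the emulated study: n=2058 protein
    species, m=15 conditions, a growth-law core of 191 proteins and
    condition-specific groups of sizes 26, 20, 10, 9, with 15 cells per
    condition per replicate, 3 replicates, and spectra on a 1 cm^-1 grid
    over 632-1862 cm^-1 (1231 channels).
    """

    n_proteins: int = 2058
    m_conditions: int = 15
    core_size: int = 191
    specific_group_sizes: tuple[int, ...] = (26, 20, 10, 9)
    noise_cv: float = 0.1
    cells_per_condition: int = 15
    replicates: int = 3
    channel_count: int = 1231
    wavenumber_range: tuple[float, float] = (632.0, 1862.0)
    spectral_noise_sd: float = 0.02
    cell_scale_cv: float = 0.05
    growth_rate_range: tuple[float, float] = (0.05, 2.0)
    amplitude_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.m_conditions < 2:
            raise ValueError("need n_proteins >= 1 and m_conditions >= 2")
        if self.core_size < 0 or any(s < 0 for s in self.specific_group_sizes):
            raise ValueError("group sizes must be non-negative")
        if self.core_size + sum(self.specific_group_sizes) > self.n_proteins:
            raise ValueError("core_size + specific group sizes exceed n_proteins")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.spectral_noise_sd < 0 or self.cell_scale_cv < 0:
            raise ValueError("noise levels must be non-negative")


def make_conditions(
    m: int,
    growth_rate_range: tuple[float, float] = (0.05, 2.0),
    seed: int = 0,
    replicate_count: int = 3,
) -> pd.DataFrame:
    """Condition table with growth rates spread across the given range.

    Rates are evenly spaced over the closed range with a small seeded
    jitter (except at the endpoints), which keeps them distinct, inside
    the range, and deterministic under the seed.
    """
    if m < 2:
        raise ValueError("at least 2 conditions are required")
    lo, hi = growth_rate_range
    if lo < 0 or not lo < hi:
        raise ValueError("growth_rate_range must satisfy 0 <= lo < hi")
    rng = np.random.default_rng(seed)
    rates = np.linspace(lo, hi, m)
    if m > 2:
        step = (hi - lo) / (m - 1)
        rates[1:-1] += rng.uniform(-0.3, 0.3, size=m - 2) * step
    return pd.DataFrame(
        {
            "condition_id": [f"cond{j + 1:02d}" for j in range(m)],
            "growth_rate": rates,
            "replicate_count": replicate_count,
        }
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=shape)


def _group_patterns(mu: np.ndarray, n_specific: int, rng: np.random.Generator) -> np.ndarray:
    """Shared condition patterns: growth-law core, exponential group, peaked groups."""
    m = mu.size
    patterns = [mu.copy()]  # core: growth law, zero intercept
    if n_specific >= 1:
        # fast-growth group: exponential in growth rate, max/min ratio ~ 30
        b = math.log(30.0) / (mu.max() - mu.min())
        patterns.append(np.exp(b * (mu - mu.min())))
    if n_specific >= 2:
        # each remaining group peaks in one distinct condition
        peak_conditions = rng.permutation(m)[: n_specific - 1]
        for c in peak_conditions:
            pat = np.full(m, 0.05)
            pat[c] = 1.0
            patterns.append(pat)
    return np.asarray(patterns[: n_specific + 1])


def make_proteome(
    cfg: GeneratorConfig, conditions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the n x m abundance matrix and its ground-truth table.

    Returns
    -------
    proteome : DataFrame, index = protein ids, columns = condition ids.
    truth : DataFrame with per-protein ``group``, ``amplitude``,
        ``signature_index`` and the planted centrality rank percentile
        ``planted_rank`` (1 = most central).
    """
    m = len(conditions)
    if m != cfg.m_conditions:
        raise ValueError(
            f"condition table has {m} rows but cfg.m_conditions={cfg.m_conditions}"
        )
    rng = np.random.default_rng(cfg.seed)
    mu = conditions["growth_rate"].to_numpy(dtype=float)

    sizes = [cfg.core_size, *cfg.specific_group_sizes]
    sizes = [s for s in sizes if s > 0]
    n_background = cfg.n_proteins - sum(sizes)
    patterns = _group_patterns(mu, len(sizes) - 1, rng)

    X = np.empty((cfg.n_proteins, m))
    groups = np.empty(cfg.n_proteins, dtype=object)
    amplitudes = rng.lognormal(mean=0.0, sigma=cfg.amplitude_sigma, size=cfg.n_proteins)

    row = 0
    for gi, size in enumerate(sizes):
        label = "core" if gi == 0 else f"scg{gi + 1}"
        X[row : row + size] = amplitudes[row : row + size, None] * patterns[gi][None, :]
        groups[row : row + size] = label
        row += size
    if n_background:
        bg = rng.lognormal(mean=0.0, sigma=0.5, size=(n_background, m))
        X[row:] = amplitudes[row:, None] * bg
        groups[row:] = "background"

    X *= _lognormal_noise(rng, cfg.noise_cv, X.shape)

    protein_ids = [f"prot{i + 1:04d}" for i in range(cfg.n_proteins)]
    proteome = pd.DataFrame(X, index=protein_ids, columns=conditions["condition_id"])
    proteome.index.name = "protein_id"

    # planted centrality ordering: core first, then specific groups by size,
    # then background; used by the annotation generator
    order = np.arange(cfg.n_proteins)
    rank = np.empty(cfg.n_proteins)
    rank[order] = np.arange(cfg.n_proteins)
    planted_rank = 1.0 - rank / max(cfg.n_proteins - 1, 1)

    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "group": groups,
            "amplitude": amplitudes,
            "signature_index": np.arange(cfg.n_proteins),
            "planted_rank": planted_rank,
        }
    ).set_index("protein_id")
    return proteome, truth


def _signature_matrix(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Fixed non-negative channels x proteins map: 3-8 Gaussian peaks each.

    Peak centers are uniform on the fingerprint region (700-1800 cm^-1
    intersected with the configured range), widths 8-25 cm^-1. Columns are
    scaled to unit total intensity so a spectrum is a signature-weighted
    average of abundances.
    """
    lo, hi = cfg.wavenumber_range
    w = np.linspace(lo, hi, cfg.channel_count)
    center_lo, center_hi = max(lo, 700.0), min(hi, 1800.0)
    if center_lo >= center_hi:
        center_lo, center_hi = lo, hi
    S = np.zeros((cfg.channel_count, cfg.n_proteins))
    for i in range(cfg.n_proteins):
        k = rng.integers(3, 9)
        centers = rng.uniform(center_lo, center_hi, size=k)
        widths = rng.uniform(8.0, 25.0, size=k)
        heights = rng.uniform(0.5, 1.0, size=k)
        S[:, i] = (heights[None, :] * np.exp(
            -0.5 * ((w[:, None] - centers[None, :]) / widths[None, :]) ** 2
        )).sum(axis=1)
    S /= S.sum(axis=0, keepdims=True)
    return S


def make_spectra(
    proteome: pd.DataFrame, truth: pd.DataFrame, cfg: GeneratorConfig
) -> SpectraSet:
    """Single-cell spectra: spectrum = S . p_j * eta + eps.

    ``S`` is the fixed signature matrix, ``eta`` a per-cell lognormal scale
    (overall intensity variation), ``eps`` i.i.d. Gaussian channel noise.
    """
    if cfg.channel_count < 8:
        raise ValueError("channel_count must be >= 8 so the smoothing window fits")
    if proteome.shape != (cfg.n_proteins, cfg.m_conditions):
        raise ValueError(
            f"proteome shape {proteome.shape} inconsistent with cfg "
            f"({cfg.n_proteins}, {cfg.m_conditions})"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    S = _signature_matrix(cfg, rng)
    clean = S @ proteome.to_numpy()  # channels x conditions

    n_cells = cfg.m_conditions * cfg.replicates * cfg.cells_per_condition
    lo, hi = cfg.wavenumber_range
    wavenumbers = np.linspace(lo, hi, cfg.channel_count)

    intensities = np.empty((n_cells, cfg.channel_count))
    condition = np.empty(n_cells, dtype=object)
    replicate = np.empty(n_cells, dtype=object)
    cell_id = np.empty(n_cells, dtype=object)
    eta = _lognormal_noise(rng, cfg.cell_scale_cv, n_cells)

    row = 0
    for j, cond in enumerate(proteome.columns):
        for rep in range(cfg.replicates):
            for c in range(cfg.cells_per_condition):
                eps = (
                    rng.normal(0.0, cfg.spectral_noise_sd, size=cfg.channel_count)
                    if cfg.spectral_noise_sd > 0
                    else 0.0
                )
                intensities[row] = clean[:, j] * eta[row] + eps
                condition[row] = cond
                replicate[row] = f"rep{rep + 1}"
                cell_id[row] = f"{cond}_rep{rep + 1}_cell{c + 1:02d}"
                row += 1

    return SpectraSet(
        intensities=intensities,
        wavenumbers=wavenumbers,
        condition=condition,
        replicate=replicate,
        cell_id=cell_id,
    )


def make_annotations(
    truth: pd.DataFrame,
    enrichment_strength: float = 0.5,
    seed: int = 0,
    stochastic: bool = True,
    base_essential_rate: float = 0.15,
    base_ortholog_mean: float = 40.0,
    base_coding_rate: float = 0.9,
) -> pd.DataFrame:
    """Synthetic gene-attribute table enriched along the planted centrality rank.

    Essentiality probability is logistic in the planted centrality rank
    percentile with slope controlled by ``enrichment_strength`` in [0, 1];
    ortholog counts are Poisson with a rank-increasing mean. With
    ``stochastic=False`` the flags are thresholded probabilities (a
    noise-free monotone variant).
    """
    if not 0.0 <= enrichment_strength <= 1.0:
        raise ValueError("enrichment_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rho = truth["planted_rank"].to_numpy(dtype=float)

    def logistic(p0: float, slope: float) -> np.ndarray:
        logit0 = math.log(p0 / (1.0 - p0))
        return 1.0 / (1.0 + np.exp(-(logit0 + enrichment_strength * slope * (rho - 0.5))))

    p_ess = logistic(base_essential_rate, 6.0)
    p_cod = logistic(base_coding_rate, 4.0)
    orth_mean = base_ortholog_mean * np.exp(enrichment_strength * 1.5 * (rho - 0.5))

    if stochastic:
        essential = rng.random(rho.size) < p_ess
        coding = rng.random(rho.size) < p_cod
        ortholog = rng.poisson(orth_mean)
    else:
        essential = p_ess >= 0.5
        coding = p_cod >= 0.5
        ortholog = np.round(orth_mean).astype(int)

    return pd.DataFrame(
        {
            "gene_id": truth.index,
            "essential": essential,
            "ortholog_count": ortholog,
            "coding": coding,
        }
    ).set_index("gene_id")


def simulate_dataset(cfg: GeneratorConfig | None = None, enrichment_strength: float = 0.5):
    """Generate the full synthetic study: conditions, proteome, spectra, annotations."""
    cfg = cfg or GeneratorConfig()
    conditions = make_conditions(
        cfg.m_conditions, cfg.growth_rate_range, cfg.seed, cfg.replicates
    )
    proteome, truth = make_proteome(cfg, conditions)
    spectra = make_spectra(proteome, truth, cfg)
    annotations = make_annotations(truth, enrichment_strength, seed=cfg.seed + 2)
    return {
        "config": cfg,
        "conditions": conditions,
        "proteome": proteome,
        "truth": truth,
        "spectra": spectra,
        "annotations": annotations,
    }
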