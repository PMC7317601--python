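"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the data shapes a hub-gene discovery study consumes:
a block-correlated expression matrix with planted co-expression modules (one
of which drives a sample trait), a collection of independent two-group studies
sharing a common standardized mean difference with between-study heterogeneity,
a scored interaction network with controllable degrees, survival times whose
hazard depends on a binary group, and annotated gene-set collections.

The expression model is a single-factor model per module:

    gene = noise_sd * (sqrt(r) * factor + sqrt(1 - r) * eps)

so two genes of the same module have correlation exactly ``r`` in expectation,
unassigned genes are pure noise, and the trait is the trait module's latent
factor mixed with noise so that cor(trait, factor) = trait_cor in expectation.
Everything is driven by a single integer seed; identical seed and configuration
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq


# ---------------------------------------------------------------------------
# configuration / truth containers


@dataclass
class SimulationConfig:
    """Parameters of the planted-module expression simulation.

    Attributes
    ----------
    n_genes, n_samples : int
        Matrix dimensions (genes x samples).
    module_sizes : list of int
        Gene count of each planted module; the remainder is unassigned noise.
    within_module_cor : float in [0, 1)
        Expected pairwise correlation of genes within a module.
    trait_module : int
        Index (0-based) of the module whose latent factor drives the trait.
    trait_cor : float in [0, 1)
        Expected correlation between the trait and that latent factor.
    noise_sd : float > 0
        Overall scale of the expression values.
    seed : int
        Seed of the random stream; fixes the output exactly.
    """

    n_genes: int = 500
    n_samples: int = 100
    module_sizes: list[int] = field(default_factory=lambda: [60, 50, 40, 30])
    within_module_cor: float = 0.64
    trait_module: int = 0
    trait_cor: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        for name in ("within_module_cor", "trait_cor"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not (0 <= self.trait_module < len(self.module_sizes)):
            raise ValueError("trait_module out of range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated expression matrix.

    ``module_label`` has one entry per gene; 0 marks unassigned (noise) genes,
    modules are numbered 1..K in the order of ``SimulationConfig.module_sizes``.
    ``latent_factors`` is a (K x n_samples) array of the module factors and
    ``trait`` the sample-length trait vector.
    """

    module_label: np.ndarray
    latent_factors: np.ndarray
    trait: np.ndarray

    def trait_module_genes(self, genes: list[str], trait_module: int = 0) -> list[str]:
        """Names of the genes planted in the trait-driving module."""
        mask = self.module_label == trait_module + 1
        return [g for g, m in zip(genes, mask) if m]


@dataclass
class StudyTable:
    """Per-sample values of one two-group study."""

    study_id: str
    case: np.ndarray
    control: np.ndarray


# ---------------------------------------------------------------------------
# generators


def generate_modular_expression(config: SimulationConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate a genes x samples matrix with planted co-expression modules.

    Returns the expression matrix (DataFrame, genes x samples) and the
    :class:`PlantedTruth` describing labels, latent factors and the trait.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_g, n_s = config.n_genes, config.n_samples
    k = len(config.module_sizes)
    r = config.within_module_cor

    factors = rng.standard_normal((k, n_s))
    labels = np.zeros(n_g, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes):
        labels[start : start + size] = m + 1
        start += size

    eps = rng.standard_normal((n_g, n_s))
    values = np.empty((n_g, n_s))
    noise_rows = labels == 0
    values[noise_rows] = eps[noise_rows]
    for m in range(k):
        rows = labels == m + 1
        values[rows] = np.sqrt(r) * factors[m] + np.sqrt(1.0 - r) * eps[rows]
    values *= config.noise_sd

    t = config.trait_cor
    trait = t * factors[config.trait_module] + np.sqrt(1.0 - t * t) * rng.standard_normal(n_s)

    genes = [f"G{i:04d}" for i in range(n_g)]
    samples = [f"S{j:04d}" for j in range(n_s)]
    expr = pd.DataFrame(values, index=genes, columns=samples)
    return expr, PlantedTruth(module_label=labels, latent_factors=factors, trait=trait)


def generate_multi_study(
    k_studies: int,
    n_cases: list[int] | np.ndarray,
    n_controls: list[int] | np.ndarray,
    true_smd: float,
    tau: float,
    seed: int,
) -> list[StudyTable]:
    """Simulate K two-group studies sharing a common effect.

    Study i draws its own effect delta_i ~ Normal(true_smd, tau^2), then
    per-sample values Normal(0, 1) for controls and Normal(delta_i, 1) for
    cases. ``tau`` is the between-study heterogeneity SD.
    """
    if k_studies < 2:
        raise ValueError("need at least 2 studies")
    if len(n_cases) != k_studies or len(n_controls) != k_studies:
        raise ValueError("group-size lists must have length k_studies")
    if any(n < 3 for n in n_cases) or any(n < 3 for n in n_controls):
        raise ValueError("every group needs at least 3 samples")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    rng = np.random.default_rng(seed)
    studies = []
    for i in range(k_studies):
        delta = rng.normal(true_smd, tau) if tau > 0 else true_smd
        case = rng.normal(delta, 1.0, size=int(n_cases[i]))
        control = rng.normal(0.0, 1.0, size=int(n_controls[i]))
        studies.append(StudyTable(study_id=f"study{i + 1}", case=case, control=control))
    return studies


def studies_to_long(studies: list[StudyTable]) -> pd.DataFrame:
    """Flatten study tables into the long-form TSV layout (study, group, value)."""
    rows = []
    for s in studies:
        rows.extend((s.study_id, "case", v) for v in s.case)
        rows.extend((s.study_id, "control", v) for v in s.control)
    return pd.DataFrame(rows, columns=["study", "group", "value"])


def generate_interaction_network(
    genes: list[str],
    mean_degree: float,
    score_range: tuple[float, float] = (0.4, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an undirected scored interaction network (Erdos-Renyi).

    Edge probability is ``mean_degree / (n - 1)`` so the expected degree of a
    node is ``mean_degree``; scores are uniform in ``score_range``. No
    self-edges, no duplicate pairs.
    """
    n = len(genes)
    if n == 0:
        raise ValueError("gene list is empty")
    if n > 1 and mean_degree >= n:
        raise ValueError("mean_degree must be below the number of genes")
    lo, hi = score_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("score_range must be within [0, 1]")
    rng = np.random.default_rng(seed)
    p = min(1.0, mean_degree / (n - 1)) if n > 1 else 0.0
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    iu, ju = iu[keep], ju[keep]
    scores = rng.uniform(lo, hi, size=iu.size)
    garr = np.asarray(genes, dtype=object)
    return pd.DataFrame({"geneA": garr[iu], "geneB": garr[ju], "score": scores})


def _censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Solve for c such that uniform-[0, c] censoring yields the target rate.

    For an exponential event time with rate lam and C ~ U(0, c):
    P(C < T) = (1 - exp(-lam c)) / (lam c); averaged over the sample's rates.
    """

    def frac_censored(c: float) -> float:
        x = rates * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    # frac_censored decreases from 1 (c -> 0) to 0 (c -> inf)
    hi = 1.0
    while frac_censored(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for sane censor rates
            break
    return brentq(lambda c: frac_censored(c) - censor_rate, 1e-9, hi)


def generate_survival(
    n: int,
    group: np.ndarray,
    hazard_ratio: float,
    censor_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate survival records with a group-dependent exponential hazard.

    Baseline rate is 1.0 for group 0 and ``hazard_ratio`` for group 1;
    censoring times are uniform on [0, c] with c solved so the expected
    fraction censored equals ``censor_rate``.
    """
    group = np.asarray(group)
    if len(group) != n:
        raise ValueError("group vector length must equal n")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rates = np.where(group == 1, hazard_ratio, 1.0).astype(float)
    t_event = rng.exponential(1.0 / rates)
    if censor_rate == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        c = _censor_horizon(rates, censor_rate)
        t_cens = rng.uniform(0.0, c, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    return pd.DataFrame(
        {
            "sample": [f"P{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "group": group.astype(int),
        }
    )


def generate_gene_sets(
    background: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    planted_set: list[str] | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Simulate a GMT-writable gene-set collection over a background universe.

    Random sets draw members uniformly without replacement; if ``planted_set``
    is given, one additional set named ``planted`` equals it exactly.
    """
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= len(background)):
        raise ValueError("set sizes must fit within the background")
    if planted_set is not None and not set(planted_set) <= set(background):
        raise ValueError("planted_set must be a subset of the background")
    rng = np.random.default_rng(seed)
    bg = np.asarray(background, dtype=object)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(bg, size=size, replace=False)
        sets[f"set{i + 1:03d}"] = sorted(members.tolist())
    if planted_set is not None:
        sets["planted"] = list(planted_set)
    return sets
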