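"""Synthetic expression cohorts with known modulation ground truth.

Two generators cover the testing needs of the whole pipeline:

* :func:`generate_null` — independent Gaussian log2-like expression for every
  gene and sample, with no dependence structure at all. Running the
  co-modulation regression on such data calibrates the empirical significance
  rate against the nominal alpha (the random-baseline control).

* :func:`generate_modulated` — data with planted modulation. Modulator
  z-scores are drawn i.i.d. standard normal, and for each planted gene pair
  the per-sample target correlation is the linear predictor

      rho_k = clip(baseline + sum_m beta_m * z_mk, -0.99, 0.99);

  the pair's two expression values in sample k are then drawn from a
  bivariate normal with correlation rho_k. The link is linear-with-clipping
  (not a sigmoid) so that the planted betas live on the same scale the
  downstream linear regression estimates, which makes parameter recovery a
  fair test. All remaining genes are independent noise.

Per-sample covariability is only a noisy proxy of rho_k, so ground-truth
betas are recovered distributionally — across replicate pairs — never
exactly per pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

__all__ = [
    "SimulationScenario",
    "generate_null",
    "generate_modulated",
    "gene_id",
    "modulator_id",
    "replicate_pair_ids",
    "scenario_with_random_effects",
]

#: Per-sample target correlations are clipped into this open interval so the
#: bivariate draw stays well defined.
RHO_CLIP = 0.99


def gene_id(i: int) -> str:
    """Canonical synthetic gene id (1-based)."""
    return f"G{i:04d}"


def modulator_id(m: int) -> str:
    """Canonical synthetic modulator id (1-based)."""
    return f"MOD{m:02d}"


def replicate_pair_ids(n_pairs: int) -> list[tuple[str, str]]:
    """Disjoint gene pairs (G0001,G0002), (G0003,G0004), ... for replicate
    plantings; disjointness keeps replicates statistically independent."""
    return [(gene_id(2 * r + 1), gene_id(2 * r + 2)) for r in range(n_pairs)]


@dataclass
class SimulationScenario:
    """Full description of one modulated synthetic cohort.

    ``planted_effects`` maps a gene pair to its modulator -> beta dictionary;
    genes may appear in at most one planted pair (the generator draws each
    pair jointly). ``noise_sd`` is the expression standard deviation in log2
    units; ``mean_expression`` mimics a typical log2 microarray intensity.
    """

    n_genes: int
    n_modulators: int
    n_samples: int
    planted_effects: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=dict
    )
    baseline_correlation: float = 0.0
    noise_sd: float = 1.0
    mean_expression: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.baseline_correlation < 1.0:
            raise ValueError("baseline_correlation must be in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        valid_genes = {gene_id(i + 1) for i in range(self.n_genes)}
        valid_mods = {modulator_id(m + 1) for m in range(self.n_modulators)}
        used: set[str] = set()
        for (gi, gj), betas in self.planted_effects.items():
            if gi == gj:
                raise ValueError(f"planted self-pair: {gi}")
            for g in (gi, gj):
                if g not in valid_genes:
                    raise ValueError(f"planted pair references unknown gene {g!r}")
                if g in used:
                    raise ValueError(
                        f"gene {g!r} appears in more than one planted pair"
                    )
                used.add(g)
            for m in betas:
                if m not in valid_mods:
                    raise ValueError(f"planted effect references unknown modulator {m!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [gene_id(i + 1) for i in range(self.n_genes)]

    @property
    def modulator_ids(self) -> list[str]:
        return [modulator_id(m + 1) for m in range(self.n_modulators)]


def scenario_with_random_effects(
    n_pairs: int,
    n_modulators: int,
    n_samples: int,
    beta_low: float = 0.2,
    beta_high: float = 0.5,
    effect_seed: int = 42,
    cohort_seed: int = 0,
    baseline_correlation: float = 0.0,
) -> SimulationScenario:
    """Scenario with ``n_pairs`` disjoint planted pairs, each modulated by all
    modulators with effect magnitudes drawn uniformly from
    ``[beta_low, beta_high]`` and random signs.

    Magnitudes are bounded away from zero so every planted pair carries a
    detectable effect, and effects vary across pairs so that per-patient
    predicted profiles are non-degenerate — both properties a recovery or
    cross-cohort check needs. ``effect_seed`` fixes the betas independently
    of ``cohort_seed``, so two cohorts generated with different cohort seeds
    share identical ground truth.
    """
    rng = np.random.default_rng(effect_seed)
    planted: dict[tuple[str, str], dict[str, float]] = {}
    for pair in replicate_pair_ids(n_pairs):
        magnitudes = rng.uniform(beta_low, beta_high, n_modulators)
        signs = rng.choice([-1.0, 1.0], n_modulators)
        planted[pair] = {
            modulator_id(m + 1): float(magnitudes[m] * signs[m])
            for m in range(n_modulators)
        }
    return SimulationScenario(
        n_genes=2 * n_pairs,
        n_modulators=n_modulators,
        n_samples=n_samples,
        planted_effects=planted,
        baseline_correlation=baseline_correlation,
        seed=cohort_seed,
    )


def generate_null(
    n_genes: int,
    n_samples: int,
    seed: int,
    mean_expression: float = 8.0,
    noise_sd: float = 1.0,
    gene_prefix: str = "G",
) -> ExpressionMatrix:
    """I.i.d. Gaussian expression matrix with no structure whatsoever.

    Deterministic given ``seed``. Needs at least 10 samples — fewer make the
    per-sample correlation decomposition too noisy to be interpretable.
    """
    if n_samples < 10:
        raise ValueError(f"need at least 10 samples, got {n_samples}")
    rng = np.random.default_rng(seed)
    values = mean_expression + noise_sd * rng.standard_normal((n_genes, n_samples))
    genes = [f"{gene_prefix}{i + 1:04d}" for i in range(n_genes)]
    samples = [f"S{k + 1:04d}" for k in range(n_samples)]
    return ExpressionMatrix(genes, samples, values)


def generate_modulated(
    scenario: SimulationScenario,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Cohort with planted modulator-dependent gene-pair correlation.

    Returns the expression matrix (modulator rows first, then genes) and a
    ground-truth table with columns gene_i, gene_j, modulator, beta listing
    every planted coefficient. Samples whose linear predictor falls outside
    (-0.99, 0.99) are clipped; if any are, a warning reports the count.
    """
    rng = np.random.default_rng(scenario.seed)
    K = scenario.n_samples
    z_mod = rng.standard_normal((scenario.n_modulators, K))
    base = rng.standard_normal((scenario.n_genes, K))
    mod_index = {m: r for r, m in enumerate(scenario.modulator_ids)}
    gene_index = {g: r for r, g in enumerate(scenario.gene_ids)}

    n_clipped = 0
    truth_rows = []
    # deterministic iteration order for reproducibility regardless of how the
    # planted_effects mapping was built
    for (gi, gj) in sorted(scenario.planted_effects):
        betas = scenario.planted_effects[(gi, gj)]
        predictor = np.full(K, scenario.baseline_correlation)
        for m, beta in betas.items():
            predictor += beta * z_mod[mod_index[m]]
            truth_rows.append(
                {"gene_i": gi, "gene_j": gj, "modulator": m, "beta": float(beta)}
            )
        rho = np.clip(predictor, -RHO_CLIP, RHO_CLIP)
        n_clipped += int(np.sum(rho != predictor))
        x = base[gene_index[gi]]
        innovation = rng.standard_normal(K)
        base[gene_index[gj]] = rho * x + np.sqrt(1.0 - rho**2) * innovation

    if n_clipped:
        warnings.warn(
            f"{n_clipped} per-sample target correlations clipped to "
            f"(-{RHO_CLIP}, {RHO_CLIP})",
            stacklevel=2,
        )

    values = np.vstack(
        [
            scenario.mean_expression + z_mod,  # modulators: unit sd
            scenario.mean_expression + scenario.noise_sd * base,
        ]
    )
    genes = scenario.modulator_ids + scenario.gene_ids
    samples = [f"S{k + 1:04d}" for k in range(K)]
    truth = pd.DataFrame(truth_rows, columns=["gene_i", "gene_j", "modulator", "beta"])
    return ExpressionMatrix(genes, samples, values), truth
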