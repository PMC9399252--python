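"""High-level analysis workflows composed from the library modules.

These are the computations the analysis drivers, the acceptance script and
the heavier tests all share: genotype comparisons, drug dose-response
curves, the robustness screen, and benchmark runs of the rhythmic-gene
caller and the kinase scoring on synthetic data with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ksea as ksea_mod
from .caller import call_matrix
from .model import (
    DEFAULT_CONFIG,
    Genotype,
    LimitCycleSummary,
    SimulationConfig,
    build_model,
    find_limit_cycle,
)
from .parameters import CryTarget, DrugPerturbation, ParameterSet, default_parameters
from .synthetic import gen_expression_matrix, gen_kinase_map, gen_phospho_dataset

#: drug/dose runs do not need period estimates stable to 0.01 hr
FAST_CONFIG = SimulationConfig(rtol=1e-7, atol=1e-9)


def genotype_summary(
    genotype: Genotype,
    params: ParameterSet | None = None,
    drug: DrugPerturbation = DrugPerturbation(),
    config: SimulationConfig = DEFAULT_CONFIG,
) -> LimitCycleSummary:
    return find_limit_cycle(build_model(genotype, params, drug, config), config)


def baseline_comparison(
    params: ParameterSet | None = None,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> dict[Genotype, LimitCycleSummary]:
    """Limit-cycle summaries of all three genotypes, no drug."""
    return {g: genotype_summary(g, params, config=config) for g in Genotype}


def cry_stabilization_response(
    fractions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8),
    target: CryTarget = CryTarget.BOTH,
    genotypes: tuple[Genotype, ...] = (Genotype.WT, Genotype.DRRE_BMAL1),
    params: ParameterSet | None = None,
    config: SimulationConfig = FAST_CONFIG,
) -> pd.DataFrame:
    """Period and p-BMAL1 amplitude across CRY-stabilization doses.

    Period changes are reported against the same genotype's drug-free
    period, mirroring the per-genotype normalization of dose-response
    figures.
    """
    rows = []
    base_period: dict[Genotype, float | None] = {}
    for genotype in genotypes:
        for fraction in fractions:
            drug = DrugPerturbation(
                cry_stabilization_fraction=fraction, cry_target=target
            )
            s = genotype_summary(genotype, params, drug, config)
            if fraction == 0.0:
                base_period[genotype] = s.period
            ref = base_period.get(genotype)
            rows.append(
                {
                    "genotype": genotype.value,
                    "fraction": fraction,
                    "period_hr": s.period,
                    "period_change_hr": (
                        np.nan
                        if s.period is None or ref is None
                        else s.period - ref
                    ),
                    "pbmal1_relamp": s.relative_amplitude["pBMAL1"],
                    "cry1_relamp": s.relative_amplitude["CRY1"],
                    "oscillating": s.oscillating,
                }
            )
    return pd.DataFrame(rows)


def reverb_agonism_response(
    fractions: tuple[float, ...] = (0.0, 0.5, 0.9),
    genotypes: tuple[Genotype, ...] = (Genotype.WT, Genotype.DRRE_BMAL1),
    params: ParameterSet | None = None,
    config: SimulationConfig = FAST_CONFIG,
) -> pd.DataFrame:
    """CRY1 / p-BMAL1 rhythm across REV-ERB agonism doses."""
    rows = []
    for genotype in genotypes:
        for fraction in fractions:
            drug = DrugPerturbation(reverb_agonism_fraction=fraction)
            s = genotype_summary(genotype, params, drug, config)
            rows.append(
                {
                    "genotype": genotype.value,
                    "fraction": fraction,
                    "period_hr": s.period,
                    "cry1_relamp": s.relative_amplitude["CRY1"],
                    "pbmal1_relamp": s.relative_amplitude["pBMAL1"],
                    "oscillating": s.oscillating,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CallerBenchmark:
    sensitivity: float
    specificity: float
    n_rhythmic_true: int
    n_flat_true: int
    calls: pd.DataFrame
    truth: pd.DataFrame


def rhythmic_gene_benchmark(
    n_genes: int = 1000,
    frac_rhythmic: float = 0.3,
    fold_amplitude: float = 2.0,
    noise_sigma: float = 0.15,
    n_reps: int = 3,
    seed: int = 0,
) -> CallerBenchmark:
    """Score the three-criteria caller against generator truth."""
    matrix, truth = gen_expression_matrix(
        n_genes=n_genes,
        frac_rhythmic=frac_rhythmic,
        fold_amplitude=fold_amplitude,
        noise_sigma=noise_sigma,
        n_reps=n_reps,
        seed=seed,
    )
    calls = call_matrix(matrix)
    merged = calls.merge(truth, on="gene", suffixes=("_called", "_true"))
    pos = merged["is_rhythmic_true"]
    called = merged["is_rhythmic_called"]
    sensitivity = float(called[pos].mean())
    specificity = float((~called[~pos]).mean())
    return CallerBenchmark(
        sensitivity, specificity, int(pos.sum()), int((~pos).sum()), calls, truth
    )


@dataclass(frozen=True)
class KseaBenchmark:
    injected_delta: float
    recovered_score: float
    max_abs_null_score: float
    scores: pd.DataFrame


def ksea_recovery_benchmark(
    delta: float = 1.0,
    shifted_kinase: str = "KIN00",
    n_kinases: int = 5,
    n_substrates: int = 20,
    n_per_group: int = 4,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> KseaBenchmark:
    """Recover an injected kinase-activity shift from synthetic phospho data."""
    kmap = gen_kinase_map(n_kinases=n_kinases, n_substrates=n_substrates)
    table, _ = gen_phospho_dataset(
        kmap,
        {shifted_kinase: delta},
        n_per_group=n_per_group,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    log2fc = ksea_mod.normalize_to_wt_mean(table)
    scores = ksea_mod.scores_to_frame(
        ksea_mod.kinase_activity_scores(log2fc, kmap)
    )
    recovered = float(
        scores.loc[scores["kinase"] == shifted_kinase, "score"].iloc[0]
    )
    null = scores.loc[scores["kinase"] != shifted_kinase, "score"]
    return KseaBenchmark(delta, recovered, float(null.abs().max()), scores)
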