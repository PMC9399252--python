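"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates the statistical shape of the study designs this
package targets — liver-style expression time courses (6 timepoints at 4-hr
intervals, a few replicates, a rhythmic fraction with phase structure),
luminometer-style traces (damped cosine on a drifting baseline), wheel-
running actograms (Poisson counts in 5-min bins with a daily active bout)
and phosphoproteome tables with kinase-level log2 shifts — and returns the
ground truth alongside the data, so detection methods can be scored
against a known answer.

All randomness flows through one ``numpy`` generator per call: the same
seed and settings reproduce the same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rhythm import Trace

CT_TIMES_DEFAULT: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)

#: phospho-residue frequencies typical of Fe-NTA-enriched liver datasets
RESIDUE_PROBS = {"S": 0.852, "T": 0.141, "Y": 0.007}


def _amplitude_from_fold(fold: float) -> float:
    """Relative cosine amplitude a with (1+a)/(1-a) = peak/trough fold."""
    if fold <= 1.0:
        raise ValueError("fold amplitude must exceed 1")
    return (fold - 1.0) / (fold + 1.0)


def gen_expression_matrix(
    n_genes: int = 1000,
    frac_rhythmic: float = 0.3,
    period: float = 24.0,
    phase_distribution: tuple = ("vonmises", 8.0, 1.0),
    fold_amplitude: float = 2.0,
    noise_sigma: float = 0.15,
    n_reps: int = 3,
    times: tuple[float, ...] = CT_TIMES_DEFAULT,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide expression matrix (gene x CT<t>_r<k>) plus a truth table.

    Rhythmic genes follow ``baseline * (1 + a cos(2 pi (t - phi)/period))``
    with multiplicative lognormal noise (sigma on the natural-log scale);
    flat genes are the same baseline with the same noise.  Phases come from
    a von Mises distribution (hours mapped to angle) or ``("uniform",)``.
    """
    if not 0.0 <= frac_rhythmic <= 1.0:
        raise ValueError("frac_rhythmic must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    n_rhythmic = int(round(frac_rhythmic * n_genes))
    rhythmic = np.zeros(n_genes, dtype=bool)
    rhythmic[:n_rhythmic] = True

    baselines = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_genes)
    a = _amplitude_from_fold(fold_amplitude)
    if phase_distribution[0] == "vonmises":
        _, mu_ct, kappa = phase_distribution
        angles = rng.vonmises(2.0 * np.pi * mu_ct / period, kappa, size=n_genes)
        phases = (angles % (2.0 * np.pi)) * period / (2.0 * np.pi)
    elif phase_distribution[0] == "uniform":
        phases = rng.uniform(0.0, period, size=n_genes)
    else:
        raise ValueError(f"unknown phase distribution {phase_distribution[0]!r}")

    clean = np.where(
        rhythmic[:, None],
        1.0 + a * np.cos(2.0 * np.pi * (t[None, :] - phases[:, None]) / period),
        1.0,
    ) * baselines[:, None]
    noise = rng.lognormal(0.0, noise_sigma, size=(n_genes, t.size, n_reps))
    values = clean[:, :, None] * noise

    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    data = {"gene": genes}
    for j, ct in enumerate(t):
        for r in range(n_reps):
            data[f"CT{ct:g}_r{r + 1}"] = values[:, j, r]
    matrix = pd.DataFrame(data)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_rhythmic": rhythmic,
            "phase_ct": np.where(rhythmic, phases, np.nan),
            "rel_amplitude": np.where(rhythmic, a, 0.0),
            "baseline": baselines,
        }
    )
    return matrix, truth


def gen_bioluminescence_trace(
    period: float = 24.0,
    damping_rate: float = 0.0,  # 1/hr
    trend_slope: float = 0.0,  # units/hr
    noise_sigma: float = 0.0,
    dt: float = 1.0 / 6.0,  # 10-min sampling
    duration: float = 120.0,
    baseline: float = 10.0,
    amplitude: float = 3.0,
    seed: int = 0,
    label: str | None = None,
) -> tuple[Trace, dict]:
    """Damped-cosine luminescence-like trace on a linear baseline trend."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2.0, dt)
    clean = (
        baseline
        + trend_slope * t
        + amplitude * np.exp(-damping_rate * t) * np.cos(2.0 * np.pi * t / period)
    )
    v = clean + rng.normal(0.0, noise_sigma, size=t.size)
    truth = {
        "period_hr": period,
        "damping_rate": damping_rate,
        "trend_slope": trend_slope,
        "amplitude": amplitude,
        "baseline": baseline,
    }
    return Trace(t, v, label), truth


def gen_wheel_activity(
    free_running_period: float = 24.0,
    active_fraction: float = 0.5,
    rate_active: float = 20.0,  # counts per bin in the active bout
    rate_rest: float = 0.5,
    bin_minutes: float = 5.0,
    days: int = 14,
    seed: int = 0,
) -> tuple[Trace, dict]:
    """Poisson wheel-revolution counts with a daily active bout."""
    rng = np.random.default_rng(seed)
    dt = bin_minutes / 60.0
    t = np.arange(0.0, days * 24.0, dt)
    phase = (t % free_running_period) / free_running_period
    rate = np.where(phase < active_fraction, rate_active, rate_rest)
    counts = rng.poisson(rate).astype(float)
    truth = {"period_hr": free_running_period, "n_bins": int(t.size)}
    return Trace(t, counts, label="wheel"), truth


def gen_kinase_map(
    n_kinases: int = 10,
    n_substrates: int = 20,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Disjoint kinase -> substrate-site map with systematic site ids."""
    return {
        f"KIN{k:02d}": {
            f"site_{k:02d}_{j:03d}" for j in range(n_substrates)
        }
        for k in range(n_kinases)
    }


def gen_phospho_dataset(
    kinase_map: dict[str, set[str]],
    kinase_shifts: dict[str, float] | None = None,
    n_per_group: int = 4,
    noise_sigma: float = 0.3,  # sigma of log2 abundance noise
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phosphosite abundance table (WT vs MUT samples) plus truth.

    Site abundances are lognormal around a site-specific WT mean; for the
    substrates of a shifted kinase the mutant mean is multiplied by
    ``2**delta``, so the generating kinase activity score is exactly delta.
    """
    kinase_shifts = kinase_shifts or {}
    unknown = set(kinase_shifts) - set(kinase_map)
    if unknown:
        raise ValueError(f"shift(s) for unmapped kinase(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    site_rows = []
    for kinase in sorted(kinase_map):
        delta = float(kinase_shifts.get(kinase, 0.0))
        for site in sorted(kinase_map[kinase]):
            site_rows.append((site, kinase, delta))
    residues = rng.choice(
        list(RESIDUE_PROBS), p=list(RESIDUE_PROBS.values()), size=len(site_rows)
    )
    rows = []
    truth_rows = []
    for (site, kinase, delta), residue in zip(site_rows, residues):
        wt_mean = float(rng.lognormal(np.log(1000.0), 0.8))
        wt = wt_mean * 2.0 ** rng.normal(0.0, noise_sigma, n_per_group)
        mut = (wt_mean * 2.0 ** delta) * 2.0 ** rng.normal(
            0.0, noise_sigma, n_per_group
        )
        rows.append(
            {
                "site_id": site,
                "protein": site.rsplit("_", 1)[0],
                "residue": residue,
                "position": int(rng.integers(1, 2000)),
                **{f"WT_{i + 1}": wt[i] for i in range(n_per_group)},
                **{f"MUT_{i + 1}": mut[i] for i in range(n_per_group)},
            }
        )
        truth_rows.append(
            {"site_id": site, "kinase": kinase, "delta_log2": delta}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def kinase_map_to_frame(kinase_map: dict[str, set[str]]) -> pd.DataFrame:
    return pd.DataFrame(
        [(k, s) for k in sorted(kinase_map) for s in sorted(kinase_map[k])],
        columns=["kinase", "site_id"],
    )
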