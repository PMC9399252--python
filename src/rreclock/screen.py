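"""Random-parameter robustness screen: WT vs constitutive-Bmal1 mutant.

Every rate constant is independently multiplied by a uniform factor in
``[1 - r, 1 + r]`` (default r = 0.5, i.e. +/-50%).  For each draw the wild
type and the DRRE_BMAL1 mutant are integrated under the *same* draw — the
mutant's Bmal1 clamp is recomputed from that draw's own WT average — and
each is classified as oscillating iff the reference species' relative
amplitude strictly exceeds the threshold.  Draws are tallied into the four
Venn cells (both / WT-only / mutant-only / neither).

Integration tolerances are looser than the single-run defaults (the
classification is threshold-based, not a precision period estimate); sets
whose integration fails are excluded from the counts and reported, with a
hard error if more than 5% fail.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Genotype,
    LimitCycleSummary,
    ModelInstance,
    NumericalError,
    SimulationConfig,
    simulate,
    summarize_limit_cycle,
    time_average,
)
from .parameters import ParameterSet, ParameterValueError, default_parameters

logger = logging.getLogger(__name__)

#: Screen-grade integration settings (coarser tolerances, same windows).
SCREEN_CONFIG = SimulationConfig(rtol=1e-6, atol=1e-8)


@dataclass(frozen=True)
class ScreenConfig:
    n_sets: int = 400
    perturbation_half_range: float = 0.5
    amplitude_threshold: float = 0.1
    reference_species: str = "Per2_mRNA"
    seed: int = 0
    base_params: ParameterSet = field(default_factory=default_parameters)
    sim: SimulationConfig = SCREEN_CONFIG
    max_failure_fraction: float = 0.05

    def __post_init__(self):
        if self.n_sets < 0:
            raise ParameterValueError("n_sets must be >= 0")
        if not 0.0 < self.perturbation_half_range < 1.0:
            raise ParameterValueError("perturbation half-range must be in (0, 1)")
        if not 0.1 <= self.amplitude_threshold <= 0.4:
            raise ParameterValueError(
                "amplitude threshold outside the supported band [0.1, 0.4]"
            )


@dataclass(frozen=True)
class VennCounts:
    """Oscillation classification of the random parameter sets."""

    both: int
    wt_only: int
    mut_only: int
    neither: int
    n_failed: int
    records: pd.DataFrame  # draw_id, wt_amplitude, mut_amplitude, status

    @property
    def completed(self) -> int:
        return self.both + self.wt_only + self.mut_only + self.neither

    def to_json(self) -> str:
        return json.dumps(
            {
                "both": self.both,
                "wt_only": self.wt_only,
                "mut_only": self.mut_only,
                "neither": self.neither,
                "n_failed": self.n_failed,
            },
            indent=2,
        )


def perturb_parameters(
    base: ParameterSet, r: float, rng: np.random.Generator
) -> ParameterSet:
    """Multiply every rate constant by an independent Uniform[1-r, 1+r] factor.

    ``r = 0`` is allowed as a degenerate case and returns the base values.
    Draws consume the generator state in a fixed (sorted-name) order, so a
    seeded generator reproduces the same sequence of parameter sets.
    """
    if not 0.0 <= r < 1.0:
        raise ParameterValueError("perturbation half-range must be in [0, 1)")
    names = sorted(base)
    factors = rng.uniform(1.0 - r, 1.0 + r, size=len(names))
    return ParameterSet(
        {name: base[name] * f for name, f in zip(names, factors)}
    )


def classify_oscillation(
    summary: LimitCycleSummary, threshold: float
) -> bool:
    """True iff the reference species' relative amplitude strictly exceeds
    the threshold (the printed criterion is a strict ``>``)."""
    ref = summary.reference_species
    if ref not in summary.relative_amplitude:
        raise ParameterValueError(f"summary lacks reference species {ref!r}")
    return summary.relative_amplitude[ref] > threshold


def _classify_pair(
    params: ParameterSet, sim: SimulationConfig, threshold: float
) -> tuple[float, float, bool, bool]:
    """Amplitudes and calls for WT and clamped mutant under one draw."""
    wt = ModelInstance(Genotype.WT, params)
    traj = simulate(
        wt, sim.t_end, sim.dt_out, rtol=sim.rtol, atol=sim.atol,
        negative_abort=sim.negative_abort,
    )
    wt_summary = summarize_limit_cycle(traj, sim)
    win = traj.window(sim.transient_discard, sim.t_end)
    clamp = time_average(win, "Bmal1_mRNA", wt_summary.period)
    mut = ModelInstance(Genotype.DRRE_BMAL1, params, {"Bmal1_mRNA": clamp})
    mut_summary = summarize_limit_cycle(
        simulate(
            mut, sim.t_end, sim.dt_out, rtol=sim.rtol, atol=sim.atol,
            negative_abort=sim.negative_abort,
        ),
        sim,
    )
    wt_amp = wt_summary.relative_amplitude[sim.reference_species]
    mut_amp = mut_summary.relative_amplitude[sim.reference_species]
    return (
        wt_amp,
        mut_amp,
        classify_oscillation(wt_summary, threshold),
        classify_oscillation(mut_summary, threshold),
    )


def run_screen(config: ScreenConfig) -> VennCounts:
    """Draw, integrate and tally ``config.n_sets`` random parameter sets."""
    rng = np.random.default_rng(config.seed)
    sim = SimulationConfig(
        dt_out=config.sim.dt_out,
        rtol=config.sim.rtol,
        atol=config.sim.atol,
        transient_discard=config.sim.transient_discard,
        analysis_window=config.sim.analysis_window,
        oscillation_threshold=config.amplitude_threshold,
        reference_species=config.reference_species,
        negative_abort=config.sim.negative_abort,
    )
    rows = []
    for draw_id in range(config.n_sets):
        params = perturb_parameters(
            config.base_params, config.perturbation_half_range, rng
        )
        try:
            wt_amp, mut_amp, wt_osc, mut_osc = _classify_pair(
                params, sim, config.amplitude_threshold
            )
        except NumericalError as err:
            logger.warning("draw %d failed: %s", draw_id, err)
            rows.append((draw_id, np.nan, np.nan, "failed"))
            continue
        status = {
            (True, True): "both",
            (True, False): "wt_only",
            (False, True): "mut_only",
            (False, False): "neither",
        }[(wt_osc, mut_osc)]
        rows.append((draw_id, wt_amp, mut_amp, status))
    records = pd.DataFrame(
        rows, columns=["draw_id", "wt_amplitude", "mut_amplitude", "status"]
    ).sort_values("draw_id", ignore_index=True)
    n_failed = int((records["status"] == "failed").sum())
    if config.n_sets and n_failed > config.max_failure_fraction * config.n_sets:
        raise NumericalError(
            f"{n_failed}/{config.n_sets} integrations failed "
            f"(> {config.max_failure_fraction:.0%})"
        )
    tally = records["status"].value_counts()
    return VennCounts(
        both=int(tally.get("both", 0)),
        wt_only=int(tally.get("wt_only", 0)),
        mut_only=int(tally.get("mut_only", 0)),
        neither=int(tally.get("neither", 0)),
        n_failed=n_failed,
        records=records,
    )


def reclassify(records: pd.DataFrame, threshold: float) -> VennCounts:
    """Re-tally completed draws at a different amplitude threshold.

    Raising the threshold on fixed draws can only shrink the oscillating
    cells; this helper makes that monotonicity cheap to check.
    """
    ok = records[records["status"] != "failed"]
    wt = ok["wt_amplitude"] > threshold
    mut = ok["mut_amplitude"] > threshold
    out = ok.copy()
    out["status"] = np.select(
        [wt & mut, wt & ~mut, ~wt & mut],
        ["both", "wt_only", "mut_only"],
        default="neither",
    )
    return VennCounts(
        both=int((wt & mut).sum()),
        wt_only=int((wt & ~mut).sum()),
        mut_only=int((~wt & mut).sum()),
        neither=int((~wt & ~mut).sum()),
        n_failed=int((records["status"] == "failed").sum()),
        records=out,
    )


def save_screen(venn: VennCounts, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "venn.json").write_text(venn.to_json() + "\n")
    venn.records.to_csv(out / "per_set.csv", index=False)
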