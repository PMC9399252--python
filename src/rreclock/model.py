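"""Compact interlocked-feedback circadian clock model.

The model couples the two transcriptional feedback loops of the mammalian
clock in 15 species:

* **E-box loop** (core negative loop): the CLOCK-BMAL1 complex activates
  Per2, Cry1 and Rev-erb transcription; PER and CRY form a complex that is
  imported into the nucleus and sequesters CLOCK-BMAL1 away from E-boxes
  (quasi-equilibrium 1:1 binding with dissociation constant ``K_seq``).
* **RRE loop**: REV-ERB protein represses the ROR/REV-ERB response elements
  (RREs) of Bmal1, Cry1 and Clock with occupancy ``R / (R + Kd)`` where
  ``Kd = unbind / bind``.

BMAL1 phosphorylation — the "functional rhythm" readout — occurs on
CLOCK-bound BMAL1, is inhibited by nuclear CRY1 (factor
``1 / (1 + CRY1 / K_cry1_inhib)``) and phospho-BMAL1 is degraded faster
than the unphosphorylated form.

E-box transcription retains a small activator-independent basal rate
(``ebox_basal``): with it, strong repressor excess (stabilized CRYs, or
hyperactive REV-ERB) can park the system in a non-oscillating repressed
state, and the rhythmic de-repression of Bmal1 through its RREs is what
rescues the wild type but not the constitutive-Bmal1 mutant.

Genotypes: ``WT``; ``DRRE_BMAL1`` replaces the Bmal1 RRE synthesis term
with a constant chosen so the clamped Bmal1 mRNA level equals the
time-averaged Bmal1 mRNA of the wild-type model under the *same*
(drug-transformed) parameters; ``DRRE_BMAL1_CLOCK`` additionally clamps
Clock mRNA the same way.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .parameters import (
    NO_DRUG,
    DrugPerturbation,
    ParameterSet,
    ParameterValueError,
    default_parameters,
)

SPECIES: tuple[str, ...] = (
    "Bmal1_mRNA",
    "Per2_mRNA",
    "Cry1_mRNA",
    "Reverb_mRNA",
    "Clock_mRNA",
    "BMAL1",
    "pBMAL1",
    "CLOCK",
    "PER",
    "CRY1",
    "CRY2",
    "REVERB",
    "CLOCK_BMAL1",
    "PER_CRY_cyt",
    "PER_CRY",
)

_IDX = {name: i for i, name in enumerate(SPECIES)}

MRNA_SPECIES = SPECIES[:5]

#: Default reference species for oscillation calls (a core E-box target).
REFERENCE_SPECIES = "Per2_mRNA"


class NumericalError(RuntimeError):
    """Stiff integration failed; carries the failing time when known."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class Genotype(enum.Enum):
    WT = "wt"
    DRRE_BMAL1 = "drre"
    DRRE_BMAL1_CLOCK = "drre-clock"


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and limit-cycle analysis settings.

    The transient discard and analysis window are long enough that period
    estimates on the default parameters are stable to < 0.01 hr.
    """

    dt_out: float = 0.1  # hr
    rtol: float = 1e-8
    atol: float = 1e-10
    transient_discard: float = 600.0  # hr
    analysis_window: float = 240.0  # hr
    oscillation_threshold: float = 0.1  # relative amplitude, "weak rhythmicity"
    reference_species: str = REFERENCE_SPECIES
    #: undershoot below this aborts; smaller negatives are clipped to 0
    negative_abort: float = -1e-8

    @property
    def t_end(self) -> float:
        return self.transient_discard + self.analysis_window


DEFAULT_CONFIG = SimulationConfig()


def free_activator(total: float, repressor: float, kd: float):
    """Free activator concentration under 1:1 quasi-equilibrium sequestration.

    Solves ``A_free = total - bound`` with ``bound`` given by tight reversible
    binding of repressor to activator with dissociation constant ``kd``.
    """
    b = total - repressor - kd
    return 0.5 * (b + np.sqrt(b * b + 4.0 * total * kd))


@dataclass(frozen=True)
class ModelInstance:
    """A right-hand-side evaluator for one genotype/parameter/drug setting."""

    genotype: Genotype
    params: ParameterSet  # drug-transformed
    clamp: dict[str, float] = field(default_factory=dict)  # species -> level

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        (Mb, Mp, Mc1, Mr, Mk, B, Bp, C, P, C1, C2, R,
         CB, PCc, PCn) = y

        af = free_activator(CB, PCn, p["K_seq"])
        ebox = p["ebox_basal"] + (1.0 - p["ebox_basal"]) * af / (p["K_act"] + af)

        kd_b = p["unbinrevb"] / p["binrevb"]
        kd_c = p["unbinrev"] / p["binrev"]
        rre_bmal1 = p["v_rre_bmal1"] * kd_b / (kd_b + R)
        rre_cry1 = p["v_rre_cry1"] * kd_c / (kd_c + R)
        rre_clock = p["v_rre_clock"] * kd_c / (kd_c + R)

        if "Bmal1_mRNA" in self.clamp:
            synth_bmal1 = p["deg_bmal1_mrna"] * self.clamp["Bmal1_mRNA"]
        else:
            synth_bmal1 = rre_bmal1
        if "Clock_mRNA" in self.clamp:
            synth_clock = p["deg_clock_mrna"] * self.clamp["Clock_mRNA"]
        else:
            synth_clock = rre_clock

        phos = p["k_phos_bmal1"] * CB / (1.0 + C1 / p["K_cry1_inhib"])
        bind_cb = p["k_bind_clockbmal1"] * C * B
        unbind_cb = p["k_unbind_clockbmal1"] * CB
        form_pc = p["k_bind_percry"] * P * (C1 + C2)

        return np.array([
            synth_bmal1 - p["deg_bmal1_mrna"] * Mb,
            p["v_ebox_per2"] * ebox - p["deg_per2_mrna"] * Mp,
            p["v_ebox_cry1"] * ebox + rre_cry1 - p["deg_cry1_mrna"] * Mc1,
            p["v_ebox_reverb"] * ebox - p["deg_reverb_mrna"] * Mr,
            synth_clock - p["deg_clock_mrna"] * Mk,
            (p["k_tl_bmal1"] * Mb + p["k_dephos_bmal1"] * Bp
             - bind_cb + unbind_cb - p["deg_bmal1"] * B),
            phos - p["k_dephos_bmal1"] * Bp - p["deg_pbmal1"] * Bp,
            (p["k_tl_clock"] * Mk - bind_cb + unbind_cb + phos
             - p["deg_clock"] * C),
            p["k_tl_per"] * Mp - form_pc - p["deg_per"] * P,
            p["k_tl_cry1"] * Mc1 - p["k_bind_percry"] * P * C1 - p["uro"] * C1,
            p["v_cry2"] - p["k_bind_percry"] * P * C2 - p["urt"] * C2,
            p["k_tl_reverb"] * Mr - p["deg_reverb"] * R,
            bind_cb - unbind_cb - phos - p["deg_clockbmal1"] * CB,
            form_pc - p["k_import_percry"] * PCc - p["deg_percry_cyt"] * PCc,
            p["k_import_percry"] * PCc - p["deg_percry_nuc"] * PCn,
        ])


@dataclass(frozen=True)
class Trajectory:
    """Species abundances on a uniform time grid (non-negative)."""

    times: np.ndarray  # hr, uniform step
    values: np.ndarray  # shape (n_species, n_times)
    species: tuple[str, ...] = SPECIES

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")

    def trace(self, name: str) -> np.ndarray:
        return self.values[self.species.index(name)]

    def window(self, t_start: float, t_stop: float) -> "Trajectory":
        m = (self.times >= t_start) & (self.times <= t_stop)
        return Trajectory(self.times[m], self.values[:, m], self.species)

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=list(self.species))
        df.insert(0, "time_hr", self.times)
        return df

    def to_tidy_frame(self) -> pd.DataFrame:
        return self.to_wide_frame().melt(
            id_vars="time_hr", var_name="species", value_name="value"
        )


def default_initial_state() -> np.ndarray:
    return np.full(len(SPECIES), 0.1)


def simulate(
    model: ModelInstance,
    t_end: float,
    dt_out: float = DEFAULT_CONFIG.dt_out,
    initial_state: np.ndarray | None = None,
    *,
    rtol: float = DEFAULT_CONFIG.rtol,
    atol: float = DEFAULT_CONFIG.atol,
    negative_abort: float = DEFAULT_CONFIG.negative_abort,
) -> Trajectory:
    """Integrate the stiff clock ODE system on a uniform output grid."""
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    y0 = default_initial_state() if initial_state is None else np.asarray(
        initial_state, dtype=float
    )
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    t_eval = np.arange(0.0, t_end + dt_out / 2.0, dt_out)
    sol = solve_ivp(
        model.rhs, (0.0, t_end), y0, t_eval=t_eval,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise NumericalError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0.0:.2f} hr: "
            f"{sol.message}",
            t_fail=float(sol.t[-1]) if len(sol.t) else None,
        )
    y = sol.y
    worst = float(y.min())
    if worst < negative_abort:
        t_bad = float(sol.t[np.argmin(y.min(axis=0))])
        raise NumericalError(
            f"state undershot to {worst:.3e} at t={t_bad:.2f} hr", t_fail=t_bad
        )
    return Trajectory(sol.t, np.clip(y, 0.0, None))


def relative_amplitude_of(values: np.ndarray) -> float:
    """(max - min) / max over a window; 0 for an all-zero trace."""
    vmax = float(np.max(values))
    if vmax <= 0:
        return 0.0
    return (vmax - float(np.min(values))) / vmax


def _refined_peak_times(t: np.ndarray, v: np.ndarray, dt: float) -> np.ndarray:
    """Local maxima with sub-grid quadratic refinement of peak times."""
    span = float(np.max(v) - np.min(v))
    if span <= 0:
        return np.empty(0)
    idx, _ = find_peaks(v, prominence=0.05 * span, distance=max(2, int(8.0 / dt)))
    times = []
    for i in idx:
        if 0 < i < len(v) - 1:
            denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
            shift = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom != 0 else 0.0
            times.append(t[i] + np.clip(shift, -1.0, 1.0) * dt)
        else:  # pragma: no cover - peaks at window edges are rare
            times.append(t[i])
    return np.asarray(times)


@dataclass(frozen=True)
class LimitCycleSummary:
    """Oscillation call, period and per-species amplitude/phase summary."""

    oscillating: bool
    status: str  # "oscillating" | "non_oscillating" | "inconclusive"
    period: float | None
    relative_amplitude: dict[str, float]
    peak_phase: dict[str, float | None]  # hr within cycle, vs reference peak
    reference_species: str = REFERENCE_SPECIES

    def to_json(self) -> str:
        return json.dumps(
            {
                "oscillating": self.oscillating,
                "status": self.status,
                "period_hr": self.period,
                "reference_species": self.reference_species,
                "relative_amplitude": self.relative_amplitude,
                "peak_phase_hr": self.peak_phase,
            },
            indent=2,
        )


def summarize_limit_cycle(
    traj: Trajectory,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> LimitCycleSummary:
    """Limit-cycle summary of an already-integrated trajectory.

    The analysis window is the last ``analysis_window`` hours of the
    trajectory.  Oscillating iff the reference species' relative amplitude
    strictly exceeds the configured threshold; with fewer than 3 reference
    peaks in the window the call is "inconclusive" rather than an error.
    """
    t_stop = float(traj.times[-1])
    win = traj.window(t_stop - config.analysis_window, t_stop)
    dt = float(win.times[1] - win.times[0])

    relamp = {s: relative_amplitude_of(win.trace(s)) for s in win.species}
    ref = config.reference_species
    if ref not in win.species:
        raise ParameterValueError(f"unknown reference species {ref!r}")

    above = relamp[ref] > config.oscillation_threshold
    ref_peaks = _refined_peak_times(win.times, win.trace(ref), dt)
    if not above:
        return LimitCycleSummary(
            False, "non_oscillating", None, relamp,
            {s: None for s in win.species}, ref,
        )
    if len(ref_peaks) < 3:
        return LimitCycleSummary(
            False, "inconclusive", None, relamp,
            {s: None for s in win.species}, ref,
        )
    period = float(np.mean(np.diff(ref_peaks)))
    ref_time = float(ref_peaks[-1])
    phases: dict[str, float | None] = {}
    for s in win.species:
        if relamp[s] < 1e-6:
            phases[s] = None
            continue
        pk = _refined_peak_times(win.times, win.trace(s), dt)
        if len(pk) == 0:
            phases[s] = None
        else:
            phases[s] = float((pk[-1] - ref_time) % period)
    return LimitCycleSummary(True, "oscillating", period, relamp, phases, ref)


def find_limit_cycle(
    model: ModelInstance,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> LimitCycleSummary:
    """Integrate past the transient and summarize the attractor."""
    traj = simulate(
        model, config.t_end, config.dt_out,
        rtol=config.rtol, atol=config.atol,
        negative_abort=config.negative_abort,
    )
    return summarize_limit_cycle(traj, config)


def time_average(
    traj: Trajectory, species: str, period: float | None = None
) -> float:
    """Trapezoidal time average of one species, over whole periods if given."""
    t, v = traj.times, traj.trace(species)
    if period is not None and period > 0:
        span = t[-1] - t[0]
        n_cycles = math.floor(span / period)
        if n_cycles >= 1:
            m = t >= t[-1] - n_cycles * period
            t, v = t[m], v[m]
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def wt_mean_mrna(
    params: ParameterSet,
    species: str,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> float:
    """Time-averaged level of one mRNA in the WT model under ``params``.

    Averaged over a whole number of periods after the transient discard when
    the model oscillates, otherwise over the whole analysis window.
    """
    if species not in SPECIES:
        raise ParameterValueError(f"unknown species {species!r}")
    wt = ModelInstance(Genotype.WT, params)
    traj = simulate(
        wt, config.t_end, config.dt_out,
        rtol=config.rtol, atol=config.atol,
        negative_abort=config.negative_abort,
    )
    summary = summarize_limit_cycle(traj, config)
    win = traj.window(config.transient_discard, config.t_end)
    return time_average(win, species, summary.period)


def build_model(
    genotype: Genotype,
    params: ParameterSet | None = None,
    drug: DrugPerturbation = NO_DRUG,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> ModelInstance:
    """Assemble a model instance; RRE-less genotypes get their clamps here.

    The clamp level for a constitutive mRNA is recomputed from the WT model
    under the *same* drug-transformed parameters, so screens and drug runs
    always clamp to the matching wild type.
    """
    params = default_parameters() if params is None else params
    params = drug.apply(params)
    clamp: dict[str, float] = {}
    if genotype in (Genotype.DRRE_BMAL1, Genotype.DRRE_BMAL1_CLOCK):
        clamp["Bmal1_mRNA"] = wt_mean_mrna(params, "Bmal1_mRNA", config)
    if genotype is Genotype.DRRE_BMAL1_CLOCK:
        clamp["Clock_mRNA"] = wt_mean_mrna(params, "Clock_mRNA", config)
    return ModelInstance(genotype, params, clamp)
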