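"""Rate-constant sets for the interlocked clock model, and drug-mimicking transforms.

A :class:`ParameterSet` is an immutable, validated mapping from rate-constant
name to a strictly positive value.  The key set is fixed for a model version:
every parameter is a first-class, perturbable quantity (the robustness screen
multiplies each one independently), so no parameter is ever silently optional.

Drug perturbations follow the pharmacology they emulate:

* CRY stabilization (KL001-like) scales the nuclear CRY degradation rates
  ``uro`` (CRY1) and/or ``urt`` (CRY2) by ``1 - fraction``.
* REV-ERB agonism (SR9009-like) scales the REV-ERB/RRE unbinding rates
  ``unbinrevb`` (Bmal1 RRE) and ``unbinrev`` (Cry1/Clock RREs) by
  ``1 - fraction``, lowering the dissociation constants by the same factor
  since the binding rates are untouched.
"""

from __future__ import annotations

import enum
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path


class MissingParameterError(KeyError):
    """A required rate constant is absent from a configuration."""


class ParameterValueError(ValueError):
    """A rate constant or perturbation fraction is out of its valid range."""


#: Default rate constants (1/hr, or concentration units for the constants
#: K_seq, K_act, K_cry1_inhib and the dimensionless ebox_basal leak).
#: Chosen so the wild-type model settles on a limit cycle with a period of
#: ~24.0 hr and a strong Per2 mRNA rhythm.
DEFAULT_VALUES: dict[str, float] = {
    # RRE-driven transcription (repressed by REV-ERB)
    "v_rre_bmal1": 0.5,
    "v_rre_cry1": 0.27,
    "v_rre_clock": 0.4,
    # E-box-driven transcription (activated by free CLOCK-BMAL1)
    "v_ebox_per2": 1.2,
    "v_ebox_cry1": 0.6,
    "v_ebox_reverb": 1.2,
    # mRNA degradation
    "deg_bmal1_mrna": 0.25,
    "deg_per2_mrna": 0.225,
    "deg_cry1_mrna": 0.25,
    "deg_reverb_mrna": 0.5,
    "deg_clock_mrna": 0.25,
    # translation / constitutive synthesis
    "k_tl_bmal1": 0.4,
    "k_tl_per": 0.3,
    "k_tl_cry1": 0.35,
    "k_tl_clock": 0.4,
    "k_tl_reverb": 0.3,
    "v_cry2": 0.30,
    # protein degradation (uro/urt: nuclear CRY1/CRY2, KL001 targets)
    "deg_bmal1": 0.15,
    "deg_pbmal1": 0.52,
    "deg_per": 0.09,
    "uro": 0.175,
    "urt": 0.25,
    "deg_clock": 0.15,
    "deg_reverb": 0.5,
    "deg_clockbmal1": 0.12,
    "deg_percry_cyt": 0.045,
    "deg_percry_nuc": 0.18,
    # complex formation and nuclear import
    "k_bind_clockbmal1": 0.5,
    "k_unbind_clockbmal1": 0.1,
    "k_bind_percry": 0.105,
    "k_import_percry": 0.225,
    # BMAL1 phosphorylation (CLOCK-bound substrate, inhibited by CRY1)
    "k_phos_bmal1": 0.50,
    "k_dephos_bmal1": 0.1,
    "K_cry1_inhib": 1.2,
    # REV-ERB binding/unbinding at RREs (SR9009 targets: unbinrevb/unbinrev)
    "binrevb": 1.0,
    "unbinrevb": 1.0,
    "binrev": 1.0,
    "unbinrev": 1.0,
    # activator-repressor sequestration and E-box activation
    "K_seq": 0.002,
    "K_act": 0.2,
    "ebox_basal": 0.07,
}

PARAMETER_NAMES: tuple[str, ...] = tuple(DEFAULT_VALUES)


class ParameterSet(Mapping[str, float]):
    """Immutable named map of strictly positive rate constants.

    The key set is exactly :data:`PARAMETER_NAMES`; construction fails with
    :class:`MissingParameterError` naming the first absent key, or with
    :class:`ParameterValueError` for non-positive or unknown entries.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        unknown = set(values) - set(PARAMETER_NAMES)
        if unknown:
            raise ParameterValueError(
                f"unknown parameter name(s): {sorted(unknown)}"
            )
        for name in PARAMETER_NAMES:
            if name not in values:
                raise MissingParameterError(name)
        vals = {}
        for name in PARAMETER_NAMES:
            v = float(values[name])
            if not v > 0:
                raise ParameterValueError(
                    f"parameter {name!r} must be strictly positive, got {v}"
                )
            vals[name] = v
        object.__setattr__(self, "_values", vals)

    # Mapping interface -------------------------------------------------
    def __getitem__(self, key: str) -> float:
        try:
            return self._values[key]
        except KeyError:
            raise MissingParameterError(key) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ParameterSet):
            return self._values == other._values
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._values.items()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParameterSet({self._values!r})"

    # construction helpers ----------------------------------------------
    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the named entries replaced."""
        vals = dict(self._values)
        vals.update(changes)
        return ParameterSet(vals)

    # serialization ------------------------------------------------------
    def to_text(self) -> str:
        """Serialize as ``name = value`` lines (lossless float repr)."""
        return "".join(f"{k} = {v!r}\n" for k, v in self._values.items())

    @classmethod
    def from_text(cls, text: str) -> "ParameterSet":
        values: dict[str, float] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterValueError(
                    f"line {lineno}: expected 'name = value', got {raw!r}"
                )
            name, _, val = line.partition("=")
            values[name.strip()] = float(val.strip())
        return cls(values)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        return cls.from_text(Path(path).read_text())


def default_parameters() -> ParameterSet:
    """The versioned default :class:`ParameterSet`."""
    return ParameterSet(DEFAULT_VALUES)


class CryTarget(enum.Enum):
    """Which nuclear CRY degradation rate a stabilizer acts on."""

    CRY1 = "cry1"
    CRY2 = "cry2"
    BOTH = "both"


def _check_fraction(fraction: float) -> float:
    fraction = float(fraction)
    if not 0.0 <= fraction < 1.0:
        raise ParameterValueError(
            f"perturbation fraction must be in [0, 1), got {fraction}"
        )
    return fraction


def apply_cry_stabilization(
    params: ParameterSet,
    fraction: float,
    target: CryTarget = CryTarget.BOTH,
) -> ParameterSet:
    """Scale nuclear CRY degradation by ``1 - fraction`` (KL001 mimic).

    ``fraction = 0`` returns the input unchanged (bit-identical values).
    """
    fraction = _check_fraction(fraction)
    if fraction == 0.0:
        return params
    changes: dict[str, float] = {}
    if target in (CryTarget.CRY1, CryTarget.BOTH):
        changes["uro"] = params["uro"] * (1.0 - fraction)
    if target in (CryTarget.CRY2, CryTarget.BOTH):
        changes["urt"] = params["urt"] * (1.0 - fraction)
    return params.replace(**changes)


def apply_reverb_agonism(params: ParameterSet, fraction: float) -> ParameterSet:
    """Scale REV-ERB/RRE unbinding rates by ``1 - fraction`` (SR9009 mimic).

    Binding rates are untouched, so both RRE dissociation constants fall by
    the same factor.
    """
    fraction = _check_fraction(fraction)
    if fraction == 0.0:
        return params
    return params.replace(
        unbinrevb=params["unbinrevb"] * (1.0 - fraction),
        unbinrev=params["unbinrev"] * (1.0 - fraction),
    )


@dataclass(frozen=True)
class DrugPerturbation:
    """Composable drug-mimicking transform of a :class:`ParameterSet`."""

    cry_stabilization_fraction: float = 0.0
    cry_target: CryTarget = CryTarget.BOTH
    reverb_agonism_fraction: float = 0.0

    def __post_init__(self) -> None:
        _check_fraction(self.cry_stabilization_fraction)
        _check_fraction(self.reverb_agonism_fraction)

    def apply(self, params: ParameterSet) -> ParameterSet:
        params = apply_cry_stabilization(
            params, self.cry_stabilization_fraction, self.cry_target
        )
        return apply_reverb_agonism(params, self.reverb_agonism_fraction)


#: A no-op perturbation, convenient as a default argument.
NO_DRUG = DrugPerturbation()
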