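"""Transition-state-theory kinetics from step free energies.

Every elementary step of a reaction network is summarised by two numbers at a
temperature: the activation free energy ΔG‡ (transition state above the step's
own reactant level) and the reaction free energy ΔG (product minus reactant).
From these, classical transition-state theory derives

* the equilibrium constant        K   = exp(−ΔG / RT),
* the forward rate constant       k_f = (kB·T/h) · exp(−ΔG‡ / RT),
* the reverse barrier             ΔG‡_rev = ΔG‡ − ΔG,
* the reverse rate and lifetime   k_r = (kB·T/h)·exp(−ΔG‡_rev/RT),  τ = 1/k_r.

The transmission coefficient is fixed at 1.  Barriers of tens of kcal·mol⁻¹
put the rates and lifetimes anywhere between 1e−55 and 1e+44 s, so all
arithmetic is done on log10 scale and exponentiated last.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "R_KCAL",
    "KB_J",
    "H_J",
    "T_DEFAULT",
    "ThermoConstants",
    "CONSTANTS",
    "StepEnergetics",
    "StepKinetics",
    "NegativeBarrierWarning",
    "eyring_prefactor",
    "equilibrium_constant",
    "eyring_rate",
    "reverse_barrier",
    "lifetime",
    "annotate_steps",
    "read_step_table",
    "annotate_table",
    "write_step_table",
    "format_sci",
]

#: Molar gas constant in kcal·mol⁻¹·K⁻¹ (CODATA-derived).
R_KCAL = 1.9872041e-3
#: Boltzmann constant, J·K⁻¹ (2019 SI exact value).
KB_J = 1.380649e-23
#: Planck constant, J·s (2019 SI exact value).
H_J = 6.62607015e-34
#: Default simulation temperature, K.
T_DEFAULT = 298.15

_LN10 = math.log(10.0)


class NegativeBarrierWarning(UserWarning):
    """A (forward or reverse) barrier came out negative.

    Composed or rounded step energetics can place a product above its own
    transition state; the formulas remain well defined, so this is a warning
    rather than an error.
    """


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants used throughout the package."""

    R: float = R_KCAL  # kcal·mol⁻¹·K⁻¹
    kB: float = KB_J  # J·K⁻¹
    h: float = H_J  # J·s
    T_default: float = T_DEFAULT  # K

    def prefactor(self, T: float | None = None) -> float:
        """Eyring frequency factor kB·T/h in s⁻¹."""
        T = self.T_default if T is None else T
        _check_temperature(T)
        return self.kB * T / self.h


CONSTANTS = ThermoConstants()

_PHASES = ("gas", "solution")


@dataclass
class StepEnergetics:
    """Activation and reaction free energies of one elementary step.

    ``dG_act`` is measured from the step's own reactant level, ``dG_rxn`` is
    product minus reactant, both in kcal·mol⁻¹.
    """

    label: str
    dG_act: float
    dG_rxn: float
    T: float = T_DEFAULT
    phase: str = "gas"

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("step label must be nonempty")
        if self.phase not in _PHASES:
            raise ValueError(f"phase must be one of {_PHASES}, got {self.phase!r}")
        _check_temperature(self.T)
        for name in ("dG_act", "dG_rxn"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class StepKinetics:
    """Derived kinetic quantities of a step: K, k_f, k_r (s⁻¹), τ (s), ΔG‡_rev."""

    K: float
    k_f: float
    k_r: float
    tau: float
    dG_rev: float
    negative_reverse_barrier: bool = field(default=False)


def _check_temperature(T: float) -> None:
    if not (math.isfinite(T) and T > 0):
        raise ValueError(f"temperature must be finite and > 0, got {T}")


def _check_finite(value: float, name: str) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


def eyring_prefactor(T: float = T_DEFAULT) -> float:
    """kB·T/h in s⁻¹ (≈ 6.21·10¹² at 298.15 K)."""
    return CONSTANTS.prefactor(T)


def log10_equilibrium_constant(dG_rxn: float, T: float = T_DEFAULT) -> float:
    """log10 K for a reaction free energy in kcal·mol⁻¹."""
    _check_temperature(T)
    _check_finite(dG_rxn, "dG_rxn")
    return -dG_rxn / (R_KCAL * T * _LN10)


def equilibrium_constant(dG_rxn: float, T: float = T_DEFAULT) -> float:
    """K = exp(−ΔG/RT); strictly decreasing in ΔG."""
    return 10.0 ** log10_equilibrium_constant(dG_rxn, T)


def log10_eyring_rate(dG_act: float, T: float = T_DEFAULT) -> float:
    """log10 of the Eyring rate constant (s⁻¹)."""
    _check_temperature(T)
    _check_finite(dG_act, "dG_act")
    if dG_act < 0:
        warnings.warn(
            f"negative activation energy {dG_act} kcal/mol (rate exceeds kB*T/h)",
            NegativeBarrierWarning,
            stacklevel=3,
        )
    return math.log10(CONSTANTS.prefactor(T)) - dG_act / (R_KCAL * T * _LN10)


def eyring_rate(dG_act: float, T: float = T_DEFAULT) -> float:
    """k = (kB·T/h)·exp(−ΔG‡/RT) in s⁻¹, transmission coefficient 1."""
    return 10.0 ** log10_eyring_rate(dG_act, T)


def reverse_barrier(dG_act: float, dG_rxn: float) -> float:
    """Barrier of the inverse process, ΔG‡ − ΔG (TS height above the product).

    A negative result (product above its own TS) raises
    :class:`NegativeBarrierWarning` but is returned as-is.
    """
    _check_finite(dG_act, "dG_act")
    _check_finite(dG_rxn, "dG_rxn")
    rev = dG_act - dG_rxn
    if rev < 0:
        warnings.warn(
            f"negative reverse barrier {rev:.3f} kcal/mol (product above TS)",
            NegativeBarrierWarning,
            stacklevel=2,
        )
    return rev


def lifetime(dG_act: float, dG_rxn: float, T: float = T_DEFAULT) -> float:
    """τ = 1/k_r, seconds: lifetime of the step's product against reversal."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeBarrierWarning)
        rev = reverse_barrier(dG_act, dG_rxn)
    return 10.0 ** (-log10_eyring_rate(rev, T))


def step_kinetics(step: StepEnergetics) -> StepKinetics:
    """All derived quantities for one step."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeBarrierWarning)
        rev = step.dG_act - step.dG_rxn
        log_kf = log10_eyring_rate(step.dG_act, step.T)
        log_kr = log10_eyring_rate(rev, step.T)
    if rev < 0:
        warnings.warn(
            f"step {step.label!r}: negative reverse barrier {rev:.3f} kcal/mol",
            NegativeBarrierWarning,
            stacklevel=2,
        )
    return StepKinetics(
        K=10.0 ** (log_kf - log_kr),
        k_f=10.0**log_kf,
        k_r=10.0**log_kr,
        tau=10.0**-log_kr,
        dG_rev=rev,
        negative_reverse_barrier=rev < 0,
    )


def annotate_steps(
    steps: Iterable[StepEnergetics],
) -> list[tuple[StepEnergetics, StepKinetics]]:
    """Attach :class:`StepKinetics` to every step, preserving order."""
    return [(s, step_kinetics(s)) for s in steps]


# ---------------------------------------------------------------------------
# Tabular interface: CSV/TSV with columns label, phase, dG_act, dG_rxn.
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("label", "phase", "dG_act", "dG_rxn")


def read_step_table(path) -> pd.DataFrame:
    """Read a step-energetics table (CSV, or TSV for ``.tsv`` paths).

    Raises ``ValueError`` naming any missing required column.  Unknown columns
    are passed through untouched.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"step table is missing required column(s): {', '.join(missing)}")
    return df


def annotate_table(df: pd.DataFrame, T: float = T_DEFAULT) -> pd.DataFrame:
    """Add ``K, k_f, k_r, tau, dG_rev`` columns computed row-wise at T."""
    missing = [c for c in ("label", "dG_act", "dG_rxn") if c not in df.columns]
    if missing:
        raise ValueError(f"step table is missing required column(s): {', '.join(missing)}")
    out = df.copy()
    cols: dict[str, list[float]] = {k: [] for k in ("K", "k_f", "k_r", "tau", "dG_rev")}
    for _, row in df.iterrows():
        kin = step_kinetics(
            StepEnergetics(
                label=str(row["label"]),
                dG_act=float(row["dG_act"]),
                dG_rxn=float(row["dG_rxn"]),
                T=T,
                phase=str(row.get("phase", "gas")),
            )
        )
        for k in cols:
            cols[k].append(getattr(kin, k))
    for k, v in cols.items():
        out[k] = v
    return out


def format_sci(x: float) -> str:
    """Mantissa·10^exponent with 3 significant digits, e.g. ``2.82e-16``."""
    return f"{x:.2e}"


def write_step_table(df: pd.DataFrame, path) -> None:
    """Write an annotated table; derived columns in 3-sig-digit scientific form."""
    out = df.copy()
    for col in ("K", "k_f", "k_r", "tau"):
        if col in out.columns:
            out[col] = out[col].map(format_sci)
    if "dG_rev" in out.columns:
        out["dG_rev"] = out["dG_rev"].map(lambda v: f"{v:.2f}")
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    out.to_csv(path, sep=sep, index=False)
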