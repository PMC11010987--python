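"""Bias-based preamplification model.

Methylation-specific preamplification deliberately amplifies
bisulphite-retained (methylated) template with a higher per-cycle
efficiency than unmethylated template.  After ``c`` cycles the share of
methylated fragments among all target fragments — the PCR bias ``B`` —
approaches 100%, which is what makes minute amounts of tumour-derived
methylated cfDNA detectable against the unmethylated background.

The model is parameterised directly by per-cycle efficiencies
``(E_m, E_u)`` because reaction conditions (annealing temperature,
Mg2+ concentration) map onto efficiencies only empirically; conditions
are carried as metadata so grids of wet-lab conditions can be screened
once efficiencies have been measured or assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PreampCondition",
    "BiasResult",
    "ScreenRecord",
    "amplify_deterministic",
    "amplify_stochastic",
    "screen_conditions",
    "cpd_check",
    "read_condition_grid",
    "write_screen_report",
]

#: Feasibility floor on PCR bias, percent (strict ``B > BIAS_FLOOR``).
BIAS_FLOOR = 90.0
#: Minimum unmethylated copies required after preamplification so that
#: the unmethylated channel remains usable as an internal control.
MIN_UNMETH_COPIES = 500.0
#: A ddPCR well is only countable while copies-per-droplet stays
#: strictly below this occupancy.
CPD_LIMIT = 6.0


@dataclass(frozen=True)
class PreampCondition:
    """One preamplification condition.

    ``annealing_temp_c`` and ``mg_mm`` are metadata describing the
    wet-lab condition; the kinetics are fully determined by the
    per-cycle duplication probabilities ``e_m`` (methylated template)
    and ``e_u`` (unmethylated template) and the cycle count ``cycles``.
    ``amplitude_proxy_m``/``_u`` are relative fluorescence expectations
    used by :func:`screen_conditions` when an amplitude floor is set.
    """

    e_m: float
    e_u: float
    cycles: int = 12
    annealing_temp_c: float | None = None
    mg_mm: float | None = None
    amplitude_proxy_m: float = 1.0
    amplitude_proxy_u: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_m <= 1.0 and 0.0 <= self.e_u <= 1.0):
            raise ValueError("efficiencies must lie in [0, 1]")
        if self.cycles < 0:
            raise ValueError("cycle count must be non-negative")
        if self.e_u > self.e_m:
            warnings.warn(
                "condition does not favour methylated template (E_u > E_m)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BiasResult:
    """Copy counts after amplification and the resulting bias in percent."""

    n_m: float
    n_u: float
    bias_pct: float


def _bias_pct(n_m: float, n_u: float) -> float:
    total = n_m + n_u
    if total <= 0:
        raise ValueError("PCR bias is undefined when no template is present")
    return 100.0 * n_m / total


def amplify_deterministic(
    n0_m: float, n0_u: float, cond: PreampCondition
) -> BiasResult:
    """Expected copy numbers after ``cond.cycles`` cycles.

    Each cycle multiplies the template pool by ``(1 + E)``, so
    ``N = N0 * (1 + E)**c``.  The bias is the methylated percentage of
    the total pool.  Raises ``ValueError`` when both inputs are zero
    (the bias is then undefined).
    """
    if n0_m < 0 or n0_u < 0:
        raise ValueError("input copy numbers must be non-negative")
    n_m = n0_m * (1.0 + cond.e_m) ** cond.cycles
    n_u = n0_u * (1.0 + cond.e_u) ** cond.cycles
    return BiasResult(n_m=n_m, n_u=n_u, bias_pct=_bias_pct(n_m, n_u))


def amplify_stochastic(
    n0_m: int, n0_u: int, cond: PreampCondition, rng: np.random.Generator
) -> BiasResult:
    """One branching-process realisation of the amplification.

    Per cycle every molecule duplicates independently with probability
    ``E``, i.e. ``N <- N + Binomial(N, E)``.  The mean over
    realisations converges to :func:`amplify_deterministic`.
    """
    if n0_m < 0 or n0_u < 0:
        raise ValueError("input copy numbers must be non-negative")
    if n0_m + n0_u == 0:
        raise ValueError("PCR bias is undefined when no template is present")
    n_m, n_u = int(n0_m), int(n0_u)
    for _ in range(cond.cycles):
        n_m += int(rng.binomial(n_m, cond.e_m)) if n_m else 0
        n_u += int(rng.binomial(n_u, cond.e_u)) if n_u else 0
    return BiasResult(n_m=float(n_m), n_u=float(n_u), bias_pct=_bias_pct(n_m, n_u))


@dataclass(frozen=True)
class ScreenRecord:
    """Screening outcome for one condition."""

    condition: PreampCondition
    result: BiasResult
    passed: bool
    failed_criteria: tuple[str, ...] = field(default_factory=tuple)


def screen_conditions(
    grid: Sequence[PreampCondition],
    n0_m: float = 50.0,
    n0_u: float = 50.0,
    bias_floor: float = BIAS_FLOOR,
    min_unmeth_copies: float = MIN_UNMETH_COPIES,
    amplitude_floor: float = 0.0,
) -> list[ScreenRecord]:
    """Screen a condition grid against the feasibility criteria.

    A condition passes when (1) the bias exceeds ``bias_floor`` percent,
    (2) fluorescence amplitude proxies reach ``amplitude_floor`` and
    (3) at least ``min_unmeth_copies`` unmethylated copies survive as an
    internal control.  Every rejection names the criteria it failed.
    The default 50/50 input emulates a 50%-methylated standard.
    """
    if len(grid) == 0:
        raise ValueError("condition grid is empty")
    records = []
    for cond in grid:
        res = amplify_deterministic(n0_m, n0_u, cond)
        failed = []
        if not res.bias_pct > bias_floor:
            failed.append("bias")
        if min(cond.amplitude_proxy_m, cond.amplitude_proxy_u) < amplitude_floor:
            failed.append("amplitude")
        if not res.n_u >= min_unmeth_copies:
            failed.append("unmethylated_copies")
        records.append(
            ScreenRecord(
                condition=cond,
                result=res,
                passed=not failed,
                failed_criteria=tuple(failed),
            )
        )
    return records


def cpd_check(
    copies_in_reaction: float, n_droplets: int, limit: float = CPD_LIMIT
) -> tuple[float, bool]:
    """Copies-per-droplet occupancy and whether it is strictly below ``limit``."""
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if copies_in_reaction < 0:
        raise ValueError("copy number must be non-negative")
    cpd = copies_in_reaction / n_droplets
    return cpd, cpd < limit


def read_condition_grid(path) -> list[PreampCondition]:
    """Read a condition grid CSV (columns temp_C, mg_mM, cycles, E_m, E_u)."""
    frame = pd.read_csv(path)
    conds = []
    for row in frame.itertuples(index=False):
        conds.append(
            PreampCondition(
                e_m=float(row.E_m),
                e_u=float(row.E_u),
                cycles=int(row.cycles),
                annealing_temp_c=float(row.temp_C) if "temp_C" in frame else None,
                mg_mm=float(row.mg_mM) if "mg_mM" in frame else None,
            )
        )
    return conds


def write_screen_report(records: Sequence[ScreenRecord], path) -> pd.DataFrame:
    """Write a per-condition pass/fail report as CSV; returns the frame."""
    rows = []
    for rec in records:
        rows.append(
            {
                "temp_C": rec.condition.annealing_temp_c,
                "mg_mM": rec.condition.mg_mm,
                "cycles": rec.condition.cycles,
                "E_m": rec.condition.e_m,
                "E_u": rec.condition.e_u,
                "N_m": rec.result.n_m,
                "N_u": rec.result.n_u,
                "bias_pct": rec.result.bias_pct,
                "passed": rec.passed,
                "failed_criteria": ";".join(rec.failed_criteria),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
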