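"""Composite prostate-cancer risk scores over cfDNA methylation markers.

Two PSA-independent scores (piRISK1/2) combine methylated RASSF1A,
MIR129-2, NRIP3 and SOX8 copies/mL with total cfDNA/mL and patient age;
the PSA-dependent scores (PRISK1/2) add the free-to-total PSA ratio
QfPSA.  Each component contributes one point when it exceeds its cutoff
in the risk direction (strictly above for markers, cfDNA and age;
strictly below for QfPSA, since a low free fraction indicates cancer),
and a patient is called positive when the point total reaches the score
threshold (3 of 6 for piRISK, 4 of 7 for PRISK).  The additive
count-of-exceedances form is a documented reconstruction of the
published integer scores.

Variant 1 of each score is calibrated so that every clinically
significant AND indolent cancer patient is positive (100% sensitivity
on both); variant 2 constrains only clinically significant cancers,
buying additional specificity for benign hyperplasia at the price of
calling some indolent cancers negative.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "RiskModel",
    "CalibrationError",
    "qfpsa",
    "component_flags",
    "score",
    "calibrate_cutoffs",
    "score_cohort",
    "records_to_frame",
    "frame_to_records",
    "model_skeleton",
    "save_model",
    "load_model",
]

PANEL_MARKERS = ("RASSF1A", "MIR129-2", "NRIP3", "SOX8")
PIRISK_COMPONENTS = PANEL_MARKERS + ("cfDNA_ng_ml", "age")
PRISK_COMPONENTS = PIRISK_COMPONENTS + ("QfPSA",)
#: Components that score a point when BELOW their cutoff.
BELOW_DIRECTION = frozenset({"QfPSA"})

VARIANTS = ("piRISK1", "piRISK2", "PRISK1", "PRISK2")


class CalibrationError(ValueError):
    """Raised when no cutoff assignment satisfies the sensitivity constraint."""


@dataclass
class PatientRecord:
    """Clinical covariates plus per-marker methylation for one patient."""

    sample_id: str
    group: str  # control / BPH / indolent_PCa / cs_PCa / unknown
    age: float
    tpsa_ng_ml: float
    fpsa_ng_ml: float
    cfdna_ng_ml: float
    plasma_ml: float
    marker_copies_per_ml: dict[str, float] = field(default_factory=dict)
    marker_positive_call: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tpsa_ng_ml > 0 and not 0 <= self.fpsa_ng_ml <= self.tpsa_ng_ml:
            raise ValueError(f"{self.sample_id}: fPSA must lie in [0, tPSA]")
        for m, v in self.marker_copies_per_ml.items():
            if v < 0:
                raise ValueError(f"{self.sample_id}: negative copies/mL for {m}")

    @property
    def qfpsa_pct(self) -> float:
        return qfpsa(self.fpsa_ng_ml, self.tpsa_ng_ml)


def qfpsa(fpsa: float, tpsa: float) -> float:
    """Free-to-total PSA ratio in percent, ``100*fPSA/tPSA``."""
    if tpsa <= 0:
        raise ValueError("tPSA must be positive")
    return 100.0 * fpsa / tpsa


@dataclass(frozen=True)
class RiskModel:
    """A fitted (or skeleton) composite risk score."""

    variant: str
    components: tuple[str, ...]
    cutoffs: dict[str, float]
    tau: int
    sensitivity_targets: tuple[str, ...]
    achieved_sen_pct: float | None = None
    achieved_spe_pct: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant.startswith("PRISK") and "QfPSA" not in self.components:
            raise ValueError("PRISK variants must include QfPSA")
        if self.variant.startswith("piRISK") and "QfPSA" in self.components:
            raise ValueError("piRISK variants must exclude QfPSA")
        if self.tau < 1:
            raise ValueError("score threshold must be >= 1")

    def direction(self, component: str) -> str:
        return "below" if component in BELOW_DIRECTION else "above"


def model_skeleton(variant: str) -> RiskModel:
    """Uncalibrated model for a variant: components, threshold, target set."""
    if variant.startswith("PRISK"):
        components, tau = PRISK_COMPONENTS, 4
    else:
        components, tau = PIRISK_COMPONENTS, 3
    targets = ("cs_PCa",) if variant.endswith("2") else ("cs_PCa", "indolent_PCa")
    return RiskModel(
        variant=variant,
        components=components,
        cutoffs={},
        tau=tau,
        sensitivity_targets=targets,
    )


def _component_value(record: PatientRecord, component: str) -> float:
    if component == "age":
        return record.age
    if component == "cfDNA_ng_ml":
        return record.cfdna_ng_ml
    if component == "QfPSA":
        return record.qfpsa_pct
    if component in record.marker_copies_per_ml:
        return record.marker_copies_per_ml[component]
    raise KeyError(component)


def _component_matrix(
    records: list[PatientRecord], components: tuple[str, ...]
) -> np.ndarray:
    rows = []
    for rec in records:
        try:
            rows.append([_component_value(rec, c) for c in components])
        except KeyError as exc:
            raise ValueError(
                f"record {rec.sample_id} is missing component {exc.args[0]!r}"
            ) from exc
    return np.asarray(rows, dtype=float)


def component_flags(record: PatientRecord, model: RiskModel) -> np.ndarray:
    """Binary risk flags for one patient, in component order.

    A component flags when it strictly exceeds its cutoff in the risk
    direction; values exactly at the cutoff never flag.
    """
    missing = [c for c in model.components if c not in model.cutoffs]
    if missing:
        raise ValueError(f"model has no cutoff for components: {missing}")
    x = _component_matrix([record], model.components)[0]
    theta = np.array([model.cutoffs[c] for c in model.components])
    below = np.array([c in BELOW_DIRECTION for c in model.components])
    return np.where(below, x < theta, x > theta).astype(int)


def score(record: PatientRecord, model: RiskModel) -> tuple[int, bool]:
    """Integer score (flag count) and the biopsy call (``score >= tau``)."""
    s = int(component_flags(record, model).sum())
    return s, s >= model.tau


def score_cohort(records: list[PatientRecord], model: RiskModel) -> pd.DataFrame:
    """Score every record; returns sample_id, group, score, call."""
    rows = []
    for rec in records:
        s, call = score(rec, model)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "group": rec.group,
                "variant": model.variant,
                "score": s,
                "call": call,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration


def _candidates(values: np.ndarray) -> np.ndarray:
    """Candidate cutoffs: midpoints between order statistics plus the
    two extremes (flag-everyone / flag-no-one).  The optimum of a step
    function in theta always lies in this set."""
    uniq = np.unique(values)
    cands = [uniq[0] - 1.0]
    if uniq.size > 1:
        cands.extend(0.5 * (uniq[:-1] + uniq[1:]))
    cands.append(uniq[-1] + 1.0)
    return np.asarray(cands)


def _flag_tables(
    x: np.ndarray, components: tuple[str, ...]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-component candidate cutoffs and (candidate x patient) flags."""
    cand_list, table_list = [], []
    for j, comp in enumerate(components):
        cands = _candidates(x[:, j])
        if comp in BELOW_DIRECTION:
            flags = x[None, :, j] < cands[:, None]
        else:
            flags = x[None, :, j] > cands[:, None]
        cand_list.append(cands)
        table_list.append(flags.astype(np.int16))
    return cand_list, table_list


def _metrics(
    s: np.ndarray, tau: int, target_mask: np.ndarray, bph_mask: np.ndarray
) -> tuple[bool, float]:
    """(sensitivity constraint satisfied, specificity on BPH)."""
    sen_ok = bool(np.all(s[target_mask] >= tau))
    spe = float(np.mean(s[bph_mask] < tau)) if bph_mask.any() else 0.0
    return sen_ok, spe


#: Exact enumeration is used while the candidate grid stays below this
#: many (combination x patient) evaluations; larger problems fall back
#: to coordinate sweeps.
EXACT_SEARCH_BUDGET = 20_000_000


def calibrate_cutoffs(
    records: list[PatientRecord],
    skeleton: RiskModel,
    max_sweeps: int = 25,
    pair_refinement: bool = True,
) -> RiskModel:
    """Fit per-component cutoffs under the 100%-sensitivity constraint.

    Grid search over the candidate cutoffs of each component (midpoints
    between observed values, plus flag-everyone / flag-no-one
    extremes): the optimum of the step-function score always lies on
    this grid.  Small grids (tiny cohorts) are enumerated exactly; for
    cohort-scale problems the search is coordinate-wise, starting from
    the all-flagging assignment (which satisfies the constraint
    trivially) and sweeping components in order, each set to the cutoff
    that keeps sensitivity at 100% on the target groups while
    maximising specificity on BPH, with a pairwise sweep to escape
    two-component local optima.  Ties prefer the more conservative
    cutoff (the one flagging fewer patients), then earlier components
    win by sweep order.  The returned model always satisfies the
    sensitivity constraint on its training cohort; this is asserted.
    """
    target_mask = np.array(
        [r.group in skeleton.sensitivity_targets for r in records]
    )
    bph_mask = np.array([r.group == "BPH" for r in records])
    if not target_mask.any():
        raise CalibrationError("no sensitivity-target patients in cohort")
    if not bph_mask.any():
        raise CalibrationError("no BPH patients in cohort")

    comps = skeleton.components
    x = _component_matrix(records, comps)
    cand_list, tables = _flag_tables(x, comps)
    k = len(comps)
    if skeleton.tau > k:
        raise CalibrationError("score threshold exceeds component count")

    n = len(records)
    grid_size = n * int(np.prod([len(c) for c in cand_list], dtype=np.int64))
    if grid_size <= EXACT_SEARCH_BUDGET:
        idx = _exact_search(
            tables, cand_list, comps, skeleton.tau, target_mask, bph_mask
        )
        if idx is None:
            raise CalibrationError("no cutoff assignment reaches 100% sensitivity")
        cutoffs = {comps[j]: float(cand_list[j][idx[j]]) for j in range(k)}
        s = sum(tables[j][idx[j]] for j in range(k))
        _, spe = _metrics(s, skeleton.tau, target_mask, bph_mask)
        return replace(
            skeleton,
            cutoffs=cutoffs,
            achieved_sen_pct=100.0,
            achieved_spe_pct=100.0 * spe,
        )

    # all-flagging start: extreme candidate index 0 ("below min") for
    # above-direction components, last ("above max") for below-direction.
    idx = [
        len(cand_list[j]) - 1 if comps[j] in BELOW_DIRECTION else 0
        for j in range(k)
    ]
    # tie-break preference: larger theta for above-direction components,
    # smaller theta for QfPSA -> both mean "flag fewer patients".
    pref = [
        np.argsort(cand_list[j])[::-1] if comps[j] not in BELOW_DIRECTION
        else np.argsort(cand_list[j])
        for j in range(k)
    ]

    def total(idx_vec):
        return sum(tables[j][idx_vec[j]] for j in range(k))

    def best_single_sweep(idx_vec, current_spe):
        improved = False
        for j in range(k):
            s_minus = total(idx_vec) - tables[j][idx_vec[j]]
            s_all = s_minus[None, :] + tables[j]  # (C_j, n)
            sen_ok = np.all(s_all[:, target_mask] >= skeleton.tau, axis=1)
            spe = np.mean(s_all[:, bph_mask] < skeleton.tau, axis=1)
            spe = np.where(sen_ok, spe, -1.0)
            best_spe = spe.max()
            if best_spe < 0:
                continue
            # among maximisers pick the preferred (most conservative) cutoff
            for c in pref[j]:
                if spe[c] == best_spe:
                    choice = int(c)
                    break
            if best_spe > current_spe + 1e-12 or (
                best_spe == current_spe and choice != idx_vec[j]
                and _is_more_conservative(cand_list[j], choice, idx_vec[j],
                                          comps[j] in BELOW_DIRECTION)
            ):
                if idx_vec[j] != choice:
                    improved = improved or best_spe > current_spe + 1e-12
                    idx_vec[j] = choice
                    current_spe = best_spe
        return idx_vec, current_spe, improved

    def best_pair_sweep(idx_vec, current_spe):
        improved = False
        for j1, j2 in itertools.combinations(range(k), 2):
            s_minus = (
                total(idx_vec) - tables[j1][idx_vec[j1]] - tables[j2][idx_vec[j2]]
            )
            s_all = (
                s_minus[None, None, :]
                + tables[j1][:, None, :]
                + tables[j2][None, :, :]
            )  # (C1, C2, n)
            sen_ok = np.all(s_all[:, :, target_mask] >= skeleton.tau, axis=2)
            spe = np.mean(s_all[:, :, bph_mask] < skeleton.tau, axis=2)
            spe = np.where(sen_ok, spe, -1.0)
            best_spe = float(spe.max())
            if best_spe > current_spe + 1e-12:
                c1, c2 = np.unravel_index(int(np.argmax(spe)), spe.shape)
                idx_vec[j1], idx_vec[j2] = int(c1), int(c2)
                current_spe = best_spe
                improved = True
        return idx_vec, current_spe, improved

    s = total(idx)
    _, spe = _metrics(s, skeleton.tau, target_mask, bph_mask)
    for _ in range(max_sweeps):
        idx, spe, improved1 = best_single_sweep(idx, spe)
        improved2 = False
        if pair_refinement and not improved1:
            idx, spe, improved2 = best_pair_sweep(idx, spe)
        if not (improved1 or improved2):
            break

    cutoffs = {comps[j]: float(cand_list[j][idx[j]]) for j in range(k)}
    s = total(idx)
    sen_ok, spe = _metrics(s, skeleton.tau, target_mask, bph_mask)
    if not sen_ok:
        bad = [
            records[i].sample_id
            for i in np.nonzero(target_mask & (s < skeleton.tau))[0]
        ]
        raise CalibrationError(
            f"no cutoff assignment reaches 100% sensitivity; failing: {bad}"
        )
    sen_pct = 100.0
    return replace(
        skeleton,
        cutoffs=cutoffs,
        achieved_sen_pct=sen_pct,
        achieved_spe_pct=100.0 * spe,
    )


def _exact_search(tables, cand_list, comps, tau, target_mask, bph_mask):
    """Enumerate the full candidate grid (small problems only).

    Candidate axes are pre-ordered most-conservative-first so the first
    maximiser found in C-order realises the tie-break preference.
    Returns candidate indices per component, or None when infeasible.
    """
    k = len(tables)
    orders = []
    for j in range(k):
        if comps[j] in BELOW_DIRECTION:
            order = np.argsort(cand_list[j])  # smaller theta flags fewer
        else:
            order = np.argsort(cand_list[j])[::-1]
        orders.append(order)
    shape = tuple(len(c) for c in cand_list)
    s = np.zeros(shape + (tables[0].shape[1],), dtype=np.int16)
    for j in range(k):
        view_shape = [1] * k + [tables[j].shape[1]]
        view_shape[j] = shape[j]
        s = s + tables[j][orders[j]].reshape(view_shape)
    sen_ok = np.all(s[..., target_mask] >= tau, axis=-1)
    spe = np.mean(s[..., bph_mask] < tau, axis=-1)
    spe = np.where(sen_ok, spe, -1.0)
    flat_best = int(np.argmax(spe))
    if spe.reshape(-1)[flat_best] < 0:
        return None
    pos = np.unravel_index(flat_best, shape)
    return [int(orders[j][pos[j]]) for j in range(k)]


def _is_more_conservative(
    cands: np.ndarray, new: int, old: int, below: bool
) -> bool:
    if below:
        return cands[new] < cands[old]
    return cands[new] > cands[old]


# ---------------------------------------------------------------------------
# container conversion and model persistence

SHEET_COLUMNS = (
    "sample_id",
    "group",
    "age",
    "tPSA",
    "fPSA",
    "QfPSA",
    "cfDNA_ng_ml",
    "plasma_ml",
)


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Sample sheet plus per-marker copies/mL columns."""
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "group": r.group,
            "age": r.age,
            "tPSA": r.tpsa_ng_ml,
            "fPSA": r.fpsa_ng_ml,
            "QfPSA": r.qfpsa_pct,
            "cfDNA_ng_ml": r.cfdna_ng_ml,
            "plasma_ml": r.plasma_ml,
        }
        row.update(r.marker_copies_per_ml)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    marker_cols = [c for c in frame.columns if c not in SHEET_COLUMNS]
    records = []
    for row in frame.to_dict(orient="records"):
        records.append(
            PatientRecord(
                sample_id=str(row["sample_id"]),
                group=str(row.get("group", "unknown")),
                age=float(row["age"]),
                tpsa_ng_ml=float(row["tPSA"]),
                fpsa_ng_ml=float(row["fPSA"]),
                cfdna_ng_ml=float(row["cfDNA_ng_ml"]),
                plasma_ml=float(row.get("plasma_ml", 3.0)),
                marker_copies_per_ml={
                    m: float(row[m]) for m in marker_cols if pd.notna(row[m])
                },
            )
        )
    return records


def save_model(model: RiskModel, path) -> None:
    payload = {
        "variant": model.variant,
        "components": list(model.components),
        "cutoffs": model.cutoffs,
        "tau": model.tau,
        "sensitivity_targets": list(model.sensitivity_targets),
        "achieved_sen_pct": model.achieved_sen_pct,
        "achieved_spe_pct": model.achieved_spe_pct,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> RiskModel:
    with open(path) as fh:
        payload = json.load(fh)
    return RiskModel(
        variant=payload["variant"],
        components=tuple(payload["components"]),
        cutoffs={k: float(v) for k, v in payload["cutoffs"].items()},
        tau=int(payload["tau"]),
        sensitivity_targets=tuple(payload["sensitivity_targets"]),
        achieved_sen_pct=payload.get("achieved_sen_pct"),
        achieved_spe_pct=payload.get("achieved_spe_pct"),
    )
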