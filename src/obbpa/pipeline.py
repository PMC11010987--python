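"""End-to-end glue: simulated cohort -> droplet wells -> measured records.

Couples the synthetic generator to the droplet quantifier the way a lab
runs the assay: duplicate wells per sample x marker, and saturated
wells (every droplet positive, concentration unresolvable) re-measured
at increasing dilution with the dilution factor multiplied back into
copies/mL.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .droplet_quant import SaturationError, VolumeModel, quantify_sample
from .risk_scoring import PatientRecord
from .synthetic_cohort import SimulationConfig, simulate_patient_wells

__all__ = ["measure_cohort", "measured_records"]

PANEL = ("RASSF1A", "MIR129-2", "NRIP3", "SOX8")
DILUTION_SERIES = (1, 10, 100, 1000)


def _diluted_record(record: PatientRecord, dilution: int) -> PatientRecord:
    if dilution == 1:
        return record
    return PatientRecord(
        sample_id=record.sample_id,
        group=record.group,
        age=record.age,
        tpsa_ng_ml=record.tpsa_ng_ml,
        fpsa_ng_ml=record.fpsa_ng_ml,
        cfdna_ng_ml=record.cfdna_ng_ml / dilution,
        plasma_ml=record.plasma_ml,
        marker_copies_per_ml={
            m: v / dilution for m, v in record.marker_copies_per_ml.items()
        },
    )


def measure_cohort(
    records: list[PatientRecord],
    config: SimulationConfig,
    markers: tuple[str, ...] = PANEL,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Simulate and quantify droplet wells for a whole cohort.

    Returns one row per sample x marker with dilution-corrected
    copies/mL for both channels, the positive call and the dilution
    used.  Wells are generated and discarded one sample at a time, so
    memory stays flat regardless of cohort size.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for record in records:
        for marker in markers:
            for dilution in DILUTION_SERIES:
                wells = simulate_patient_wells(
                    _diluted_record(record, dilution), marker, config, rng,
                    n_replicates=n_replicates,
                )
                vm = VolumeModel(
                    plasma_volume_ml=record.plasma_ml,
                    preamp_gain_m=config.ddpcr.preamp_gain_m,
                    preamp_gain_u=config.ddpcr.preamp_gain_u,
                )
                try:
                    res = quantify_sample(wells, vm)
                except SaturationError:
                    continue
                res["copies_per_ml_m"] *= dilution
                res["copies_per_ml_u"] *= dilution
                res["dilution"] = dilution
                rows.append(res)
                break
            else:
                raise SaturationError(
                    f"{record.sample_id}/{marker} saturated at every dilution"
                )
    return pd.DataFrame(rows)


def measured_records(
    records: list[PatientRecord], quant: pd.DataFrame
) -> list[PatientRecord]:
    """Clone patient records with marker levels replaced by measured ones."""
    by_sample: dict[str, dict[str, float]] = {}
    calls: dict[str, dict[str, bool]] = {}
    for row in quant.itertuples(index=False):
        by_sample.setdefault(row.sample_id, {})[row.marker] = row.copies_per_ml_m
        if row.positive_call is not None:
            calls.setdefault(row.sample_id, {})[row.marker] = bool(row.positive_call)
    out = []
    for rec in records:
        out.append(
            PatientRecord(
                sample_id=rec.sample_id,
                group=rec.group,
                age=rec.age,
                tpsa_ng_ml=rec.tpsa_ng_ml,
                fpsa_ng_ml=rec.fpsa_ng_ml,
                cfdna_ng_ml=rec.cfdna_ng_ml,
                plasma_ml=rec.plasma_ml,
                marker_copies_per_ml=dict(by_sample.get(rec.sample_id, {})),
                marker_positive_call=dict(calls.get(rec.sample_id, {})),
            )
        )
    return out
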