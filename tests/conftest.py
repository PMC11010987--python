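import dataclasses

import numpy as np
import pytest

from obbpa import synthetic_cohort as sc
from obbpa.risk_scoring import PatientRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return sc.default_config(seed=7)


def make_record(sample_id="p0", group="BPH", age=65.0, tpsa=5.0, qfpsa=25.0,
                cfdna=40.0, **markers) -> PatientRecord:
    """Minimal patient record; marker levels default to 0."""
    levels = {m: 0.0 for m in ("RASSF1A", "MIR129-2", "NRIP3", "SOX8")}
    levels.update(markers)
    return PatientRecord(
        sample_id=sample_id,
        group=group,
        age=age,
        tpsa_ng_ml=tpsa,
        fpsa_ng_ml=tpsa * qfpsa / 100.0,
        cfdna_ng_ml=cfdna,
        plasma_ml=3.0,
        marker_copies_per_ml=levels,
    )


def degenerate_config(seed=0):
    """All dispersion removed: every draw equals its group mean."""
    cfg = sc.default_config(seed=seed)
    groups = {}
    for label, gp in cfg.groups.items():
        groups[label] = dataclasses.replace(
            gp,
            age_sd=0.0,
            qfpsa_sd=0.0,
            cfdna_sd=0.0,
            marker_params={m: (mv[0], 0.0) for m, mv in gp.marker_params.items()},
            zero_fraction=0.0,
        )
    return dataclasses.replace(cfg, groups=groups, marker_correlation=0.0)
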