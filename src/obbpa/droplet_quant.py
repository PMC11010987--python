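"""Droplet-level ddPCR quantification.

Turns two-channel droplet fluorescence (FAM = methylated target,
HEX = unmethylated target) into copies per mL of blood plasma:

1. per-well baseline normalisation, so wells are comparable;
2. droplet classification against a per-channel threshold;
3. Poisson inversion of the positive-droplet fraction,
   ``lambda = -ln(1 - k/n)``, to copies per droplet and per reaction;
4. volume back-calculation to copies per mL plasma;
5. the duplicate-well positive-call rule (more than 5 positive
   droplets in at least two wells) and fractional abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DropletWell",
    "QuantResult",
    "VolumeModel",
    "SaturationError",
    "normalize_well",
    "classify_droplets",
    "poisson_concentration",
    "copies_per_ml",
    "call_sample",
    "fractional_abundance",
    "spike_recovery",
    "quantify_well",
    "quantify_sample",
    "read_droplet_csv",
    "write_droplet_csv",
    "two_means_1d",
]

#: Minimum droplet count for a stable baseline estimate.
MIN_DROPLETS_FOR_BASELINE = 100
#: Below this separation (RFU) between the two 1-D cluster centres a
#: well is treated as single-cluster (no positive population).
MIN_CLUSTER_SEPARATION = 1000.0
#: A sample is positive when more than this many droplets are positive
#: in at least MIN_POSITIVE_WELLS replicate wells.
MIN_POSITIVE_DROPLETS = 5
MIN_POSITIVE_WELLS = 2


class SaturationError(ValueError):
    """Raised when every droplet is positive; the sample must be diluted."""


@dataclass(frozen=True)
class DropletWell:
    """Per-droplet two-channel amplitudes for one well of one marker."""

    well_id: str
    sample_id: str
    marker: str
    replicate: int
    ch1: np.ndarray  # FAM, methylated
    ch2: np.ndarray  # HEX, unmethylated

    def __post_init__(self) -> None:
        object.__setattr__(self, "ch1", np.asarray(self.ch1, dtype=float))
        object.__setattr__(self, "ch2", np.asarray(self.ch2, dtype=float))
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise ValueError("channel vectors must be 1-D and equally long")
        if self.n_droplets == 0:
            raise ValueError("a well must contain at least one droplet")

    @property
    def n_droplets(self) -> int:
        return int(self.ch1.size)


@dataclass(frozen=True)
class VolumeModel:
    """Volume chain from blood plasma to the ddPCR reaction.

    cfDNA is extracted from ``plasma_volume_ml`` of plasma, eluted and
    concentrated down to ``final_eluate_ul`` of which
    ``input_per_well_ul`` is loaded per preamplification/ddPCR well.
    ``preamp_gain_m``/``_u`` divide reaction-level copies back to
    template scale; the default of 1 reports copies on the scale of the
    loaded template (the convention used for all cohort-level numbers
    here, since preamplified product is diluted back before ddPCR).
    """

    plasma_volume_ml: float = 3.0
    extraction_elution_ul: float = 40.0
    bisulphite_elution_ul: float = 40.0
    final_eluate_ul: float = 12.0
    input_per_well_ul: float = 4.0
    droplet_volume_nl: float = 0.85
    preamp_gain_m: float = 1.0
    preamp_gain_u: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "plasma_volume_ml",
            "extraction_elution_ul",
            "bisulphite_elution_ul",
            "final_eluate_ul",
            "input_per_well_ul",
            "droplet_volume_nl",
            "preamp_gain_m",
            "preamp_gain_u",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one well (both channels)."""

    k_m: int
    k_u: int
    n: int
    lambda_m: float
    lambda_u: float
    copies_reaction_m: float
    copies_reaction_u: float
    copies_per_ml_m: float
    copies_per_ml_u: float
    fractional_abundance_pct: float | None


def two_means_1d(x: np.ndarray) -> tuple[float, float]:
    """Exact 1-D two-means: centres of the optimal two-cluster split.

    Sorts the values and scans every split point, minimising the total
    within-cluster sum of squares with prefix sums — deterministic and
    O(n log n), unlike seeded k-means.  Returns ``(low, high)`` centre;
    for constant input both centres coincide.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        m = float(x.mean()) if n else 0.0
        return m, m
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)  # left cluster size
    left_mean = csum[:-1] / k
    right_mean = (csum[-1] - csum[:-1]) / (n - k)
    left_ss = csq[:-1] - csum[:-1] ** 2 / k
    right_ss = (csq[-1] - csq[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - k)
    best = int(np.argmin(left_ss + right_ss))
    return float(left_mean[best]), float(right_mean[best])


def _channel_baseline(x: np.ndarray) -> float:
    """Baseline of one channel: the centre of the negative population.

    The two-cluster split is computed first; when the clusters are
    separated the baseline is the median of the droplets below the
    midpoint (the negative cluster), which stays correct even when
    positives outnumber negatives.  Single-cluster wells fall back to
    the overall median.
    """
    lo, hi = two_means_1d(x)
    if hi - lo < MIN_CLUSTER_SEPARATION:
        return float(np.median(x))
    mid = 0.5 * (lo + hi)
    return float(np.median(x[x < mid]))


def normalize_well(well: DropletWell) -> DropletWell:
    """Return the well with baseline-relative amplitudes per channel.

    Removes well-to-well shifts in absolute fluorescence so thresholds
    and downstream classification are comparable across wells.  Wells
    with fewer than 100 droplets are normalised anyway but trigger a
    low-confidence warning.
    """
    if well.n_droplets < MIN_DROPLETS_FOR_BASELINE:
        warnings.warn(
            f"well {well.well_id}: only {well.n_droplets} droplets; "
            "baseline estimate is low-confidence",
            stacklevel=2,
        )
    return replace(
        well,
        ch1=well.ch1 - _channel_baseline(well.ch1),
        ch2=well.ch2 - _channel_baseline(well.ch2),
    )


def _auto_threshold(x: np.ndarray) -> float:
    """Midpoint between the two cluster centres of a normalised channel.

    When no second cluster is resolvable (separation below
    ``MIN_CLUSTER_SEPARATION``) the threshold falls back to half the
    minimum separation above baseline, classifying every droplet of a
    clean negative well as negative.
    """
    lo, hi = two_means_1d(x)
    if hi - lo < MIN_CLUSTER_SEPARATION:
        return MIN_CLUSTER_SEPARATION / 2.0
    return 0.5 * (lo + hi)


def classify_droplets(
    well: DropletWell,
    threshold: tuple[float, float] | None = None,
) -> tuple[int, int, int]:
    """Count positive droplets per channel on a normalised well.

    ``threshold`` gives fixed per-channel cutoffs in baseline-relative
    RFU; by default each channel gets the midpoint between its two
    cluster centres.  Droplets strictly above threshold are positive.
    """
    if threshold is None:
        thr1, thr2 = _auto_threshold(well.ch1), _auto_threshold(well.ch2)
    else:
        thr1, thr2 = threshold
    if thr1 < 0 or thr2 < 0:
        raise ValueError("threshold below 0 after normalisation")
    k_m = int(np.count_nonzero(well.ch1 > thr1))
    k_u = int(np.count_nonzero(well.ch2 > thr2))
    return k_m, k_u, well.n_droplets


def poisson_concentration(k: int, n: int) -> tuple[float, float]:
    """Invert droplet occupancy to copies per droplet and per reaction.

    Molecules distribute over droplets approximately Poisson, so a
    positive fraction ``p = k/n`` implies ``lambda = -ln(1 - p)`` copies
    per droplet and ``lambda * n`` copies in the partitioned reaction.
    A fully saturated well (``k == n``) carries no concentration
    information and raises :class:`SaturationError`.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if k == n:
        raise SaturationError(
            "all droplets positive; concentration unresolvable - dilute the sample"
        )
    lam = float(-np.log1p(-k / n))
    return lam, lam * n


def copies_per_ml(
    copies_reaction: float, vm: VolumeModel, channel: str = "m"
) -> float:
    """Back-calculate reaction copies to copies per mL plasma.

    The whole eluate represents the full plasma draw, and one well sees
    ``input_per_well/final_eluate`` of it, so reaction copies are scaled
    by the inverse loading fraction, divided by the preamplification
    gain of the channel, and referred to the plasma volume.
    """
    if copies_reaction < 0:
        raise ValueError("copies_reaction must be non-negative")
    gain = vm.preamp_gain_m if channel == "m" else vm.preamp_gain_u
    return (
        copies_reaction
        * (vm.final_eluate_ul / vm.input_per_well_ul)
        / gain
        / vm.plasma_volume_ml
    )


def call_sample(
    k_m_per_well: Sequence[int],
    min_positive_droplets: int = MIN_POSITIVE_DROPLETS,
    min_positive_wells: int = MIN_POSITIVE_WELLS,
) -> bool | None:
    """Duplicate-well positive-call rule for one sample x marker.

    Positive only when at least ``min_positive_wells`` wells each show
    strictly more than ``min_positive_droplets`` positive droplets; the
    stringency guards against over-calling trace template that the
    biased preamplification inflates.  With a single replicate the call
    is indeterminate (returns ``None`` with a warning).
    """
    if len(k_m_per_well) < 2:
        warnings.warn("single replicate: positive call is indeterminate", stacklevel=2)
        return None
    hits = sum(1 for k in k_m_per_well if k > min_positive_droplets)
    return hits >= min_positive_wells


def fractional_abundance(copies_m: float, copies_u: float) -> float:
    """Methylated percentage of total marker copies, ``100*m/(m+u)``."""
    if copies_m < 0 or copies_u < 0:
        raise ValueError("copy numbers must be non-negative")
    total = copies_m + copies_u
    if total == 0:
        raise ValueError("fractional abundance undefined: both channels zero")
    return 100.0 * copies_m / total


def spike_recovery(
    measured_copies: float,
    expected_copies: float,
    qc_floor_pct: float = 50.0,
    qc_ceiling_pct: float = 150.0,
) -> tuple[float, bool]:
    """Spike-in recovery in percent and a QC pass flag.

    An external double-stranded DNA standard spiked into plasma tracks
    the joint loss of extraction and bisulphite conversion; recoveries
    outside ``[qc_floor_pct, qc_ceiling_pct]`` fail QC.
    """
    if expected_copies <= 0:
        raise ValueError("expected_copies must be positive")
    pct = 100.0 * measured_copies / expected_copies
    return pct, qc_floor_pct <= pct <= qc_ceiling_pct


def quantify_well(
    well: DropletWell,
    vm: VolumeModel,
    threshold: tuple[float, float] | None = None,
) -> QuantResult:
    """Normalise, classify and quantify one raw well on both channels."""
    norm = normalize_well(well)
    k_m, k_u, n = classify_droplets(norm, threshold)
    lam_m, copies_m = poisson_concentration(k_m, n)
    lam_u, copies_u = poisson_concentration(k_u, n)
    cpm_m = copies_per_ml(copies_m, vm, "m")
    cpm_u = copies_per_ml(copies_u, vm, "u")
    fa = None
    if cpm_m + cpm_u > 0:
        fa = fractional_abundance(cpm_m, cpm_u)
    return QuantResult(
        k_m=k_m,
        k_u=k_u,
        n=n,
        lambda_m=lam_m,
        lambda_u=lam_u,
        copies_reaction_m=copies_m,
        copies_reaction_u=copies_u,
        copies_per_ml_m=cpm_m,
        copies_per_ml_u=cpm_u,
        fractional_abundance_pct=fa,
    )


def quantify_sample(
    wells: Sequence[DropletWell],
    vm: VolumeModel,
    threshold: tuple[float, float] | None = None,
) -> dict:
    """Aggregate replicate wells of one sample x marker.

    Copies/mL are averaged over replicates; the positive call follows
    the duplicate-well rule on per-well positive-droplet counts.
    """
    if not wells:
        raise ValueError("no wells given")
    results = [quantify_well(w, vm, threshold) for w in wells]
    cpm_m = float(np.mean([r.copies_per_ml_m for r in results]))
    cpm_u = float(np.mean([r.copies_per_ml_u for r in results]))
    fa = fractional_abundance(cpm_m, cpm_u) if cpm_m + cpm_u > 0 else None
    return {
        "sample_id": wells[0].sample_id,
        "marker": wells[0].marker,
        "k_m": [r.k_m for r in results],
        "k_u": [r.k_u for r in results],
        "n": [r.n for r in results],
        "lambda_m": [r.lambda_m for r in results],
        "copies_per_ml_m": cpm_m,
        "copies_per_ml_u": cpm_u,
        "FA": fa,
        "positive_call": call_sample([r.k_m for r in results]),
    }


#: Column mapping for instrument-software droplet exports.
QUANTASOFT_COLUMNS = {
    "Ch1 Amplitude": "ch1_amplitude",
    "Ch2 Amplitude": "ch2_amplitude",
}


def read_droplet_csv(path, column_map: dict | None = None) -> list[DropletWell]:
    """Read a droplet CSV into wells.

    The native dialect has columns ``well_id, sample_id, marker,
    replicate, ch1_amplitude, ch2_amplitude`` (one row per droplet).
    ``column_map`` renames foreign dialects (e.g. instrument exports
    with ``Ch1 Amplitude``/``Ch2 Amplitude``) onto the native one.
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    wells = []
    for (well_id, sample_id, marker, rep), grp in frame.groupby(
        ["well_id", "sample_id", "marker", "replicate"], sort=True
    ):
        wells.append(
            DropletWell(
                well_id=str(well_id),
                sample_id=str(sample_id),
                marker=str(marker),
                replicate=int(rep),
                ch1=grp["ch1_amplitude"].to_numpy(),
                ch2=grp["ch2_amplitude"].to_numpy(),
            )
        )
    return wells


def write_droplet_csv(wells: Iterable[DropletWell], path) -> None:
    """Write wells to the native droplet CSV dialect."""
    frames = []
    for w in wells:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": w.well_id,
                    "sample_id": w.sample_id,
                    "marker": w.marker,
                    "replicate": w.replicate,
                    "ch1_amplitude": w.ch1,
                    "ch2_amplitude": w.ch2,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
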