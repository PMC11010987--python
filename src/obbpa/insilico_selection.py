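"""In-silico CpG biomarker selection on methylation beta values.

Candidate marker CpGs for a blood-based assay must be (i) strongly
hypermethylated in tumour tissue relative to the tissue of origin and
every other major cfDNA-shedding tissue, and (ii) essentially
unmethylated in the dominant cfDNA background (white blood cells,
healthy serum).  This module filters probes x samples beta-value
matrices accordingly: a general probe mask is applied first, per-probe
tumour-vs-tissue contrasts are tested, and probes passing every
contrast with a low background are ranked by their worst-case effect
size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BetaMatrix",
    "ProbeContrast",
    "SelectionCriteria",
    "apply_probe_mask",
    "probe_contrasts",
    "select_markers",
    "selection_table",
    "read_beta_tsv",
    "read_labels_csv",
    "read_mask_list",
]

TISSUE_LABELS = (
    "PCa_tissue",
    "prostate_normal",
    "bladder",
    "kidney",
    "liver",
    "lung",
    "WBC",
    "serum_ctrl",
    "serum_PCa",
)

DEFAULT_NORMAL_TISSUES = ("prostate_normal", "bladder", "kidney", "liver", "lung")
#: Below this per-group sample size Welch's t is replaced by a
#: permutation test on the mean difference.
SMALL_SAMPLE_N = 5


@dataclass
class BetaMatrix:
    """Beta values (probes x samples) with a tissue label per sample."""

    beta: pd.DataFrame
    tissue_labels: pd.Series

    def __post_init__(self) -> None:
        self.tissue_labels = self.tissue_labels.reindex(self.beta.columns)
        if self.tissue_labels.isna().any():
            missing = self.tissue_labels.index[self.tissue_labels.isna()].tolist()
            raise ValueError(f"samples without tissue label: {missing[:5]}")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1] (or be missing)")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    def samples_for(self, label: str) -> pd.DataFrame:
        cols = self.tissue_labels.index[self.tissue_labels == label]
        if len(cols) == 0:
            raise ValueError(f"tissue label not present in matrix: {label!r}")
        return self.beta[cols]


@dataclass(frozen=True)
class ProbeContrast:
    """Per-probe contrasts against each normal tissue plus backgrounds."""

    probe_id: str
    delta_beta: dict[str, float]  # tumour mean - tissue mean, per tissue
    p_value: dict[str, float]
    background_beta_wbc: float
    background_beta_serum: float


@dataclass(frozen=True)
class SelectionCriteria:
    """Filter thresholds for marker selection.

    ``allowed_exceptions`` lists (probe_id, tissue) pairs exempt from
    one contrast — the mechanism that records a deliberate keep of a
    probe elevated in a single off-target tissue.
    """

    alpha: float = 0.001
    min_delta_beta: float = 0.2
    max_background_beta: float = 0.10
    allowed_exceptions: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def apply_probe_mask(matrix: BetaMatrix, mask: Sequence[str]) -> BetaMatrix:
    """Drop masked probes, preserving the original probe order."""
    mask_set = set(mask)
    keep = [p for p in matrix.probe_ids if p not in mask_set]
    if not keep:
        warnings.warn("probe mask removed every probe", stacklevel=2)
    return BetaMatrix(
        beta=matrix.beta.loc[keep], tissue_labels=matrix.tissue_labels.copy()
    )


def _welch_or_permutation(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample p-value: Welch's t, permutation fallback for tiny groups.

    Degenerate inputs are conventioned: identical constant groups give
    p = 1, zero-variance groups with different means give p = 0.
    """
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if min(a.size, b.size) < SMALL_SAMPLE_N:
        res = stats.permutation_test(
            (a, b),
            lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=9999,
            rng=np.random.default_rng(0),
        )
        return float(res.pvalue)
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def probe_contrasts(
    matrix: BetaMatrix,
    tumour_label: str = "PCa_tissue",
    normal_labels: Sequence[str] = DEFAULT_NORMAL_TISSUES,
    background_labels: tuple[str, str] = ("WBC", "serum_ctrl"),
) -> list[ProbeContrast]:
    """Per-probe tumour-vs-normal contrasts with background means.

    For every probe and every normal tissue, computes the mean beta
    difference (tumour minus tissue) and a two-sample p-value (Welch's
    t; exact-ish permutation when a group has fewer than 5 samples).
    Missing betas are dropped pairwise, never imputed.
    """
    tumour = matrix.samples_for(tumour_label).to_numpy(dtype=float)
    normals = {
        lab: matrix.samples_for(lab).to_numpy(dtype=float) for lab in normal_labels
    }
    wbc = matrix.samples_for(background_labels[0]).to_numpy(dtype=float)
    serum = matrix.samples_for(background_labels[1]).to_numpy(dtype=float)

    out = []
    tumour_mean = np.nanmean(tumour, axis=1)
    wbc_mean = np.nanmean(wbc, axis=1)
    serum_mean = np.nanmean(serum, axis=1)
    for i, probe in enumerate(matrix.probe_ids):
        deltas, pvals = {}, {}
        for lab, arr in normals.items():
            deltas[lab] = float(tumour_mean[i] - np.nanmean(arr[i]))
            pvals[lab] = _welch_or_permutation(tumour[i], arr[i])
        out.append(
            ProbeContrast(
                probe_id=probe,
                delta_beta=deltas,
                p_value=pvals,
                background_beta_wbc=float(wbc_mean[i]),
                background_beta_serum=float(serum_mean[i]),
            )
        )
    return out


def _passes(contrast: ProbeContrast, criteria: SelectionCriteria) -> bool:
    alpha = criteria.alpha
    if criteria.bonferroni and contrast.p_value:
        alpha = alpha / len(contrast.p_value)
    for tissue in contrast.p_value:
        if (contrast.probe_id, tissue) in criteria.allowed_exceptions:
            continue
        p = contrast.p_value[tissue]
        if not (np.isfinite(p) and p < alpha):
            return False
        if not contrast.delta_beta[tissue] > criteria.min_delta_beta:
            return False
    if contrast.background_beta_wbc > criteria.max_background_beta:
        return False
    if contrast.background_beta_serum > criteria.max_background_beta:
        return False
    return True


def _rank_key(contrast: ProbeContrast, criteria: SelectionCriteria):
    considered = [
        d
        for t, d in contrast.delta_beta.items()
        if (contrast.probe_id, t) not in criteria.allowed_exceptions
    ]
    worst = min(considered) if considered else float("-inf")
    return (-worst, contrast.probe_id)


def select_markers(
    contrasts: Sequence[ProbeContrast], criteria: SelectionCriteria | None = None
) -> list[str]:
    """Filter and rank candidate probes.

    Keeps probes whose every non-exempt contrast is significant below
    ``alpha`` with a beta difference above ``min_delta_beta`` and whose
    background means stay at or below ``max_background_beta``.  Probes
    are ranked by their minimum (worst-case) beta difference across
    contrasts, descending, ties broken by probe id.
    """
    if not contrasts:
        raise ValueError("no contrasts given")
    criteria = criteria or SelectionCriteria()
    kept = [c for c in contrasts if _passes(c, criteria)]
    kept.sort(key=lambda c: _rank_key(c, criteria))
    return [c.probe_id for c in kept]


def selection_table(
    contrasts: Sequence[ProbeContrast], criteria: SelectionCriteria | None = None
) -> pd.DataFrame:
    """Ranked-candidates table with per-tissue deltas and p-values."""
    criteria = criteria or SelectionCriteria()
    selected = select_markers(contrasts, criteria)
    order = {p: i for i, p in enumerate(selected)}
    rows = []
    for c in contrasts:
        row = {
            "probe_id": c.probe_id,
            "selected": c.probe_id in order,
            "rank": order.get(c.probe_id, pd.NA),
            "min_delta_beta": min(c.delta_beta.values()),
            "background_beta_WBC": c.background_beta_wbc,
            "background_beta_serum": c.background_beta_serum,
        }
        for t in c.delta_beta:
            row[f"delta_{t}"] = c.delta_beta[t]
            row[f"p_{t}"] = c.p_value[t]
        rows.append(row)
    frame = pd.DataFrame(rows).sort_values(
        ["selected", "rank"], ascending=[False, True]
    )
    return frame.reset_index(drop=True)


def read_beta_tsv(beta_path, labels_path) -> BetaMatrix:
    """Read a probes-x-samples beta TSV plus a sample,label CSV."""
    beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path)
    series = pd.Series(
        labels.iloc[:, 1].to_numpy(), index=labels.iloc[:, 0].astype(str)
    )
    return BetaMatrix(beta=beta, tissue_labels=series)


def read_labels_csv(path) -> pd.Series:
    frame = pd.read_csv(path)
    return pd.Series(frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0].astype(str))


def read_mask_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
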