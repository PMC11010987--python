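"""CpG marker selection filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from obbpa.insilico_selection import (
    BetaMatrix,
    SelectionCriteria,
    apply_probe_mask,
    probe_contrasts,
    select_markers,
)
from obbpa.synthetic_cohort import generate_beta_matrix

SMALL_SIZES = {
    "PCa_tissue": 20,
    "prostate_normal": 12,
    "bladder": 8,
    "kidney": 12,
    "liver": 10,
    "lung": 10,
    "WBC": 15,
    "serum_ctrl": 5,
    "serum_PCa": 6,
}


def toy_matrix(probe_values: dict[str, dict[str, float]], n_per_tissue=20, noise=0.0,
               seed=0):
    """Build a BetaMatrix from per-probe per-tissue means."""
    rng = np.random.default_rng(seed)
    tissues = ("PCa_tissue", "prostate_normal", "bladder", "kidney", "liver",
               "lung", "WBC", "serum_ctrl")
    cols, labels, rows = [], [], {p: [] for p in probe_values}
    for t in tissues:
        for j in range(n_per_tissue):
            cols.append(f"{t}_{j}")
            labels.append(t)
            for p, means in probe_values.items():
                v = means.get(t, 0.05)
                if noise:
                    v = float(np.clip(v + rng.normal(0, noise), 0, 1))
                rows[p].append(v)
    beta = pd.DataFrame(rows, index=cols).T
    return BetaMatrix(beta=beta, tissue_labels=pd.Series(labels, index=cols))


def brute_force_select(matrix, criteria):
    """Independent oracle: explicit loop over probes x contrasts."""
    normals = ("prostate_normal", "bladder", "kidney", "liver", "lung")
    tumour = matrix.samples_for("PCa_tissue")
    kept = []
    for probe in matrix.probe_ids:
        t_vals = tumour.loc[probe].dropna().to_numpy()
        ok = True
        worst_delta = np.inf
        for tissue in normals:
            n_vals = matrix.samples_for(tissue).loc[probe].dropna().to_numpy()
            delta = t_vals.mean() - n_vals.mean()
            worst_delta = min(worst_delta, delta)
            if (probe, tissue) in criteria.allowed_exceptions:
                continue
            if t_vals.std(ddof=1) == 0 and n_vals.std(ddof=1) == 0:
                p = 1.0 if t_vals.mean() == n_vals.mean() else 0.0
            else:
                p = stats.ttest_ind(t_vals, n_vals, equal_var=False).pvalue
            if not (p < criteria.alpha and delta > criteria.min_delta_beta):
                ok = False
                break
        if not ok:
            continue
        wbc = matrix.samples_for("WBC").loc[probe].mean()
        serum = matrix.samples_for("serum_ctrl").loc[probe].mean()
        if wbc > criteria.max_background_beta or serum > criteria.max_background_beta:
            continue
        kept.append((probe, worst_delta))
    kept.sort(key=lambda pw: (-pw[1], pw[0]))
    return [p for p, _ in kept]


class TestApplyProbeMask:
    def test_empty_mask_is_identity(self):
        m = toy_matrix({f"cg{i}": {"PCa_tissue": 0.5} for i in range(5)})
        assert apply_probe_mask(m, []).probe_ids == m.probe_ids

    def test_full_mask_empties_with_warning(self):
        m = toy_matrix({f"cg{i}": {} for i in range(3)})
        with pytest.warns(UserWarning, match="every probe"):
            out = apply_probe_mask(m, m.probe_ids)
        assert out.probe_ids == []

    def test_partial_mask_preserves_order(self):
        m = toy_matrix({f"cg{i:02d}": {} for i in range(10)})
        out = apply_probe_mask(m, ["cg01", "cg04", "cg07"])
        assert out.probe_ids == [
            "cg00", "cg02", "cg03", "cg05", "cg06", "cg08", "cg09"
        ]


class TestProbeContrasts:
    def test_separated_groups_give_large_delta_tiny_p(self):
        m = toy_matrix({"cgA": {"PCa_tissue": 0.8, "prostate_normal": 0.05}})
        c = probe_contrasts(m)[0]
        assert c.delta_beta["prostate_normal"] == pytest.approx(0.75)
        assert c.p_value["prostate_normal"] < 1e-6

    def test_constant_probe_conventioned_to_p_one(self):
        m = toy_matrix({"cgA": {t: 0.3 for t in ("PCa_tissue", "prostate_normal",
                                                 "bladder", "kidney", "liver",
                                                 "lung", "WBC", "serum_ctrl")}})
        c = probe_contrasts(m)[0]
        assert c.p_value["liver"] == 1.0
        assert c.delta_beta["liver"] == pytest.approx(0.0)

    def test_null_probe_has_small_delta_and_nonsignificant_p(self):
        m = toy_matrix({"cgA": {}}, noise=0.02, seed=4)
        c = probe_contrasts(m)[0]
        assert abs(c.delta_beta["kidney"]) < 0.05
        assert c.p_value["kidney"] > 0.001

    def test_missing_label_is_named_in_error(self):
        m = toy_matrix({"cgA": {}})
        with pytest.raises(ValueError, match="serum_PCa"):
            probe_contrasts(m, tumour_label="serum_PCa")

    def test_small_groups_use_permutation_and_stay_valid(self):
        rng = np.random.default_rng(0)
        cols = [f"t_{i}" for i in range(4)] + [f"n_{i}" for i in range(4)]
        beta = pd.DataFrame(
            [np.concatenate([rng.uniform(0.7, 0.9, 4), rng.uniform(0.0, 0.1, 4)])],
            index=["cgA"], columns=cols,
        )
        labels = pd.Series(["PCa_tissue"] * 4 + ["prostate_normal"] * 4, index=cols)
        m = BetaMatrix(beta=beta, tissue_labels=labels)
        c = probe_contrasts(m, normal_labels=("prostate_normal",),
                            background_labels=("prostate_normal",
                                               "prostate_normal"))[0]
        assert 0 <= c.p_value["prostate_normal"] < 0.05


class TestSelectMarkers:
    def test_perfect_probe_ranked_first(self):
        values = {"cgGOOD": {"PCa_tissue": 0.8},
                  "cgWEAK": {"PCa_tissue": 0.3}}
        m = toy_matrix(values, noise=0.01, seed=1)
        ranked = select_markers(probe_contrasts(m), SelectionCriteria())
        assert ranked[0] == "cgGOOD"

    def test_liver_elevated_probe_excluded_without_exception(self):
        values = {"cgLIV": {"PCa_tissue": 0.31, "liver": 0.25}}
        m = toy_matrix(values, noise=0.01, seed=2)
        contrasts = probe_contrasts(m)
        assert select_markers(contrasts, SelectionCriteria()) == []
        with_exception = SelectionCriteria(
            allowed_exceptions=frozenset({("cgLIV", "liver")})
        )
        assert select_markers(contrasts, with_exception) == ["cgLIV"]

    def test_vacuous_criteria_pass_everything(self):
        m = toy_matrix({f"cg{i}": {} for i in range(4)}, noise=0.01, seed=3)
        vacuous = SelectionCriteria(
            alpha=0.999999, min_delta_beta=-1.0, max_background_beta=1.0
        )
        assert len(select_markers(probe_contrasts(m), vacuous)) == 4

    def test_high_background_rejected(self):
        values = {"cgBG": {"PCa_tissue": 0.8, "WBC": 0.4}}
        m = toy_matrix(values, noise=0.01, seed=5)
        assert select_markers(probe_contrasts(m), SelectionCriteria()) == []

    def test_invariant_to_sample_column_permutation(self):
        matrix, _ = generate_beta_matrix(
            n_probes=20, n_planted=3, seed=7, tissue_sizes=SMALL_SIZES
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.beta.columns)
        shuffled = BetaMatrix(
            beta=matrix.beta[perm], tissue_labels=matrix.tissue_labels[perm]
        )
        r1 = select_markers(probe_contrasts(matrix), SelectionCriteria())
        r2 = select_markers(probe_contrasts(shuffled), SelectionCriteria())
        assert r1 == r2

    def test_agrees_with_brute_force_on_planted_matrix(self):
        criteria = SelectionCriteria()
        for seed in range(3):
            matrix, planted = generate_beta_matrix(
                n_probes=40, n_planted=5, seed=seed, tissue_sizes=SMALL_SIZES
            )
            ranked = select_markers(probe_contrasts(matrix), criteria)
            assert ranked == brute_force_select(matrix, criteria)

    def test_planted_probes_recalled_at_study_scale_sample_sizes(self):
        matrix, planted = generate_beta_matrix(n_probes=40, n_planted=5, seed=0)
        ranked = select_markers(probe_contrasts(matrix), SelectionCriteria())
        assert set(planted) <= set(ranked)
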