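"""Reference gating, enrichment arithmetic, group rules, sample comparison."""

import numpy as np
import pandas as pd
import pytest

import mapsfc as m
from mapsfc.cluster import combine
from mapsfc.errors import ContractError, GatingError
from mapsfc.phase import (GROUPS, PHASES, CompositionReport, GateConfig, assign_by_arrest,
                          assign_groups, compare_samples, enrichment_table, gate_phases,
                          gate_singlets)
from mapsfc.pipeline import transfer_assign


# --- gating ----------------------------------------------------------------


def test_singlet_gate_excludes_doublets(small_cohort):
    _, ev, gt = small_cohort
    gated = gate_singlets(ev)
    dbl = gt["doublet"].to_numpy()
    # doublets sit far off the PI-W ~ PI-H band; most are rejected
    assert gated.loc[dbl, "singlet"].mean() < 0.3
    assert gated.loc[~dbl, "singlet"].mean() > 0.9


def test_phase_gate_matches_ground_truth(small_cohort):
    _, ev, gt = small_cohort
    gated = gate_phases(gate_singlets(ev))
    labeled = gated["reference_phase"].isin(PHASES)
    assert labeled.mean() > 0.7
    acc = (gated.loc[labeled, "reference_phase"].to_numpy()
           == gt.loc[labeled.to_numpy(), "phase"].to_numpy()).mean()
    assert acc > 0.95
    fitinfo = gated.attrs["gate_fit"]
    assert fitinfo["pi_2n_window"][1] < fitinfo["pi_4n_window"][0]


def test_gate_contract_and_window_validation(small_cohort):
    _, ev, _ = small_cohort
    with pytest.raises(ContractError):
        gate_singlets(ev.drop(columns=["PI-W"]))
    with pytest.raises(ContractError):
        gate_phases(ev.drop(columns=["singlet"]))   # singlet gate not run
    overlapping = GateConfig(pi_2n_window=(10_000, 30_000), pi_4n_window=(25_000, 50_000))
    with pytest.raises(GatingError):
        gate_phases(gate_singlets(ev), overlapping)


# --- enrichment ------------------------------------------------------------


def _toy_events(phases):
    return pd.DataFrame({"reference_phase": phases})


def test_enrichment_factors_and_conservation_identity(fitted_reference):
    _, _, fit = fitted_reference
    table = fit.enrichment
    f_all = table.attrs["f_all"]
    assert table["n"].sum() == fit.combined.n_events
    # per cluster with labeled members: sum_p f_all(p) * e(c, p) == 1
    has = table[[f"e_{p}" for p in PHASES]].notna().all(axis=1)
    lhs = sum(f_all[p] * table.loc[has, f"e_{p}"] for p in PHASES)
    np.testing.assert_allclose(lhs, 1.0, atol=1e-9)


def test_enrichment_table_toy_example():
    # 2 clusters (k_a=2, k_b=1): cluster 0 all G1, cluster 1 an even G1/S split
    labels_a = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    cc = combine(labels_a, np.zeros(8, dtype=int), k_a=2, k_b=1)
    ev = _toy_events(["G1"] * 4 + ["G1", "G1", "S", "S"])
    table = enrichment_table(cc, ev, size_cutoff_fraction=0.0)
    f_all_g1 = 6 / 8
    assert table.loc[0, "f_G1"] == pytest.approx(1.0)
    assert table.loc[0, "e_G1"] == pytest.approx(1.0 / f_all_g1)
    assert table.loc[1, "e_S"] == pytest.approx(0.5 / (2 / 8))
    assert not table["below_cutoff"].any()


def test_enrichment_requires_labels():
    cc = combine(np.zeros(4, dtype=int), np.zeros(4, dtype=int), k_a=1, k_b=1)
    with pytest.raises(ContractError):
        enrichment_table(cc, _toy_events(["unlabeled"] * 4))


# --- group assignment rules ------------------------------------------------


def _table_row(e_g1, e_s, e_g2m, n=100, below=False):
    return {"n": n, "e_G1": e_g1, "e_S": e_s, "e_G2M": e_g2m,
            "f_G1": 0.3, "f_S": 0.3, "f_G2M": 0.4, "below_cutoff": below}


def test_group_rules():
    table = pd.DataFrame([
        _table_row(2.0, 0.5, 0.3),          # pure G1
        _table_row(0.2, 0.6, 1.8),          # pure G2M
        _table_row(1.4, 1.3, 0.2),          # mixed, G1 leads -> G1&S
        _table_row(1.2, 1.6, 0.4),          # mixed, S leads  -> S&G1
        _table_row(0.3, 1.3, 1.5),          # mixed S/G2M (either order) -> S&G2M
        _table_row(1.6, 0.4, 1.3),          # G1 top but G2M >= t_mixed: not pure,
                                            # G1-G2M not adjacent -> undefined
        _table_row(1.0, 1.0, 1.0),          # nothing enriched -> undefined
        _table_row(9.0, 0.0, 0.0, below=True),
    ])
    table.index.name = "cluster"
    out = assign_groups(table, t_specific=1.5, t_mixed=1.1)
    assert out["group"].tolist() == [
        "G1", "G2M", "G1&S", "S&G1", "S&G2M", "undefined", "undefined", "below_cutoff"]
    assert set(out["group"]) <= set(GROUPS)


def test_s_g2m_mixed_group_name_is_order_independent():
    table = pd.DataFrame([_table_row(0.2, 1.7, 1.2), _table_row(0.2, 1.2, 1.7)])
    out = assign_groups(table)
    assert out["group"].tolist() == ["S&G2M", "S&G2M"]


# --- sample comparison -----------------------------------------------------


def test_compare_probe_equal_to_reference_is_identity(fitted_reference):
    ds, _, fit = fitted_reference
    probe = transfer_assign(ds, fit)
    rep = compare_samples(fit.combined, probe, fit.enrichment)
    assert isinstance(rep, CompositionReport)
    populated = rep.fold_change.dropna()
    np.testing.assert_allclose(populated, 1.0, atol=1e-12)
    np.testing.assert_allclose(rep.group_fractions.loc["reference"],
                               rep.group_fractions.loc["probe"], atol=1e-12)
    assert rep.group_fractions.loc["reference"].sum() == pytest.approx(1.0)


def test_compare_samples_fingerprint_guard(fitted_reference):
    _, _, fit = fitted_reference
    probe = combine(fit.combined.labels_a, fit.combined.labels_b, 8, 8,
                    fingerprint_a="deadbeefdeadbeef",
                    fingerprint_b=fit.combined.fingerprint_b)
    with pytest.raises(ContractError):
        compare_samples(fit.combined, probe, fit.enrichment)


def test_compare_samples_requires_groups(fitted_reference):
    _, _, fit = fitted_reference
    with pytest.raises(ContractError):
        compare_samples(fit.combined, fit.combined,
                        fit.enrichment.drop(columns=["group"]))


# --- arrest time course ----------------------------------------------------


def test_assign_by_arrest_rule():
    control = np.array([0.25, 0.25, 0.25, 0.25, 0.0])
    arrested = np.array([0.50, 0.10, 0.25, 0.15, 0.0])
    out = assign_by_arrest(control, arrested, ratio_threshold=1.2)
    assert out.tolist() == ["G2M", "G1&S", "unassigned", "G1&S", "unassigned"]
    with pytest.raises(ContractError):
        assign_by_arrest(control, arrested[:3])


def test_arrest_identifies_g2m_clusters_label_free(fitted_reference):
    ds, _, fit = fitted_reference
    # simulate the t=0 sample of a G2-arrest release: G2/M dominates
    w = m.simulate.arrest_timecourse_weights([0.0])[0]
    classes = m.default_classes()
    arrested = [type(c)(**{**c.__dict__, "mixture_weight": wi})
                for c, wi in zip(classes, w)]
    dsa, _, _ = m.simulate_cohort(classes=arrested, n_events=1200,
                                  noise=m.default_noise(0.0), seed=31)
    probe = transfer_assign(dsa, fit)
    amap = assign_by_arrest(fit.combined.sizes() / fit.combined.n_events,
                            probe.sizes() / probe.n_events)
    # clusters flagged G2M by the label-free rule agree with the labeled groups
    g2m_flagged = set(amap[amap == "G2M"].index)
    labeled_g2m = set(fit.enrichment.index[fit.enrichment["group"] == "G2M"])
    assert labeled_g2m & g2m_flagged
    labeled_g1 = set(fit.enrichment.index[fit.enrichment["group"] == "G1"])
    assert not (labeled_g1 & g2m_flagged)
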