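"""Quantitation: PSM ratios, aggregation, and the curation cascade."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_psm
from oracles import brute_force_cascade

from nucmap.design import CascadeParams, ChannelDesign
from nucmap.quant import (
    aggregate_protein_fc,
    call_de_table,
    curation_cascade,
    psm_ratio,
    quants_to_frame,
)


class TestPsmRatio:
    @pytest.mark.parametrize(
        "grade,ratio", [("IV", 2.0), ("II", 0.25), ("III", 1.0)]
    )
    def test_direct_division(self, design, grade, ratio):
        psm = make_psm(ratios={grade: ratio}, control=200.0)
        assert psm_ratio(psm, design, grade) == pytest.approx(ratio)

    def test_zero_control_is_precondition_violation(self, design):
        psm = make_psm(control=0.0)
        with pytest.raises(ValueError, match="control"):
            psm_ratio(psm, design, "IV")


class TestAggregate:
    def test_zero_variance(self):
        assert aggregate_protein_fc([2.0, 2.0, 2.0]) == (pytest.approx(2.0), pytest.approx(0.0))

    def test_sample_sd_uses_n_minus_1(self):
        fc, cv = aggregate_protein_fc([1.0, 2.0, 3.0])
        assert fc == pytest.approx(2.0)
        assert cv == pytest.approx(50.0)  # sample SD of {1,2,3} is exactly 1

    def test_single_ratio_cv_not_assessable(self):
        assert aggregate_protein_fc([0.5]) == (pytest.approx(0.5), None)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_protein_fc([])


def _psms_with_ratios(ratios, grade="IV", protein="GENE0001", peptides=None):
    peptides = peptides or [f"PEP{i}" for i in range(len(ratios))]
    return [
        make_psm(ratios={grade: r}, proteins=(protein,), peptide=pep)
        for r, pep in zip(ratios, peptides)
    ]


class TestCascadeStages:
    def test_provisional_mean_below_pregate_exits_stage1(self, design):
        quants = curation_cascade(_psms_with_ratios([1.6, 0.6]), design)
        q = next(q for q in quants if q.grade == "IV")
        assert q.exit_stage == "stage1_provisional_fc"
        assert q.fold_change == pytest.approx(1.1)
        assert not q.is_de

    def test_discordant_psm_dropped_then_called(self, design):
        quants = curation_cascade(_psms_with_ratios([2.0, 2.0, 1.1]), design)
        q = next(q for q in quants if q.grade == "IV")
        assert q.exit_stage == "pass"
        assert q.fold_change == pytest.approx(2.0)
        assert q.cv_percent == pytest.approx(0.0)
        assert q.n_psms == 2

    def test_high_fold_change_with_two_peptides_eight_psms_called_up(self, design):
        # the hallmark pattern: ~7.1-fold, 2 unique peptides, 8 PSMs, low CV
        ratios = [7.0, 7.2, 7.1, 7.05, 7.15, 7.1, 7.0, 7.2]
        peptides = ["PEPA"] * 4 + ["PEPB"] * 4
        quants = curation_cascade(
            _psms_with_ratios(ratios, peptides=peptides), design
        )
        q = next(q for q in quants if q.grade == "IV")
        assert q.is_de and q.direction == "up"
        assert q.fold_change == pytest.approx(7.1, rel=0.01)
        assert q.n_unique_peptides == 2 and q.n_psms == 8
        assert q.cv_percent < 40

    def test_downregulation_uses_reciprocal_thresholds(self, design):
        quants = curation_cascade(_psms_with_ratios([0.5, 0.55, 0.45]), design)
        q = next(q for q in quants if q.grade == "IV")
        assert q.is_de and q.direction == "down"
        assert q.fold_change < 1 / 1.5

    def test_cv_gate_blocks_variable_protein(self, design):
        # mean 2.5 passes both fold gates but CV is far above 40%
        quants = curation_cascade(_psms_with_ratios([1.31, 1.31, 4.88]), design)
        q = next(q for q in quants if q.grade == "IV")
        assert q.exit_stage == "stage4_cv"

    def test_min_psm_gate(self, design):
        quants = curation_cascade(_psms_with_ratios([2.0]), design)
        q = next(q for q in quants if q.grade == "IV")
        assert q.exit_stage == "stage4_min_psms"


def _random_instance(rng, n_proteins=None):
    """Random small instance: package PSMs plus oracle rows side by side."""
    design = ChannelDesign()
    n_proteins = n_proteins or int(rng.integers(1, 21))
    psms, rows = [], []
    for i in range(n_proteins):
        prot = f"P{i:03d}"
        n_psm = int(rng.integers(1, 11))
        for j in range(n_psm):
            ratios = {g: float(np.exp(rng.normal(0, 0.6))) for g in design.grades}
            snr = {c: float(rng.uniform(0.8, 4.0)) for c in ("114", "115", "116", "117")}
            psms.append(
                make_psm(ratios=ratios, proteins=(prot,), peptide=f"{prot}_PEP{j}", snr=snr)
            )
            for g in design.grades:
                rows.append(
                    {
                        "protein": prot,
                        "grade": g,
                        "ratio": ratios[g],
                        "snr_control": snr["114"],
                        "snr_grade": snr[design.grade_channels[g]],
                        "peptide": f"{prot}_PEP{j}",
                    }
                )
    return psms, rows


@pytest.mark.parametrize("seed", range(10))
def test_cascade_agrees_with_bruteforce_on_random_instances(seed, design):
    rng = np.random.default_rng(100 + seed)
    psms, rows = _random_instance(rng)
    quants = curation_cascade(psms, design)
    expected = brute_force_cascade(rows)
    got = {(q.accession, q.grade): (q.is_de, q.fold_change) for q in quants}
    assert set(got) == set(expected)
    for key in expected:
        assert got[key][0] == expected[key][0], key
        assert got[key][1] == pytest.approx(expected[key][1])


@pytest.mark.parametrize("seed", range(5))
def test_tightening_thresholds_never_adds_de_calls(seed, design):
    rng = np.random.default_rng(200 + seed)
    psms, _ = _random_instance(rng, n_proteins=15)
    base = {(q.accession, q.grade) for q in curation_cascade(psms, design) if q.is_de}
    higher_fc = {
        (q.accession, q.grade)
        for q in curation_cascade(psms, design, CascadeParams(final_fc=2.0))
        if q.is_de
    }
    lower_cv = {
        (q.accession, q.grade)
        for q in curation_cascade(psms, design, CascadeParams(cv_max=15.0))
        if q.is_de
    }
    assert higher_fc <= base
    assert lower_cv <= base


@pytest.mark.parametrize("seed", range(3))
def test_de_up_proteins_supported_only_by_concordant_ratios(seed, design):
    rng = np.random.default_rng(300 + seed)
    psms, rows = _random_instance(rng, n_proteins=12)
    quants = curation_cascade(psms, design)
    by_key = {}
    for r in rows:
        by_key.setdefault((r["protein"], r["grade"]), []).append(r)
    for q in quants:
        if not q.is_de:
            continue
        kept = [
            r["ratio"]
            for r in by_key[(q.accession, q.grade)]
            if r["snr_control"] >= 1.5 and r["snr_grade"] >= 1.5
            and (r["ratio"] >= 1.3 if q.direction == "up" else r["ratio"] <= 1 / 1.3)
        ]
        if q.direction == "up":
            assert all(r > 1 for r in kept)
        else:
            assert all(r < 1 for r in kept)
        assert q.fold_change == pytest.approx(np.mean(kept))


class TestDeTable:
    def test_empty_input_gives_zero_bins(self):
        de_df, summary = call_de_table([])
        assert de_df.empty
        assert (summary[["n_de", "n_up", "n_down"]] == 0).all().all()

    def test_peptide_support_bins_match_recount(self, design):
        rng = np.random.default_rng(42)
        psms, _ = _random_instance(rng, n_proteins=20)
        quants = curation_cascade(psms, design)
        de_df, summary = call_de_table(quants)
        for row in summary.itertuples():
            sub = de_df[de_df.grade == row.grade]
            assert row.n_de == len(sub)
            assert row.n_up == (sub.direction == "up").sum()
            assert row.n_down == (sub.direction == "down").sum()
            assert row.upep_ge4 == (sub.n_unique_peptides >= 4).sum()
            assert row.upep_3 == (sub.n_unique_peptides == 3).sum()
            assert row.upep_2 == (sub.n_unique_peptides == 2).sum()
            assert row.upep_1_ge2psms == (
                (sub.n_unique_peptides == 1) & (sub.n_psms >= 2)
            ).sum()
            assert row.n_de == row.upep_ge4 + row.upep_3 + row.upep_2 + row.upep_1_ge2psms

    def test_protein_with_three_peptides_binned_once(self, design):
        psms = _psms_with_ratios(
            [2.0, 2.1, 1.9], peptides=["A", "B", "C"]
        )
        quants = curation_cascade(psms, design)
        _, summary = call_de_table(quants)
        row = summary[summary.grade == "IV"].iloc[0]
        assert row.upep_3 == 1
        assert row.upep_ge4 == 0 and row.upep_2 == 0 and row.upep_1_ge2psms == 0

    def test_frame_has_expected_columns(self, design):
        quants = curation_cascade(_psms_with_ratios([2.0, 2.0]), design)
        df = quants_to_frame(quants)
        assert list(df.columns) == [
            "accession", "grade", "fold_change", "direction",
            "n_unique_peptides", "n_psms", "cv_percent", "exit_stage",
        ]
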