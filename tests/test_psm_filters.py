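"""Identification filters: decoy FDR, reporter quality, uniqueness, both-runs."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_psm
from oracles import ranked_fdr_reference

from nucmap.io import FormatError, read_psm_table, write_psm_table
from nucmap.psm_filters import (
    apply_identification_filters,
    estimate_decoy_fdr,
    filter_reporter_quality,
    proteins_in_both_runs,
    retain_unique_peptides,
)


def _scored(scores, decoy_scores):
    psms = [
        make_psm(score=s, peptide=f"TGT{i}", proteins=(f"P{i}",))
        for i, s in enumerate(scores)
    ]
    psms += [
        make_psm(score=s, peptide=f"DEC{i}", proteins=(f"D{i}",), is_decoy=True)
        for i, s in enumerate(decoy_scores)
    ]
    return psms


class TestDecoyFdr:
    def test_worked_ranked_list(self):
        # targets 10, 9, 8 and one decoy at 8.5: the decoy precedes the last
        # target, giving it raw FDR 1/3 and q = 1/3
        result, retained = estimate_decoy_fdr(_scored([10, 9, 8], [8.5]), nominal=0.5)
        assert result.qvalues["TGT0"] == 0.0
        assert result.qvalues["TGT1"] == 0.0
        assert result.qvalues["TGT2"] == pytest.approx(1 / 3)
        assert {p.peptide for p in retained} == {"TGT0", "TGT1", "TGT2"}

    def test_no_decoys_all_retained_with_zero_q(self):
        result, retained = estimate_decoy_fdr(_scored([5, 4, 3], []), nominal=0.01)
        assert all(q == 0.0 for q in result.qvalues.values())
        assert len(retained) == 3

    def test_nominal_zero_keeps_only_targets_above_every_decoy(self):
        _, retained = estimate_decoy_fdr(_scored([10, 9, 8], [8.5]), nominal=0.0)
        assert {p.peptide for p in retained} == {"TGT0", "TGT1"}

    def test_all_decoy_input_errors(self):
        with pytest.raises(ValueError, match="target"):
            estimate_decoy_fdr(_scored([], [5, 4]), nominal=0.01)

    def test_score_tie_counts_decoy_first(self):
        # at a 9/9 tie the decoy ranks ahead, so the tied target already
        # carries the decoy in its raw FDR (conservative)
        result, _ = estimate_decoy_fdr(_scored([10, 9], [9]), nominal=1.0)
        assert result.qvalues["TGT1"] == pytest.approx(1 / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_ranked_list_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(8, 2, size=60)
        decoys = rng.normal(5, 2, size=25)
        psms = _scored(scores, decoys)
        nominal = 0.1
        result, retained = estimate_decoy_fdr(psms, nominal)
        entries = [(p.peptide, p.score, p.is_decoy) for p in psms]
        expect_retained, expect_q = ranked_fdr_reference(entries, nominal)
        assert {p.peptide for p in retained} == expect_retained
        for pep, q in expect_q.items():
            assert result.qvalues[pep] == pytest.approx(q)

    def test_qvalues_monotone_in_score(self):
        rng = np.random.default_rng(1)
        psms = _scored(rng.normal(8, 2, 50), rng.normal(5, 2, 20))
        result, _ = estimate_decoy_fdr(psms, 0.05)
        ranked = sorted(psms, key=lambda p: -p.score)
        qs = [result.qvalues[p.peptide] for p in ranked]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))


class TestReporterQuality:
    def test_all_channels_good_quantifiable_everywhere(self, design):
        psms = [make_psm(snr=2.0)]
        out = filter_reporter_quality(psms, design)
        assert all(len(out[g]) == 1 for g in design.grades)

    def test_failed_control_blocks_all_grades(self, design):
        psms = [make_psm(snr={"114": 1.0, "115": 2.0, "116": 2.0, "117": 2.0})]
        out = filter_reporter_quality(psms, design)
        assert all(len(out[g]) == 0 for g in design.grades)

    def test_per_grade_channel_rule(self, design):
        psms = [make_psm(snr={"114": 2.0, "115": 1.0, "116": 2.0, "117": 2.0})]
        out = filter_reporter_quality(psms, design)
        assert len(out["II"]) == 0
        assert len(out["III"]) == 1 and len(out["IV"]) == 1


def test_unique_peptide_rule_counts():
    psms = [make_psm(proteins=("A",), peptide=f"U{i}") for i in range(7)]
    psms += [make_psm(proteins=("A", "B"), peptide=f"S{i}") for i in range(3)]
    unique, shared = retain_unique_peptides(psms)
    assert len(unique) == 7 and len(shared) == 3


class TestBothRuns:
    def test_intersection_matches_set_oracle(self):
        rng = np.random.default_rng(5)
        psms = []
        seen = {"run1": set(), "run2": set()}
        for i in range(200):
            prot = f"P{rng.integers(50)}"
            run = "run1" if rng.random() < 0.5 else "run2"
            seen[run].add(prot)
            psms.append(make_psm(run_id=run, proteins=(prot,), peptide=f"PEP{i}"))
        assert proteins_in_both_runs(psms) == seen["run1"] & seen["run2"]

    def test_single_run_input_errors_naming_rule(self):
        with pytest.raises(ValueError, match="both-runs"):
            proteins_in_both_runs([make_psm(run_id="run1")])


def test_uniqueness_and_reporter_filters_commute(design):
    rng = np.random.default_rng(9)
    psms = []
    for i in range(100):
        proteins = ("A",) if rng.random() < 0.7 else ("A", "B")
        snr = {c: float(rng.uniform(0.5, 4)) for c in ("114", "115", "116", "117")}
        psms.append(make_psm(proteins=proteins, peptide=f"PEP{i}", snr=snr))
    u_then_r = filter_reporter_quality(retain_unique_peptides(psms)[0], design)
    r_then_u = {
        g: retain_unique_peptides(v)[0]
        for g, v in filter_reporter_quality(psms, design).items()
    }
    for g in design.grades:
        assert {p.psm_id for p in u_then_r[g]} == {p.psm_id for p in r_then_u[g]}


def test_no_decoy_reaches_quantitation(design):
    rng = np.random.default_rng(2)
    psms = []
    for i in range(150):
        decoy = rng.random() < 0.3
        run = "run1" if i % 2 else "run2"
        psms.append(
            make_psm(
                run_id=run,
                peptide=f"PEP{i}",
                proteins=(f"{'D' if decoy else 'P'}{i % 20}",),
                score=float(rng.normal(4 if decoy else 8, 2)),
                is_decoy=decoy,
            )
        )
    retained, counts = apply_identification_filters(psms, design, fdr=0.5)
    assert not any(p.is_decoy for p in retained)
    assert counts["after_fdr"] <= counts["input_psms"]


class TestPsmTableIo:
    def test_roundtrip_preserves_records(self, tmp_path):
        psms = [
            make_psm(ratios={"II": 2.0}, peptide="AAAK", proteins=("P1",)),
            make_psm(ratios={"IV": 0.5}, peptide="CCCK", proteins=("P1", "P2")),
            make_psm(peptide="DDDK", proteins=("D1",), is_decoy=True),
        ]
        path = tmp_path / "psms.tsv"
        write_psm_table(psms, path)
        back = read_psm_table(path)
        assert len(back) == 3
        for a, b in zip(psms, back):
            assert (a.peptide, a.proteins, a.is_decoy) == (b.peptide, b.proteins, b.is_decoy)
            for c in a.intensity:
                assert b.intensity[c] == pytest.approx(a.intensity[c], rel=1e-5)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_psm_table([make_psm()], path)
        text = path.read_text().replace("int_117", "int_999")
        path.write_text(text)
        with pytest.raises(FormatError, match="int_117"):
            read_psm_table(path)

    def test_negative_intensity_reports_line(self, tmp_path):
        path = tmp_path / "neg.tsv"
        write_psm_table([make_psm(), make_psm()], path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace("100", "-100", 1)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 3"):
            read_psm_table(path)
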