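"""Identification-level quality control preceding quantitation.

The filters implement the curation funnel applied to the search-engine
output: target-decoy FDR at the peptide level (1% default), reporter-ion
signal-to-noise gating per grade, the unique-peptide rule, and the
requirement that a protein be identified in both replicate runs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ChannelDesign
from .io import PsmRecord


@dataclass(frozen=True)
class FdrResult:
    """Outcome of target-decoy FDR estimation at the peptide level.

    ``qvalues`` maps each peptide sequence (best-PSM representative) to its
    q-value; ``score_threshold`` is the lowest score among retained target
    peptides, or ``None`` when nothing is retained.
    """

    qvalues: dict[str, float]
    score_threshold: float | None
    n_targets: int
    n_decoys: int


def estimate_decoy_fdr(
    psms: list[PsmRecord], nominal: float = 0.01
) -> tuple[FdrResult, list[PsmRecord]]:
    """Peptide-level target-decoy FDR with q-value monotonization.

    PSMs are collapsed to the best-scoring PSM per peptide sequence, ranked
    by decreasing score (decoys first on ties, conservatively).  The raw FDR
    at rank k is (#decoys at or above k)/(#targets at or above k); q-values
    are the running minimum from the bottom of the list.  Target PSMs whose
    peptide has q <= ``nominal`` are retained; decoys are removed.
    """
    if not any(not p.is_decoy for p in psms):
        raise ValueError("FDR estimation requires at least one target PSM")

    best: dict[str, PsmRecord] = {}
    for p in psms:
        cur = best.get(p.peptide)
        if cur is None or p.score > cur.score:
            best[p.peptide] = p
    # decoy-first tie break: decoys sort ahead of targets at equal score
    ranked = sorted(best.values(), key=lambda p: (-p.score, not p.is_decoy, p.peptide))

    n_dec = 0
    n_tgt = 0
    raw = np.empty(len(ranked))
    for i, p in enumerate(ranked):
        if p.is_decoy:
            n_dec += 1
        else:
            n_tgt += 1
        raw[i] = n_dec / n_tgt if n_tgt else np.inf
    q = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.minimum(q, 1.0)

    qvalues = {p.peptide: float(qi) for p, qi in zip(ranked, q)}
    retained_peptides = {
        p.peptide for p, qi in zip(ranked, q) if not p.is_decoy and qi <= nominal
    }
    retained = [p for p in psms if not p.is_decoy and p.peptide in retained_peptides]
    threshold = (
        min(best[pep].score for pep in retained_peptides) if retained_peptides else None
    )
    result = FdrResult(
        qvalues=qvalues,
        score_threshold=threshold,
        n_targets=sum(1 for p in ranked if not p.is_decoy),
        n_decoys=sum(1 for p in ranked if p.is_decoy),
    )
    return result, retained


def filter_reporter_quality(
    psms: list[PsmRecord], design: ChannelDesign, sn_min: float = 1.5
) -> dict[str, list[PsmRecord]]:
    """Per-grade reporter-quality gate.

    A PSM is quantifiable for a grade iff both the control channel and that
    grade's channel have S/N >= ``sn_min`` and strictly positive intensity.
    A PSM may be quantifiable for some grades and not others.
    """
    out: dict[str, list[PsmRecord]] = {g: [] for g in design.grades}
    ctrl = design.control_channel
    for p in psms:
        ctrl_ok = p.snr[ctrl] >= sn_min and p.intensity[ctrl] > 0
        if not ctrl_ok:
            continue
        for grade, ch in design.grade_channels.items():
            if p.snr[ch] >= sn_min and p.intensity[ch] > 0:
                out[grade].append(p)
    return out


def retain_unique_peptides(
    psms: list[PsmRecord],
) -> tuple[list[PsmRecord], list[PsmRecord]]:
    """Split PSMs into protein-unique (quantifiable) and shared (id-only)."""
    unique = [p for p in psms if len(p.proteins) == 1]
    shared = [p for p in psms if len(p.proteins) > 1]
    return unique, shared


def proteins_in_both_runs(psms: list[PsmRecord]) -> set[str]:
    """Accessions with at least one retained PSM in each of the two runs."""
    runs = sorted({p.run_id for p in psms})
    if len(runs) != 2:
        raise ValueError(
            "the both-runs rule requires PSMs from exactly two runs; "
            f"found run id(s): {runs}"
        )
    per_run: dict[str, set[str]] = defaultdict(set)
    for p in psms:
        for acc in p.proteins:
            per_run[p.run_id].add(acc)
    return per_run[runs[0]] & per_run[runs[1]]


def apply_identification_filters(
    psms: list[PsmRecord],
    design: ChannelDesign,
    fdr: float = 0.01,
    sn_min: float = 1.5,
) -> tuple[list[PsmRecord], dict[str, int]]:
    """Run the full identification funnel and report per-stage counts.

    Order: decoy FDR -> unique-peptide rule -> both-runs rule.  The
    reporter-quality gate is applied per grade downstream (quantifiability
    is grade-specific), so it is not part of this funnel.  Returns the
    retained quantifiable PSMs and a stage->count log.
    """
    counts = {"input_psms": len(psms)}
    _, after_fdr = estimate_decoy_fdr(psms, nominal=fdr)
    counts["after_fdr"] = len(after_fdr)
    counts["peptides_identified"] = len({p.peptide for p in after_fdr})
    counts["proteins_identified"] = len({a for p in after_fdr for a in p.proteins})
    unique, shared = retain_unique_peptides(after_fdr)
    counts["after_unique"] = len(unique)
    both = proteins_in_both_runs(unique)
    counts["proteins_in_both_runs"] = len(both)
    retained = [p for p in unique if p.proteins[0] in both]
    counts["after_both_runs"] = len(retained)
    return retained, counts
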