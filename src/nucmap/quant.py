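"""Reporter-ion quantitation and the two-tier fold-change curation cascade.

Per grade, each quantifiable unique PSM yields a tumor/control reporter
ratio.  The cascade then proceeds in four stages per protein:

1. provisional fold change = arithmetic mean of all its PSM ratios; keep
   proteins at or beyond the 1.3-fold pre-gate (either direction);
2. within kept proteins, retain only PSMs whose own ratio passes the same
   1.3-fold rule in the protein's direction (concordant peptide evidence);
3. recompute the fold change and percent CV from the retained ratios;
4. final differential-expression call: recomputed fold change at or beyond
   1.5-fold in the protein's direction, >= 2 retained PSMs, and CV < 40%.

Down-regulation uses reciprocal thresholds throughout.  The exit stage of
every protein is recorded so the curation funnel can be audited.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ChannelDesign, CascadeParams
from .io import PsmRecord
from .psm_filters import filter_reporter_quality

EXIT_STAGES = ("stage1_provisional_fc", "stage4_final_fc", "stage4_min_psms", "stage4_cv", "pass")


@dataclass(frozen=True)
class ProteinQuant:
    """Per-protein, per-grade quantitation outcome.

    ``fold_change`` is the recomputed value when the protein reached stage 3,
    otherwise the provisional stage-1 mean.  ``cv_percent`` is ``None`` when
    not assessable (fewer than two retained ratios).  ``exit_stage`` is
    ``"pass"`` for differentially expressed proteins.
    """

    accession: str
    grade: str
    fold_change: float
    direction: str
    n_unique_peptides: int
    n_psms: int
    cv_percent: float | None
    exit_stage: str
    stage_flags: tuple[bool, bool, bool]  # passed pre-gate, >=min_psms, cv ok

    @property
    def is_de(self) -> bool:
        return self.exit_stage == "pass"


def psm_ratio(psm: PsmRecord, design: ChannelDesign, grade: str) -> float:
    """Reporter-ion ratio of the grade channel over the control channel."""
    ctrl = psm.intensity[design.control_channel]
    if ctrl <= 0:
        raise ValueError("PSM not quantifiable: non-positive control intensity")
    return psm.intensity[design.grade_channels[grade]] / ctrl


def aggregate_protein_fc(ratios: list[float]) -> tuple[float, float | None]:
    """Mean fold change and percent CV (sample SD, n-1) of PSM ratios.

    A single ratio yields a fold change with CV reported as ``None``
    (not assessable).
    """
    if not ratios:
        raise ValueError("cannot aggregate an empty list of ratios")
    arr = np.asarray(ratios, dtype=float)
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    cv = float(100.0 * arr.std(ddof=1) / mean)
    return mean, cv


def _passes(fc: float, threshold: float, direction: str) -> bool:
    return fc >= threshold if direction == "up" else fc <= 1.0 / threshold


def curation_cascade(
    psms: list[PsmRecord],
    design: ChannelDesign,
    params: CascadeParams = CascadeParams(),
) -> list[ProteinQuant]:
    """Run the four-stage curation cascade for every grade.

    ``psms`` must already have passed the identification filters (decoys
    removed, unique peptides only, both-runs proteins); runs are pooled for
    quantitation.  Returns one :class:`ProteinQuant` per (protein, grade)
    with at least one quantifiable PSM.
    """
    by_grade = filter_reporter_quality(psms, design)
    out: list[ProteinQuant] = []
    for grade in design.grades:
        groups: dict[str, list[PsmRecord]] = defaultdict(list)
        for p in by_grade[grade]:
            groups[p.accession].append(p)
        for acc in sorted(groups):
            members = groups[acc]
            ratios = [psm_ratio(p, design, grade) for p in members]
            fc0, _ = aggregate_protein_fc(ratios)
            direction = "up" if fc0 > 1 else "down"
            if not _passes(fc0, params.pre_fc, direction):
                out.append(
                    ProteinQuant(
                        accession=acc,
                        grade=grade,
                        fold_change=fc0,
                        direction=direction,
                        n_unique_peptides=len({p.peptide for p in members}),
                        n_psms=len(members),
                        cv_percent=aggregate_protein_fc(ratios)[1],
                        exit_stage="stage1_provisional_fc",
                        stage_flags=(False, False, False),
                    )
                )
                continue
            kept = [
                (p, r) for p, r in zip(members, ratios)
                if _passes(r, params.pre_fc, direction)
            ]
            kept_ratios = [r for _, r in kept]
            fc, cv = aggregate_protein_fc(kept_ratios)
            n_psms = len(kept)
            n_upep = len({p.peptide for p, _ in kept})
            fc_ok = _passes(fc, params.final_fc, direction)
            n_ok = n_psms >= params.min_psms
            cv_ok = cv is not None and cv < params.cv_max
            if not fc_ok:
                exit_stage = "stage4_final_fc"
            elif not n_ok:
                exit_stage = "stage4_min_psms"
            elif not cv_ok:
                exit_stage = "stage4_cv"
            else:
                exit_stage = "pass"
            out.append(
                ProteinQuant(
                    accession=acc,
                    grade=grade,
                    fold_change=fc,
                    direction=direction,
                    n_unique_peptides=n_upep,
                    n_psms=n_psms,
                    cv_percent=cv,
                    exit_stage=exit_stage,
                    stage_flags=(True, n_ok, cv_ok),
                )
            )
    return out


def quants_to_frame(quants: list[ProteinQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": q.accession,
                "grade": q.grade,
                "fold_change": q.fold_change,
                "direction": q.direction,
                "n_unique_peptides": q.n_unique_peptides,
                "n_psms": q.n_psms,
                "cv_percent": q.cv_percent if q.cv_percent is not None else np.nan,
                "exit_stage": q.exit_stage,
            }
            for q in quants
        ],
        columns=[
            "accession", "grade", "fold_change", "direction",
            "n_unique_peptides", "n_psms", "cv_percent", "exit_stage",
        ],
    )


def call_de_table(
    quants: list[ProteinQuant], params: CascadeParams = CascadeParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-expression table plus a grade-wise peptide-support summary.

    The summary has one row per grade with total/up/down DE counts and DE
    proteins binned by unique-peptide support: >=4, exactly 3, exactly 2,
    and exactly 1 unique peptide backed by >= ``min_psms`` PSMs.
    """
    de = [q for q in quants if q.is_de]
    de_df = quants_to_frame(de).sort_values(["grade", "accession"]).reset_index(drop=True)
    rows = []
    grades = sorted({q.grade for q in quants}) or ["II", "III", "IV"]
    for grade in grades:
        gq = [q for q in de if q.grade == grade]
        rows.append(
            {
                "grade": grade,
                "n_de": len(gq),
                "n_up": sum(q.direction == "up" for q in gq),
                "n_down": sum(q.direction == "down" for q in gq),
                "upep_ge4": sum(q.n_unique_peptides >= 4 for q in gq),
                "upep_3": sum(q.n_unique_peptides == 3 for q in gq),
                "upep_2": sum(q.n_unique_peptides == 2 for q in gq),
                "upep_1_ge2psms": sum(
                    q.n_unique_peptides == 1 and q.n_psms >= params.min_psms for q in gq
                ),
            }
        )
    return de_df, pd.DataFrame(rows)
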