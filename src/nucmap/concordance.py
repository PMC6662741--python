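"""Cross-dataset direction matching.

Protein-level differential-expression calls are compared with transcript
trends gene-by-gene and grade-by-grade, intersected across grades, and
summarized against signature gene sets and subcellular annotation.
Matching is by uppercased gene symbol; direction ("up"/"down") is the only
evidence used unless an optional transcript p-value gate is requested.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd


def match_transcript_trends(
    de_table: pd.DataFrame,
    transcripts: pd.DataFrame,
    p_max: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Label each DE protein concordant / discordant / unmatched.

    A protein is concordant at a grade iff a transcript record exists for the
    same (gene, grade) with the same direction.  Two rates are reported:
    ``rate_all_de`` (concordant over all DE proteins) and ``rate_matched``
    (concordant over proteins with any matching transcript record) — the
    appropriate denominator depends on how complete the transcript resource
    is, so both are given.  ``p_max`` optionally drops transcript records
    above a p-value threshold before matching (off by default).
    """
    tx = transcripts.copy()
    tx["gene"] = tx["gene"].str.upper()
    if p_max is not None and "p_value" in tx.columns:
        tx = tx[tx["p_value"] <= p_max]
    key = {(g, gr): d for g, gr, d in zip(tx["gene"], tx["grade"], tx["direction"])}

    out = de_table.copy()
    out["gene"] = out["accession"].str.upper()
    status = []
    for gene, grade, direction in zip(out["gene"], out["grade"], out["direction"]):
        tdir = key.get((gene, grade))
        if tdir is None:
            status.append("unmatched")
        elif tdir == direction:
            status.append("concordant")
        else:
            status.append("discordant")
    out["transcript_status"] = status

    n = len(out)
    n_conc = int((out["transcript_status"] == "concordant").sum())
    n_matched = int((out["transcript_status"] != "unmatched").sum())
    rates = {
        "n_de": float(n),
        "n_matched": float(n_matched),
        "n_concordant": float(n_conc),
        "rate_all_de": n_conc / n if n else float("nan"),
        "rate_matched": n_conc / n_matched if n_matched else float("nan"),
    }
    return out, rates


def common_across_grades(
    de_table: pd.DataFrame, grades: Iterable[str] = ("II", "III", "IV")
) -> set[str]:
    """Proteins DE in every grade with the same direction throughout."""
    grades = list(grades)
    per_grade: list[dict[str, str]] = []
    for grade in grades:
        sub = de_table[de_table["grade"] == grade]
        per_grade.append(dict(zip(sub["accession"], sub["direction"])))
    if not per_grade:
        return set()
    common = set(per_grade[0])
    for d in per_grade[1:]:
        common &= set(d)
    return {a for a in common if len({d[a] for d in per_grade}) == 1}


def signature_overlap(
    identified: Iterable[str], signature: Iterable[str]
) -> tuple[int, float]:
    """Overlap of identified proteins with a (stromal/immune) gene signature.

    Returns the overlap count and its fraction of the identified proteins.
    """
    identified = {g.upper() for g in identified}
    signature = {g.upper() for g in signature}
    if not signature:
        raise ValueError("signature gene set must be non-empty")
    overlap = identified & signature
    frac = len(overlap) / len(identified) if identified else 0.0
    return len(overlap), frac


def subcellular_fraction(
    de_table: pd.DataFrame, annotation: Mapping[str, Iterable[str]]
) -> dict[str, float]:
    """Fraction of annotated DE proteins per subcellular compartment.

    A multi-compartment protein counts once per compartment, so fractions
    can sum beyond 1.  Proteins are deduplicated across grades; the
    denominator is the number of annotated DE proteins.
    """
    ann = {k.upper(): set(v) for k, v in annotation.items()}
    proteins = {a.upper() for a in de_table["accession"].unique()}
    annotated = [p for p in proteins if p in ann]
    if not annotated:
        return {}
    counts: dict[str, int] = {}
    for p in annotated:
        for comp in ann[p]:
            counts[comp] = counts.get(comp, 0) + 1
    return {comp: c / len(annotated) for comp, c in sorted(counts.items())}
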