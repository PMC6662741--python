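"""miRNA -> mRNA -> protein inverse-expression cascade mapping.

Builds the "2-dimensional molecular map": regulatory cascades in which a
network entity's protein and transcript trends agree and a validated miRNA
regulator shows the inverse trend — the pattern expected of an active
miRNA repressor (e.g. a down-regulated miRNA whose up-regulated target is a
transcription factor).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

_OPPOSITE = {"up": "down", "down": "up"}


def inverse_pairs(
    pairs: pd.DataFrame,
    mirna_directions: Mapping[str, str],
    target_directions: Mapping[str, str],
) -> tuple[pd.DataFrame, int]:
    """Retain validated (miRNA, target) pairs with strictly opposite trends.

    Pairs whose miRNA or target lack a direction record are dropped and
    counted (database joins are lossy); the dropped count is returned.
    """
    validated = pairs[pairs["validated"]] if "validated" in pairs.columns else pairs
    rows = []
    dropped = 0
    for mirna, gene in zip(validated["mirna"], validated["target_gene"]):
        mdir = mirna_directions.get(mirna)
        tdir = target_directions.get(gene)
        if mdir is None or tdir is None:
            dropped += 1
            continue
        if _OPPOSITE.get(mdir) == tdir:
            rows.append({"mirna": mirna, "target_gene": gene,
                         "direction_mirna": mdir, "direction_target": tdir})
    out = pd.DataFrame(rows, columns=["mirna", "target_gene", "direction_mirna", "direction_target"])
    out = (
        out.drop_duplicates()
        .sort_values(["mirna", "target_gene"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out, dropped


def build_2d_map(
    network_entities: Iterable[str],
    pairs: pd.DataFrame,
    protein_directions: Mapping[str, str],
    transcript_directions: Mapping[str, str],
    mirna_directions: Mapping[str, str],
) -> pd.DataFrame:
    """One cascade row per conforming (miRNA, entity) combination.

    A cascade requires three-layer agreement: the entity's protein and
    transcript directions are equal, and the miRNA's direction is their
    opposite.  A miRNA regulating several entities yields several rows.
    Output is sorted (mirna, gene) and invariant to input row order.
    """
    entities = {e for e in network_entities}
    validated = pairs[pairs["validated"]] if "validated" in pairs.columns else pairs
    rows = []
    for mirna, gene in zip(validated["mirna"], validated["target_gene"]):
        if gene not in entities:
            continue
        pdir = protein_directions.get(gene)
        tdir = transcript_directions.get(gene)
        mdir = mirna_directions.get(mirna)
        if pdir is None or tdir is None or mdir is None:
            continue
        if pdir == tdir and _OPPOSITE.get(mdir) == pdir:
            rows.append(
                {"mirna": mirna, "dir_mirna": mdir, "gene": gene,
                 "dir_mrna": tdir, "dir_protein": pdir}
            )
    out = pd.DataFrame(rows, columns=["mirna", "dir_mirna", "gene", "dir_mrna", "dir_protein"])
    return (
        out.drop_duplicates()
        .sort_values(["mirna", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )


def conformance_fraction(
    cascades: pd.DataFrame,
    candidate_mirnas: Iterable[str],
    candidate_entities: Iterable[str] | None = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Fraction of candidates appearing in at least one conforming cascade.

    Reports both the miRNA-side fraction (candidate miRNAs with a cascade)
    and, when ``candidate_entities`` is given, the entity-side fraction
    (entities with at least one conforming regulator) — the two natural
    denominators for a "more than X% conform" statement.  Also returns a
    per-miRNA target-count summary.
    """
    candidates = sorted(set(candidate_mirnas))
    if not candidates:
        raise ValueError("candidate miRNA list must be non-empty")
    with_cascade = set(cascades["mirna"]) if len(cascades) else set()
    frac = sum(m in with_cascade for m in candidates) / len(candidates)
    stats = {
        "n_candidate_mirnas": float(len(candidates)),
        "n_conforming_mirnas": float(sum(m in with_cascade for m in candidates)),
        "mirna_fraction": frac,
    }
    if candidate_entities is not None:
        ents = sorted(set(candidate_entities))
        covered = set(cascades["gene"]) if len(cascades) else set()
        stats["n_candidate_entities"] = float(len(ents))
        stats["entity_fraction"] = (
            sum(e in covered for e in ents) / len(ents) if ents else float("nan")
        )
    per_mirna = (
        cascades.groupby("mirna", as_index=False)
        .agg(n_targets=("gene", "nunique"), dir_mirna=("dir_mirna", "first"))
        if len(cascades)
        else pd.DataFrame(columns=["mirna", "n_targets", "dir_mirna"])
    )
    return stats, per_mirna
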