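"""Independent brute-force references used to cross-check the package.

Deliberately written in a different style from the implementation (plain
dict/loop code, statistics module instead of numpy) so that agreement is
meaningful.
"""

from __future__ import annotations

import statistics


def brute_force_cascade(
    psm_rows,
    pre_fc: float = 1.3,
    final_fc: float = 1.5,
    cv_max: float = 40.0,
    min_psms: int = 2,
    sn_min: float = 1.5,
):
    """Reference four-stage curation over simple dict rows.

    ``psm_rows``: dicts with keys protein, grade, ratio, snr_control,
    snr_grade, peptide.  Returns {(protein, grade): (is_de, fold_change)}
    for every group with at least one quantifiable PSM.
    """
    groups: dict[tuple[str, str], list[dict]] = {}
    for row in psm_rows:
        if row["snr_control"] < sn_min or row["snr_grade"] < sn_min:
            continue
        groups.setdefault((row["protein"], row["grade"]), []).append(row)

    out = {}
    for key, rows in groups.items():
        ratios = [r["ratio"] for r in rows]
        provisional = sum(ratios) / len(ratios)
        up = provisional > 1
        # stage 1: provisional 1.3-fold gate
        if up and provisional < pre_fc:
            out[key] = (False, provisional)
            continue
        if not up and provisional > 1 / pre_fc:
            out[key] = (False, provisional)
            continue
        # stage 2: keep concordant PSMs passing the same gate
        kept = [
            r for r in rows
            if (r["ratio"] >= pre_fc if up else r["ratio"] <= 1 / pre_fc)
        ]
        kratios = [r["ratio"] for r in kept]
        # stage 3: recompute
        fc = sum(kratios) / len(kratios)
        cv = (
            100.0 * statistics.stdev(kratios) / fc if len(kratios) >= 2 else None
        )
        # stage 4: final call
        ok = (
            (fc >= final_fc if up else fc <= 1 / final_fc)
            and len(kept) >= min_psms
            and cv is not None
            and cv < cv_max
        )
        out[key] = (ok, fc)
    return out


def ranked_fdr_reference(entries, nominal):
    """Enumerate the ranked target/decoy list and return retained targets.

    ``entries``: (id, score, is_decoy) with one entry per peptide.  Decoys
    rank ahead of targets on score ties.
    """
    ranked = sorted(entries, key=lambda e: (-e[1], not e[2], e[0]))
    raws = []
    d = t = 0
    for _, _, is_decoy in ranked:
        if is_decoy:
            d += 1
        else:
            t += 1
        raws.append(d / t if t else float("inf"))
    qs = []
    running = float("inf")
    for raw in reversed(raws):
        running = min(running, raw)
        qs.append(min(running, 1.0))
    qs.reverse()
    return {
        e[0] for e, q in zip(ranked, qs) if not e[2] and q <= nominal
    }, {e[0]: q for e, q in zip(ranked, qs)}


def hypergeom_tail(k: int, n_bg: int, n_target: int, n_query: int) -> float:
    """P(overlap >= k) by exhaustive summation of hypergeometric masses."""
    from math import comb

    total = comb(n_bg, n_query)
    acc = 0
    for i in range(k, min(n_target, n_query) + 1):
        acc += comb(n_target, i) * comb(n_bg - n_target, n_query - i)
    return acc / total
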