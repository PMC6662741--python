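"""Synthetic 4-plex proteomics data with planted ground truth.

Emulates the data regime of a two-run iTRAQ LC-MS/MS experiment comparing
three glioma grades against a pooled control, together with the companion
inputs of the downstream integration stages: a transcript table with a set
direction-concordance rate, validated miRNA-target pairs with a set
inverse-expression conformance rate, and a STRING-style weighted PPI
background with a planted dense module among differentially expressed
transcription regulators.

Every quantity that downstream stages estimate (fold changes, DE status,
concordance and conformance rates, module membership) is recorded in a
:class:`GroundTruth` so recovery can be checked exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .design import CHANNELS, GRADES, ChannelDesign
from .io import PsmRecord, write_psm_table, write_table

RUN_IDS = ("run1", "run2")
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

COMPARTMENTS = ("nuclear", "cytoplasmic", "membrane")


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic experiment.

    Fold changes are tumor/control ratios (unitless).  Reporter noise is
    multiplicative log-normal with coefficient of variation
    ``reporter_noise_cv`` applied independently to each channel.  Decoy PSMs
    carry scores from a Normal shifted ``score_separation`` standard
    deviations below the target score distribution.
    """

    n_proteins: int = 500
    frac_de_per_grade: float = 0.3
    true_fc_range_up: tuple[float, float] = (1.5, 8.0)
    true_fc_range_null: tuple[float, float] = (1 / 1.2, 1.2)
    peptides_per_protein: tuple[int, int] = (1, 6)
    psms_per_peptide_per_run: tuple[int, int] = (1, 4)
    reporter_noise_cv: float = 0.15
    decoy_fraction: float = 0.1
    score_separation: float = 4.0
    concordance_rate: float = 0.65
    mirna_conformance_rate: float = 0.8
    background_nodes: int = 200
    background_edge_prob: float = 0.05
    planted_module_size: int = 10
    planted_module_edge_prob: float = 0.8
    seed: int = 0
    # plumbing knobs, not grade-level biology
    dropout_prob: float = 0.1            # protein missing from one of the two runs
    shared_peptide_fraction: float = 0.05  # peptides mapping to two accessions
    noise_floor: float = 940.0           # S/N = intensity / floor; ~5% of PSMs fail S/N>=1.5
    target_score_mean: float = 8.0
    nuclear_fraction: float = 0.65

    def __post_init__(self) -> None:
        for name in (
            "frac_de_per_grade",
            "reporter_noise_cv",
            "decoy_fraction",
            "concordance_rate",
            "mirna_conformance_rate",
            "background_edge_prob",
            "planted_module_edge_prob",
            "dropout_prob",
            "shared_peptide_fraction",
            "nuclear_fraction",
        ):
            v = getattr(self, name)
            if name == "reporter_noise_cv":
                if v < 0:
                    raise ValueError(f"{name} must be non-negative")
            elif not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_proteins", "background_nodes", "planted_module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("true_fc_range_up", "true_fc_range_null"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0:
                raise ValueError(f"{name} must be strictly positive")
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high")
        for name in ("peptides_per_protein", "psms_per_peptide_per_run"):
            lo, hi = getattr(self, name)
            if lo < 1 or lo > hi:
                raise ValueError(f"{name} must be an ordered interval of positive counts")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorParams":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown generator parameter(s): {sorted(unknown)}")
        for name in ("true_fc_range_up", "true_fc_range_null",
                     "peptides_per_protein", "psms_per_peptide_per_run"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted truth for every downstream recovery check.

    ``proteins`` has one row per (protein, grade): true fold change, DE flag
    and direction.  ``compartments`` maps each protein to its subcellular
    labels.  Transcript-, miRNA- and network-level truth is attached by the
    corresponding generators.
    """

    proteins: pd.DataFrame
    compartments: dict[str, tuple[str, ...]]
    dropped_run: dict[str, str] = field(default_factory=dict)
    transcripts: pd.DataFrame | None = None
    mirna_pairs: pd.DataFrame | None = None
    module_members: list[str] = field(default_factory=list)
    tf_nodes: list[str] = field(default_factory=list)

    def true_fc(self, protein: str, grade: str) -> float:
        df = self.proteins
        row = df[(df.protein == protein) & (df.grade == grade)]
        return float(row.true_fc.iloc[0])

    def de_set(self, grade: str) -> set[str]:
        df = self.proteins
        return set(df[(df.grade == grade) & df.is_de].protein)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def generate_psm_dataset(
    params: GeneratorParams,
) -> tuple[dict[str, list[PsmRecord]], GroundTruth]:
    """Simulate two replicate run-level PSM tables plus their ground truth.

    Each PSM's reporter intensity in channel *c* is
    ``control_intensity × true_fc(c) × lognormal(cv)`` with ``true_fc = 1``
    for the control channel, so in the zero-noise limit every PSM ratio
    equals the protein's planted fold change exactly.  Decoy PSMs are
    appended at the requested fraction with scores from the shifted decoy
    distribution and carry no planted signal.
    """
    rng = np.random.default_rng(params.seed)
    design = ChannelDesign()
    sigma = _lognormal_sigma(params.reporter_noise_cv)

    proteins = [f"GENE{i:04d}" for i in range(1, params.n_proteins + 1)]

    # per-(protein, grade) truth
    rows = []
    fc_map: dict[tuple[str, str], float] = {}
    lo_u, hi_u = params.true_fc_range_up
    lo_n, hi_n = params.true_fc_range_null
    for prot in proteins:
        for grade in GRADES:
            is_de = rng.random() < params.frac_de_per_grade
            if is_de:
                fc = float(np.exp(rng.uniform(np.log(lo_u), np.log(hi_u))))
                if rng.random() < 0.5:
                    fc = 1.0 / fc
            else:
                fc = float(np.exp(rng.uniform(np.log(lo_n), np.log(hi_n))))
            direction = "up" if fc > 1 else "down"
            rows.append((prot, grade, fc, is_de, direction))
            fc_map[(prot, grade)] = fc
    truth_df = pd.DataFrame(rows, columns=["protein", "grade", "true_fc", "is_de", "direction"])

    compartments: dict[str, tuple[str, ...]] = {}
    for prot in proteins:
        primary = "nuclear" if rng.random() < params.nuclear_fraction else (
            "cytoplasmic" if rng.random() < 0.7 else "membrane"
        )
        labels = [primary]
        if rng.random() < 0.1:  # a minority of proteins are multi-localized
            extra = [c for c in COMPARTMENTS if c != primary]
            labels.append(extra[int(rng.integers(len(extra)))])
        compartments[prot] = tuple(labels)

    dropped_run: dict[str, str] = {}
    for prot in proteins:
        if rng.random() < params.dropout_prob:
            dropped_run[prot] = RUN_IDS[int(rng.integers(2))]

    # peptide catalogue per protein (shared across runs, as in a real search)
    peptide_catalog: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    n_pep = rng.integers(params.peptides_per_protein[0],
                         params.peptides_per_protein[1] + 1, size=len(proteins))
    for prot, k in zip(proteins, n_pep):
        peps = []
        for j in range(int(k)):
            seq = "".join(rng.choice(_AA, size=10))
            accs: tuple[str, ...] = (prot,)
            if params.shared_peptide_fraction > 0 and rng.random() < params.shared_peptide_fraction:
                other = proteins[int(rng.integers(len(proteins)))]
                if other != prot:
                    accs = tuple(sorted((prot, other)))
            peps.append((seq, accs))
        peptide_catalog[prot] = peps

    runs: dict[str, list[PsmRecord]] = {r: [] for r in RUN_IDS}
    counter = 0
    for prot in proteins:
        for run in RUN_IDS:
            if dropped_run.get(prot) == run:
                continue
            for seq, accs in peptide_catalog[prot]:
                n_psm = int(rng.integers(params.psms_per_peptide_per_run[0],
                                         params.psms_per_peptide_per_run[1] + 1))
                for _ in range(n_psm):
                    counter += 1
                    i0 = float(10 ** rng.uniform(3.0, 6.0))
                    intensity: dict[str, float] = {}
                    for ch in CHANNELS:
                        if ch == design.control_channel:
                            fc_ch = 1.0
                        else:
                            grade = next(g for g, c in design.grade_channels.items() if c == ch)
                            fc_ch = fc_map[(prot, grade)]
                        noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
                        intensity[ch] = i0 * fc_ch * noise
                    snr = {ch: intensity[ch] / params.noise_floor for ch in CHANNELS}
                    runs[run].append(
                        PsmRecord(
                            run_id=run,
                            psm_id=f"psm{counter:06d}",
                            peptide=seq,
                            proteins=accs,
                            score=float(rng.normal(params.target_score_mean, 1.0)),
                            is_decoy=False,
                            intensity=intensity,
                            snr=snr,
                        )
                    )

    # decoys: a decoy_fraction share of the final PSM total
    n_targets = sum(len(v) for v in runs.values())
    if params.decoy_fraction > 0:
        n_decoys = int(round(params.decoy_fraction / (1 - params.decoy_fraction) * n_targets))
        for d in range(n_decoys):
            counter += 1
            run = RUN_IDS[int(rng.integers(2))]
            i0 = float(10 ** rng.uniform(3.0, 6.0))
            intensity = {}
            for ch in CHANNELS:
                noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
                intensity[ch] = i0 * noise
            snr = {ch: intensity[ch] / params.noise_floor for ch in CHANNELS}
            runs[run].append(
                PsmRecord(
                    run_id=run,
                    psm_id=f"psm{counter:06d}",
                    peptide="".join(rng.choice(_AA, size=10)),
                    proteins=(f"DECOY_{d + 1:04d}",),
                    score=float(rng.normal(params.target_score_mean - params.score_separation, 1.0)),
                    is_decoy=True,
                    intensity=intensity,
                    snr=snr,
                )
            )

    truth = GroundTruth(proteins=truth_df, compartments=compartments, dropped_run=dropped_run)
    return runs, truth


def generate_transcriptome(
    truth: GroundTruth, concordance_rate: float, seed: int
) -> pd.DataFrame:
    """Transcript differential-expression table with a set concordance rate.

    For every DE (protein, grade) the transcript direction matches the
    protein direction with probability ``concordance_rate``; otherwise the
    record is emitted flipped or omitted (equal odds).  The realized outcome
    per entity is recorded in ``truth.transcripts``.
    """
    if not 0.0 <= concordance_rate <= 1.0:
        raise ValueError("concordance_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    de = truth.proteins[truth.proteins.is_de]
    for row in de.itertuples(index=False):
        log2fc = float(np.log2(row.true_fc) + rng.normal(0.0, 0.1))
        if rng.random() < concordance_rate:
            outcome = "concordant"
            direction = row.direction
            if (direction == "up") != (log2fc > 0):
                log2fc = -log2fc
        elif rng.random() < 0.5:
            outcome = "flipped"
            direction = "down" if row.direction == "up" else "up"
            log2fc = -abs(log2fc) if direction == "down" else abs(log2fc)
        else:
            outcome = "absent"
            direction = None
        truth_rows.append((row.protein, row.grade, outcome))
        if direction is not None:
            rows.append((row.protein, row.grade, log2fc, direction))
    truth.transcripts = pd.DataFrame(truth_rows, columns=["gene", "grade", "outcome"])
    return pd.DataFrame(rows, columns=["gene", "grade", "log2fc", "direction"])


def generate_mirna_pairs(
    truth: GroundTruth, conformance_rate: float, seed: int, grade: str = "IV"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validated miRNA-target pairs plus miRNA expression directions.

    Each DE protein at ``grade`` receives one putative miRNA regulator; with
    probability ``conformance_rate`` the miRNA's direction is the inverse of
    its target's (a conforming, biologically consistent repressor), otherwise
    it shares the target's direction.  Truth lands in ``truth.mirna_pairs``.
    """
    if not 0.0 <= conformance_rate <= 1.0:
        raise ValueError("mirna conformance rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    de = truth.proteins[(truth.proteins.grade == grade) & truth.proteins.is_de]
    pair_rows, dir_rows, truth_rows = [], [], []
    for i, row in enumerate(de.itertuples(index=False), start=1):
        mirna = f"miR-{i:04d}"
        conforming = bool(rng.random() < conformance_rate)
        if conforming:
            mdir = "down" if row.direction == "up" else "up"
        else:
            mdir = row.direction
        pair_rows.append((mirna, row.protein, True))
        dir_rows.append((mirna, mdir))
        truth_rows.append((mirna, row.protein, mdir, row.direction, conforming))
    pairs = pd.DataFrame(pair_rows, columns=["mirna", "target_gene", "validated"])
    dirs = pd.DataFrame(dir_rows, columns=["mirna", "direction"])
    truth.mirna_pairs = pd.DataFrame(
        truth_rows,
        columns=["mirna", "target_gene", "direction_mirna", "direction_target", "conforming"],
    )
    return pairs, dirs


def generate_ppi(truth: GroundTruth, params: GeneratorParams) -> nx.Graph:
    """STRING-style background interactome with a planted dense module.

    An Erdős–Rényi graph over ``background_nodes`` proteins plus extra edges
    with probability ``planted_module_edge_prob`` among a designated module
    of DE transcription regulators.  Combined scores are uniform in
    [400, 999].
    """
    rng = np.random.default_rng(params.seed + 1)
    nodes = list(truth.proteins.protein.unique())[: params.background_nodes]
    if not nodes:
        raise ValueError("cannot build a PPI graph over an empty node set")
    if params.planted_module_size > len(nodes):
        raise ValueError("planted module larger than the background node set")

    # plant the module among DE-up grade-IV proteins where possible
    de_up = [
        p for p in nodes
        if p in set(
            truth.proteins[
                (truth.proteins.grade == "IV")
                & truth.proteins.is_de
                & (truth.proteins.direction == "up")
            ].protein
        )
    ]
    pool = de_up if len(de_up) >= params.planted_module_size else nodes
    module = sorted(rng.choice(pool, size=params.planted_module_size, replace=False).tolist())
    module_set = set(module)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    n = len(nodes)
    idx_u, idx_v = np.triu_indices(n, k=1)
    u_draw = rng.random(idx_u.size)
    for ui, vi, u in zip(idx_u, idx_v, u_draw):
        a, b = nodes[ui], nodes[vi]
        p = (
            params.planted_module_edge_prob
            if a in module_set and b in module_set
            else params.background_edge_prob
        )
        if u < p:
            g.add_edge(a, b, combined_score=int(rng.integers(400, 1000)))
    truth.module_members = module
    truth.tf_nodes = module
    return g


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    df = truth.proteins.copy()
    df["compartments"] = df.protein.map(lambda p: ";".join(truth.compartments.get(p, ())))
    df["dropped_run"] = df.protein.map(lambda p: truth.dropped_run.get(p, ""))
    write_table(df, path)


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    rows = [
        (min(a, b), max(a, b), d["combined_score"]) for a, b, d in g.edges(data=True)
    ]
    rows.sort()
    write_table(
        pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]), path
    )


def write_dataset(outdir: str | Path, params: GeneratorParams) -> dict[str, Path]:
    """Generate and write every pipeline input under ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runs, truth = generate_psm_dataset(params)
    tx = generate_transcriptome(truth, params.concordance_rate, params.seed + 2)
    pairs, mdirs = generate_mirna_pairs(truth, params.mirna_conformance_rate, params.seed + 3)
    ppi = generate_ppi(truth, params)
    paths = {}
    for run_id, psms in runs.items():
        paths[run_id] = outdir / f"psms_{run_id}.tsv"
        write_psm_table(psms, paths[run_id])
    paths["transcripts"] = outdir / "transcripts.tsv"
    write_table(tx, paths["transcripts"])
    paths["mirna_pairs"] = outdir / "mirna_pairs.tsv"
    write_table(pairs, paths["mirna_pairs"])
    paths["mirna_dirs"] = outdir / "mirna_dirs.tsv"
    write_table(mdirs, paths["mirna_dirs"])
    paths["edges"] = outdir / "ppi_edges.tsv"
    write_edge_list(ppi, paths["edges"])
    paths["truth"] = outdir / "truth.tsv"
    write_truth(truth, paths["truth"])
    return paths


def generate_score_set(
    n_correct: int,
    n_incorrect: int,
    score_separation: float,
    seed: int,
    target_score_mean: float = 8.0,
) -> pd.DataFrame:
    """Scores for FDR-calibration studies.

    Correct target identifications score Normal(mu, 1); incorrect targets and
    decoys both score Normal(mu - separation, 1), the usual equal-size decoy
    database assumption.  Columns: score, is_decoy, is_correct (truth).
    """
    rng = np.random.default_rng(seed)
    mu = target_score_mean
    rows = (
        [(s, False, True) for s in rng.normal(mu, 1.0, n_correct)]
        + [(s, False, False) for s in rng.normal(mu - score_separation, 1.0, n_incorrect)]
        + [(s, True, False) for s in rng.normal(mu - score_separation, 1.0, n_incorrect)]
    )
    return pd.DataFrame(rows, columns=["score", "is_decoy", "is_correct"])
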