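"""Readers and writers for the pipeline's tab-separated file dialects.

All tables are plain TSV with headers.  Multi-protein PSM assignments are
semicolon-separated in the ``protein`` column.  Gene-set files use the GMT
dialect (set name, description, then one gene per column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import CHANNELS


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


PSM_COLUMNS = [
    "run_id",
    "psm_id",
    "peptide",
    "protein",
    "score",
    "is_decoy",
    *[f"int_{c}" for c in CHANNELS],
    *[f"snr_{c}" for c in CHANNELS],
]


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with 4-plex reporter quantities.

    ``proteins`` lists every accession the peptide maps to; quantitation
    uses only records with a single accession ("unique" peptides).
    Decoy records (``is_decoy``) exist solely for FDR estimation and never
    enter quantitation.
    """

    run_id: str
    psm_id: str
    peptide: str
    proteins: tuple[str, ...]
    score: float
    is_decoy: bool
    intensity: Mapping[str, float] = field(hash=False)
    snr: Mapping[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        if set(self.intensity) != set(CHANNELS) or set(self.snr) != set(CHANNELS):
            raise ValueError(f"reporter channels must be exactly {set(CHANNELS)}")
        for ch, v in self.intensity.items():
            if v < 0:
                raise ValueError(f"negative intensity in channel {ch}")

    @property
    def accession(self) -> str:
        """Single accession of a unique PSM (errors if shared)."""
        if len(self.proteins) != 1:
            raise ValueError("PSM maps to multiple proteins")
        return self.proteins[0]


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Parse a run-level PSM TSV into records.

    Raises :class:`FormatError` naming any missing column, and ``ValueError``
    with the offending line number for malformed rows (non-numeric or
    negative intensities, empty protein cells).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        row = row._asdict()
        try:
            proteins = tuple(p for p in str(row["protein"]).split(";") if p)
            if not proteins:
                raise ValueError("empty protein cell")
            intensity = {c: float(row[f"int_{c}"]) for c in CHANNELS}
            snr = {c: float(row[f"snr_{c}"]) for c in CHANNELS}
            records.append(
                PsmRecord(
                    run_id=str(row["run_id"]),
                    psm_id=str(row["psm_id"]),
                    peptide=str(row["peptide"]),
                    proteins=proteins,
                    score=float(row["score"]),
                    is_decoy=_parse_bool(row["is_decoy"]),
                    intensity=intensity,
                    snr=snr,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return records


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in {"true", "1"}:
        return True
    if v in {"false", "0"}:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def psms_to_frame(psms: Iterable[PsmRecord]) -> pd.DataFrame:
    rows = []
    for p in psms:
        row = {
            "run_id": p.run_id,
            "psm_id": p.psm_id,
            "peptide": p.peptide,
            "protein": ";".join(p.proteins),
            "score": p.score,
            "is_decoy": p.is_decoy,
        }
        for c in CHANNELS:
            row[f"int_{c}"] = p.intensity[c]
        for c in CHANNELS:
            row[f"snr_{c}"] = p.snr[c]
        rows.append(row)
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def write_psm_table(psms: Iterable[PsmRecord], path: str | Path) -> None:
    psms_to_frame(psms).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Generic TSV reader that validates required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: GMT line {lineno} has fewer than 3 fields")
        name = parts[0]
        sets[name] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(set(genes))]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_node_set(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.upper())
    return out
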