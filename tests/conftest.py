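from __future__ import annotations

import itertools

import pytest

from nucmap.design import CHANNELS, ChannelDesign
from nucmap.io import PsmRecord

_counter = itertools.count(1)


def make_psm(
    ratios: dict[str, float] | None = None,
    control: float = 100.0,
    run_id: str = "run1",
    peptide: str = "PEPTIDEK",
    proteins: tuple[str, ...] = ("GENE0001",),
    score: float = 10.0,
    is_decoy: bool = False,
    snr: float | dict[str, float] = 5.0,
    psm_id: str | None = None,
) -> PsmRecord:
    """Build a PSM whose grade-channel ratios are given explicitly.

    ``ratios`` maps grade -> tumor/control ratio (missing grades default
    to 1.0); ``snr`` may be a scalar (all channels) or per-channel map.
    """
    design = ChannelDesign()
    ratios = ratios or {}
    intensity = {design.control_channel: control}
    for grade, ch in design.grade_channels.items():
        intensity[ch] = control * ratios.get(grade, 1.0)
    if isinstance(snr, dict):
        snr_map = {c: snr.get(c, 5.0) for c in CHANNELS}
    else:
        snr_map = {c: float(snr) for c in CHANNELS}
    return PsmRecord(
        run_id=run_id,
        psm_id=psm_id or f"t{next(_counter):05d}",
        peptide=peptide,
        proteins=proteins,
        score=score,
        is_decoy=is_decoy,
        intensity=intensity,
        snr=snr_map,
    )


@pytest.fixture
def design() -> ChannelDesign:
    return ChannelDesign()
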