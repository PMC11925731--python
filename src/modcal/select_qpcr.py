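"""SELECT single-base qPCR: ΔΔCT computation and modified/unmodified calls.

SELECT probes a suspected m6A site with one oligo and a nearby unmodified A
with a control oligo; the modification hinders elongation/ligation at the
target.  ΔCT = CT(target) − CT(A control) within one sample; ΔΔCT compares
the native sample with an unmodified reference (IVT RNA, or a
methyltransferase-deletion mutant for sites with a known writer).  A site is
classified modified when ΔΔCT ≤ −1.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import CtMeasurement

DDCT_MODIFIED_MAX = -1.0  # inclusive: ddct <= -1 classifies modified


@dataclass(frozen=True)
class SelectResult:
    assay_id: str
    delta_ct_wt: float
    delta_ct_ref: float
    ddct: float
    classified_modified: bool
    ref_type: str = "IVT"
    sd_wt: float = 0.0
    sd_ref: float = 0.0


def select_classify(ct: Sequence[CtMeasurement], ref_type: str = "IVT"
                    ) -> list[SelectResult]:
    """Classify each assay from replicate-averaged ΔCT values.

    ΔCT is computed per replicate (CT target − CT A-control) and averaged
    arithmetically within each sample type; the replicate standard deviation
    is reported.  An assay missing WT or the reference sample type is an
    error.
    """
    if ref_type not in ("IVT", "Mut"):
        raise ValueError(f"ref_type must be 'IVT' or 'Mut', got {ref_type!r}")
    by_assay: dict[str, dict[str, list[float]]] = {}
    for m in ct:
        by_assay.setdefault(m.assay_id, {}).setdefault(m.sample_type, []).append(
            m.ct_target - m.ct_control_a
        )
    out: list[SelectResult] = []
    for assay_id in sorted(by_assay):
        groups = by_assay[assay_id]
        for needed in ("WT", ref_type):
            if needed not in groups:
                raise ValueError(f"assay {assay_id!r} has no {needed} measurements")
        dct_wt = statistics.fmean(groups["WT"])
        dct_ref = statistics.fmean(groups[ref_type])
        ddct = dct_wt - dct_ref
        out.append(
            SelectResult(
                assay_id=assay_id,
                delta_ct_wt=dct_wt,
                delta_ct_ref=dct_ref,
                ddct=ddct,
                classified_modified=ddct <= DDCT_MODIFIED_MAX,
                ref_type=ref_type,
                sd_wt=statistics.stdev(groups["WT"]) if len(groups["WT"]) > 1 else 0.0,
                sd_ref=statistics.stdev(groups[ref_type]) if len(groups[ref_type]) > 1 else 0.0,
            )
        )
    return out


def select_frame(results: Iterable[SelectResult]) -> pd.DataFrame:
    rows = list(results)
    return pd.DataFrame(
        {
            "assay_id": [r.assay_id for r in rows],
            "delta_ct_wt": [r.delta_ct_wt for r in rows],
            "delta_ct_ref": [r.delta_ct_ref for r in rows],
            "ddct": [r.ddct for r in rows],
            "classified_modified": [r.classified_modified for r in rows],
            "ref_type": [r.ref_type for r in rows],
            "sd_wt": [r.sd_wt for r in rows],
            "sd_ref": [r.sd_ref for r in rows],
        }
    )
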