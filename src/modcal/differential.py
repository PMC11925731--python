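"""Condition-dependent modification changes via ΔESB, site sharing, MS cross-check.

ΔESB (ESB test − ESB control within one condition) proxies modification
stoichiometry; its change between two conditions (a = control temperature,
b = stress) proxies the change in modification level.  Positions not detected
in a condition get ΔESB 0 there, which makes the per-position comparison
total over the union of called sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .io_formats import MsMeasurement, SiteRecord

logger = logging.getLogger(__name__)

CHANGE_LABELS = ("increased", "decreased", "unchanged")
SHARED_LABELS = ("shared", "unique_modification", "modification_in_unique_rna")


@dataclass(frozen=True)
class DeltaEsbRecord:
    molecule_id: str
    position: int
    esb_test_a: float
    esb_control_a: float
    esb_test_b: float
    esb_control_b: float
    delta_a: float
    delta_b: float
    ratio: float  # delta_b / delta_a; NaN when delta_a == 0
    change: str

    def __post_init__(self) -> None:
        if self.change not in CHANGE_LABELS:
            raise ValueError(f"unknown change label {self.change!r}")


@dataclass(frozen=True)
class SharedStatus:
    molecule_id: str
    position: int
    status: str

    def __post_init__(self) -> None:
        if self.status not in SHARED_LABELS:
            raise ValueError(f"unknown status {self.status!r}")


def compute_delta_esb(sites_a: Sequence[SiteRecord], sites_b: Sequence[SiteRecord],
                      called_a: set[tuple[str, int]], called_b: set[tuple[str, int]],
                      epsilon: float = 1e-6) -> list[DeltaEsbRecord]:
    """Per-position ΔESB for both conditions over the union of called sites.

    A position counts as detected in a condition when it was called there and
    has a row in that condition's site table; otherwise its ΔESB is set to 0
    (and its ESB fields are NaN).  ``change`` compares the two deltas with an
    ``epsilon`` equality band.
    """
    index_a = {(s.molecule_id, s.position): s for s in sites_a}
    index_b = {(s.molecule_id, s.position): s for s in sites_b}
    out: list[DeltaEsbRecord] = []
    for key in sorted(called_a | called_b):
        rec_a = index_a.get(key) if key in called_a else None
        rec_b = index_b.get(key) if key in called_b else None
        delta_a = rec_a.esb_test - rec_a.esb_control if rec_a else 0.0
        delta_b = rec_b.esb_test - rec_b.esb_control if rec_b else 0.0
        if delta_b > delta_a + epsilon:
            change = "increased"
        elif delta_b < delta_a - epsilon:
            change = "decreased"
        else:
            change = "unchanged"
        out.append(
            DeltaEsbRecord(
                molecule_id=key[0], position=key[1],
                esb_test_a=rec_a.esb_test if rec_a else math.nan,
                esb_control_a=rec_a.esb_control if rec_a else math.nan,
                esb_test_b=rec_b.esb_test if rec_b else math.nan,
                esb_control_b=rec_b.esb_control if rec_b else math.nan,
                delta_a=delta_a, delta_b=delta_b,
                ratio=delta_b / delta_a if delta_a != 0 else math.nan,
                change=change,
            )
        )
    return out


def compare_conditions(called_a: set[tuple[str, int]], called_b: set[tuple[str, int]],
                       depth_a: Mapping[str, int], depth_b: Mapping[str, int],
                       min_depth: int = 20,
                       delta_records: Sequence[DeltaEsbRecord] | None = None,
                       biotype_by_site: Mapping[tuple[str, int], str] | None = None,
                       ) -> tuple[list[SharedStatus], dict]:
    """Label every called position as shared between conditions or unique.

    A position called in only one condition is a "modification in a unique
    RNA" when its molecule is under ``min_depth`` reads in the other
    condition (the RNA itself was effectively absent there), and a "unique
    modification" otherwise.  The summary reports label counts; when ΔESB
    records and per-site biotypes are supplied it also reports the fraction
    of comparable (shared) CDS sites with increased abundance.
    """
    statuses: list[SharedStatus] = []
    for key in sorted(called_a | called_b):
        mol = key[0]
        for depth_map, name in ((depth_a, "a"), (depth_b, "b")):
            if mol not in depth_map:
                raise KeyError(f"molecule {mol!r} missing from condition-{name} depth map")
        if key in called_a and key in called_b:
            status = "shared"
        else:
            other_depth = depth_b[mol] if key in called_a else depth_a[mol]
            status = (
                "modification_in_unique_rna" if other_depth < min_depth
                else "unique_modification"
            )
        statuses.append(SharedStatus(key[0], key[1], status))
    summary: dict = {
        "counts": {
            label: sum(s.status == label for s in statuses) for label in SHARED_LABELS
        },
        "total": len(statuses),
    }
    if delta_records is not None and biotype_by_site is not None:
        shared = {
            (s.molecule_id, s.position) for s in statuses if s.status == "shared"
        }
        cds_shared = [
            r for r in delta_records
            if (r.molecule_id, r.position) in shared
            and biotype_by_site.get((r.molecule_id, r.position)) == "CDS"
        ]
        increased = sum(r.change == "increased" for r in cds_shared)
        summary["cds_shared"] = len(cds_shared)
        summary["cds_shared_increased"] = increased
        summary["cds_increased_fraction"] = (
            increased / len(cds_shared) if cds_shared else math.nan
        )
    return statuses, summary


def ms_correlation(delta_records: Sequence[DeltaEsbRecord],
                   ms: Sequence[MsMeasurement],
                   mod_name_by_site: Mapping[tuple[str, int], str],
                   condition_a: str = "37C", condition_b: str = "45C",
                   use_ratios: bool = True, log_scale: bool = False,
                   ) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation between sequencing-based and MS-based changes.

    Per modification type, the sequencing-side change is mean ΔESB(b) / mean
    ΔESB(a) over that type's sites (records with ΔESB(a) = 0, i.e. undefined
    per-site ratio, are excluded) and the MS-side change is mean abundance(b)
    / mean abundance(a) across replicates.  With ``use_ratios=False`` the
    per-type condition-b means are paired directly instead of ratios;
    ``log_scale`` correlates natural logs of the paired values.

    Returns (rho, two-sided p, paired table).
    """
    by_type: dict[str, list[DeltaEsbRecord]] = {}
    for r in delta_records:
        if r.delta_a == 0:
            continue
        name = mod_name_by_site.get((r.molecule_id, r.position))
        if name is not None:
            by_type.setdefault(name, []).append(r)

    ms_means: dict[tuple[str, str], float] = {}
    for name in {m.mod_name for m in ms}:
        for cond in (condition_a, condition_b):
            vals = [m.abundance for m in ms
                    if m.mod_name == name and m.condition == cond]
            if vals:
                ms_means[(name, cond)] = sum(vals) / len(vals)

    rows = []
    for name, recs in sorted(by_type.items()):
        if (name, condition_a) not in ms_means or (name, condition_b) not in ms_means:
            continue
        mean_a = sum(r.delta_a for r in recs) / len(recs)
        mean_b = sum(r.delta_b for r in recs) / len(recs)
        if mean_a == 0 or ms_means[(name, condition_a)] == 0:
            continue
        if use_ratios:
            seq_val = mean_b / mean_a
            ms_val = ms_means[(name, condition_b)] / ms_means[(name, condition_a)]
        else:
            seq_val = mean_b
            ms_val = ms_means[(name, condition_b)]
        rows.append({"mod_name": name, "n_sites": len(recs),
                     "seq_change": seq_val, "ms_change": ms_val})
    paired = pd.DataFrame(rows, columns=["mod_name", "n_sites", "seq_change", "ms_change"])
    if len(paired) < 3:
        raise ValueError(
            f"need >= 3 paired modification types for a correlation, got {len(paired)}"
        )
    x = paired["seq_change"].to_numpy(dtype=float)
    y = paired["ms_change"].to_numpy(dtype=float)
    if log_scale:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log-scale correlation needs positive paired values")
        import numpy as np
        x, y = np.log(x), np.log(y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    rho, p = stats.pearsonr(x, y)
    return float(rho), float(p), paired


def delta_ttest(esb_replicates_a: Sequence[float],
                esb_replicates_b: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-sample t-test over replicate-level ESB values at one site."""
    t, p = stats.ttest_ind(esb_replicates_b, esb_replicates_a)
    return float(t), float(p)


def delta_frame(records: Iterable[DeltaEsbRecord]) -> pd.DataFrame:
    rows = list(records)
    return pd.DataFrame(
        {
            "molecule": [r.molecule_id for r in rows],
            "position": [r.position for r in rows],
            "esb_test_a": [r.esb_test_a for r in rows],
            "esb_control_a": [r.esb_control_a for r in rows],
            "esb_test_b": [r.esb_test_b for r in rows],
            "esb_control_b": [r.esb_control_b for r in rows],
            "delta_a": [r.delta_a for r in rows],
            "delta_b": [r.delta_b for r in rows],
            "ratio": [r.ratio for r in rows],
            "change": [r.change for r in rows],
        }
    )


def shared_frame(statuses: Iterable[SharedStatus]) -> pd.DataFrame:
    rows = list(statuses)
    return pd.DataFrame(
        {
            "molecule": [s.molecule_id for s in rows],
            "position": [s.position for s in rows],
            "status": [s.status for s in rows],
        }
    )
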