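"""Threshold application, detection benchmarking and the precision/recall grid search.

The calibration strategy: apply a four-parameter cutoff (ESB test >=, ESB
control <=, odds ratio >=, adjusted p <=) to per-site caller output, merge
called positions into signal regions, score regions against a catalogue of
known modifications with a +-10 nt tolerance (modification signals smear over
neighbouring nucleotides in nanopore data), and pick the cutoff combination
with the highest recall subject to a precision floor.  Among ties the least
restrictive threshold values are preferred.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import KnownSite, SiteRecord
from .regions import merge_regions
from .utils import percent_half_up, percent_truncated

logger = logging.getLogger(__name__)

DETECTION_CATEGORIES = (
    "detected",
    "detected_with_offset",
    "type_not_detectable",
    "depth_insufficient",
    "not_detected",
)


@dataclass(frozen=True)
class ThresholdSet:
    """The four cutoffs the grid search optimizes (all comparisons inclusive)."""

    esb_test_min: float
    esb_control_max: float
    oddr_min: float
    padj_max: float

    def __post_init__(self) -> None:
        for name in ("esb_test_min", "esb_control_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("oddr_min", "padj_max"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


def _default_grid_lists() -> dict[str, list[float]]:
    return {
        "esb_test_values": [round(0.01 * i, 2) for i in range(1, 21)],
        "esb_control_values": [round(0.005 * i, 3) for i in range(1, 21)],
        "oddr_values": [0.5 * i for i in range(1, 21)],
        "padj_values": [1e-5, 1e-3, 1e-2, 5e-2],
    }


@dataclass(frozen=True)
class GridSpec:
    """Candidate cutoff lists; the Cartesian product is searched exhaustively.

    The default is 20 x 20 x 20 x 4 = 32,000 combinations on the fraction
    scale, containing the canonical selected set (OddR 3, adjusted p .05).
    """

    esb_test_values: tuple[float, ...] = ()
    esb_control_values: tuple[float, ...] = ()
    oddr_values: tuple[float, ...] = ()
    padj_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        defaults = _default_grid_lists()
        for name in defaults:
            vals = tuple(getattr(self, name))
            if not vals:
                vals = tuple(defaults[name])
            if list(vals) != sorted(set(vals)):
                raise ValueError(f"{name} must be strictly sorted ascending")
            object.__setattr__(self, name, vals)

    @property
    def n_combinations(self) -> int:
        return (
            len(self.esb_test_values) * len(self.esb_control_values)
            * len(self.oddr_values) * len(self.padj_values)
        )

    def __contains__(self, t: ThresholdSet) -> bool:
        return (
            t.esb_test_min in self.esb_test_values
            and t.esb_control_max in self.esb_control_values
            and t.oddr_min in self.oddr_values
            and t.padj_max in self.padj_values
        )


@dataclass(frozen=True)
class PRPoint:
    """Region-level precision and exact-site recall for one threshold set."""

    thresholds: ThresholdSet
    true_regions: int
    false_regions: int
    known_detected: int
    known_total: int
    precision: float = field(default=math.nan)
    recall: float = field(default=math.nan)

    def __post_init__(self) -> None:
        denom = self.true_regions + self.false_regions
        precision = self.true_regions / denom if denom > 0 else math.nan
        recall = self.known_detected / self.known_total if self.known_total > 0 else 0.0
        object.__setattr__(self, "precision", precision)
        object.__setattr__(self, "recall", recall)


@dataclass(frozen=True)
class DetectionOutcome:
    """One known site's five-way detection classification."""

    known_site: KnownSite
    category: str
    offset_nt: int | None = None

    def __post_init__(self) -> None:
        if self.category not in DETECTION_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.offset_nt is not None) != (self.category == "detected_with_offset"):
            raise ValueError("offset_nt present iff category is detected_with_offset")


# ---------------------------------------------------------------------------
# thresholding and tool-specific candidate filters
# ---------------------------------------------------------------------------

def apply_thresholds(sites: Iterable[SiteRecord], t: ThresholdSet
                     ) -> set[tuple[str, int]]:
    """Positions called modified: all four inclusive criteria satisfied."""
    return {
        (s.molecule_id, s.position)
        for s in sites
        if s.esb_test >= t.esb_test_min
        and s.esb_control <= t.esb_control_max
        and s.odds_ratio >= t.oddr_min
        and s.p_adj <= t.padj_max
    }


#: author-suggested candidate rules, comparisons exactly as printed
CANDIDATE_RULES = {
    # OddR >= 2.5 and adjusted p <= 1e-5
    "eligos": lambda df: (df["odds_ratio"] >= 2.5) & (df["p_adj"] <= 1e-5),
    # GMM logit p <= .01
    "nanocompore": lambda df: df["p_gmm"] <= 0.01,
    # stoichiometry difference >= 0.1 and adjusted p <= .05
    "cheui_diff": lambda df: (df["stoich_diff"] >= 0.1) & (df["p_adj"] <= 0.05),
    # OddR >= 1.5 and adjusted p < .05 for both the G-test and the OddR
    "drummer": lambda df: (
        (df["odds_ratio"] >= 1.5) & (df["p_g"] < 0.05) & (df["p_oddr"] < 0.05)
    ),
    # modification probability >= 0.9999 in WT and < 0.999 in the IVT control
    "cheui_solo": lambda df: (df["prob_wt"] >= 0.9999) & (df["prob_ivt"] < 0.999),
}


def candidate_filter(rows: pd.DataFrame, tool_rule: str) -> set[tuple[str, int]]:
    """Apply a named tool's suggested candidate rule to its output rows.

    ``rows`` must carry ``molecule``/``position`` plus the fields the rule
    tests (see :data:`CANDIDATE_RULES`).  Strict-vs-inclusive comparisons are
    preserved as printed by each tool's authors.
    """
    if tool_rule not in CANDIDATE_RULES:
        raise ValueError(
            f"unknown candidate rule {tool_rule!r}; "
            f"known: {sorted(CANDIDATE_RULES)}"
        )
    try:
        mask = CANDIDATE_RULES[tool_rule](rows)
    except KeyError as exc:
        raise ValueError(f"rule {tool_rule!r} needs column {exc}") from exc
    kept = rows.loc[mask]
    return set(zip(kept["molecule"].astype(str), kept["position"].astype(int)))


# ---------------------------------------------------------------------------
# five-way classification of known sites
# ---------------------------------------------------------------------------

def classify_known_sites(called: set[tuple[str, int]], known: Iterable[KnownSite],
                         depth_by_molecule: Mapping[str, int], min_depth: int = 20,
                         offset_window: int = 10) -> list[DetectionOutcome]:
    """Assign each known site exactly one of five detection categories.

    Precedence: type not detectable -> read depth insufficient -> detected at
    the exact site -> detected through an offset signal within the window
    (nearest call; ties to the upstream position) -> not detected.
    """
    by_molecule: dict[str, list[int]] = {}
    for mol, pos in called:
        by_molecule.setdefault(mol, []).append(pos)
    for positions in by_molecule.values():
        positions.sort()
    out: list[DetectionOutcome] = []
    for site in known:
        if site.molecule_id not in depth_by_molecule:
            raise KeyError(
                f"molecule {site.molecule_id!r} carries a known site but is "
                f"absent from the depth map"
            )
        if site.detectable is False:
            out.append(DetectionOutcome(site, "type_not_detectable"))
            continue
        if depth_by_molecule[site.molecule_id] < min_depth:
            out.append(DetectionOutcome(site, "depth_insufficient"))
            continue
        calls = by_molecule.get(site.molecule_id, [])
        if site.position in calls:
            out.append(DetectionOutcome(site, "detected"))
            continue
        nearby = [
            p for p in calls
            if p != site.position and abs(p - site.position) <= offset_window
        ]
        if nearby:
            best = min(nearby, key=lambda p: (abs(p - site.position), p))
            out.append(
                DetectionOutcome(site, "detected_with_offset",
                                 offset_nt=best - site.position)
            )
        else:
            out.append(DetectionOutcome(site, "not_detected"))
    return out


# ---------------------------------------------------------------------------
# precision / recall
# ---------------------------------------------------------------------------

def precision_recall(called: set[tuple[str, int]], known: Sequence[KnownSite],
                     tolerance: int = 10, thresholds: ThresholdSet | None = None,
                     detectable_only: bool = False, recall_window: int = 0
                     ) -> PRPoint:
    """Region-tolerant precision and known-site recall for one called set.

    Called positions are merged into signal regions; a region is TRUE when it
    contains a known site or lies within ``tolerance`` nt of one on the same
    molecule.  Recall counts known sites with a call at the exact position
    (``recall_window`` > 0 widens the match).  With ``detectable_only`` the
    recall counts exclude modification types not detectable by error-based
    calling; region truth always uses the full catalogue.
    """
    if thresholds is None:
        thresholds = ThresholdSet(0.0, 1.0, 0.0, 1.0)
    known_by_mol: dict[str, list[int]] = {}
    for s in known:
        known_by_mol.setdefault(s.molecule_id, []).append(s.position)
    regions = merge_regions(called)
    true_regions = 0
    for r in regions:
        positions = known_by_mol.get(r.molecule_id, [])
        if any(r.start - tolerance <= p <= r.end + tolerance for p in positions):
            true_regions += 1
    false_regions = len(regions) - true_regions
    if not regions:
        logger.warning("empty called set: precision undefined")
    recall_known = [s for s in known if not (detectable_only and s.detectable is False)]
    detected = 0
    for s in recall_known:
        if recall_window == 0:
            hit = (s.molecule_id, s.position) in called
        else:
            hit = any(
                (s.molecule_id, s.position + d) in called
                for d in range(-recall_window, recall_window + 1)
            )
        detected += hit
    return PRPoint(
        thresholds=thresholds, true_regions=true_regions,
        false_regions=false_regions, known_detected=detected,
        known_total=len(recall_known),
    )


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

class _GridEvaluator:
    """Vectorized per-combination precision/recall over a fixed site table."""

    def __init__(self, sites: Sequence[SiteRecord], known: Sequence[KnownSite],
                 tolerance: int, detectable_only: bool) -> None:
        order = sorted(range(len(sites)),
                       key=lambda i: (sites[i].molecule_id, sites[i].position))
        self.mol = np.array([sites[i].molecule_id for i in order])
        self.pos = np.array([sites[i].position for i in order], dtype=np.int64)
        self.et = np.array([sites[i].esb_test for i in order])
        self.ec = np.array([sites[i].esb_control for i in order])
        self.orr = np.array([sites[i].odds_ratio for i in order])
        self.pa = np.array([sites[i].p_adj for i in order])
        mol_codes, _ = pd.factorize(self.mol)
        self.mol_codes = mol_codes

        known_by_mol: dict[str, np.ndarray] = {}
        for s in known:
            known_by_mol.setdefault(s.molecule_id, [])  # type: ignore[arg-type]
        for s in known:
            known_by_mol[s.molecule_id].append(s.position)  # type: ignore[attr-defined]
        known_by_mol = {m: np.array(sorted(p)) for m, p in known_by_mol.items()}

        # distance from each site row to the nearest known site on its molecule
        near = np.zeros(len(sites), dtype=bool)
        for m, kpos in known_by_mol.items():
            idx = np.flatnonzero(self.mol == m)
            if idx.size == 0:
                continue
            j = np.searchsorted(kpos, self.pos[idx])
            dist = np.full(idx.size, np.iinfo(np.int64).max, dtype=np.int64)
            left = j > 0
            dist[left] = np.abs(self.pos[idx[left]] - kpos[j[left] - 1])
            right = j < kpos.size
            dist[right] = np.minimum(
                dist[right], np.abs(kpos[j[right]] - self.pos[idx[right]])
            )
            near[idx] = dist <= tolerance
        self.near_known = near

        recall_known = [
            s for s in known if not (detectable_only and s.detectable is False)
        ]
        self.known_total = len(recall_known)
        index = {(s.molecule_id, s.position): k for k, s in enumerate(recall_known)}
        self.known_idx = np.array(
            [index.get((m, p), -1) for m, p in zip(self.mol, self.pos)],
            dtype=np.int64,
        )

    def evaluate(self, t: ThresholdSet) -> PRPoint:
        mask = (
            (self.et >= t.esb_test_min) & (self.ec <= t.esb_control_max)
            & (self.orr >= t.oddr_min) & (self.pa <= t.padj_max)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return PRPoint(t, 0, 0, 0, self.known_total)
        breaks = np.flatnonzero(
            (self.mol_codes[idx[1:]] != self.mol_codes[idx[:-1]])
            | (self.pos[idx[1:]] != self.pos[idx[:-1]] + 1)
        )
        starts = np.concatenate(([0], breaks + 1))
        n_regions = starts.size
        region_true = np.bitwise_or.reduceat(self.near_known[idx], starts)
        true_regions = int(region_true.sum())
        hits = self.known_idx[idx]
        detected = int(np.unique(hits[hits >= 0]).size)
        return PRPoint(
            t, true_regions, n_regions - true_regions, detected, self.known_total
        )


def _pr_key(p: PRPoint) -> tuple[float, float]:
    return (p.recall, p.precision)


def grid_search(sites: Sequence[SiteRecord], known: Sequence[KnownSite],
                grid: GridSpec | None = None, precision_floor: float = 0.85,
                tolerance: int = 10, detectable_only: bool = False
                ) -> tuple[ThresholdSet | None, list[PRPoint]]:
    """Exhaustive search for the highest-recall cutoffs at a precision floor.

    Every combination in the grid's Cartesian product is evaluated with
    region-tolerant precision and exact-site recall.  The best combination
    maximizes recall subject to precision >= ``precision_floor``; among
    recall ties the highest-precision, most restrictive combination is the
    starting point, after which each parameter is independently relaxed to
    its least restrictive value that leaves precision and recall unchanged,
    in the fixed order padj, ESB control, OddR, ESB test.

    Returns the best set (None when no combination reaches the floor, with a
    warning) and the full landscape for plotting/export.
    """
    if grid is None:
        grid = GridSpec()
    ev = _GridEvaluator(sites, known, tolerance, detectable_only)
    landscape: list[PRPoint] = []
    for a in grid.esb_test_values:
        for b in grid.esb_control_values:
            for c in grid.oddr_values:
                for d in grid.padj_values:
                    landscape.append(ev.evaluate(ThresholdSet(a, b, c, d)))
    feasible = [
        p for p in landscape
        if not math.isnan(p.precision) and p.precision >= precision_floor
    ]
    if not feasible:
        logger.warning(
            "no threshold combination reaches precision >= %.2f", precision_floor
        )
        return None, landscape
    best_recall = max(p.recall for p in feasible)
    tied = [p for p in feasible if p.recall == best_recall]
    best_precision = max(p.precision for p in tied)
    tied = [p for p in tied if p.precision == best_precision]
    # deterministic, most restrictive starting point
    start = max(
        tied,
        key=lambda p: (
            p.thresholds.esb_test_min, p.thresholds.oddr_min,
            -p.thresholds.esb_control_max, -p.thresholds.padj_max,
        ),
    )
    current = start
    # relax each parameter to its least restrictive equal-performance value
    relax_plan = [
        ("padj_max", sorted(grid.padj_values, reverse=True)),          # larger = looser
        ("esb_control_max", sorted(grid.esb_control_values, reverse=True)),
        ("oddr_min", sorted(grid.oddr_values)),                        # smaller = looser
        ("esb_test_min", sorted(grid.esb_test_values)),
    ]
    for param, candidates in relax_plan:
        for value in candidates:
            trial_t = replace(current.thresholds, **{param: value})
            trial = ev.evaluate(trial_t)
            if trial.precision == current.precision and trial.recall == current.recall:
                current = trial
                break
    return current.thresholds, landscape


def landscape_frame(landscape: Iterable[PRPoint]) -> pd.DataFrame:
    """One row per evaluated threshold combination (TSV-ready)."""
    rows = list(landscape)
    return pd.DataFrame(
        {
            "esb_test_min": [p.thresholds.esb_test_min for p in rows],
            "esb_control_max": [p.thresholds.esb_control_max for p in rows],
            "oddr_min": [p.thresholds.oddr_min for p in rows],
            "padj_max": [p.thresholds.padj_max for p in rows],
            "true_regions": [p.true_regions for p in rows],
            "false_regions": [p.false_regions for p in rows],
            "known_detected": [p.known_detected for p in rows],
            "known_total": [p.known_total for p in rows],
            "precision": [p.precision for p in rows],
            "recall": [p.recall for p in rows],
        }
    )


# ---------------------------------------------------------------------------
# detection summary
# ---------------------------------------------------------------------------

def detection_summary(outcomes: Sequence[DetectionOutcome]) -> dict:
    """Per-category counts/percentages plus recall under several denominators.

    Recall counts exact and offset detections together (an offset signal still
    reveals the modification).  Percentages are rounded half-up to one
    decimal; a truncated variant and the raw fraction are reported alongside
    so printed-value conventions are auditable.
    """
    if not outcomes:
        raise ValueError("outcomes must be nonempty")
    counts = {c: 0 for c in DETECTION_CATEGORIES}
    for o in outcomes:
        counts[o.category] += 1
    total = len(outcomes)
    categories = pd.DataFrame(
        {
            "category": list(DETECTION_CATEGORIES),
            "count": [counts[c] for c in DETECTION_CATEGORIES],
            "percent": [percent_half_up(counts[c], total) for c in DETECTION_CATEGORIES],
            "percent_truncated": [
                percent_truncated(counts[c], total) for c in DETECTION_CATEGORIES
            ],
        }
    )
    detected = counts["detected"] + counts["detected_with_offset"]

    def recall_entry(numerator: int, denominator: int) -> dict:
        return {
            "detected": numerator,
            "total": denominator,
            "fraction": numerator / denominator if denominator else math.nan,
            "percent": percent_half_up(numerator, denominator),
            "percent_truncated": percent_truncated(numerator, denominator),
        }

    n_detectable = total - counts["type_not_detectable"]
    n_covered = total - counts["depth_insufficient"]
    n_both = total - counts["type_not_detectable"] - counts["depth_insufficient"]
    return {
        "categories": categories,
        "recall": {
            "overall": recall_entry(detected, total),
            "detectable": recall_entry(detected, n_detectable),
            "covered": recall_entry(detected, n_covered),
            "detectable_and_covered": recall_entry(detected, n_both),
        },
    }


def outcomes_frame(outcomes: Sequence[DetectionOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule": [o.known_site.molecule_id for o in outcomes],
            "position": [o.known_site.position for o in outcomes],
            "symbol": [o.known_site.mod_symbol for o in outcomes],
            "category": [o.category for o in outcomes],
            "offset_nt": [o.offset_nt if o.offset_nt is not None else "" for o in outcomes],
        }
    )
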