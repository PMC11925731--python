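"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plainly as possible (explicit loops, no numpy,
no reuse of package internals) so it can disagree with the real
implementations when they are wrong.
"""

from __future__ import annotations

import math
from itertools import product


def naive_merge(called):
    """Maximal runs of consecutive positions per molecule, as (mol, lo, hi)."""
    regions = []
    by_mol = {}
    for mol, pos in called:
        by_mol.setdefault(mol, set()).add(pos)
    for mol in sorted(by_mol):
        for pos in sorted(by_mol[mol]):
            if (mol, pos - 1) in called:
                continue  # not a run start
            hi = pos
            while (mol, hi + 1) in called:
                hi += 1
            regions.append((mol, pos, hi))
    return regions


def naive_precision_recall(called, known, tolerance=10):
    """(true_regions, false_regions, detected, total) by direct enumeration."""
    regions = naive_merge(called)
    true_regions = 0
    for mol, lo, hi in regions:
        is_true = False
        for k in known:
            if k.molecule_id == mol and lo - tolerance <= k.position <= hi + tolerance:
                is_true = True
        true_regions += is_true
    detected = 0
    for k in known:
        if (k.molecule_id, k.position) in called:
            detected += 1
    return true_regions, len(regions) - true_regions, detected, len(known)


def naive_classify(called, known, depth_by_molecule, min_depth=20, offset_window=10):
    """Five-way category per known site, checked position by position."""
    out = []
    for site in known:
        if site.detectable is False:
            out.append((site, "type_not_detectable", None))
            continue
        if depth_by_molecule[site.molecule_id] < min_depth:
            out.append((site, "depth_insufficient", None))
            continue
        if (site.molecule_id, site.position) in called:
            out.append((site, "detected", None))
            continue
        hit = None
        for d in range(1, offset_window + 1):
            if (site.molecule_id, site.position - d) in called:
                hit = -d  # upstream preferred on distance ties
                break
            if (site.molecule_id, site.position + d) in called:
                hit = d
                break
        if hit is not None:
            out.append((site, "detected_with_offset", hit))
        else:
            out.append((site, "not_detected", None))
    return out


def naive_apply(sites, t):
    out = set()
    for s in sites:
        if (s.esb_test >= t.esb_test_min and s.esb_control <= t.esb_control_max
                and s.odds_ratio >= t.oddr_min and s.p_adj <= t.padj_max):
            out.add((s.molecule_id, s.position))
    return out


def naive_grid_search(sites, known, grid, precision_floor=0.85, tolerance=10):
    """Exhaustive enumeration with the stated tie-break, all in plain loops.

    Returns (best ThresholdSet as a 4-tuple or None, {combo: (P, R)}).
    """
    results = {}
    for combo in product(grid.esb_test_values, grid.esb_control_values,
                         grid.oddr_values, grid.padj_values):
        from modcal.benchmark import ThresholdSet  # data container only

        t = ThresholdSet(*combo)
        tr, fr, det, tot = naive_precision_recall(
            naive_apply(sites, t), known, tolerance
        )
        precision = tr / (tr + fr) if (tr + fr) > 0 else math.nan
        recall = det / tot if tot > 0 else 0.0
        results[combo] = (precision, recall)
    feasible = {c: pr for c, pr in results.items()
                if not math.isnan(pr[0]) and pr[0] >= precision_floor}
    if not feasible:
        return None, results
    best_recall = max(r for _, r in feasible.values())
    tied = {c: pr for c, pr in feasible.items() if pr[1] == best_recall}
    best_precision = max(p for p, _ in tied.values())
    tied = {c: pr for c, pr in tied.items() if pr[0] == best_precision}
    # most restrictive start: max esb_test, max oddr, min esb_control, min padj
    start = max(tied, key=lambda c: (c[0], c[2], -c[1], -c[3]))
    current = list(start)
    plan = [
        (3, sorted(grid.padj_values, reverse=True)),
        (1, sorted(grid.esb_control_values, reverse=True)),
        (2, sorted(grid.oddr_values)),
        (0, sorted(grid.esb_test_values)),
    ]
    for axis, candidates in plan:
        for value in candidates:
            trial = list(current)
            trial[axis] = value
            if results[tuple(trial)] == results[tuple(current)]:
                current = trial
                break
    return tuple(current), results
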