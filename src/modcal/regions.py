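"""Signal-region merging, biotype annotation and metagene positions.

A "signal region" is a maximal run of adjacent nucleotides on one molecule
that were all called modified; nanopore modification signals smear over
neighbouring positions, so one region is treated as one modification signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import groupby
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

from .io_formats import GeneModel
from .utils import percent_half_up

REGION_BIOTYPES = ("tRNA", "rRNA", "CDS", "UTR5", "UTR3", "ncRNA", "intergenic")
#: fixed precedence used when a region's midpoint is covered by several features
BIOTYPE_PRECEDENCE = ("tRNA", "rRNA", "CDS", "UTR5", "UTR3", "ncRNA")

#: metagene band offsets: UTR5 -> [0,1], CDS -> [1,2], UTR3 -> [2,3]
SEGMENT_BANDS = {"UTR5": 0.0, "CDS": 1.0, "UTR3": 2.0}


@dataclass
class SignalRegion:
    molecule_id: str
    start: int
    end: int
    n_sites: int
    mean_esb_test: float = math.nan
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.n_sites != self.end - self.start + 1:
            raise ValueError("n_sites must equal end - start + 1")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class MetagenePoint:
    point_id: str
    segment: str
    normalized_pos: float
    ref_base: str | None = None


def merge_regions(called: Iterable[tuple[str, int]],
                  esb_by_site: Mapping[tuple[str, int], float] | None = None
                  ) -> list[SignalRegion]:
    """Merge called (molecule, position) pairs into maximal adjacent runs.

    Output is deterministic: regions sorted by (molecule, start).  When
    ``esb_by_site`` is given, each region carries the mean ESB-test of its
    member positions.
    """
    out: list[SignalRegion] = []
    ordered = sorted(set(called))
    for mol, group in groupby(ordered, key=lambda x: x[0]):
        positions = [p for _, p in group]
        run_start = positions[0]
        prev = positions[0]
        for p in positions[1:] + [None]:  # type: ignore[list-item]
            if p is not None and p == prev + 1:
                prev = p
                continue
            region = SignalRegion(
                molecule_id=mol, start=run_start, end=prev,
                n_sites=prev - run_start + 1,
            )
            if esb_by_site is not None:
                vals = [esb_by_site[(mol, q)] for q in range(run_start, prev + 1)
                        if (mol, q) in esb_by_site]
                region.mean_esb_test = sum(vals) / len(vals) if vals else math.nan
            out.append(region)
            if p is not None:
                run_start = prev = p
    return out


def _midpoint_biotypes(molecule_id: str, midpoint: float,
                       models: Sequence[GeneModel]) -> set[str]:
    found: set[str] = set()
    for m in models:
        if m.molecule_id != molecule_id:
            continue
        if m.biotype in ("tRNA", "rRNA"):
            if m.cds_start <= midpoint <= m.cds_end:
                found.add(m.biotype)
        elif m.biotype == "mRNA":
            if m.cds_start <= midpoint <= m.cds_end:
                found.add("CDS")
            if m.utr5_start is not None and m.utr5_start <= midpoint <= m.utr5_end:
                found.add("UTR5")
            if m.utr3_start is not None and m.utr3_start <= midpoint <= m.utr3_end:
                found.add("UTR3")
        else:  # ncRNA, tmRNA, pseudogene -> non-coding bucket
            if m.cds_start <= midpoint <= m.cds_end:
                found.add("ncRNA")
    return found


def classify_biotype(region: SignalRegion, models: Sequence[GeneModel]) -> SignalRegion:
    """Assign the region's biotype from its midpoint, with fixed precedence.

    A region covered by no annotated feature is intergenic.  Straddling
    regions are resolved by the midpoint; overlapping features by the
    precedence tRNA > rRNA > CDS > UTR5 > UTR3 > ncRNA.
    """
    found = _midpoint_biotypes(region.molecule_id, region.midpoint, models)
    biotype = next((b for b in BIOTYPE_PRECEDENCE if b in found), "intergenic")
    return replace(region, biotype=biotype)


def annotate_regions(regions: Iterable[SignalRegion],
                     models: Sequence[GeneModel]) -> list[SignalRegion]:
    return [classify_biotype(r, models) for r in regions]


def biotype_proportions(regions: Iterable[SignalRegion],
                        include: Iterable[str] | None = None,
                        count_sites: bool = False) -> pd.DataFrame:
    """Counts and one-decimal percentages of regions (or sites) per biotype.

    ``include`` restricts both the rows and the percentage denominator; by
    default every biotype present is included.  ``count_sites`` counts member
    positions instead of regions.
    """
    regions = list(regions)
    if any(r.biotype is None for r in regions):
        raise ValueError("all regions must be annotated with a biotype")
    counts: dict[str, int] = {}
    for r in regions:
        counts[r.biotype] = counts.get(r.biotype, 0) + (r.n_sites if count_sites else 1)
    if include is not None:
        include = set(include)
        if not include:
            raise ValueError("include must be nonempty")
        counts = {b: c for b, c in counts.items() if b in include}
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "biotype": [b for b, _ in rows],
            "count": [c for _, c in rows],
            "percent": [percent_half_up(c, total) for _, c in rows],
        }
    )


def _segment_interval(model: GeneModel, segment: str) -> tuple[int, int]:
    if segment == "CDS":
        return model.cds_start, model.cds_end
    if segment == "UTR5":
        if model.utr5_start is None:
            raise ValueError(f"gene {model.gene_id} has no 5' UTR")
        return model.utr5_start, model.utr5_end
    if segment == "UTR3":
        if model.utr3_start is None:
            raise ValueError(f"gene {model.gene_id} has no 3' UTR")
        return model.utr3_start, model.utr3_end
    raise ValueError(f"no metagene segment {segment!r}")


def normalized_position(position: float, model: GeneModel, segment: str) -> float:
    """Map a position to the [0, 3] metagene scale, strand-aware.

    Within a segment the position is the fractional distance from the first
    to the last nucleotide in transcript (5'->3') orientation, so 0 is always
    the transcript 5' end.  Single-nucleotide segments cannot be normalized.
    """
    s, e = _segment_interval(model, segment)
    if e == s:
        raise ValueError(
            f"gene {model.gene_id}: zero-length {segment} segment cannot be normalized"
        )
    if model.strand == "+":
        rel = (position - s) / (e - s)
    else:
        rel = (e - position) / (e - s)
    return SEGMENT_BANDS[segment] + rel


def metagene_positions(regions: Iterable[SignalRegion], models: Sequence[GeneModel],
                       per_position: bool = False,
                       ref_base_by_site: Mapping[tuple[str, int], str] | None = None,
                       ) -> list[MetagenePoint]:
    """Normalized metagene locations for regions in UTR5/CDS/UTR3.

    One point per region midpoint by default; with ``per_position`` one point
    per member nucleotide (each re-classified by its own location), carrying
    the reference base when a lookup is supplied.
    """
    models_by_mol: dict[str, list[GeneModel]] = {}
    for m in models:
        models_by_mol.setdefault(m.molecule_id, []).append(m)
    out: list[MetagenePoint] = []
    for region in regions:
        if region.biotype not in SEGMENT_BANDS:
            raise ValueError(
                f"region {region.molecule_id}:{region.start}-{region.end} has "
                f"biotype {region.biotype!r}; metagene needs UTR5/CDS/UTR3"
            )
        candidates = models_by_mol.get(region.molecule_id, [])
        points = (
            range(region.start, region.end + 1) if per_position else [region.midpoint]
        )
        for pos in points:
            segment = region.biotype
            host = None
            for m in candidates:
                if m.biotype != "mRNA":
                    continue
                try:
                    s, e = _segment_interval(m, segment)
                except ValueError:
                    continue
                if s <= pos <= e:
                    host = m
                    break
            if host is None:
                # per-position points near region edges may spill out of the
                # midpoint's segment; re-classify by own location
                found = _midpoint_biotypes(region.molecule_id, pos, candidates)
                segment = next((b for b in ("CDS", "UTR5", "UTR3") if b in found), None)
                if segment is None:
                    continue
                for m in candidates:
                    s, e = _segment_interval(m, segment)
                    if s <= pos <= e:
                        host = m
                        break
            if host is None:
                continue
            base = None
            if ref_base_by_site is not None and isinstance(pos, int):
                base = ref_base_by_site.get((region.molecule_id, pos))
            out.append(
                MetagenePoint(
                    point_id=f"{region.molecule_id}:{pos}",
                    segment=segment,
                    normalized_pos=normalized_position(pos, host, segment),
                    ref_base=base,
                )
            )
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_regions_bed(regions: Iterable[SignalRegion], path: str | Path) -> None:
    """Export regions as BED6 (0-based half-open; name=biotype, score=n_sites)."""
    rows = sorted(regions, key=lambda r: (r.molecule_id, r.start))
    with open(path, "w") as fh:
        for r in rows:
            name = r.biotype if r.biotype is not None else "."
            fh.write(f"{r.molecule_id}\t{r.start - 1}\t{r.end}\t{name}\t{r.n_sites}\t+\n")


def write_metagene_table(points: Iterable[MetagenePoint], path: str | Path) -> None:
    rows = sorted(points, key=lambda p: (p.segment, p.normalized_pos, p.point_id))
    pd.DataFrame(
        {
            "point_id": [p.point_id for p in rows],
            "segment": [p.segment for p in rows],
            "normalized_pos": [p.normalized_pos for p in rows],
            "ref_base": [p.ref_base if p.ref_base is not None else "." for p in rows],
        }
    ).to_csv(path, sep="\t", index=False)
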