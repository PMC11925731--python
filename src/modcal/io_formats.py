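"""Readers, writers and domain records for every table the pipeline touches.

All tables are tab-separated text with a header line.  Internal coordinates
are 1-based inclusive on the molecule (the convention of the MODOMICS
catalogue); BED input/output is converted from/to 0-based half-open.  ESB
values ("error of specific bases") are stored as fractions in [0, 1];
dialects declare whether a source table is on the percent scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGU")
GENE_BIOTYPES = frozenset({"tRNA", "rRNA", "ncRNA", "mRNA", "tmRNA", "pseudogene"})

#: MODOMICS-style single-character symbols -> (modification name, detectable by
#: error-based calling).  Thiolated/minor types that leave basecalling errors
#: essentially unchanged are flagged not detectable.
MOD_SYMBOLS: dict[str, tuple[str, bool]] = {
    "D": ("D", True),            # dihydrouridine
    "*": ("ms2i6A", True),
    "ʤ": ("s2C", False),    # ʤ 2-thiocytidine
    "/": ("m2A", True),
    "4": ("s4U", False),         # 4-thiouridine
    "V": ("cmo5U", True),
    "M": ("ac4C", True),
    ")": ("cmnm5Um", True),
    "$": ("cmnm5s2U", True),
    "S": ("mnm5s2U", True),
    "{": ("mnm5U", False),       # 5-methylaminomethyluridine
    "}": ("k2C", False),         # lysidine
    "+": ("i6A", False),         # N6-isopentenyladenosine
    "K": ("m1G", True),
    "6": ("t6A", True),
    "P": ("Y", True),            # pseudouridine
    "T": ("m5U", True),
    "L": ("m2G", True),
    "Ƒ": ("m3Y", True),     # Ƒ 3-methylpseudouridine
    "?": ("m5C", False),         # 5-methylcytidine
    "E": ("m6t6A", False),
    "Ж": ("m6A", True),     # Ж N6-methyladenosine
    "7": ("m7G", True),
    "J": ("Um", True),
    "#": ("Gm", True),
    "B": ("Cm", True),
    "Ç": ("ho5C", True),    # Ç 5-hydroxycytidine
    "ɿ": ("m2A", True),     # ɿ
    "λ": ("m4Cm", False),   # λ N4,2'-O-dimethylcytidine
    "δ": ("m3U", True),     # δ 3-methyluridine
    "ζ": ("m66A", True),    # ζ N6,N6-dimethyladenosine
    "⊄": ("gluQ", True),    # ⊄ glutamyl-queuosine
    "Q": ("Q", True),
    "X": ("acp3U", True),
}

#: Reverse lookup: modification name -> symbol.
SYMBOL_BY_NAME: dict[str, str] = {name: sym for sym, (name, _) in MOD_SYMBOLS.items()}


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteRecord:
    """One molecule/position row of an error-based caller's output."""

    molecule_id: str
    position: int
    ref_base: str
    esb_test: float
    esb_control: float
    odds_ratio: float
    p_adj: float
    depth: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_base not in VALID_BASES:
            raise ValueError(f"ref_base must be one of A/C/G/U, got {self.ref_base!r}")
        for name in ("esb_test", "esb_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.odds_ratio < 0:
            raise ValueError(f"odds_ratio must be >= 0, got {self.odds_ratio}")
        if not 0.0 <= self.p_adj <= 1.0:
            raise ValueError(f"p_adj must be in [0, 1], got {self.p_adj}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")


@dataclass(frozen=True)
class KnownSite:
    """A catalogued modification (MODOMICS-style entry).

    ``detectable`` is True/False when the symbol is in the built-in map and
    None when the symbol is unknown (kept with a warning).
    """

    molecule_id: str
    position: int
    mod_symbol: str
    detectable: bool | None = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.mod_symbol:
            raise ValueError("mod_symbol must be nonempty")

    @property
    def mod_name(self) -> str:
        entry = MOD_SYMBOLS.get(self.mod_symbol)
        return entry[0] if entry else self.mod_symbol


@dataclass(frozen=True)
class GeneModel:
    """A gene with CDS and optional UTR intervals, 1-based inclusive.

    For non-coding biotypes (tRNA, rRNA, ncRNA, ...) ``cds_start``/``cds_end``
    hold the span of the gene body.
    """

    gene_id: str
    molecule_id: str
    strand: str
    biotype: str
    cds_start: int
    cds_end: int
    utr5_start: int | None = None
    utr5_end: int | None = None
    utr3_start: int | None = None
    utr3_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in GENE_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.cds_start > self.cds_end:
            raise ValueError("cds_start must be <= cds_end")
        for prefix in ("utr5", "utr3"):
            s = getattr(self, f"{prefix}_start")
            e = getattr(self, f"{prefix}_end")
            if (s is None) != (e is None):
                raise ValueError(f"{prefix} interval must have both ends or neither")
            if s is not None:
                if s > e:
                    raise ValueError(f"{prefix}_start must be <= {prefix}_end")
                if not (e < self.cds_start or s > self.cds_end):
                    raise ValueError(f"{prefix} interval overlaps the CDS")


@dataclass(frozen=True)
class MsMeasurement:
    """One mass-spectrometry abundance value (per 1000 canonical nucleosides)."""

    mod_name: str
    condition: str
    abundance: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(f"abundance must be >= 0, got {self.abundance}")


@dataclass(frozen=True)
class CtMeasurement:
    """One SELECT qPCR threshold-cycle measurement."""

    assay_id: str
    sample_type: str
    ct_target: float
    ct_control_a: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.sample_type not in ("WT", "IVT", "Mut"):
            raise ValueError(f"sample_type must be WT/IVT/Mut, got {self.sample_type!r}")
        for name in ("ct_target", "ct_control_a"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite, got {v}")


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

#: dialect -> (column map {internal field: source column}, esb scale divisor)
SITE_DIALECTS: dict[str, tuple[dict[str, str], float]] = {
    "modcal": (
        {
            "molecule_id": "molecule",
            "position": "position",
            "ref_base": "ref_base",
            "esb_test": "esb_test",
            "esb_control": "esb_control",
            "odds_ratio": "odds_ratio",
            "p_adj": "p_adj",
            "depth": "depth",
        },
        1.0,
    ),
    # best-effort mapping of ELIGOS-style output; ESB columns on the 0-1 scale
    "eligos": (
        {
            "molecule_id": "chrom",
            "position": "end_loc",
            "ref_base": "ref",
            "esb_test": "ESB_test",
            "esb_control": "ESB_ctrl",
            "odds_ratio": "oddR",
            "p_adj": "adjPval",
            "depth": "total_reads",
        },
        1.0,
    ),
    # same layout with %ESB columns printed on the percent scale
    "eligos_percent": (
        {
            "molecule_id": "chrom",
            "position": "end_loc",
            "ref_base": "ref",
            "esb_test": "pct_ESB_test",
            "esb_control": "pct_ESB_ctrl",
            "odds_ratio": "oddR",
            "p_adj": "adjPval",
            "depth": "total_reads",
        },
        100.0,
    ),
}


def read_site_table(path: str | Path, dialect: str = "modcal") -> list[SiteRecord]:
    """Read a per-site caller output table into validated :class:`SiteRecord`s.

    Percent-scaled ESB columns are converted to fractions.  Rows violating an
    invariant or missing a mandatory field raise with the offending 1-based
    data row number; duplicate (molecule, position) rows are an error because
    inputs are assumed pre-deduplicated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in SITE_DIALECTS:
        raise ValueError(f"unknown site-table dialect {dialect!r}")
    colmap, divisor = SITE_DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns for dialect {dialect!r}: {missing}")
    records: list[SiteRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        try:
            vals = {f: raw[c] for f, c in colmap.items()}
            if any(pd.isna(v) for v in vals.values()):
                raise ValueError("missing mandatory field")
            rec = SiteRecord(
                molecule_id=str(vals["molecule_id"]),
                position=int(vals["position"]),
                ref_base=str(vals["ref_base"]),
                esb_test=float(vals["esb_test"]) / divisor,
                esb_control=float(vals["esb_control"]) / divisor,
                odds_ratio=float(vals["odds_ratio"]),
                p_adj=float(vals["p_adj"]),
                depth=int(vals["depth"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        key = (rec.molecule_id, rec.position)
        if key in seen:
            raise ValueError(f"{path}: row {i}: duplicate site {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_site_table(records: Iterable[SiteRecord], path: str | Path,
                     dialect: str = "modcal") -> None:
    """Write site records as TSV in deterministic (molecule, position) order."""
    if dialect not in SITE_DIALECTS:
        raise ValueError(f"unknown site-table dialect {dialect!r}")
    colmap, divisor = SITE_DIALECTS[dialect]
    rows = sorted(records, key=lambda r: (r.molecule_id, r.position))
    df = pd.DataFrame(
        {
            col: [
                getattr(r, f) * divisor if f in ("esb_test", "esb_control")
                else getattr(r, f)
                for r in rows
            ]
            for f, col in colmap.items()
        }
    )
    df.to_csv(path, sep="\t", index=False)


def sites_to_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    """Columnar view of a site collection (fraction scale)."""
    return pd.DataFrame(
        {f.name: [getattr(r, f.name) for r in records] for f in fields(SiteRecord)}
    )


# ---------------------------------------------------------------------------
# known-modification catalogue
# ---------------------------------------------------------------------------

def read_known_sites(path: str | Path) -> list[KnownSite]:
    """Read a known-modification catalogue (molecule, position, symbol).

    Detectability is populated from the built-in symbol map; unknown symbols
    are kept with ``detectable=None`` and a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        logger.warning("%s: empty known-site catalogue", path)
        return []
    required = {"molecule", "position", "symbol"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out: list[KnownSite] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        sym = str(raw["symbol"])
        entry = MOD_SYMBOLS.get(sym)
        if entry is None:
            logger.warning("%s: row %d: unknown modification symbol %r", path, i, sym)
            detectable: bool | None = None
        else:
            detectable = entry[1]
        try:
            out.append(
                KnownSite(
                    molecule_id=str(raw["molecule"]),
                    position=int(raw["position"]),
                    mod_symbol=sym,
                    detectable=detectable,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return out


def write_known_sites(sites: Iterable[KnownSite], path: str | Path) -> None:
    rows = sorted(sites, key=lambda s: (s.molecule_id, s.position))
    pd.DataFrame(
        {
            "molecule": [s.molecule_id for s in rows],
            "position": [s.position for s in rows],
            "symbol": [s.mod_symbol for s in rows],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models: GFF3 + UTR BED
# ---------------------------------------------------------------------------

def read_gene_models(gff_path: str | Path, utr_bed_path: str | Path | None = None
                     ) -> list[GeneModel]:
    """Read gene models from GFF3 plus UTR coordinates from a BED6 file.

    GFF3 is 1-based inclusive; BED is 0-based half-open and is converted on
    the way in.  The BED name column carries the gene ID; laterality (5' vs
    3') is inferred from the interval's position relative to the CDS and the
    gene strand.  UTRs referencing unknown genes are skipped with a warning.
    """
    gff_path = Path(gff_path)
    if not gff_path.exists():
        raise FileNotFoundError(gff_path)
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        biotype = gene.attributes.get("gene_biotype", ["mRNA"])[0]
        cds = list(db.children(gene, featuretype="CDS"))
        if cds:
            cds_start = min(c.start for c in cds)
            cds_end = max(c.end for c in cds)
        else:
            cds_start, cds_end = gene.start, gene.end
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            molecule_id=gene.seqid,
            strand=gene.strand,
            biotype=biotype,
            cds_start=cds_start,
            cds_end=cds_end,
        )
    if utr_bed_path is not None:
        utr_bed_path = Path(utr_bed_path)
        if not utr_bed_path.exists():
            raise FileNotFoundError(utr_bed_path)
        bed = pd.read_csv(
            utr_bed_path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
        for i, row in bed.iterrows():
            gene_id = str(row["name"])
            model = models.get(gene_id)
            if model is None:
                logger.warning(
                    "%s: row %d: UTR references unknown gene %r; skipped",
                    utr_bed_path, i + 1, gene_id,
                )
                continue
            start1 = int(row["start"]) + 1  # BED -> 1-based inclusive
            end1 = int(row["end"])
            upstream = end1 < model.cds_start
            is_utr5 = upstream if model.strand == "+" else not upstream
            if is_utr5:
                model = replace(model, utr5_start=start1, utr5_end=end1)
            else:
                model = replace(model, utr3_start=start1, utr3_end=end1)
            models[gene_id] = model
    return sorted(models.values(), key=lambda m: (m.molecule_id, m.cds_start))


def write_gene_models(models: Iterable[GeneModel], gff_path: str | Path,
                      utr_bed_path: str | Path) -> None:
    """Write gene models as GFF3 plus a BED6 file of UTR intervals."""
    rows = sorted(models, key=lambda m: (m.molecule_id, m.cds_start))
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for m in rows:
            span_start = min(
                v for v in (m.cds_start, m.utr5_start, m.utr3_start) if v is not None
            )
            span_end = max(
                v for v in (m.cds_end, m.utr5_end, m.utr3_end) if v is not None
            )
            gff.write(
                f"{m.molecule_id}\tmodcal\tgene\t{span_start}\t{span_end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id};gene_biotype={m.biotype}\n"
            )
            if m.biotype == "mRNA":
                gff.write(
                    f"{m.molecule_id}\tmodcal\tCDS\t{m.cds_start}\t{m.cds_end}\t.\t"
                    f"{m.strand}\t.\tID={m.gene_id}.cds;Parent={m.gene_id}\n"
                )
    with open(utr_bed_path, "w") as bed:
        for m in rows:
            for s, e in ((m.utr5_start, m.utr5_end), (m.utr3_start, m.utr3_end)):
                if s is not None:
                    bed.write(
                        f"{m.molecule_id}\t{s - 1}\t{e}\t{m.gene_id}\t.\t{m.strand}\n"
                    )


# ---------------------------------------------------------------------------
# assay tables (MS and SELECT CT)
# ---------------------------------------------------------------------------

def read_assay_tables(ms_path: str | Path, ct_path: str | Path
                      ) -> tuple[list[MsMeasurement], list[CtMeasurement]]:
    """Read the MS abundance table and the SELECT CT table."""
    ms_path, ct_path = Path(ms_path), Path(ct_path)
    for p in (ms_path, ct_path):
        if not p.exists():
            raise FileNotFoundError(p)
    ms_df = pd.read_csv(ms_path, sep="\t")
    ms: list[MsMeasurement] = []
    for i, row in enumerate(ms_df.itertuples(index=False), start=1):
        raw = dict(zip(ms_df.columns, row))
        try:
            if any(pd.isna(v) for v in raw.values()):
                raise ValueError("missing mandatory field")
            ms.append(
                MsMeasurement(
                    mod_name=str(raw["mod_name"]),
                    condition=str(raw["condition"]),
                    abundance=float(raw["abundance"]),
                    replicate=int(raw.get("replicate", 1)),
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"{ms_path}: row {i}: {exc}") from exc
    ct_df = pd.read_csv(ct_path, sep="\t")
    ct: list[CtMeasurement] = []
    for i, row in enumerate(ct_df.itertuples(index=False), start=1):
        raw = dict(zip(ct_df.columns, row))
        try:
            if any(pd.isna(v) for v in raw.values()):
                raise ValueError("missing mandatory field")
            ct.append(
                CtMeasurement(
                    assay_id=str(raw["assay_id"]),
                    sample_type=str(raw["sample_type"]),
                    ct_target=float(raw["ct_target"]),
                    ct_control_a=float(raw["ct_control_a"]),
                    replicate=int(raw.get("replicate", 1)),
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"{ct_path}: row {i}: {exc}") from exc
    return ms, ct


def write_assay_tables(ms: Iterable[MsMeasurement], ct: Iterable[CtMeasurement],
                       ms_path: str | Path, ct_path: str | Path) -> None:
    ms_rows = sorted(ms, key=lambda m: (m.mod_name, m.condition, m.replicate))
    pd.DataFrame(
        {
            "mod_name": [m.mod_name for m in ms_rows],
            "condition": [m.condition for m in ms_rows],
            "abundance": [m.abundance for m in ms_rows],
            "replicate": [m.replicate for m in ms_rows],
        }
    ).to_csv(ms_path, sep="\t", index=False)
    ct_rows = sorted(ct, key=lambda c: (c.assay_id, c.sample_type, c.replicate))
    pd.DataFrame(
        {
            "assay_id": [c.assay_id for c in ct_rows],
            "sample_type": [c.sample_type for c in ct_rows],
            "ct_target": [c.ct_target for c in ct_rows],
            "ct_control_a": [c.ct_control_a for c in ct_rows],
            "replicate": [c.replicate for c in ct_rows],
        }
    ).to_csv(ct_path, sep="\t", index=False)
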