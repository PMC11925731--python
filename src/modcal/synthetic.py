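"""Ground-truthed synthetic inputs with the signal structure the analysis assumes.

The generator emulates per-site output of an error-based modification caller
on a bacterial transcriptome: elevated ESB at modified positions scaled by
stoichiometry, a signal smear decaying geometrically within +-10 nt of each
modification, systemic-noise decoy positions that appear in the native sample
but not at known sites, per-molecule read-depth heterogeneity including RNAs
below the 20-read floor, two-condition stoichiometry shifts mirrored in an MS
abundance table, and CT delays at modified SELECT targets.

The planted cutoff set is made identifiable by construction: a few known
sites hug each threshold from the inside ("sentinels", low-stoichiometry
signals just above the cutoffs) and decoy noise positions hug each threshold
from the outside, so that one grid step looser admits decoy false regions and
one step tighter loses sentinel recall.  This gives the precision/recall
landscape a well-defined optimum at the planted set, mirroring how real
calibration data pins thresholds at the signal/noise boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .benchmark import ThresholdSet
from .io_formats import (
    CtMeasurement,
    GeneModel,
    KnownSite,
    MOD_SYMBOLS,
    MsMeasurement,
    SiteRecord,
    write_assay_tables,
    write_gene_models,
    write_known_sites,
    write_site_table,
)

#: canonical tRNA modification positions and the symbol pool at each.  Types
#: invisible to error-based calling are planted only at positions isolated
#: from other modifications (s4U at position 8), so the benchmark's recall
#: reflects genuine on-site signals rather than neighbour bleed-through at
#: catalogued positions; detectable types keep their clustered placement.
TRNA_SITE_POOL: tuple[tuple[int, tuple[str, ...]], ...] = (
    (8, ("4",)),
    (16, ("D",)), (17, ("D",)), (18, ("#",)), (20, ("D",)),
    (32, ("B", "J")),
    (34, ("V", "Q", "S", "M", "$", ")")),
    (35, ("P",)),
    (37, ("6", "ɿ", "*", "K", "Ж")),
    (38, ("P",)), (39, ("P",)), (40, ("P",)),
    (46, ("7",)), (47, ("X",)), (54, ("T",)), (55, ("P",)),
)

#: rRNA modification symbol pool (weighted toward detectable types; includes
#: the m5C/m4Cm types invisible to error-based calling)
RRNA_SYMBOL_POOL: tuple[str, ...] = (
    "Ж", "ζ", "L", "T", "P", "7", "Ç", "#", "J", "B", "/", "Ƒ", "K",
    "?", "?", "?", "λ",
)

#: target base per modification name (for planted ref_base realism)
BASE_BY_NAME = {
    "m6A": "A", "m66A": "A", "m2A": "A", "t6A": "A", "i6A": "A", "ms2i6A": "A",
    "m6t6A": "A", "m1G": "G", "m2G": "G", "m7G": "G", "Gm": "G", "gluQ": "G",
    "Q": "G", "m5C": "C", "Cm": "C", "ac4C": "C", "s2C": "C", "ho5C": "C",
    "m4Cm": "C", "k2C": "C",
}

#: heat-stress abundance multipliers per modification type (condition b / a)
DEFAULT_TYPE_MULTIPLIERS = {
    "D": 0.95, "Gm": 1.12, "m7G": 1.00, "m5U": 1.02, "Y": 0.78, "Cm": 0.85,
    "Um": 0.72, "m1G": 1.00, "m2G": 1.05, "t6A": 0.98, "m66A": 1.18,
    "m6A": 1.12, "acp3U": 1.00, "m3U": 1.00, "cmo5U": 0.90, "Q": 0.95,
    "mnm5s2U": 0.88, "ms2i6A": 1.00, "m2A": 1.05, "ac4C": 0.92, "ho5C": 0.80,
    "m3Y": 1.00, "cmnm5Um": 0.90, "cmnm5s2U": 0.95, "m5C": 1.10,
}


def _default_mrna_sites() -> dict[str, int]:
    # proportions follow the biotype distribution typical of bacterial
    # transcriptome-wide calls (CDS-dominated)
    return {"CDS": 60, "UTR5": 12, "intergenic": 5, "UTR3": 3, "ncRNA": 2}


@dataclass
class SimConfig:
    """All tunables of the generator; defaults are the desk-scale profile."""

    seed: int = 0
    # molecules
    n_trna: int = 40
    trna_len: tuple[int, int] = (74, 90)
    rrna_lens: tuple[int, ...] = (1542, 2904)
    n_mrna: int = 120
    n_ncrna: int = 10
    utr5_len: tuple[int, int] = (20, 60)
    cds_len: tuple[int, int] = (210, 600)
    utr3_len: tuple[int, int] = (20, 80)
    pad_len: int = 30           # unannotated flank -> intergenic positions
    ncrna_len: tuple[int, int] = (80, 300)
    # planted sites
    sites_per_trna: tuple[int, int] = (4, 8)
    sites_per_rrna: int = 18
    n_mrna_sites: dict = field(default_factory=_default_mrna_sites)
    n_offset_sites: int = 2     # known sites whose signal is displaced
    offset_shift: int = -5
    n_unique_rna: int = 6       # molecules absent (under-covered) per condition
    n_unique_mod: int = 5       # CDS sites with zero stoichiometry in one condition
    # ESB signal model (fraction scale)
    esb_effect: float = 0.45    # mean ESB elevation at stoichiometry 1
    smear_width: int = 10
    smear_decay: float = 0.5    # per-nt geometric decay
    background_shape: float = 2.0
    background_scale: float = 0.002  # gamma background, mean ~0.004
    background_cap: float = 0.0199
    elevation_noise_sd: float = 0.08  # multiplicative, per site
    oddr_floor: float = 1e-3
    pval_gain: float = 15.0     # p_adj = exp(-gain * (esb diff) * sqrt(depth))
    # depth model
    depth_median: float = 120.0
    depth_sigma: float = 1.0
    rrna_depth: int = 800
    low_depth_fraction: float = 0.12  # tRNAs under the 20-read floor
    min_depth: int = 20
    # threshold identifiability
    planted_thresholds: ThresholdSet = field(
        default_factory=lambda: ThresholdSet(0.05, 0.02, 3.0, 0.05)
    )
    plant_sentinels: bool = True
    plant_decoys: bool = True
    # condition b
    type_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MULTIPLIERS)
    )
    cds_increase_fraction: float = 0.6
    condition_a: str = "37C"
    condition_b: str = "45C"
    # assays
    ms_noise_sd: float = 0.05
    ms_replicates: int = 3
    ms_scale: float = 2.0       # abundance per 1000 nucleosides at stoichiometry 1
    n_select_modified: int = 3
    n_select_unmodified: int = 7
    ct_effect: float = 2.5
    ct_noise_sd: float = 0.05
    ct_replicates: int = 3

    def __post_init__(self) -> None:
        if self.smear_width < 0:
            raise ValueError("smear_width must be >= 0")
        for name in ("smear_decay", "low_depth_fraction", "cds_increase_fraction",
                     "ms_noise_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(m <= 0 for m in self.type_multipliers.values()):
            raise ValueError("type multipliers must be > 0")

    @classmethod
    def small(cls, seed: int = 0) -> "SimConfig":
        """Reduced profile for Monte-Carlo loops (tRNA/rRNA + assays only)."""
        return cls(seed=seed, n_trna=24, n_mrna=0, n_ncrna=0,
                   rrna_lens=(1542,), sites_per_rrna=12)


@dataclass(frozen=True)
class PlantedSite:
    molecule_id: str
    position: int
    mod_symbol: str
    mod_name: str
    detectable: bool
    biotype: str
    stoich_a: float
    stoich_b: float
    offset: int = 0           # signal center displacement (0 = on-site)
    role: str = "standard"    # standard / sentinel_<param> / unique_a / unique_b
    in_catalogue: bool = False


@dataclass(frozen=True)
class DecoySite:
    """A systemic-noise position just outside one planted cutoff."""

    molecule_id: str
    position: int
    pinned: str               # which threshold excludes it
    esb_test: float
    esb_control: float
    odds_ratio: float | None  # None -> quotient rule
    p_adj: float


@dataclass
class GroundTruth:
    planted: list[PlantedSite]
    decoys: list[DecoySite]
    thresholds: ThresholdSet
    models: list[GeneModel]
    depth_a: dict[str, int]
    depth_b: dict[str, int]
    select_assays: list[tuple[str, bool, bool]]  # (assay_id, modified, has Mut)

    @property
    def known_sites(self) -> list[KnownSite]:
        return [
            KnownSite(p.molecule_id, p.position, p.mod_symbol,
                      detectable=p.detectable)
            for p in self.planted if p.in_catalogue
        ]

    @property
    def mod_name_by_site(self) -> dict[tuple[str, int], str]:
        return {(p.molecule_id, p.position): p.mod_name for p in self.planted}

    @property
    def biotype_by_site(self) -> dict[tuple[str, int], str]:
        return {(p.molecule_id, p.position): p.biotype for p in self.planted}


@dataclass
class SimResult:
    config: SimConfig
    truth: GroundTruth
    sites_a: list[SiteRecord]
    sites_b: list[SiteRecord]
    control: list[SiteRecord]
    ms: list[MsMeasurement]
    ct: list[CtMeasurement]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig, out_dir: str | Path | None = None
                        ) -> tuple[list[GeneModel], dict[str, int]]:
    """Gene models (one molecule per transcript unit) and molecule lengths.

    mRNA molecules carry 5'UTR/CDS/3'UTR plus unannotated flanks (intergenic
    positions); strand alternates, and on the minus strand the 5' UTR sits at
    the high-coordinate end.  tRNA/rRNA/ncRNA molecules are standalone
    transcripts spanned by their gene.  With ``out_dir`` the GFF3 and UTR BED
    files are written there.
    """
    rng = np.random.default_rng(config.seed)
    models: list[GeneModel] = []
    lengths: dict[str, int] = {}

    for i in range(config.n_trna):
        mol = f"trna{i + 1:03d}"
        length = int(rng.integers(config.trna_len[0], config.trna_len[1] + 1))
        lengths[mol] = length
        models.append(GeneModel(mol, mol, "+", "tRNA", 1, length))
    for i, length in enumerate(config.rrna_lens):
        mol = f"rrna{i + 1:02d}"
        if length < 200:
            raise ValueError(f"rRNA length {length} too short to host sites")
        lengths[mol] = int(length)
        models.append(GeneModel(mol, mol, "+", "rRNA", 1, int(length)))
    for i in range(config.n_ncrna):
        mol = f"ncrna{i + 1:03d}"
        length = int(rng.integers(config.ncrna_len[0], config.ncrna_len[1] + 1))
        lengths[mol] = length
        models.append(GeneModel(mol, mol, "+", "ncRNA", 1, length))
    for i in range(config.n_mrna):
        mol = f"gene{i + 1:03d}"
        u5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        cds = int(rng.integers(config.cds_len[0], config.cds_len[1] + 1))
        u3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        pad = config.pad_len
        length = pad + u5 + cds + u3 + pad
        lengths[mol] = length
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            utr5 = (pad + 1, pad + u5)
            cds_iv = (pad + u5 + 1, pad + u5 + cds)
            utr3 = (pad + u5 + cds + 1, pad + u5 + cds + u3)
        else:
            utr3 = (pad + 1, pad + u3)
            cds_iv = (pad + u3 + 1, pad + u3 + cds)
            utr5 = (pad + u3 + cds + 1, pad + u3 + cds + u5)
        models.append(
            GeneModel(mol, mol, strand, "mRNA", cds_iv[0], cds_iv[1],
                      utr5_start=utr5[0], utr5_end=utr5[1],
                      utr3_start=utr3[0], utr3_end=utr3[1])
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gene_models(models, out_dir / "annotation.gff3", out_dir / "utrs.bed")
    return models, lengths


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _spaced_positions(rng: np.random.Generator, lo: int, hi: int, n: int,
                      min_gap: int, taken: Sequence[int] = ()) -> list[int]:
    chosen: list[int] = []
    occupied = list(taken)
    for _ in range(4000):
        if len(chosen) == n:
            break
        p = int(rng.integers(lo, hi + 1))
        if all(abs(p - q) >= min_gap for q in occupied):
            chosen.append(p)
            occupied.append(p)
    if len(chosen) < n:
        raise ValueError("could not place spaced positions; molecule too short")
    return sorted(chosen)


def build_ground_truth(config: SimConfig) -> GroundTruth:
    """Plant sites, stoichiometries, sentinels, decoys and depths."""
    rng = np.random.default_rng(config.seed + 1)
    models, lengths = simulate_annotation(config)
    t = config.planted_thresholds
    planted: list[PlantedSite] = []
    decoys: list[DecoySite] = []

    def stoich() -> float:
        return float(rng.uniform(0.6, 1.0))

    def mult_for(name: str) -> float:
        return float(config.type_multipliers.get(name, 1.0))

    # --- tRNA known sites -------------------------------------------------
    trna_ids = [m.molecule_id for m in models if m.biotype == "tRNA"]
    for mol in trna_ids:
        k = int(rng.integers(config.sites_per_trna[0], config.sites_per_trna[1] + 1))
        rows = rng.choice(len(TRNA_SITE_POOL), size=min(k, len(TRNA_SITE_POOL)),
                          replace=False)
        for row in sorted(rows):
            pos, pool = TRNA_SITE_POOL[row]
            sym = str(pool[rng.integers(len(pool))])
            name, detectable = MOD_SYMBOLS[sym]
            s_a = stoich()
            planted.append(
                PlantedSite(mol, pos, sym, name, detectable, "tRNA",
                            s_a, s_a * mult_for(name), in_catalogue=True)
            )

    # --- rRNA known sites, offsets, sentinels -----------------------------
    rrna_ids = [m.molecule_id for m in models if m.biotype == "rRNA"]
    # sentinel symbols are fixed, common, detectable types whose heat-stress
    # multipliers keep the site callable in condition b (quotient stays >= 3)
    sentinel_specs = [
        # (role, symbol, esb_test, esb_control, odds_ratio override, p_adj)
        ("sentinel_esb_test", "7", 0.055, 0.004, None, 1e-4),
        ("sentinel_esb_control", "T", 0.30, 0.018, None, 1e-4),
        ("sentinel_oddr", "L", 0.065, 0.0199, None, 1e-4),  # quotient ~3.27
        ("sentinel_padj", "D", 0.25, 0.004, None, 0.03),
    ]
    # key -> (esb_test condition a, esb_test condition b, esb_control,
    #         odds-ratio override, p_adj); condition b scales the elevation by
    #         the type multiplier so sentinel stoichiometry shifts stay real
    sentinel_overrides: dict[
        tuple[str, int], tuple[float, float, float, float | None, float]
    ] = {}
    offsets_left = config.n_offset_sites
    sentinels_left = list(sentinel_specs) if config.plant_sentinels else []
    rrna_known_positions: dict[str, list[int]] = {}
    for mol in rrna_ids:
        length = lengths[mol]
        positions = _spaced_positions(rng, 60, length - 60, config.sites_per_rrna, 30)
        rrna_known_positions[mol] = positions
        for j, pos in enumerate(positions):
            sym = str(RRNA_SYMBOL_POOL[rng.integers(len(RRNA_SYMBOL_POOL))])
            name, detectable = MOD_SYMBOLS[sym]
            role = "standard"
            offset = 0
            if sentinels_left:
                role, sym, et, ec, orr, pa = sentinels_left.pop(0)
                name, detectable = MOD_SYMBOLS[sym]
                et_b = ec + (et - ec) * mult_for(name)
                sentinel_overrides[(mol, pos)] = (et, et_b, ec, orr, pa)
            elif offsets_left > 0 and detectable and j >= len(positions) - 2:
                # displaced signal, like the 16S m3U offset
                sym, (name, detectable) = "δ", MOD_SYMBOLS["δ"]
                offset = config.offset_shift
                offsets_left -= 1
                role = "offset"
            s_a = stoich()
            planted.append(
                PlantedSite(mol, pos, sym, name, detectable, "rRNA",
                            s_a, s_a * mult_for(name), offset=offset, role=role,
                            in_catalogue=True)
            )

    # --- decoys pinning each threshold from outside -----------------------
    if config.plant_decoys:
        host = rrna_ids[0]
        taken = list(rrna_known_positions[host])
        decoy_specs: list[tuple[str, float, float, float | None]] = []
        for et in (0.012, 0.018, 0.025, 0.032, 0.038, 0.044, 0.048):
            decoy_specs.append(("esb_test", et, 0.003, None))
        for ec in (0.024, 0.030, 0.040, 0.055, 0.070, 0.085, 0.098):
            decoy_specs.append(("esb_control", 0.50, ec, None))
        for orr in (0.6, 1.0, 1.5, 2.0, 2.4, 2.6, 2.9):
            decoy_specs.append(("oddr", 0.06, 0.010, orr))
        pos_list = _spaced_positions(
            rng, 30, lengths[host] - 30, len(decoy_specs),
            min_gap=3, taken=taken,
        )
        # keep decoys out of the +-(tolerance) truth window of known sites
        pos_list = [p for p in pos_list
                    if all(abs(p - q) >= 15 for q in taken)]
        while len(pos_list) < len(decoy_specs):
            extra = _spaced_positions(rng, 30, lengths[host] - 30, 1, 3,
                                      taken=taken + pos_list)
            if all(abs(extra[0] - q) >= 15 for q in taken):
                pos_list.extend(extra)
        for (pinned, et, ec, orr), pos in zip(decoy_specs, pos_list):
            decoys.append(DecoySite(host, pos, pinned, et, ec, orr, 1e-4))

    # --- novel sites outside tRNA/rRNA ------------------------------------
    mrna_models = [m for m in models if m.biotype == "mRNA"]
    ncrna_ids = [m.molecule_id for m in models if m.biotype == "ncRNA"]
    novel: list[PlantedSite] = []
    mrna_cycle = 0
    counts = dict(config.n_mrna_sites)
    for b, n in counts.items():
        for j in range(n):
            if b == "ncRNA":
                if not ncrna_ids:
                    continue
                mol = ncrna_ids[j % len(ncrna_ids)]
                pos = max(12, lengths[mol] // 2)
                biotype = "ncRNA"
            else:
                if not mrna_models:
                    continue
                m = mrna_models[mrna_cycle % len(mrna_models)]
                mrna_cycle += 1
                mol = m.molecule_id
                if b == "CDS":
                    lo, hi = m.cds_start + 12, m.cds_end - 12
                elif b == "UTR5":
                    lo, hi = m.utr5_start, m.utr5_end
                elif b == "UTR3":
                    lo, hi = m.utr3_start, m.utr3_end
                else:  # intergenic: middle of the left flank
                    lo = hi = max(1, config.pad_len // 2)
                pos = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                biotype = b
            s_a = stoich()
            if b == "CDS":
                if rng.random() < config.cds_increase_fraction:
                    mult = float(rng.uniform(1.15, 1.50))
                else:
                    mult = float(rng.uniform(0.60, 0.87))
            else:
                mult = float(rng.uniform(0.80, 1.25))
            base = "A" if rng.random() < 0.4 else str(rng.choice(list("CGU")))
            novel.append(
                PlantedSite(mol, pos, base, "novel", True, biotype,
                            s_a, min(s_a * mult, 1.9))
            )
    # a few CDS sites present in only one condition (zero stoichiometry in
    # the other), exercising the unique-modification class
    cds_novel = [i for i, p in enumerate(novel) if p.biotype == "CDS"]
    uniq = cds_novel[-2 * config.n_unique_mod:] if config.n_unique_mod else []
    for k, i in enumerate(uniq):
        p = novel[i]
        if k < config.n_unique_mod:
            novel[i] = PlantedSite(p.molecule_id, p.position, p.mod_symbol,
                                   p.mod_name, True, p.biotype, p.stoich_a, 0.0,
                                   role="unique_a")
        else:
            novel[i] = PlantedSite(p.molecule_id, p.position, p.mod_symbol,
                                   p.mod_name, True, p.biotype, 0.0, p.stoich_b,
                                   role="unique_b")
    planted.extend(novel)

    # --- depths ------------------------------------------------------------
    depth_a: dict[str, int] = {}
    depth_b: dict[str, int] = {}

    def draw_depth() -> int:
        return max(config.min_depth + 5,
                   int(rng.lognormal(math.log(config.depth_median),
                                     config.depth_sigma)))

    n_low_trna = int(round(config.low_depth_fraction * len(trna_ids)))
    low_trna = set(trna_ids[:n_low_trna])
    for mol in trna_ids:
        if mol in low_trna:
            depth_a[mol] = depth_b[mol] = int(rng.integers(5, config.min_depth))
        else:
            depth_a[mol] = draw_depth()
            depth_b[mol] = draw_depth()
    for mol in rrna_ids:
        depth_a[mol] = depth_b[mol] = config.rrna_depth
    for mol in ncrna_ids:
        depth_a[mol] = draw_depth()
        depth_b[mol] = draw_depth()
    mrna_with_sites = sorted({p.molecule_id for p in novel if p.biotype != "ncRNA"})
    low_in_b = set(mrna_with_sites[: config.n_unique_rna])
    low_in_a = set(mrna_with_sites[config.n_unique_rna: 2 * config.n_unique_rna])
    for m in mrna_models:
        mol = m.molecule_id
        depth_a[mol] = (int(rng.integers(5, config.min_depth))
                        if mol in low_in_a else draw_depth())
        depth_b[mol] = (int(rng.integers(5, config.min_depth))
                        if mol in low_in_b else draw_depth())

    # SELECT assays
    assays: list[tuple[str, bool, bool]] = []
    for i in range(config.n_select_modified):
        assays.append((f"site_mod{i + 1:02d}", True, i < 2))
    for i in range(config.n_select_unmodified):
        assays.append((f"site_unmod{i + 1:02d}", False, False))

    truth = GroundTruth(planted, decoys, t, models, depth_a, depth_b, assays)
    truth._lengths = lengths  # type: ignore[attr-defined]
    truth._sentinel_overrides = sentinel_overrides  # type: ignore[attr-defined]
    truth._low_in_a = low_in_a  # type: ignore[attr-defined]
    truth._low_in_b = low_in_b  # type: ignore[attr-defined]
    truth._low_trna = low_trna  # type: ignore[attr-defined]
    return truth


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, config: SimConfig, size: int) -> np.ndarray:
    bg = rng.gamma(config.background_shape, config.background_scale, size)
    return np.minimum(bg, config.background_cap)


def simulate_site_tables(config: SimConfig, truth: GroundTruth
                         ) -> tuple[list[SiteRecord], list[SiteRecord], list[SiteRecord]]:
    """Per-site tables for condition a, condition b and an IVT-like control.

    Modified positions carry background + effect x stoichiometry; neighbours
    within the smear width get geometrically decayed elevation; low-coverage
    molecules produce no modification signal.  The control table is
    background-only (IVT against itself).  p_adj is a deterministic monotone
    transform of the ESB difference and depth.
    """
    rng = np.random.default_rng(config.seed + 2)
    lengths: dict[str, int] = truth._lengths  # type: ignore[attr-defined]
    overrides = truth._sentinel_overrides  # type: ignore[attr-defined]
    low_maps = {
        "a": truth._low_in_a | truth._low_trna,  # type: ignore[attr-defined]
        "b": truth._low_in_b | truth._low_trna,  # type: ignore[attr-defined]
    }
    sites_by_mol: dict[str, list[PlantedSite]] = {}
    for p in truth.planted:
        sites_by_mol.setdefault(p.molecule_id, []).append(p)
    decoys_by_mol: dict[str, list[DecoySite]] = {}
    for d in truth.decoys:
        decoys_by_mol.setdefault(d.molecule_id, []).append(d)

    tables: dict[str, list[SiteRecord]] = {"a": [], "b": [], "control": []}
    w, decay = config.smear_width, config.smear_decay

    for mol in sorted(lengths):
        n = lengths[mol]
        ec = _background(rng, config, n)               # shared IVT control ESB
        bg = {"a": _background(rng, config, n), "b": _background(rng, config, n),
              "control": _background(rng, config, n)}
        bases = rng.choice(list("ACGU"), size=n)
        elev = {"a": np.zeros(n), "b": np.zeros(n)}
        for p in sites_by_mol.get(mol, []):
            if p.role.startswith("sentinel") or not p.detectable:
                # sentinels carry hand-placed signals; non-detectable types
                # leave basecalling errors unchanged
                continue
            center = p.position + p.offset
            noise = 1.0 + float(rng.normal(0, config.elevation_noise_sd))
            noise = max(noise, 0.2)
            for cond, s in (("a", p.stoich_a), ("b", p.stoich_b)):
                if mol in low_maps[cond] or s == 0:
                    continue
                amp = config.esb_effect * s * noise
                lo = max(1, center - w)
                hi = min(n, center + w)
                d = np.abs(np.arange(lo, hi + 1) - center)
                contrib = amp * decay ** d
                if p.offset != 0 and lo <= p.position <= hi:
                    # a displaced signal leaves the catalogued position itself
                    # error-free; that is what makes it an offset detection
                    contrib = contrib.copy()
                    contrib[p.position - lo] = 0.0
                elev[cond][lo - 1: hi] += contrib
            want = BASE_BY_NAME.get(p.mod_name)
            if want:
                bases[p.position - 1] = want
        for cond in ("a", "b", "control"):
            if cond == "control":
                et = bg[cond]
            else:
                et = np.minimum(bg[cond] + elev[cond], 0.95)
            ecc = ec.copy()
            orr = et / np.maximum(ecc, config.oddr_floor)
            depth_map = truth.depth_a if cond != "b" else truth.depth_b
            depth = depth_map.get(mol, config.rrna_depth)
            z = np.maximum(et - ecc, 0.0) * math.sqrt(depth)
            pa = np.exp(-config.pval_gain * z)
            if cond != "control":
                for key, (o_et_a, o_et_b, o_ec, o_orr, o_pa) in overrides.items():
                    if key[0] != mol:
                        continue
                    i = key[1] - 1
                    o_et = o_et_a if cond == "a" else o_et_b
                    et[i], ecc[i], pa[i] = o_et, o_ec, o_pa
                    orr[i] = o_orr if o_orr is not None else (
                        et[i] / max(ecc[i], config.oddr_floor)
                    )
                for d_ in decoys_by_mol.get(mol, []):
                    i = d_.position - 1
                    et[i], ecc[i], pa[i] = d_.esb_test, d_.esb_control, d_.p_adj
                    orr[i] = d_.odds_ratio if d_.odds_ratio is not None else (
                        et[i] / max(ecc[i], config.oddr_floor)
                    )
            table = tables[cond]
            for i in range(n):
                table.append(
                    SiteRecord(mol, i + 1, str(bases[i]),
                               float(et[i]), float(ecc[i]), float(orr[i]),
                               float(min(pa[i], 1.0)), int(depth))
                )
    return tables["a"], tables["b"], tables["control"]


# ---------------------------------------------------------------------------
# assays
# ---------------------------------------------------------------------------

def simulate_assays(config: SimConfig, truth: GroundTruth
                    ) -> tuple[list[MsMeasurement], list[CtMeasurement]]:
    """MS abundance table mirroring planted stoichiometries, and SELECT CTs.

    MS abundance per type and condition is the planted mean stoichiometry
    times a fixed scale, with multiplicative Gaussian noise per replicate.
    Modified SELECT targets get a CT offset of ``ct_effect`` planted so that
    the assay's ΔΔCT equals −ct_effect in expectation (the sign convention of
    the SELECT readout, where modification makes ΔΔCT negative).
    """
    rng = np.random.default_rng(config.seed + 3)
    ms: list[MsMeasurement] = []
    by_type: dict[str, list[PlantedSite]] = {}
    for p in truth.planted:
        if p.biotype in ("tRNA", "rRNA") and p.mod_name != "novel":
            by_type.setdefault(p.mod_name, []).append(p)
    for name in sorted(by_type):
        sites = by_type[name]
        for cond, attr in ((config.condition_a, "stoich_a"),
                           (config.condition_b, "stoich_b")):
            mean_stoich = sum(getattr(p, attr) for p in sites) / len(sites)
            for rep in range(1, config.ms_replicates + 1):
                noise = (1.0 + float(rng.normal(0, config.ms_noise_sd))
                         if config.ms_noise_sd > 0 else 1.0)
                ms.append(
                    MsMeasurement(name, cond,
                                  max(config.ms_scale * mean_stoich * noise, 0.0),
                                  replicate=rep)
                )
    ct: list[CtMeasurement] = []
    for assay_id, modified, has_mut in truth.select_assays:
        base_target = float(rng.uniform(18, 26))
        base_ctrl = base_target + float(rng.uniform(-1, 1))
        sample_types = ["WT", "IVT"] + (["Mut"] if has_mut else [])
        for stype in sample_types:
            offset = -config.ct_effect if (modified and stype == "WT") else 0.0
            for rep in range(1, config.ct_replicates + 1):
                ct.append(
                    CtMeasurement(
                        assay_id, stype,
                        base_target + offset + float(rng.normal(0, config.ct_noise_sd)),
                        base_ctrl + float(rng.normal(0, config.ct_noise_sd)),
                        replicate=rep,
                    )
                )
    return ms, ct


# ---------------------------------------------------------------------------
# bundle + file emission
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig) -> SimResult:
    """Generate the full ground-truthed input bundle for one seed."""
    truth = build_ground_truth(config)
    sites_a, sites_b, control = simulate_site_tables(config, truth)
    ms, ct = simulate_assays(config, truth)
    return SimResult(config, truth, sites_a, sites_b, control, ms, ct)


def write_simulation(result: SimResult, out_dir: str | Path) -> Path:
    """Write every emitted table in the pipeline's external formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_gene_models(result.truth.models, out_dir / "annotation.gff3",
                      out_dir / "utrs.bed")
    write_site_table(result.sites_a, out_dir / "sites_a.tsv")
    write_site_table(result.sites_b, out_dir / "sites_b.tsv")
    write_site_table(result.control, out_dir / "sites_control.tsv")
    write_known_sites(result.truth.known_sites, out_dir / "known_sites.tsv")
    write_assay_tables(result.ms, result.ct, out_dir / "ms.tsv", out_dir / "ct.tsv")
    return out_dir
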