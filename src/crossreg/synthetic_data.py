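"""Seeded synthetic-panel generator.

Produces every input the pipeline consumes — peak BEDs, fragment BEDs with
library-size manifests, gene annotations, expression counts, alignment
chains linking three toy genomes, and conservation-score tracks — together
with a table of planted ground-truth labels, so every stage is testable
without external downloads.

Geometry is integer-grid and fragment counts are exact (no sampling noise
by default), so downstream quantifications have crisp expected values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_intervals import GenomicInterval, write_bed
from .conservation import ChainAlignment, write_chain
from .gene_assoc import GeneModel, TSSIndex

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticPanel", "generate_panel"]


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel. Defaults give a small three-species,
    three-tissue panel that runs end-to-end in seconds."""

    seed: int = 0
    species: Sequence[str] = ("spA", "spB", "spC")  # [focal, reference, other]
    tissues: Sequence[str] = ("tissue1", "tissue2", "tissue3")
    chrom_names: Sequence[str] = ("chr1", "chr2")
    chrom_length: int = 5_000_000
    aligned_length: int = 4_000_000  # chromosome prefix covered by chains

    # enhancer (H3K27ac-like) landscape
    n_background_enh: int = 30
    background_enh_width: tuple[int, int] = (600, 1_400)
    n_se_clusters: int = 10
    peaks_per_cluster: int = 4
    cluster_peak_width: int = 1_000
    cluster_gap: int = 2_000  # intra-cluster, < stitching gap
    fraction_private: float = 0.5
    n_conserved_se: int = 4

    # promoter (H3K4me3-like) landscape
    n_background_prom: int = 57
    background_prom_width: tuple[int, int] = (300, 900)
    n_planted_bd: int = 3
    bd_width_multiplier: float = 3.0
    bd_fraction_private: float = 0.5  # rounded over n_planted_bd
    n_conserved_bd: int = 1

    # signal scaling (library_size 1e6 makes rpm == fragment count)
    chip_library_size: int = 1_000_000
    background_rpm: float = 10.0
    se_effect_size: float = 10.0  # per cluster peak: effect * background rpm
    fragment_width: int = 100
    poisson_noise: bool = False

    # chain geometry: identity-with-holes (dt == dq keeps coordinates fixed)
    chain_block_size: int = 200_000
    chain_gap: int = 40

    # expression
    gene_span: int = 20_000
    gene_spacing: int = 50_000
    expr_log_mean: float = 3.5
    expr_log_sigma: float = 0.5
    proximity_boost: float = 30.0
    rna_library_size: int = 10_000_000

    # conservation scores
    score_conserved: float = 0.8
    score_background: float = 0.2
    conserved_scores_high: bool = True  # False reverses the planted direction

    @property
    def reference(self) -> str:
        return self.species[1]

    @property
    def cluster_span(self) -> int:
        return (
            self.peaks_per_cluster * self.cluster_peak_width
            + (self.peaks_per_cluster - 1) * self.cluster_gap
        )

    @property
    def bd_width(self) -> int:
        return int(self.bd_width_multiplier * max(self.background_prom_width))

    @property
    def n_private_se(self) -> int:
        return round(self.fraction_private * self.n_se_clusters)

    @property
    def n_private_bd(self) -> int:
        return round(self.bd_fraction_private * self.n_planted_bd)

    def validate(self) -> None:
        if len(self.species) != 3:
            raise ConfigError("exactly three species are required")
        if len(self.tissues) < 2:
            raise ConfigError("at least two tissues are required")
        if not (0 <= self.fraction_private <= 1 and 0 <= self.bd_fraction_private <= 1):
            raise ConfigError("private fractions must lie in [0, 1]")
        for count in (self.n_background_enh, self.n_se_clusters, self.n_planted_bd,
                      self.n_background_prom, self.n_conserved_se, self.n_conserved_bd):
            if count < 0:
                raise ConfigError("counts must be non-negative")
        if self.n_conserved_se > self.n_se_clusters - self.n_private_se:
            raise ConfigError("conserved SE clusters must fit among shared clusters")
        if self.n_conserved_bd > self.n_planted_bd - self.n_private_bd:
            raise ConfigError("conserved BDs must fit among shared BDs")
        if self.cluster_gap >= 12_500:
            raise ConfigError("intra-cluster gap must stay below the stitching gap")
        if self.aligned_length > self.chrom_length:
            raise ConfigError("aligned prefix exceeds chromosome length")
        if self.bd_width <= max(self.background_prom_width):
            raise ConfigError("planted BD width must exceed background widths")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for key in ("species", "tissues", "chrom_names"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("background_enh_width", "background_prom_width"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted labels: one row per emitted element, plus boosted genes."""

    elements: pd.DataFrame  # species,tissue,element_class,chrom,start,end,is_private,is_conserved,slot
    boosted_genes: pd.DataFrame  # species,tissue,gene_id

    def planted(self, species: str, tissue: str, element_class: str) -> pd.DataFrame:
        df = self.elements
        return df[
            (df.species == species)
            & (df.tissue == tissue)
            & (df.element_class == element_class)
        ]


@dataclass
class SyntheticPanel:
    config: SimulationConfig
    root: Path
    truth: SyntheticTruth
    run_config: Path  # run.yaml consumed by the pipeline


class _Cursor:
    """Sequential slot allocator along one chromosome region."""

    def __init__(self, chrom: str, start: int, limit: int, separation: int) -> None:
        self.chrom = chrom
        self.pos = start
        self.limit = limit
        self.separation = separation

    def take(self, span: int) -> int:
        start = self.pos
        if start + span > self.limit:
            raise ConfigError(
                f"infeasible geometry: elements exceed {self.chrom} "
                f"(need {start + span}, limit {self.limit})"
            )
        self.pos = start + span + self.separation
        return start


@dataclass
class _Slot:
    slot_id: int
    chrom: str
    start: int
    span: int

    @property
    def end(self) -> int:
        return self.start + self.span


def _identity_chain(
    t_name: str, q_name: str, size: int, aligned: int,
    block_size: int, gap: int, q_strand: str, score: int, chain_id: str,
) -> ChainAlignment:
    """Identity-with-holes chain: aligned blocks separated by equal dt=dq
    gaps, so in-block coordinates map onto themselves (reflected on '-')."""
    blocks: list[tuple[int, int, int]] = []
    pos = 0
    while pos < aligned:
        blk = min(block_size - gap, aligned - pos)
        if aligned - (pos + blk) <= gap:  # absorb the remainder, no final gap
            blk = aligned - pos
            blocks.append((blk, 0, 0))
            pos = aligned
        else:
            blocks.append((blk, gap, gap))
            pos += blk + gap
    return ChainAlignment(
        score=score, t_name=t_name, t_size=size, t_strand="+",
        t_start=0, t_end=aligned,
        q_name=q_name, q_size=size, q_strand=q_strand,
        q_start=0, q_end=aligned, chain_id=chain_id, blocks=blocks,
    )


def generate_panel(config: SimulationConfig, out_dir) -> SyntheticPanel:
    """Emit the full synthetic input tree plus ground truth under ``out_dir``.

    Identical config (including seed) produces byte-identical files.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)

    focal, reference, other = cfg.species
    chr1, chr2 = cfg.chrom_names[0], cfg.chrom_names[1]
    L = cfg.chrom_length

    # --- slot allocation -------------------------------------------------
    separation = 14_000  # > stitching gap and > widest merge distance
    limit = cfg.aligned_length - 50_000
    cur_chr1 = _Cursor(chr1, 100_000, limit, separation)
    cur_chr2_cons = _Cursor(chr2, 100_000, min(450_000, limit), separation)
    # background may spill past the aligned prefix (only planted SE/BD
    # classes need to be liftable) but must stay clear of the zone where the
    # reference genome carries reflected minus-strand conserved slots
    cur_chr2_bg = _Cursor(chr2, min(500_000, limit), L - 450_000, separation)
    slot_counter = [0]

    def take(cursor: _Cursor, span: int) -> _Slot:
        start = cursor.take(span)
        slot = _Slot(slot_counter[0], cursor.chrom, start, span)
        slot_counter[0] += 1
        return slot

    # conserved slots alternate chromosomes to exercise both chain strands
    conserved_se_slots = [
        take(cur_chr2_cons if i % 2 else cur_chr1, cfg.cluster_span)
        for i in range(cfg.n_conserved_se)
    ]
    conserved_bd_slots = [
        take(cur_chr2_cons if i % 2 else cur_chr1, cfg.bd_width)
        for i in range(cfg.n_conserved_bd)
    ]
    # shared-but-not-conserved slots are species-specific positions
    n_shared_se = cfg.n_se_clusters - cfg.n_private_se
    n_shared_bd = cfg.n_planted_bd - cfg.n_private_bd
    shared_se_slots = {
        sp: [take(cur_chr1, cfg.cluster_span)
             for _ in range(n_shared_se - cfg.n_conserved_se)]
        for sp in cfg.species
    }
    shared_bd_slots = {
        sp: [take(cur_chr1, cfg.bd_width)
             for _ in range(n_shared_bd - cfg.n_conserved_bd)]
        for sp in cfg.species
    }
    private_se_slots = {
        (sp, t): [take(cur_chr1, cfg.cluster_span) for _ in range(cfg.n_private_se)]
        for sp in cfg.species for t in cfg.tissues
    }
    private_bd_slots = {
        (sp, t): [take(cur_chr1, cfg.bd_width) for _ in range(cfg.n_private_bd)]
        for sp in cfg.species for t in cfg.tissues
    }
    # background positions are shared across species and tissues: only the
    # planted classes carry cross-species / cross-tissue semantics
    bg_enh_widths = rng.integers(*cfg.background_enh_width, endpoint=True,
                                 size=cfg.n_background_enh)
    bg_enh_slots = [take(cur_chr2_bg, int(w)) for w in bg_enh_widths]
    bg_prom_widths = rng.integers(*cfg.background_prom_width, endpoint=True,
                                  size=cfg.n_background_prom)
    bg_prom_slots = [take(cur_chr2_bg, int(w)) for w in bg_prom_widths]

    def reflect(slot: _Slot) -> tuple[int, int]:
        return L - slot.end, L - slot.start

    def species_coords(sp: str, slot: _Slot, conserved: bool) -> tuple[str, int, int]:
        """Coordinates of a slot in a given species' frame. Conserved chr2
        slots lie on minus-strand chains for both non-reference species, so
        only the reference carries them reflected."""
        if conserved and slot.chrom == chr2 and sp == reference:
            s, e = reflect(slot)
            return slot.chrom, s, e
        return slot.chrom, slot.start, slot.end

    # --- per-species element tables --------------------------------------
    truth_rows = []
    cluster_count = int(np.ceil(cfg.se_effect_size * cfg.background_rpm))
    bg_count = int(round(cfg.background_rpm))

    def emit_count(target: int) -> int:
        if cfg.poisson_noise:
            return int(rng.poisson(target))
        return target

    def cluster_peaks(chrom: str, start: int) -> list[tuple[str, int, int]]:
        peaks = []
        pos = start
        for _ in range(cfg.peaks_per_cluster):
            peaks.append((chrom, pos, pos + cfg.cluster_peak_width))
            pos += cfg.cluster_peak_width + cfg.cluster_gap
        return peaks

    def fragments_for(chrom: str, start: int, end: int, count: int):
        """``count`` fragments fully inside [start, end)."""
        width = min(cfg.fragment_width, end - start)
        span = end - start - width
        out = []
        for j in range(count):
            off = (j * 37) % (span + 1)  # deterministic spread, no rng
            out.append(GenomicInterval(chrom, start + off, start + off + width))
        return out

    manifest_rows = []
    for sp in cfg.species:
        sp_dir = root / sp
        sp_dir.mkdir(exist_ok=True)
        for t in cfg.tissues:
            enh_peaks, enh_frags = [], []
            prom_peaks, prom_frags = [], []

            se_slots = (
                [(s, False, True) for s in conserved_se_slots]
                + [(s, False, False) for s in shared_se_slots[sp]]
                + [(s, True, False) for s in private_se_slots[(sp, t)]]
            )
            for slot, is_private, is_conserved in se_slots:
                chrom, start, end = species_coords(sp, slot, is_conserved)
                for pc, ps, pe in cluster_peaks(chrom, start):
                    n = emit_count(cluster_count)
                    enh_peaks.append(GenomicInterval(pc, ps, pe, name=f"se{slot.slot_id}",
                                                     signal=float(n)))
                    enh_frags.extend(fragments_for(pc, ps, pe, n))
                truth_rows.append((sp, t, "se_cluster", chrom, start, end,
                                   is_private, is_conserved, slot.slot_id))
            for slot in bg_enh_slots:
                n = emit_count(bg_count)
                enh_peaks.append(GenomicInterval(slot.chrom, slot.start, slot.end,
                                                 name=f"bg{slot.slot_id}", signal=float(n)))
                enh_frags.extend(fragments_for(slot.chrom, slot.start, slot.end, n))
                truth_rows.append((sp, t, "enhancer_bg", slot.chrom, slot.start,
                                   slot.end, False, False, slot.slot_id))

            bd_slots = (
                [(s, False, True) for s in conserved_bd_slots]
                + [(s, False, False) for s in shared_bd_slots[sp]]
                + [(s, True, False) for s in private_bd_slots[(sp, t)]]
            )
            for slot, is_private, is_conserved in bd_slots:
                chrom, start, end = species_coords(sp, slot, is_conserved)
                n = emit_count((end - start) // 50)
                prom_peaks.append(GenomicInterval(chrom, start, end,
                                                  name=f"bd{slot.slot_id}", signal=float(n)))
                prom_frags.extend(fragments_for(chrom, start, end, n))
                truth_rows.append((sp, t, "broad_domain", chrom, start, end,
                                   is_private, is_conserved, slot.slot_id))
            for slot in bg_prom_slots:
                n = emit_count(max(5, slot.span // 100))
                prom_peaks.append(GenomicInterval(slot.chrom, slot.start, slot.end,
                                                  name=f"nd{slot.slot_id}", signal=float(n)))
                prom_frags.extend(fragments_for(slot.chrom, slot.start, slot.end, n))
                truth_rows.append((sp, t, "promoter_bg", slot.chrom, slot.start,
                                   slot.end, False, False, slot.slot_id))

            for mark, peaks, frags in (("enh", enh_peaks, enh_frags),
                                       ("prom", prom_peaks, prom_frags)):
                write_bed(sp_dir / f"{t}.{mark}.peaks.bed",
                          sorted(peaks, key=GenomicInterval.sort_key))
                write_bed(sp_dir / f"{t}.{mark}.chip.bed",
                          sorted(frags, key=GenomicInterval.sort_key))
                (sp_dir / f"{t}.{mark}.control.bed").write_text("")
                for kind in ("chip", "control"):
                    manifest_rows.append(
                        (f"{sp}.{t}.{mark}.{kind}",
                         f"{sp}/{t}.{mark}.{kind}.bed", cfg.chip_library_size)
                    )

    with open(root / "manifest.tsv", "w") as fh:
        for label, path, size in manifest_rows:
            fh.write(f"{label}\t{path}\t{size}\n")

    # --- chromosome sizes -------------------------------------------------
    for sp in cfg.species:
        with open(root / f"{sp}.chrom.sizes", "w") as fh:
            for c in cfg.chrom_names:
                fh.write(f"{c}\t{L}\n")

    # --- genes and expression --------------------------------------------
    boosted_rows = []
    genes_by_species: dict[str, list[GeneModel]] = {}
    for sp in cfg.species:
        genes = []
        i = 0
        for c in cfg.chrom_names:
            for s in range(10_000, L - cfg.gene_span, cfg.gene_spacing):
                strand = "+" if i % 2 == 0 else "-"
                genes.append(GeneModel(f"{sp}_g{i:05d}", c, strand,
                                       s, s + cfg.gene_span, cfg.gene_span))
                i += 1
        genes_by_species[sp] = genes
        with open(root / sp / "genes.tsv", "w") as fh:
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\t{g.length}\n")

    truth = pd.DataFrame(
        truth_rows,
        columns=["species", "tissue", "element_class", "chrom", "start", "end",
                 "is_private", "is_conserved", "slot"],
    )

    for sp in cfg.species:
        index = TSSIndex(genes_by_species[sp])
        gene_ids = [g.gene_id for g in genes_by_species[sp]]
        for t in cfg.tissues:
            base = np.floor(rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sigma,
                                          size=len(gene_ids))).astype(int)
            planted = truth[(truth.species == sp) & (truth.tissue == t)
                            & truth.element_class.isin(["se_cluster", "broad_domain"])]
            boosted = set()
            for _, row in planted.iterrows():
                gid = index.nearest(row.chrom, (int(row.start) + int(row.end)) // 2)
                if gid is not None:
                    boosted.add(gid)
            counts = {
                gid: int(c * cfg.proximity_boost) if gid in boosted else int(c)
                for gid, c in zip(gene_ids, base)
            }
            with open(root / sp / f"{t}.counts.tsv", "w") as fh:
                for gid in gene_ids:
                    fh.write(f"{gid}\t{counts[gid]}\n")
            for gid in sorted(boosted):
                boosted_rows.append((sp, t, gid))

    # --- chains -----------------------------------------------------------
    chains_dir = root / "chains"
    chains_dir.mkdir(exist_ok=True)
    for src in (focal, other):
        chains = [
            _identity_chain(chr1, chr1, L, cfg.aligned_length,
                            cfg.chain_block_size, cfg.chain_gap,
                            "+", 1000, "1"),
            _identity_chain(chr2, chr2, L, cfg.aligned_length,
                            cfg.chain_block_size, cfg.chain_gap,
                            "-", 900, "2"),
        ]
        write_chain(chains_dir / f"{src}_to_{reference}.chain", chains)

    # --- conservation score track (focal frame) ---------------------------
    hi, lo = cfg.score_conserved, cfg.score_background
    if not cfg.conserved_scores_high:
        hi, lo = lo, hi
    scores_dir = root / "scores"
    scores_dir.mkdir(exist_ok=True)
    focal_elements = truth[truth.species == focal].drop_duplicates(
        subset=["chrom", "start", "end"]
    ).sort_values(["chrom", "start", "end"])
    with open(scores_dir / f"{focal}.wig", "w") as fh:
        for _, row in focal_elements.iterrows():
            width = int(row.end) - int(row.start)
            value = hi if row.is_conserved else lo
            fh.write(f"fixedStep chrom={row.chrom} start={int(row.start) + 1} "
                     f"step={width} span={width}\n{value}\n")

    truth_obj = SyntheticTruth(
        elements=truth,
        boosted_genes=pd.DataFrame(boosted_rows,
                                   columns=["species", "tissue", "gene_id"]),
    )
    truth.to_csv(root / "truth_elements.tsv", sep="\t", index=False)
    truth_obj.boosted_genes.to_csv(root / "truth_genes.tsv", sep="\t", index=False)

    run_config = _write_run_config(cfg, root)
    with open(root / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=True)
    return SyntheticPanel(config=cfg, root=root, truth=truth_obj, run_config=run_config)


def _config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    for key in ("species", "tissues", "chrom_names",
                "background_enh_width", "background_prom_width"):
        d[key] = list(d[key])
    return d


def _write_run_config(cfg: SimulationConfig, root: Path) -> Path:
    focal, reference, other = cfg.species
    doc = {
        "species": list(cfg.species),
        "reference": reference,
        "tissues": list(cfg.tissues),
        "chrom_sizes": {sp: f"{sp}.chrom.sizes" for sp in cfg.species},
        "manifest": "manifest.tsv",
        "peaks": {
            sp: {t: {"enh": f"{sp}/{t}.enh.peaks.bed",
                     "prom": f"{sp}/{t}.prom.peaks.bed"}
                 for t in cfg.tissues}
            for sp in cfg.species
        },
        "genes": {sp: f"{sp}/genes.tsv" for sp in cfg.species},
        "counts": {sp: {t: f"{sp}/{t}.counts.tsv" for t in cfg.tissues}
                   for sp in cfg.species},
        "rna_library_size": cfg.rna_library_size,
        "chains": {focal: f"chains/{focal}_to_{reference}.chain",
                   other: f"chains/{other}_to_{reference}.chain"},
        "scores": {focal: f"scores/{focal}.wig"},
        "params": {
            "max_gap": 12_500,
            "bd_fraction": 0.05,
            "unify_widths": [2_000, 4_000, 8_000],
            "merge_distances": [2_000, 4_000, 8_000],
            "conserve_distance": 0,
            "min_match": 0.2,
        },
    }
    path = root / "run.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return path
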