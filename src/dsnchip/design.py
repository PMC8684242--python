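"""Array-content design: technical filters and the ordered 10-category selection.

The engine consumes technically scored variants (depth, per-breed AAF,
p-convert, consequence impact) plus category input lists and haplotype
blocks, and produces a :class:`ChipDesign`: the ordered set of selected
variants, each attributed to the first category (in the fixed order) that
picked it, with per-variant probeset counts.

Selection categories, processed in order:

1. prior-array informative SNPs
2. trait-associated (GWAS) variants
3. high/moderate/low predicted impact
4. focal-breed unique variants
5. high focal-vs-reference AAF divergence (|diff| > 0.70)
6. Y chromosome
7. mitochondria
8. parentage-panel variants
9. one tag variant per still-uncovered haplotype block
10. fillers for residual gaps > 250 kb

A variant already on the chip still counts in a later category's *total*,
but its *unique* attribution stays with the earlier category — the
uniqueness arithmetic of the accounting tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import impact as impact_mod
from .ld import BlockConfig, HaploBlock, pairwise_ld
from .variants import (
    FLAG_DIVERGENT,
    FLAG_EMPIRICAL,
    FLAG_GWAS,
    FLAG_IMPUTED,
    FLAG_PARENTAGE,
    FLAG_PRIOR_ARRAY,
    FLAG_UNIQUE,
    BreedPanel,
    GenotypeMatrix,
    VariantRecord,
)

PRIORITY_CATEGORIES = (2, 3, 4)  # stricter 20-bp neighbourhood window


@dataclass
class FilterConfig:
    """Thresholds of the technical-suitability filter chain."""

    neighborhood_bp_default: int = 35
    neighborhood_bp_priority: int = 20
    depth_per_animal: int = 10
    min_total_depth: int | None = None  # absolute override for non-Y chromosomes
    min_aaf_focal: float = 0.05
    rescue_min_aaf: float = 0.01
    rescue_breed_min_aaf: float = 0.05
    rescue_breeds: tuple[str, ...] = ()
    min_pconvert: float = 0.6
    aaf_exempt_chroms: tuple[str, ...] = ("Y", "MT")
    y_chroms: tuple[str, ...] = ("Y",)

    def __post_init__(self) -> None:
        if self.neighborhood_bp_priority > self.neighborhood_bp_default:
            raise ValueError("priority window must not exceed the default window")
        for name in ("min_aaf_focal", "rescue_min_aaf", "rescue_breed_min_aaf", "min_pconvert"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SelectionConfig:
    """Knobs of the category-selection stage."""

    divergence_threshold: float = 0.70
    block_min_span_bp: int = 5_000
    block_alt_min_span_bp: int = 1_000
    gene_proximity_bp: int = 100_000
    gap_limit_bp: int = 250_000
    complete_ld_tol: float = 1e-9
    complete_ld_statistic: str = "r2"  # or "dprime"
    max_complete_ld_per_block: int = 2
    gwas_replicate_factor: int = 2
    capacity: int = 210_000
    mt_chroms: tuple[str, ...] = ("MT",)
    y_chroms: tuple[str, ...] = ("Y",)


@dataclass(frozen=True)
class FilterStep:
    """Accounting record of one filter: n_out = n_in - n_removed always."""

    name: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass(frozen=True)
class CategoryAssignment:
    variant_id: str
    category: int  # the unique (first-selecting) category, 1..10

    def __post_init__(self) -> None:
        if not 1 <= self.category <= 10:
            raise ValueError(f"category {self.category} outside 1..10")


@dataclass
class CategoryInputs:
    """External id lists and annotations feeding the selection categories."""

    prior_array_ids: frozenset[str] = frozenset()
    gwas_ids: frozenset[str] = frozenset()
    parentage_ids: frozenset[str] = frozenset()
    divergence_breeds: tuple[str, str] | None = None  # (focal, reference)
    gene_regions: tuple[tuple[str, int, int], ...] | None = None  # coding genes, 1-based


@dataclass
class ChipDesign:
    """Result of the selection: who is on the chip, why, and at what cost."""

    selected: list[CategoryAssignment]
    category_members: dict[int, list[str]]  # totals, independent of order
    probesets_per_variant: dict[str, int]
    variant_class: dict[str, str]
    positions: dict[str, tuple[str, int]]  # id -> (chrom, pos)
    capacity: int

    @property
    def n_variants(self) -> int:
        return len(self.selected)

    @property
    def n_snps(self) -> int:
        return sum(1 for a in self.selected if self.variant_class[a.variant_id] == "SNP")

    @property
    def n_indels(self) -> int:
        return self.n_variants - self.n_snps

    @property
    def n_probesets(self) -> int:
        return sum(self.probesets_per_variant.values())

    def unique_counts(self) -> dict[int, int]:
        counts = {c: 0 for c in range(1, 11)}
        for a in self.selected:
            counts[a.category] += 1
        return counts

    def total_counts(self) -> dict[int, int]:
        return {c: len(self.category_members.get(c, [])) for c in range(1, 11)}

    def selected_ids(self) -> list[str]:
        return [a.variant_id for a in self.selected]

    def to_frame(self):
        import pandas as pd

        rows = []
        for a in self.selected:
            chrom, pos = self.positions[a.variant_id]
            rows.append(
                {
                    "variant_id": a.variant_id,
                    "chrom": chrom,
                    "pos": pos,
                    "class": self.variant_class[a.variant_id],
                    "category": a.category,
                    "probesets": self.probesets_per_variant[a.variant_id],
                }
            )
        return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)


class CapacityExceededError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# technical-suitability filters
# ---------------------------------------------------------------------------

def filter_neighborhood(
    variants: Sequence[VariantRecord],
    config: FilterConfig,
    priority_ids: Iterable[str] = (),
) -> tuple[list[VariantRecord], FilterStep]:
    """Drop variants with an interfering neighbour inside the probe window.

    Every input variant interferes (surviving or not); distances are between
    start positions.  The default window removes a variant whose nearest
    neighbour is <= 35 bp away; variants flagged priority (headed for the
    high-value categories) tolerate a neighbour at exactly 20 bp and are
    removed only below 20 bp.
    """
    priority = set(priority_ids)
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    survivors: list[VariantRecord] = []
    for vs in by_chrom.values():
        vs.sort(key=lambda v: (v.pos, v.id))
        pos = np.array([v.pos for v in vs], dtype=np.int64)
        for i, v in enumerate(vs):
            nearest = np.inf
            if i > 0:
                nearest = min(nearest, pos[i] - pos[i - 1])
            if i + 1 < len(vs):
                nearest = min(nearest, pos[i + 1] - pos[i])
            if v.id in priority:
                keep = nearest >= config.neighborhood_bp_priority
            else:
                keep = nearest > config.neighborhood_bp_default
            if keep:
                survivors.append(v)
    survivors.sort(key=lambda v: (v.chrom, v.pos, v.id))
    return survivors, FilterStep("neighborhood", len(variants), len(variants) - len(survivors))


def filter_depth(
    variants: Sequence[VariantRecord],
    n_animals: int,
    config: FilterConfig,
    n_males: int | None = None,
) -> tuple[list[VariantRecord], FilterStep]:
    """Keep variants with total read depth >= 10 x expected carriers.

    Autosomes/X expect all animals as carriers (or the absolute
    ``min_total_depth`` override); Y-chromosome variants scale to the male
    count, since only males carry reads there.
    """
    survivors = []
    for v in variants:
        if v.chrom in config.y_chroms:
            carriers = n_males if n_males is not None else n_animals
            threshold = config.depth_per_animal * carriers
        else:
            threshold = (
                config.min_total_depth
                if config.min_total_depth is not None
                else config.depth_per_animal * n_animals
            )
        if v.total_depth >= threshold:
            survivors.append(v)
    return survivors, FilterStep("depth", len(variants), len(variants) - len(survivors))


def classify_unique(variants: Sequence[VariantRecord], panel: BreedPanel) -> None:
    """Flag variants present in the focal breed but absent in all comparisons.

    Unique := AAF_focal > 0.01 and AAF = 0 in every comparison breed whose
    AAF is defined (breeds with no observed genotypes do not veto).
    """
    for v in variants:
        focal = v.aaf.get(panel.focal, float("nan"))
        if not (focal > 0.01):  # nan fails too
            v.flags.discard(FLAG_UNIQUE)
            continue
        comps = [v.aaf[b] for b in panel.comparison if b in v.aaf and not np.isnan(v.aaf[b])]
        if comps and all(c == 0.0 for c in comps):
            v.flags.add(FLAG_UNIQUE)
        elif not comps:
            # no comparison data at all: cannot claim uniqueness
            v.flags.discard(FLAG_UNIQUE)
        else:
            v.flags.discard(FLAG_UNIQUE)


def classify_divergent(
    variants: Sequence[VariantRecord],
    breed_a: str,
    breed_b: str,
    threshold: float = 0.70,
) -> None:
    """Flag variants with |AAF_a - AAF_b| strictly above the threshold.

    A small guard keeps a difference of exactly the threshold (up to
    floating-point noise) unflagged.
    """
    for v in variants:
        fa = v.aaf.get(breed_a, float("nan"))
        fb = v.aaf.get(breed_b, float("nan"))
        if not np.isnan(fa) and not np.isnan(fb) and abs(fa - fb) > threshold + 1e-9:
            v.flags.add(FLAG_DIVERGENT)
        else:
            v.flags.discard(FLAG_DIVERGENT)


def filter_aaf(
    variants: Sequence[VariantRecord],
    panel: BreedPanel,
    config: FilterConfig,
) -> tuple[list[VariantRecord], FilterStep]:
    """Frequency filter with the rescue clause.

    Keep iff AAF_focal >= 0.05, OR AAF_focal > 0.01 and the variant is either
    focal-unique or common (AAF > 0.05) in a rescue breed.  Y/mitochondrial
    variants are exempt (their categories take every detected variant).
    Undefined focal AAF removes the variant.
    """
    rescue = config.rescue_breeds or tuple(panel.comparison[:1])
    survivors = []
    for v in variants:
        if v.chrom in config.aaf_exempt_chroms:
            survivors.append(v)
            continue
        focal = v.aaf.get(panel.focal, float("nan"))
        if np.isnan(focal):
            continue
        if focal >= config.min_aaf_focal:
            survivors.append(v)
            continue
        if focal > config.rescue_min_aaf:
            rescued = FLAG_UNIQUE in v.flags or any(
                (not np.isnan(v.aaf.get(b, float("nan"))))
                and v.aaf[b] > config.rescue_breed_min_aaf
                for b in rescue
            )
            if rescued:
                survivors.append(v)
    return survivors, FilterStep("aaf", len(variants), len(variants) - len(survivors))


def filter_pconvert(
    variants: Sequence[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], FilterStep]:
    """Keep variants whose better strand scores >= 0.6; unscored ones fail."""
    survivors = [
        v
        for v in variants
        if not np.isnan(v.pconvert_max) and v.pconvert_max >= config.min_pconvert
    ]
    return survivors, FilterStep("pconvert", len(variants), len(variants) - len(survivors))


def run_filter_chain(
    variants: Sequence[VariantRecord],
    panel: BreedPanel,
    n_animals: int,
    config: FilterConfig | None = None,
    priority_ids: Iterable[str] = (),
    n_males: int | None = None,
) -> tuple[list[VariantRecord], list[FilterStep]]:
    """Neighbourhood -> depth -> AAF (with rescue) -> p-convert, in order."""
    cfg = config or FilterConfig()
    classify_unique(variants, panel)  # uniqueness feeds the AAF rescue clause
    steps: list[FilterStep] = []
    out, step = filter_neighborhood(variants, cfg, priority_ids)
    steps.append(step)
    out, step = filter_depth(out, n_animals, cfg, n_males=n_males)
    steps.append(step)
    out, step = filter_aaf(out, panel, cfg)
    steps.append(step)
    out, step = filter_pconvert(out, cfg)
    steps.append(step)
    return out, steps


# ---------------------------------------------------------------------------
# category selection
# ---------------------------------------------------------------------------

def _variant_impact(v: VariantRecord, imap: impact_mod.ImpactMap) -> str:
    if v.impact is not None:
        return v.impact
    if not v.consequence_terms:
        return "modifier"
    return impact_mod.classify_impact(v.consequence_terms, imap, strict=False)


def _complete_ld_prune(
    member_ids: list[str],
    blocks_of: Mapping[str, int],
    already_selected: set[str],
    genotypes: GenotypeMatrix,
    cfg: SelectionConfig,
    order: Mapping[str, tuple],
) -> list[str]:
    """Cap mutually complete-LD variants at two per haplotype block.

    Groups are connected components of the complete-LD graph (r2 = 1 within
    tolerance, or D' = 1 when configured) among the member set of one block.
    Members already on the chip via an earlier category count toward the cap.
    Survivors are chosen in genomic order.
    """
    by_block: dict[int, list[str]] = {}
    for vid in member_ids:
        b = blocks_of.get(vid)
        if b is not None:
            by_block.setdefault(b, []).append(vid)
    dropped: set[str] = set()
    stat = "r2" if cfg.complete_ld_statistic == "r2" else "dprime"
    for vids in by_block.values():
        if len(vids) < 2:
            continue
        vids = sorted(vids, key=lambda v: order[v])
        rows = np.array([genotypes.variant_index(v) for v in vids])
        k = len(vids)
        ia, ib = np.triu_indices(k, k=1)
        ld = pairwise_ld(genotypes.codes, rows[ia], rows[ib])
        complete = ld["defined"] & (ld[stat] >= 1.0 - cfg.complete_ld_tol)
        # union-find over complete-LD edges
        parent = list(range(k))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in zip(ia[complete], ib[complete]):
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[rb] = ra
        groups: dict[int, list[str]] = {}
        for i, vid in enumerate(vids):
            groups.setdefault(find(i), []).append(vid)
        for group in groups.values():
            if len(group) <= cfg.max_complete_ld_per_block:
                continue
            kept = [g for g in group if g in already_selected]
            for g in group:
                if g in already_selected:
                    continue
                if len(kept) < cfg.max_complete_ld_per_block:
                    kept.append(g)
                else:
                    dropped.add(g)
    return [v for v in member_ids if v not in dropped]


def _block_eligible(
    block: HaploBlock, inputs: CategoryInputs, cfg: SelectionConfig
) -> bool:
    span = block.length_bp
    if span > cfg.block_min_span_bp:
        return True
    if span > cfg.block_alt_min_span_bp and inputs.gene_regions is not None:
        for chrom, start, end in inputs.gene_regions:
            if chrom != block.chrom:
                continue
            if block.start_pos <= end + cfg.gene_proximity_bp and (
                block.end_pos >= start - cfg.gene_proximity_bp
            ):
                return True
    return False


def residual_gaps(
    positions: Mapping[str, Sequence[int]],
    limit_bp: int = 250_000,
) -> list[tuple[str, int, int]]:
    """Gaps between adjacent variants whose span exceeds the limit.

    ``positions`` maps chromosome -> sorted variant positions; a gap is the
    interval between two adjacent variants, reported when its span
    (difference of positions) is strictly greater than ``limit_bp``.
    """
    gaps = []
    for chrom in sorted(positions):
        pos = sorted(positions[chrom])
        for a, b in zip(pos, pos[1:]):
            if b - a > limit_bp:
                gaps.append((chrom, a, b))
    return gaps


def select_categories(
    candidates: Sequence[VariantRecord],
    blocks: Sequence[HaploBlock],
    genotypes: GenotypeMatrix,
    inputs: CategoryInputs,
    config: SelectionConfig | None = None,
    panel: BreedPanel | None = None,
) -> ChipDesign:
    """Run the ordered 10-category selection and assemble the chip design."""
    cfg = config or SelectionConfig()
    imap = impact_mod.ImpactMap()
    by_id = {v.id: v for v in candidates}
    order = {v.id: (v.chrom, v.pos, v.id) for v in candidates}

    block_index: dict[str, int] = {}
    for bi, b in enumerate(blocks):
        for vid in b.variant_ids:
            if vid in by_id:
                block_index[vid] = bi

    focal = panel.focal if panel else None
    div_pair = inputs.divergence_breeds
    if div_pair is None and panel and panel.comparison:
        div_pair = (panel.focal, panel.comparison[0])

    def in_order(ids: Iterable[str]) -> list[str]:
        return sorted(ids, key=lambda v: order[v])

    members: dict[int, list[str]] = {}
    members[1] = in_order(v.id for v in candidates if FLAG_PRIOR_ARRAY in v.flags or v.id in inputs.prior_array_ids)
    members[2] = in_order(v.id for v in candidates if FLAG_GWAS in v.flags or v.id in inputs.gwas_ids)
    members[3] = in_order(
        v.id for v in candidates if _variant_impact(v, imap) in ("high", "moderate", "low")
    )
    members[4] = in_order(v.id for v in candidates if FLAG_UNIQUE in v.flags)
    if div_pair is not None:
        a, b = div_pair
        members[5] = in_order(
            v.id
            for v in candidates
            if not np.isnan(v.aaf.get(a, float("nan")))
            and not np.isnan(v.aaf.get(b, float("nan")))
            and abs(v.aaf[a] - v.aaf[b]) > cfg.divergence_threshold + 1e-9
        )
    else:
        members[5] = in_order(v.id for v in candidates if FLAG_DIVERGENT in v.flags)
    members[6] = in_order(v.id for v in candidates if v.chrom in cfg.y_chroms)
    members[7] = in_order(v.id for v in candidates if v.chrom in cfg.mt_chroms)
    members[8] = in_order(v.id for v in candidates if FLAG_PARENTAGE in v.flags or v.id in inputs.parentage_ids)

    selected: dict[str, int] = {}  # id -> unique category

    def take(cat: int, ids: Iterable[str]) -> None:
        for vid in ids:
            if vid not in selected:
                selected[vid] = cat

    take(1, members[1])
    take(2, members[2])
    # LD pruning inside categories 3 and 4 before they join the chip
    sel_set = set(selected)
    members[3] = _complete_ld_prune(members[3], block_index, sel_set, genotypes, cfg, order)
    take(3, members[3])
    sel_set = set(selected)
    members[4] = _complete_ld_prune(members[4], block_index, sel_set, genotypes, cfg, order)
    take(4, members[4])
    for cat in (5, 6, 7, 8):
        take(cat, members[cat])

    # category 9: tag one variant per still-uncovered eligible block
    covered = {block_index[vid] for vid in selected if vid in block_index}
    cat9: list[str] = []
    for bi, block in enumerate(blocks):
        if bi in covered or not _block_eligible(block, inputs, cfg):
            continue
        in_block = [vid for vid in block.variant_ids if vid in by_id and vid not in selected]
        if not in_block:
            continue
        def rank(vid: str):
            v = by_id[vid]
            focal_aaf = v.aaf.get(focal, float("nan")) if focal else float("nan")
            maf = min(focal_aaf, 1 - focal_aaf) if not np.isnan(focal_aaf) else 0.0
            if div_pair and not np.isnan(v.aaf.get(div_pair[0], float("nan"))) and not np.isnan(
                v.aaf.get(div_pair[1], float("nan"))
            ):
                diff = abs(v.aaf[div_pair[0]] - v.aaf[div_pair[1]])
            else:
                diff = 0.0
            pc = v.pconvert_max
            return (
                -(FLAG_EMPIRICAL in v.flags),
                -(pc if not np.isnan(pc) else 0.0),
                -(maf > 0.05),
                -diff,
                v.pos,
                v.id,
            )
        best = min(in_block, key=rank)
        cat9.append(best)
    members[9] = in_order(cat9)
    take(9, members[9])
    # the block-tag totals also count every already-selected variant sitting
    # in an eligible uncovered-at-start block; simpler convention: totals =
    # one tag per eligible block that has any chip variant
    members9_total = set(members[9])
    for bi, block in enumerate(blocks):
        if not _block_eligible(block, inputs, cfg):
            continue
        reps = [vid for vid in block.variant_ids if vid in selected]
        if reps:
            members9_total.add(min(reps, key=lambda v: order[v]))
    members[9] = in_order(members9_total)

    # category 10: greedy gap filling, longest gap first
    cat10: list[str] = []
    pos_by_chrom: dict[str, list[int]] = {}
    for vid in selected:
        chrom, p = by_id[vid].chrom, by_id[vid].pos
        pos_by_chrom.setdefault(chrom, []).append(p)
    unselected = [v for v in candidates if v.id not in selected]
    cand_by_chrom: dict[str, list[VariantRecord]] = {}
    for v in unselected:
        cand_by_chrom.setdefault(v.chrom, []).append(v)
    for vs in cand_by_chrom.values():
        vs.sort(key=lambda v: (v.pos, v.id))
    while True:
        gaps = residual_gaps(pos_by_chrom, cfg.gap_limit_bp)
        gaps = [
            g
            for g in gaps
            if any(g[1] < v.pos < g[2] and v.id not in selected for v in cand_by_chrom.get(g[0], []))
        ]
        if not gaps:
            break
        chrom, lo, hi = max(gaps, key=lambda g: (g[2] - g[1], g[0], g[1]))
        mid = (lo + hi) / 2.0
        inside = [
            v for v in cand_by_chrom[chrom] if lo < v.pos < hi and v.id not in selected
        ]
        pick = min(inside, key=lambda v: (abs(v.pos - mid), v.pos, v.id))
        selected[pick.id] = 10
        cat10.append(pick.id)
        pos_by_chrom[chrom].append(pick.pos)
        pos_by_chrom[chrom].sort()
    members[10] = in_order(cat10)

    # probeset accounting
    probesets: dict[str, int] = {}
    for vid, cat in selected.items():
        v = by_id[vid]
        n = 2 if v.needs_extra_probeset() else 1
        if cat == 2 and FLAG_IMPUTED not in v.flags:
            n *= cfg.gwas_replicate_factor
        probesets[vid] = n

    assignments = [
        CategoryAssignment(vid, cat)
        for vid, cat in sorted(selected.items(), key=lambda kv: order[kv[0]])
    ]
    design = ChipDesign(
        selected=assignments,
        category_members=members,
        probesets_per_variant=probesets,
        variant_class={vid: by_id[vid].variant_class for vid in selected},
        positions={vid: (by_id[vid].chrom, by_id[vid].pos) for vid in selected},
        capacity=cfg.capacity,
    )
    if design.n_probesets > cfg.capacity:
        raise CapacityExceededError(
            f"{design.n_probesets - cfg.capacity} probesets over the "
            f"{cfg.capacity}-probeset capacity"
        )
    return design


class ChipDesigner:
    """Convenience wrapper: filter chain + selection in one object."""

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        genotypes: GenotypeMatrix,
        panel: BreedPanel,
        filter_config: FilterConfig | None = None,
        selection_config: SelectionConfig | None = None,
        inputs: CategoryInputs | None = None,
        n_males: int | None = None,
    ) -> None:
        self.variants = list(variants)
        self.genotypes = genotypes
        self.panel = panel
        self.filter_config = filter_config or FilterConfig()
        self.selection_config = selection_config or SelectionConfig()
        self.inputs = inputs or CategoryInputs()
        self.n_males = n_males
        self.filter_steps: list[FilterStep] | None = None
        self.candidates: list[VariantRecord] | None = None

    def _priority_ids(self) -> set[str]:
        imap = impact_mod.ImpactMap()
        ids = set(self.inputs.gwas_ids)
        for v in self.variants:
            if FLAG_GWAS in v.flags or FLAG_UNIQUE in v.flags:
                ids.add(v.id)
            elif v.consequence_terms and _variant_impact(v, imap) in ("high", "moderate", "low"):
                ids.add(v.id)
        return ids

    def run_filters(self) -> list[VariantRecord]:
        classify_unique(self.variants, self.panel)  # before priority lookup
        self.candidates, self.filter_steps = run_filter_chain(
            self.variants,
            self.panel,
            self.genotypes.n_animals,
            self.filter_config,
            priority_ids=self._priority_ids(),
            n_males=self.n_males,
        )
        return self.candidates

    def design(self, blocks: Sequence[HaploBlock]) -> ChipDesign:
        if self.candidates is None:
            self.run_filters()
        return select_categories(
            self.candidates,
            blocks,
            self.genotypes,
            self.inputs,
            self.selection_config,
            panel=self.panel,
        )
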