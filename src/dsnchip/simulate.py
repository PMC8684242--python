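"""Synthetic multi-breed cohort and chip-run generator.

The generator reproduces the statistical structure the design pipeline
assumes, at desk scale:

* block-structured LD — each chromosome is partitioned into segments; within
  a segment every animal's two haplotypes are drawn from a small pool of 2-4
  founder haplotypes, so intra-segment pairwise D' is high; segments
  recombine freely;
* per-breed allele-frequency spectra with a configurable fraction of
  variants private to the focal breed;
* per-animal fold coverage ~ Normal(18.72, 2.44^2) truncated at 1, with
  per-variant depths Poisson around it;
* consequence-impact classes at 97.17 / 2.19 / 0.60 / 0.04 % (modifier /
  low / moderate / high);
* p-convert scores as a mixture with most mass near 1 and a tail over
  [0.3, 0.8];
* a chip run whose variant-level failures are enriched at p-convert
  0.6-0.7 and at low MAF (small, unsharp genotype clusters), with per-call
  corruption and Beta-distributed call confidences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import ChipDesign
from .evaluate import CallResultSet
from .ld import HaploBlock
from .variants import (
    FLAG_EMPIRICAL,
    FLAG_GWAS,
    FLAG_IMPUTED,
    FLAG_PARENTAGE,
    FLAG_PRIOR_ARRAY,
    MISSING,
    GenotypeMatrix,
    VariantRecord,
    annotate_breed_aafs,
    write_vcf,
)

_TERMS_BY_IMPACT = {
    "modifier": ("intergenic_variant", "intron_variant", "upstream_gene_variant", "downstream_gene_variant"),
    "low": ("synonymous_variant", "3_prime_UTR_variant", "5_prime_UTR_variant", "splice_region_variant"),
    "moderate": ("missense_variant", "inframe_deletion"),
    "high": ("stop_gained", "splice_donor_variant", "frameshift_variant"),
}
_IMPACT_ORDER = ("modifier", "low", "moderate", "high")
_BASES = np.array(list("ACGT"))


@dataclass
class CohortSpec:
    """Parameters of the simulated sequencing cohort.

    Defaults mirror the study conditions the pipeline was built around: a
    focal breed plus one close comparison breed, ~1 variant/kb, ~10 kb LD
    segments, 18.72 +/- 2.44-fold coverage, the observed impact-class
    proportions, and p-convert mass concentrated in [0.6, 1].
    """

    breeds: tuple[tuple[str, int], ...] = (("DSN", 100), ("Holstein", 100))
    chromosomes: tuple[tuple[str, int], ...] = (("1", 5_000_000),)
    variant_density_per_kb: float = 1.0
    block_length_mean_bp: float = 10_000.0
    block_length_shape: float = 2.0
    aaf_beta: tuple[float, float] = (0.5, 1.5)
    unique_fraction: float = 0.10
    indel_fraction: float = 0.10
    depth_mean: float = 18.72
    depth_sd: float = 2.44
    impact_proportions: tuple[float, float, float, float] = (0.9717, 0.0219, 0.0060, 0.0004)
    pconvert_high_weight: float = 0.8
    pconvert_high_beta: tuple[float, float] = (24.0, 3.0)
    pconvert_tail_range: tuple[float, float] = (0.3, 0.8)
    n_founders: tuple[int, int] = (2, 4)
    prior_array_fraction: float = 0.02
    gwas_fraction: float = 0.002
    parentage_fraction: float = 0.001
    empirical_fraction: float = 0.30
    imputed_gwas_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.impact_proportions) - 1.0) > 1e-9:
            raise ValueError("impact_proportions must sum to 1 within 1e-9")
        if any(p < 0 for p in self.impact_proportions):
            raise ValueError("impact_proportions must be nonnegative")
        for name, val in (
            ("variant_density_per_kb", self.variant_density_per_kb),
            ("block_length_mean_bp", self.block_length_mean_bp),
            ("block_length_shape", self.block_length_shape),
            ("depth_mean", self.depth_mean),
            ("depth_sd", self.depth_sd),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name, n in self.breeds:
            if n <= 0:
                raise ValueError(f"breed {name!r}: animal count must be positive")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r}: length must be positive")
        if not 0.0 <= self.unique_fraction <= 1.0:
            raise ValueError("unique_fraction must be in [0, 1]")
        if not 2 <= self.n_founders[0] <= self.n_founders[1]:
            raise ValueError("n_founders must satisfy 2 <= lo <= hi")

    @property
    def focal_breed(self) -> str:
        return self.breeds[0][0]


@dataclass
class ChipRunSpec:
    """Parameters of the simulated genotyping run.

    Variant-level failure probability rises as the better-strand p-convert
    drops below ~0.7 and at low MAF; per-call corruption replaces a genotype
    with one of the two other codes.  Call confidences come from Beta
    distributions: sharply near 0 for clean calls, diffuse for corrupted
    ones.  ``replicate_animals`` lists animal ids receiving one extra
    genotyping instance per occurrence.
    """

    base_failure_rate: float = 0.03
    pconvert_failure_slope: float = 2.0
    rare_allele_cluster_penalty: float = 0.05
    call_error_rate: float = 0.002
    confidence_good_beta: tuple[float, float] = (1.0, 200.0)
    confidence_bad_beta: tuple[float, float] = (2.0, 6.0)
    replicate_animals: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_failure_rate", "rare_allele_cluster_penalty", "call_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pconvert_failure_slope < 0:
            raise ValueError("pconvert_failure_slope must be >= 0")


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth the generator knows."""

    spec: CohortSpec
    variants: list[VariantRecord]
    genotypes: GenotypeMatrix
    true_blocks: list[HaploBlock]
    true_unique_ids: frozenset[str] = frozenset()

    def write(self, directory: str | Path) -> dict[str, Path]:
        """VCF + breed table + category id lists, deterministic bytes."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {"vcf": directory / "cohort.vcf", "breeds": directory / "breeds.tsv"}
        echo = {
            "seed": self.spec.seed,
            "breeds": ";".join(f"{b}:{n}" for b, n in self.spec.breeds),
            "chromosomes": ";".join(f"{c}:{l}" for c, l in self.spec.chromosomes),
            "variant_density_per_kb": self.spec.variant_density_per_kb,
            "unique_fraction": self.spec.unique_fraction,
            "depth_mean": self.spec.depth_mean,
            "depth_sd": self.spec.depth_sd,
        }
        write_vcf(self.variants, self.genotypes, paths["vcf"], config_echo=echo)
        with open(paths["breeds"], "w") as fh:
            fh.write("sample\tbreed\n")
            for a in self.genotypes.animal_ids:
                fh.write(f"{a}\t{self.genotypes.breed_of[a]}\n")
        for flag, fname in (
            (FLAG_PRIOR_ARRAY, "prior_array.tsv"),
            (FLAG_GWAS, "gwas.tsv"),
            (FLAG_PARENTAGE, "parentage.tsv"),
        ):
            path = directory / fname
            with open(path, "w") as fh:
                fh.write("variant_id\n")
                for v in self.variants:
                    if flag in v.flags:
                        fh.write(v.id + "\n")
            paths[fname] = path
        return paths


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate variants, genotypes and the true LD-segment structure."""
    rng = np.random.default_rng(spec.seed)
    animal_ids: list[str] = []
    breed_of: dict[str, str] = {}
    for breed, n in spec.breeds:
        for k in range(n):
            aid = f"{breed}_{k:04d}"
            animal_ids.append(aid)
            breed_of[aid] = breed
    n_animals = len(animal_ids)
    breed_cols = {
        breed: np.array([i for i, a in enumerate(animal_ids) if breed_of[a] == breed])
        for breed, _ in spec.breeds
    }
    focal = spec.focal_breed

    # per-animal fold coverage, drawn once
    coverage = rng.normal(spec.depth_mean, spec.depth_sd, size=n_animals)
    coverage = np.maximum(coverage, 1.0)

    variants: list[VariantRecord] = []
    geno_rows: list[np.ndarray] = []
    true_blocks: list[HaploBlock] = []
    unique_ids: set[str] = set()

    for chrom, length in spec.chromosomes:
        n_var = max(2, int(round(spec.variant_density_per_kb * length / 1000.0)))
        positions = np.sort(rng.choice(length, size=n_var, replace=False)) + 1

        # partition the chromosome into LD segments
        scale = spec.block_length_mean_bp / spec.block_length_shape
        bounds = [0]
        while bounds[-1] < length:
            bounds.append(bounds[-1] + max(200.0, rng.gamma(spec.block_length_shape, scale)))
        bounds = np.asarray(bounds[1:], dtype=float)
        seg_of = np.searchsorted(bounds, positions, side="left")

        for seg in np.unique(seg_of):
            idx = np.nonzero(seg_of == seg)[0]
            m = len(idx)
            k = int(rng.integers(spec.n_founders[0], spec.n_founders[1] + 1))
            target = rng.beta(*spec.aaf_beta, size=m)
            founders = (rng.random((k, m)) < target).astype(np.int8)
            # force polymorphism within the founder pool
            mono = founders.sum(axis=0)
            for j in np.nonzero(mono == 0)[0]:
                founders[rng.integers(k), j] = 1
            for j in np.nonzero(mono == k)[0]:
                founders[rng.integers(k), j] = 0

            founders_by_breed = {b: founders.copy() for b, _ in spec.breeds}
            unique_mask = rng.random(m) < spec.unique_fraction
            for b, _ in spec.breeds:
                if b == focal:
                    continue
                founders_by_breed[b][:, unique_mask] = 0

            seg_geno = np.zeros((m, n_animals), dtype=np.int8)
            for b, _ in spec.breeds:
                cols = breed_cols[b]
                weights = rng.dirichlet(np.full(k, 2.0))
                h1 = rng.choice(k, size=len(cols), p=weights)
                h2 = rng.choice(k, size=len(cols), p=weights)
                fb = founders_by_breed[b]
                seg_geno[:, cols] = fb[h1].T + fb[h2].T

            # make the designated-unique set exactly the breed-uniqueness
            # truth: unique variants get enough focal carriers to clear the
            # presence threshold; non-unique variants that drifted to zero in
            # a comparison breed while present in the focal breed get one
            # carrier planted there
            fcols = breed_cols[focal]
            n_focal = len(fcols)
            min_alt = int(0.01 * 2 * n_focal) + 1
            for j in np.nonzero(unique_mask)[0]:
                alt = int(seg_geno[j, fcols].sum())
                need = min_alt - alt
                if need > 0:
                    zeros = fcols[seg_geno[j, fcols] == 0]
                    seg_geno[j, zeros[:need]] = 1
            focal_alt = seg_geno[:, fcols].sum(axis=1)
            for b, _ in spec.breeds:
                if b == focal:
                    continue
                cols = breed_cols[b]
                drifted = np.nonzero(
                    (~unique_mask) & (seg_geno[:, cols].sum(axis=1) == 0) & (focal_alt > 0)
                )[0]
                for j in drifted:
                    seg_geno[j, cols[int(rng.integers(len(cols)))]] = 1
            geno_rows.append(seg_geno)
            unique_ids.update(
                f"{chrom}_{positions[idx[j]]}" for j in np.nonzero(unique_mask)[0]
            )

            if m >= 2:
                true_blocks.append(
                    HaploBlock(
                        chrom=chrom,
                        start_pos=int(positions[idx[0]]),
                        end_pos=int(positions[idx[-1]]),
                        variant_ids=tuple(f"{chrom}_{positions[i]}" for i in idx),
                    )
                )

        # per-variant annotations
        depth = rng.poisson(np.broadcast_to(coverage, (n_var, n_animals))).sum(axis=1)
        impact_idx = rng.choice(4, size=n_var, p=spec.impact_proportions)
        is_indel = rng.random(n_var) < spec.indel_fraction
        high = rng.random(n_var) < spec.pconvert_high_weight
        lo, hi = spec.pconvert_tail_range

        def draw_pconvert() -> np.ndarray:
            a, b = spec.pconvert_high_beta
            vals = np.where(
                high,
                rng.beta(a, b, size=n_var),
                rng.uniform(lo, hi, size=n_var),
            )
            return np.round(vals, 6)

        pcf = draw_pconvert()
        pcr = draw_pconvert()
        prior = rng.random(n_var) < spec.prior_array_fraction
        gwas = rng.random(n_var) < spec.gwas_fraction
        parent = rng.random(n_var) < spec.parentage_fraction
        empirical = rng.random(n_var) < spec.empirical_fraction
        imputed = rng.random(n_var) < spec.imputed_gwas_fraction

        for j in range(n_var):
            ref_i = int(rng.integers(4))
            if is_indel[j]:
                ins = rng.random() < 0.5
                extra = "".join(_BASES[rng.integers(4, size=int(rng.integers(1, 4)))])
                ref = _BASES[ref_i] if ins else _BASES[ref_i] + extra
                alt = _BASES[ref_i] + extra if ins else _BASES[ref_i]
            else:
                alt_i = int((ref_i + 1 + rng.integers(3)) % 4)
                ref, alt = _BASES[ref_i], _BASES[alt_i]
            imp = _IMPACT_ORDER[impact_idx[j]]
            term = _TERMS_BY_IMPACT[imp][int(rng.integers(len(_TERMS_BY_IMPACT[imp])))]
            flags = set()
            if prior[j] and not is_indel[j]:
                flags.add(FLAG_PRIOR_ARRAY)
            if gwas[j]:
                flags.add(FLAG_GWAS)
                if imputed[j]:
                    flags.add(FLAG_IMPUTED)
            if parent[j]:
                flags.add(FLAG_PARENTAGE)
            if empirical[j]:
                flags.add(FLAG_EMPIRICAL)
            variants.append(
                VariantRecord(
                    id=f"{chrom}_{positions[j]}",
                    chrom=chrom,
                    pos=int(positions[j]),
                    ref=str(ref),
                    alt=str(alt),
                    total_depth=int(depth[j]),
                    consequence_terms=[term],
                    pconvert_fwd=float(pcf[j]),
                    pconvert_rev=float(pcr[j]),
                    flags=flags,
                )
            )

    codes = np.vstack(geno_rows)
    genotypes = GenotypeMatrix([v.id for v in variants], animal_ids, codes, breed_of)
    annotate_breed_aafs(variants, genotypes)
    return SimulatedCohort(
        spec=spec,
        variants=variants,
        genotypes=genotypes,
        true_blocks=true_blocks,
        true_unique_ids=frozenset(unique_ids),
    )


def simulate_chip_run(
    design: ChipDesign,
    genotypes: GenotypeMatrix,
    run: ChipRunSpec,
    variants: Sequence[VariantRecord] | None = None,
) -> CallResultSet:
    """Simulate genotyping the cohort on the designed chip.

    Needs the variant records for p-convert scores; when absent, every
    variant is treated as scoring 1.0 (no score-driven failure).
    """
    rng = np.random.default_rng(run.seed)
    vids = design.selected_ids()
    missing = [v for v in vids if v not in genotypes._vindex]
    if missing:
        raise KeyError(f"design variants absent from genotype matrix: {missing[:5]}")
    unknown_reps = [a for a in run.replicate_animals if a not in genotypes.animal_ids]
    if unknown_reps:
        raise KeyError(f"replicate animals not in cohort: {unknown_reps[:5]}")

    pconv = {v.id: v.pconvert_max for v in variants} if variants else {}
    rows = np.array([genotypes.variant_index(v) for v in vids])
    truth = genotypes.codes[rows]

    instances: list[tuple[str, int]] = [(a, 0) for a in genotypes.animal_ids]
    batch_count: dict[str, int] = {}
    for a in run.replicate_animals:
        batch_count[a] = batch_count.get(a, 0) + 1
        instances.append((a, batch_count[a]))
    inst_cols = np.array([genotypes.animal_ids.index(a) for a, _ in instances])

    nvar, ninst = len(vids), len(instances)
    obs = genotypes.codes[rows][:, inst_cols].astype(float)
    valid = obs >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(valid, obs, 0).sum(axis=1) / np.maximum(2 * valid.sum(axis=1), 1e-12)
    maf = np.minimum(aaf, 1 - aaf)

    p_fail = np.full(nvar, run.base_failure_rate)
    pmax = np.array([pconv.get(v, 1.0) for v in vids])
    pmax = np.where(np.isnan(pmax), 1.0, pmax)
    p_fail = p_fail + run.pconvert_failure_slope * np.maximum(0.0, 0.7 - pmax)
    p_fail = p_fail + run.rare_allele_cluster_penalty * np.maximum(0.0, 1.0 - maf / 0.05)
    p_fail = np.clip(p_fail, 0.0, 1.0)
    failed = rng.random(nvar) < p_fail

    codes = truth[:, inst_cols].copy()
    p_err = np.clip(
        run.call_error_rate
        + run.rare_allele_cluster_penalty * run.call_error_rate * np.maximum(0.0, 1.0 - maf / 0.05),
        0.0,
        1.0,
    )
    corrupt = rng.random((nvar, ninst)) < p_err[:, None]
    corrupt &= codes != MISSING
    shift = rng.integers(1, 3, size=(nvar, ninst))
    codes = np.where(corrupt, (codes + shift) % 3, codes).astype(np.int8)

    a_good, b_good = run.confidence_good_beta
    a_bad, b_bad = run.confidence_bad_beta
    conf = rng.beta(a_good, b_good, size=(nvar, ninst))
    conf_bad = rng.beta(a_bad, b_bad, size=(nvar, ninst))
    conf = np.where(corrupt, conf_bad, conf)

    codes[failed, :] = MISSING
    conf[failed, :] = 1.0
    conf[codes == MISSING] = np.maximum(conf[codes == MISSING], 1.0)

    return CallResultSet(vids, instances, codes, np.clip(conf, 0, 1), genotypes.breed_of)
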