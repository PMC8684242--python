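"""Core variant/genotype data model and standard-format I/O.

Coordinates are 1-based inclusive (VCF convention) everywhere inside the
package; BED output is converted to 0-based half-open at the writer.

Allele frequencies are *alternative* allele frequencies (AAF).  An AAF can be
*undefined* for a breed when every genotype of that breed is missing at the
variant; undefined is represented as ``nan`` and is deliberately distinct from
0.0 — the breed-uniqueness rule needs "observed absent" (AAF = 0) versus
"never observed" (undefined).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing call

#: flag vocabulary used on :class:`VariantRecord.flags`
FLAG_PRIOR_ARRAY = "prior-array-informative"
FLAG_GWAS = "gwas-associated"
FLAG_IMPUTED = "imputed-source"
FLAG_PARENTAGE = "parentage-panel"
FLAG_EMPIRICAL = "empirical-evidence"
FLAG_UNIQUE = "focal-unique"
FLAG_DIVERGENT = "aaf-divergent"

KNOWN_FLAGS = {
    FLAG_PRIOR_ARRAY,
    FLAG_GWAS,
    FLAG_IMPUTED,
    FLAG_PARENTAGE,
    FLAG_EMPIRICAL,
    FLAG_UNIQUE,
    FLAG_DIVERGENT,
}


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce an allele pair to its minimal representation.

    Shared suffix bases are removed first, then shared prefix bases (always
    keeping at least one base of each allele and advancing ``pos`` for every
    trimmed prefix base).  This is reference-free parsimony trimming; full
    left-alignment across repeat tracts would additionally need the reference
    sequence, which the pipeline does not carry.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class VariantRecord:
    """One biallelic sequence variant and its design-relevant annotations."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    total_depth: int = 0
    aaf: dict[str, float] = field(default_factory=dict)  # breed -> AAF (nan = undefined)
    consequence_terms: list[str] = field(default_factory=list)
    impact: str | None = None
    pconvert_fwd: float | None = None
    pconvert_rev: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"{self.id}: empty allele")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1")
        if self.total_depth < 0:
            raise ValueError(f"{self.id}: negative depth")
        for breed, f in self.aaf.items():
            if not np.isnan(f) and not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.id}: AAF[{breed}]={f} outside [0,1]")

    @property
    def variant_class(self) -> str:
        """``"SNP"`` iff both alleles are single bases, else ``"indel"``."""
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def pconvert_max(self) -> float:
        """Best p-convert score across the two strands (nan if both absent)."""
        scores = [s for s in (self.pconvert_fwd, self.pconvert_rev) if s is not None]
        return max(scores) if scores else float("nan")

    def needs_extra_probeset(self) -> bool:
        """A/T and C/G SNPs are invisible to a two-dye system with one probeset."""
        return self.variant_class == "SNP" and {self.ref, self.alt} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class BreedPanel:
    """The focal breed and the genetically closely related comparison breeds."""

    focal: str
    comparison: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.focal in self.comparison:
            raise ValueError(f"focal breed {self.focal!r} also listed as comparison breed")


class GenotypeMatrix:
    """Animals x variants genotype codes with breed labels.

    Codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.  Stored as an
    ``int8`` array of shape (n_variants, n_animals); an optional confidence
    matrix of the same shape carries per-call confidences in [0, 1].
    """

    def __init__(
        self,
        variant_ids: Sequence[str],
        animal_ids: Sequence[str],
        codes: np.ndarray,
        breed_of: Mapping[str, str],
        confidence: np.ndarray | None = None,
    ) -> None:
        self.variant_ids = list(variant_ids)
        self.animal_ids = list(animal_ids)
        self.codes = np.asarray(codes, dtype=np.int8)
        if self.codes.shape != (len(self.variant_ids), len(self.animal_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.variant_ids)}, {len(self.animal_ids)})"
            )
        bad = set(np.unique(self.codes)) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        missing_breed = [a for a in self.animal_ids if a not in breed_of]
        if missing_breed:
            raise ValueError(f"animals without breed assignment: {missing_breed[:5]}")
        self.breed_of = {a: breed_of[a] for a in self.animal_ids}
        if confidence is not None:
            confidence = np.asarray(confidence, dtype=float)
            if confidence.shape != self.codes.shape:
                raise ValueError("confidence shape mismatch")
            if np.nanmin(confidence) < 0 or np.nanmax(confidence) > 1:
                raise ValueError("confidences outside [0, 1]")
        self.confidence = confidence
        self._vindex = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.animal_ids:
            seen.setdefault(self.breed_of[a], None)
        return list(seen)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vindex[variant_id]
        except KeyError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None

    def animal_columns(self, breed: str | None = None) -> np.ndarray:
        """Column indices of the animals of one breed (all animals if None)."""
        if breed is None:
            return np.arange(self.n_animals)
        cols = np.array(
            [i for i, a in enumerate(self.animal_ids) if self.breed_of[a] == breed],
            dtype=int,
        )
        if cols.size == 0:
            raise KeyError(f"no animals of breed {breed!r} in matrix")
        return cols

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        rows = np.array([self.variant_index(v) for v in variant_ids], dtype=int)
        return GenotypeMatrix(
            [self.variant_ids[r] for r in rows],
            self.animal_ids,
            self.codes[rows],
            self.breed_of,
            None if self.confidence is None else self.confidence[rows],
        )


def compute_aaf(genotypes: GenotypeMatrix, breed: str | None = None) -> np.ndarray:
    """Alternative-allele frequency per variant within one breed.

    AAF = (# alt alleles) / (2 x non-missing animals of the breed); missing
    genotypes contribute to neither numerator nor denominator.  Variants with
    every genotype missing in the breed get ``nan`` (undefined — not 0).
    """
    cols = genotypes.animal_columns(breed)
    g = genotypes.codes[:, cols].astype(float)
    obs = g >= 0
    alt = np.where(obs, g, 0.0).sum(axis=1)
    n = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, alt / (2.0 * n), np.nan)


def compute_maf(genotypes: GenotypeMatrix, breed: str | None = None) -> np.ndarray:
    """Minor-allele frequency: min(AAF, 1 - AAF); nan where AAF undefined."""
    aaf = compute_aaf(genotypes, breed)
    return np.minimum(aaf, 1.0 - aaf)


def annotate_breed_aafs(
    variants: Sequence[VariantRecord], genotypes: GenotypeMatrix
) -> None:
    """Fill ``VariantRecord.aaf`` for every breed present in the matrix."""
    per_breed = {b: compute_aaf(genotypes, b) for b in genotypes.breeds}
    for v in variants:
        i = genotypes.variant_index(v.id)
        v.aaf = {b: float(per_breed[b][i]) for b in per_breed}


# ---------------------------------------------------------------------------
# sidecar tables
# ---------------------------------------------------------------------------

def read_breed_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, breed) with header ``sample<TAB>breed``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "breed"):
        if col not in df.columns:
            raise ValueError(f"breed table {path}: missing column {col!r}")
    return dict(zip(df["sample"], df["breed"]))


def read_id_list(path: str | Path) -> set[str]:
    """Single-column TSV of variant ids, header ``variant_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "variant_id" not in df.columns:
        raise ValueError(f"id list {path}: missing column 'variant_id'")
    return set(df["variant_id"])


def read_pconvert_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """TSV keyed by variant id: ``variant_id  pconvert_fwd  pconvert_rev``."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    for col in ("variant_id", "pconvert_fwd", "pconvert_rev"):
        if col not in df.columns:
            raise ValueError(f"p-convert table {path}: missing column {col!r}")
    return {
        r.variant_id: (float(r.pconvert_fwd), float(r.pconvert_rev))
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_INFO_HEADERS = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth across animals">',
    '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence terms">',
    '##INFO=<ID=PCF,Number=1,Type=Float,Description="p-convert score, forward strand">',
    '##INFO=<ID=PCR,Number=1,Type=Float,Description="p-convert score, reverse strand">',
    '##INFO=<ID=FLAGS,Number=.,Type=String,Description="Design flags">',
]


def write_vcf(
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    path: str | Path,
    config_echo: Mapping[str, object] | None = None,
) -> None:
    """Write variants + genotypes as uncompressed VCFv4.2 (GT:DP per sample).

    ``config_echo`` key/value pairs are echoed into ``##dsnchip_*`` header
    lines so a simulated cohort records the parameters that produced it.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    order = sorted(
        range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos, variants[i].id)
    )
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=dsnchip\n")
    if config_echo:
        for k, v in config_echo.items():
            buf.write(f"##dsnchip_{k}={v}\n")
    for chrom in dict.fromkeys(variants[i].chrom for i in order):
        buf.write(f"##contig=<ID={chrom}>\n")
    for line in _INFO_HEADERS:
        buf.write(line + "\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.animal_ids)
        + "\n"
    )
    for i in order:
        v = variants[i]
        row = genotypes.codes[genotypes.variant_index(v.id)]
        info = [f"DP={v.total_depth}"]
        if v.consequence_terms:
            info.append("CSQ=" + ",".join(v.consequence_terms))
        if v.pconvert_fwd is not None:
            info.append(f"PCF={v.pconvert_fwd:.6g}")
        if v.pconvert_rev is not None:
            info.append(f"PCR={v.pconvert_rev:.6g}")
        if v.flags:
            info.append("FLAGS=" + ",".join(sorted(v.flags)))
        buf.write(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t"
            + ";".join(info)
            + "\tGT\t"
            + "\t".join(gt_str[int(g)] for g in row)
            + "\n"
        )
    Path(path).write_text(buf.getvalue())


def read_vcf(
    path: str | Path, breed_table: Mapping[str, str]
) -> tuple[list[VariantRecord], GenotypeMatrix, int]:
    """Read a VCF into the data model.

    Multiallelic sites are excluded; the exclusion count is returned as the
    third element.  Every sample must appear in ``breed_table``; indel alleles
    are trimmed to minimal representation on the way in.

    Returns (variants, genotypes, n_multiallelic_excluded).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unassigned = [s for s in samples if s not in breed_table]
    if unassigned:
        raise ValueError(f"samples without breed assignment: {unassigned[:5]}")

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        pos, ref, alt = trim_alleles(rec.POS, rec.REF, rec.ALT[0])
        info = dict(rec.INFO)
        flags = set(str(info.get("FLAGS", "")).split(",")) & KNOWN_FLAGS
        terms = str(info["CSQ"]).split(",") if "CSQ" in info else []
        v = VariantRecord(
            id=rec.ID or f"{rec.CHROM}_{pos}",
            chrom=rec.CHROM,
            pos=pos,
            ref=ref,
            alt=alt,
            total_depth=int(info.get("DP", 0)),
            consequence_terms=terms,
            pconvert_fwd=float(info["PCF"]) if "PCF" in info else None,
            pconvert_rev=float(info["PCR"]) if "PCR" in info else None,
            flags=flags,
        )
        variants.append(v)
        # gts012: 0/1/2 alt-allele dosage, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)

    codes = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    gm = GenotypeMatrix([v.id for v in variants], samples, codes, dict(breed_table))
    annotate_breed_aafs(variants, gm)
    return variants, gm, n_multi
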