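"""Post-genotyping evaluation of an array design.

Quality control follows the genotyping-suite convention: a call's
*confidence* is 1 - genotype-cluster probability (0 = best), calls above the
confidence threshold are masked to missing, and a variant counts as
*successfully called* when its post-masking call rate clears the call-rate
threshold.  Segregation, concordance, per-category accounting and the
failing-vs-working LD summary all operate downstream of that definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ChipDesign, residual_gaps
from .ld import HaploBlock, LDUndefinedError, dprime_ci
from .variants import MISSING, GenotypeMatrix

CATEGORY_LABELS = {
    1: "prior-array informative",
    2: "trait-associated (GWAS)",
    3: "high/moderate/low impact",
    4: "breed unique",
    5: "high AAF divergence",
    6: "Y chromosome",
    7: "mitochondria",
    8: "parentage panels",
    9: "haplotype blocks",
    10: "filling gaps > 250 kb",
}


def pct(numerator: int, denominator: int) -> float | None:
    """Percentage rounded half-up to 2 decimals; None on a 0/0 stratum."""
    if denominator == 0:
        return None
    exact = Decimal(numerator) * 100 / Decimal(denominator)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class CallResultSet:
    """Per variant x animal-instance genotype calls with confidences.

    Animal *instances* allow technical replicates: the same animal may appear
    several times with different batch labels; batch 0 is the primary run.
    """

    def __init__(
        self,
        variant_ids: Sequence[str],
        instances: Sequence[tuple[str, int]],
        codes: np.ndarray,
        confidence: np.ndarray,
        breed_of: Mapping[str, str],
    ) -> None:
        self.variant_ids = list(variant_ids)
        self.instances = list(instances)
        self.codes = np.asarray(codes, dtype=np.int8)
        self.confidence = np.asarray(confidence, dtype=float)
        shape = (len(self.variant_ids), len(self.instances))
        if self.codes.shape != shape or self.confidence.shape != shape:
            raise ValueError("calls/confidence shape mismatch")
        if self.confidence.size and (
            self.confidence.min() < 0 or self.confidence.max() > 1
        ):
            raise ValueError("confidences outside [0, 1]")
        self.breed_of = dict(breed_of)
        self._vindex = {v: i for i, v in enumerate(self.variant_ids)}

    def variant_index(self, vid: str) -> int:
        return self._vindex[vid]

    def instance_columns(self, breed: str | None = None, batch: int | None = 0) -> np.ndarray:
        cols = [
            i
            for i, (animal, b) in enumerate(self.instances)
            if (batch is None or b == batch)
            and (breed is None or self.breed_of.get(animal) == breed)
        ]
        return np.array(cols, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Long-format Axiom-style export: variant, sample, batch, call, confidence."""
        rows = []
        for j, (animal, b) in enumerate(self.instances):
            for i, vid in enumerate(self.variant_ids):
                rows.append((vid, animal, b, int(self.codes[i, j]), float(self.confidence[i, j])))
        return pd.DataFrame(rows, columns=["variant_id", "sample", "batch", "call", "confidence"])


def mask_low_confidence(calls: CallResultSet, conf_threshold: float = 0.05) -> np.ndarray:
    """Copy of the call matrix with confidences > threshold set to missing."""
    masked = calls.codes.copy()
    masked[calls.confidence > conf_threshold] = MISSING
    return masked


def qc_calls(
    calls: CallResultSet,
    conf_threshold: float = 0.05,
    callrate_threshold: float = 0.95,
    breed: str | None = None,
    callrate_inclusive: bool = False,
) -> tuple[set[str], np.ndarray]:
    """Confidence masking, then the call-rate gate.

    Masking happens *before* the call rate is computed.  The call rate must
    strictly exceed the threshold by default ("had to exceed"); set
    ``callrate_inclusive`` for >=.  ``breed`` restricts both the masking
    denominator and the call-rate computation to that breed's primary
    instances.  Returns (successfully-called variant ids, masked matrix over
    the selected columns).
    """
    cols = calls.instance_columns(breed=breed, batch=0)
    if cols.size == 0:
        raise ValueError("no animals to QC")
    masked = mask_low_confidence(calls, conf_threshold)[:, cols]
    rate = (masked != MISSING).mean(axis=1)
    ok = rate >= callrate_threshold if callrate_inclusive else rate > callrate_threshold
    return {calls.variant_ids[i] for i in np.nonzero(ok)[0]}, masked


def called_in_any_breed(
    calls: CallResultSet,
    conf_threshold: float = 0.05,
    callrate_threshold: float = 0.95,
    callrate_inclusive: bool = False,
) -> set[str]:
    """Union of per-breed successfully-called sets (QC run breed by breed)."""
    breeds = sorted({calls.breed_of[a] for a, b in calls.instances if b == 0})
    out: set[str] = set()
    for breed in breeds:
        ok, _ = qc_calls(calls, conf_threshold, callrate_threshold, breed, callrate_inclusive)
        out |= ok
    return out


def segregating(
    called_ids: set[str],
    calls: CallResultSet,
    maf_threshold: float = 0.01,
    conf_threshold: float = 0.05,
    breed: str | None = None,
) -> set[str]:
    """Successfully called variants with MAF strictly above the threshold.

    MAF is computed from the confidence-masked calls of the target
    population's primary instances.
    """
    cols = calls.instance_columns(breed=breed, batch=0)
    masked = mask_low_confidence(calls, conf_threshold)[:, cols].astype(float)
    obs = masked >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(obs, masked, 0.0).sum(axis=1) / np.maximum(2.0 * obs.sum(axis=1), 1e-12)
    maf = np.minimum(aaf, 1 - aaf)
    out = set()
    for vid in called_ids:
        i = calls.variant_index(vid)
        if obs[i].any() and maf[i] > maf_threshold:
            out.add(vid)
    return out


@dataclass
class ConcordanceSummary:
    per_pair: list[float]
    n_undefined: int
    ddof: int = 1

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_pair)) if self.per_pair else float("nan")

    @property
    def sd(self) -> float:
        if len(self.per_pair) <= self.ddof:
            return float("nan")
        return float(np.std(self.per_pair, ddof=self.ddof))


def concordance_vectors(a: np.ndarray, b: np.ndarray) -> float | None:
    """Fraction of matching calls where both vectors are non-missing."""
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0:
        return None
    return float((a[both] == b[both]).sum() / n)


def concordance(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    pairing: Sequence[tuple[int, int]],
    ddof: int = 1,
) -> ConcordanceSummary:
    """Per-animal concordance between two call matrices (columns = animals).

    ``pairing`` lists (column-in-a, column-in-b) pairs; pairs with zero
    comparable calls are reported as undefined and excluded from the mean.
    """
    rates = []
    undefined = 0
    for ia, ib in pairing:
        r = concordance_vectors(calls_a[:, ia], calls_b[:, ib])
        if r is None:
            undefined += 1
        else:
            rates.append(100.0 * r)
    return ConcordanceSummary(rates, undefined, ddof)


def replicate_concordance(calls: CallResultSet, ddof: int = 1) -> ConcordanceSummary:
    """Concordance across repeat runs of the same animal (batch 0 vs others)."""
    by_animal: dict[str, list[int]] = {}
    for j, (animal, _) in enumerate(calls.instances):
        by_animal.setdefault(animal, []).append(j)
    pairing = []
    for cols in by_animal.values():
        for extra in cols[1:]:
            pairing.append((cols[0], extra))
    return concordance(calls.codes, calls.codes, pairing, ddof)


def truth_concordance(
    calls: CallResultSet, truth: GenotypeMatrix, animals: Sequence[str], ddof: int = 1
) -> ConcordanceSummary:
    """Chip calls vs an external truth (e.g. sequencing-derived genotypes)."""
    tcol = {a: i for i, a in enumerate(truth.animal_ids)}
    ccol = {a: j for j, (a, b) in enumerate(calls.instances) if b == 0}
    rows = np.array([truth.variant_index(v) for v in calls.variant_ids])
    truth_codes = truth.codes[rows]
    pairing = [(ccol[a], tcol[a]) for a in animals]
    return concordance(calls.codes, truth_codes, pairing, ddof)


def maf_histogram(
    calls: CallResultSet,
    called_ids: set[str],
    breed: str | None = None,
    conf_threshold: float = 0.05,
) -> pd.DataFrame:
    """MAF histogram of called variants: 0.05 bins, the lowest starting at 0.01."""
    cols = calls.instance_columns(breed=breed, batch=0)
    masked = mask_low_confidence(calls, conf_threshold)[:, cols].astype(float)
    obs = masked >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(obs, masked, 0.0).sum(axis=1) / np.maximum(2.0 * obs.sum(axis=1), 1e-12)
    maf = np.minimum(aaf, 1 - aaf)
    idx = [calls.variant_index(v) for v in called_ids]
    vals = maf[idx]
    edges = np.concatenate([[0.01], np.arange(0.05, 0.501, 0.05)])
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {
            "maf_low": edges[:-1],
            "maf_high": edges[1:],
            "n_variants": counts,
        }
    )


@dataclass
class EvaluationReport:
    """Per-category accounting plus the run-level summaries."""

    table: pd.DataFrame
    totals: dict[str, object]
    concordance_replicates: ConcordanceSummary | None = None
    concordance_truth: ConcordanceSummary | None = None
    residual_gaps: list[tuple[str, int, int]] = field(default_factory=list)
    ld_failing_vs_working: dict[str, float] | None = None
    maf_hist: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {
            "categories": self.table.to_dict(orient="records"),
            "totals": self.totals,
            "residual_gaps": [list(g) for g in self.residual_gaps],
        }
        if self.concordance_replicates:
            out["concordance_replicates"] = {
                "mean": self.concordance_replicates.mean,
                "sd": self.concordance_replicates.sd,
            }
        if self.concordance_truth:
            out["concordance_truth"] = {
                "mean": self.concordance_truth.mean,
                "sd": self.concordance_truth.sd,
            }
        if self.ld_failing_vs_working is not None:
            out["ld_failing_vs_working"] = self.ld_failing_vs_working
        return out


def category_table(
    design: ChipDesign,
    called_focal: set[str],
    called_any: set[str],
    segregating_focal: set[str],
) -> pd.DataFrame:
    """Accounting table: unique/total/called/segregating per category.

    Counts are over unique-category membership; percentages are
    count / category-unique-total, rounded half-up to 2 decimals, and None
    for empty categories.
    """
    unique = design.unique_counts()
    totals = design.total_counts()
    unique_ids: dict[int, set[str]] = {c: set() for c in range(1, 11)}
    for a in design.selected:
        unique_ids[a.category].add(a.variant_id)
    rows = []
    for c in range(1, 11):
        uids = unique_ids[c]
        n_called = len(uids & called_focal)
        n_any = len(uids & called_any)
        n_seg = len(uids & segregating_focal)
        rows.append(
            {
                "category": c,
                "label": CATEGORY_LABELS[c],
                "n_unique": unique[c],
                "n_total": totals[c],
                "n_called_focal": n_called,
                "pct_called_focal": pct(n_called, unique[c]),
                "n_called_any_breed": n_any,
                "pct_called_any_breed": pct(n_any, unique[c]),
                "n_segregating_focal": n_seg,
                "pct_segregating_focal": pct(n_seg, unique[c]),
            }
        )
    return pd.DataFrame(rows)


def evaluation_report(
    design: ChipDesign,
    calls: CallResultSet,
    focal_breed: str,
    truth: GenotypeMatrix | None = None,
    truth_animals: Sequence[str] | None = None,
    blocks: Sequence[HaploBlock] | None = None,
    genotypes: GenotypeMatrix | None = None,
    conf_threshold: float = 0.05,
    callrate_threshold: float = 0.95,
    gap_limit_bp: int = 250_000,
) -> EvaluationReport:
    """Full evaluation: QC, accounting, concordance, gaps, LD of failures."""
    called_focal, _ = qc_calls(calls, conf_threshold, callrate_threshold, breed=focal_breed)
    called_any = called_in_any_breed(calls, conf_threshold, callrate_threshold)
    seg = segregating(called_focal, calls, breed=focal_breed, conf_threshold=conf_threshold)
    table = category_table(design, called_focal, called_any, seg)

    snp_ids = {v for v, c in design.variant_class.items() if c == "SNP"}
    sel = set(design.selected_ids())
    totals = {
        "n_selected": design.n_variants,
        "n_snps": design.n_snps,
        "n_indels": design.n_indels,
        "n_probesets": design.n_probesets,
        "n_called_focal": len(called_focal & sel),
        "pct_called_focal": pct(len(called_focal & sel), design.n_variants),
        "n_called_focal_snps": len(called_focal & snp_ids),
        "n_called_focal_indels": len(called_focal & (sel - snp_ids)),
        "n_called_any_breed": len(called_any & sel),
        "pct_called_any_breed": pct(len(called_any & sel), design.n_variants),
        "n_segregating_focal": len(seg & sel),
        "pct_segregating_focal": pct(len(seg & sel), design.n_variants),
    }

    pos_called: dict[str, list[int]] = {}
    for vid in called_focal & sel:
        chrom, p = design.positions[vid]
        pos_called.setdefault(chrom, []).append(p)
    gaps = residual_gaps(pos_called, gap_limit_bp)

    report = EvaluationReport(table=table, totals=totals, residual_gaps=gaps)
    report.concordance_replicates = replicate_concordance(calls)
    if truth is not None and truth_animals:
        report.concordance_truth = truth_concordance(calls, truth, truth_animals)
    if blocks is not None and genotypes is not None:
        report.ld_failing_vs_working = failing_vs_working_ld(
            design, called_focal, genotypes, blocks
        )
    report.maf_hist = maf_histogram(calls, called_focal & sel, breed=focal_breed)
    return report


def failing_vs_working_ld(
    design: ChipDesign,
    called_ids: set[str],
    genotypes: GenotypeMatrix,
    blocks: Sequence[HaploBlock],
    ddof: int = 1,
) -> dict[str, float]:
    """LD between each failed chip variant and its nearest working one.

    The partner is the closest successfully called variant in the same
    haplotype block; failing that, the closest on the chromosome.  LD comes
    from the sequencing genotype matrix, so a failed assay can still be
    judged by whether a working neighbour carries its information.
    """
    sel = set(design.selected_ids())
    failed = sorted(sel - called_ids)
    working = sel & called_ids
    block_of: dict[str, int] = {}
    for bi, b in enumerate(blocks):
        for vid in b.variant_ids:
            block_of[vid] = bi
    work_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for vid in working:
        chrom, p = design.positions[vid]
        work_by_chrom.setdefault(chrom, []).append((p, vid))
    for lst in work_by_chrom.values():
        lst.sort()

    dprimes, r2s = [], []
    for vid in failed:
        chrom, p = design.positions[vid]
        partner = None
        bi = block_of.get(vid)
        if bi is not None:
            in_block = [w for w in blocks[bi].variant_ids if w in working]
            if in_block:
                partner = min(in_block, key=lambda w: abs(design.positions[w][1] - p))
        if partner is None:
            near = work_by_chrom.get(chrom, [])
            if near:
                partner = min(near, key=lambda t: abs(t[0] - p))[1]
        if partner is None:
            continue
        try:
            stats = dprime_ci(
                genotypes.codes[genotypes.variant_index(vid)],
                genotypes.codes[genotypes.variant_index(partner)],
            )
        except (LDUndefinedError, KeyError):
            continue
        dprimes.append(stats.dprime)
        r2s.append(stats.r2)

    def _summ(x: list[float]) -> tuple[float, float]:
        if not x:
            return float("nan"), float("nan")
        sd = float(np.std(x, ddof=ddof)) if len(x) > ddof else float("nan")
        return float(np.mean(x)), sd

    dmean, dsd = _summ(dprimes)
    rmean, rsd = _summ(r2s)
    return {
        "n_pairs": float(len(dprimes)),
        "dprime_mean": dmean,
        "dprime_sd": dsd,
        "r2_mean": rmean,
        "r2_sd": rsd,
    }


def read_calls_tsv(path, breed_of: Mapping[str, str]) -> CallResultSet:
    """Ingest an Axiom-style long-format call export.

    Expected columns: variant_id, sample, batch, call (0/1/2/-1), confidence.
    The matrix layout (variant order, instance order) follows first
    appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "sample": str})
    for col in ("variant_id", "sample", "batch", "call", "confidence"):
        if col not in df.columns:
            raise ValueError(f"calls table {path}: missing column {col!r}")
    variant_ids = list(dict.fromkeys(df["variant_id"]))
    instances = list(dict.fromkeys(zip(df["sample"], df["batch"].astype(int))))
    vindex = {v: i for i, v in enumerate(variant_ids)}
    iindex = {inst: j for j, inst in enumerate(instances)}
    codes = np.full((len(variant_ids), len(instances)), MISSING, dtype=np.int8)
    conf = np.ones((len(variant_ids), len(instances)))
    for row in df.itertuples():
        i = vindex[row.variant_id]
        j = iindex[(row.sample, int(row.batch))]
        codes[i, j] = int(row.call)
        conf[i, j] = float(row.confidence)
    return CallResultSet(variant_ids, instances, codes, conf, breed_of)


def write_gaps_bed(gaps: Sequence[tuple[str, int, int]], path) -> None:
    """Residual gaps as BED: 1-based inclusive positions become 0-based
    half-open intervals spanning the gap between the two flanking variants."""
    with open(path, "w") as fh:
        for chrom, lo, hi in gaps:
            fh.write(f"{chrom}\t{lo}\t{hi - 1}\n")
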