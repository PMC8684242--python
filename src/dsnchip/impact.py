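"""Consequence-term to impact-class mapping.

The bundled table mirrors the Ensembl VEP consequence/impact assignment; on
top of it sits an override set that promotes five term types from "modifier"
to "low": coding sequence, mature miRNA, 5' UTR, 3' UTR and non-coding
transcript exon variants.  These are variants inside transcribed sequence
whose functional relevance a plain modifier label would understate when
prioritising array content.

A variant may carry several terms (one per overlapping transcript); the
variant-level impact is the most severe class among them, VEP's "most
severe" convention.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable

import pandas as pd

IMPACTS = ("modifier", "low", "moderate", "high")  # ascending severity
_SEVERITY = {imp: i for i, imp in enumerate(IMPACTS)}

#: terms reclassified from modifier to low impact
DEFAULT_OVERRIDES = frozenset(
    {
        "coding_sequence_variant",
        "mature_miRNA_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "non_coding_transcript_exon_variant",
    }
)


class ImpactMap:
    """Term -> impact lookup with a low-impact override set."""

    def __init__(
        self,
        table: dict[str, str] | None = None,
        overrides: Iterable[str] = DEFAULT_OVERRIDES,
    ) -> None:
        self.table = dict(table) if table is not None else _load_bundled_table()
        bad = {t: i for t, i in self.table.items() if i not in IMPACTS}
        if bad:
            raise ValueError(f"unknown impact classes in table: {bad}")
        self.overrides = frozenset(overrides)

    def lookup(self, term: str, strict: bool = True) -> str:
        if term in self.overrides:
            return "low"
        try:
            return self.table[term]
        except KeyError:
            if strict:
                raise KeyError(f"unknown consequence term {term!r}") from None
            warnings.warn(f"unknown consequence term {term!r}; classifying as modifier")
            return "modifier"


def _load_bundled_table() -> dict[str, str]:
    with resources.files("dsnchip.data").joinpath("consequence_impact.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["term"], df["impact"]))


def classify_impact(
    terms: Iterable[str], impact_map: ImpactMap | None = None, strict: bool = True
) -> str:
    """Most severe impact class across a variant's consequence terms."""
    impact_map = impact_map or ImpactMap()
    terms = list(terms)
    if not terms:
        raise ValueError("variant has no consequence terms")
    return max((impact_map.lookup(t, strict=strict) for t in terms), key=_SEVERITY.get)


def severity(impact: str) -> int:
    """Ordinal severity: modifier=0 < low < moderate < high=3."""
    return _SEVERITY[impact]
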