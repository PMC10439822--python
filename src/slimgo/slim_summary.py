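"""Annotation transfer from best hits to GO slim categories and tabulation.

Counting unit: one increment per distinct (query, category) pair, so a
query annotated with three slim categories contributes three counts and
frequency tables normalize by total annotation pairs (they sum to 1).
"""

from __future__ import annotations

import re
from typing import Mapping

from .best_hits import BestHitMap
from .formats_io import SlimCountTable, SlimMapping

__all__ = [
    "to_locus_id",
    "annotate_queries",
    "count_slims",
    "to_frequencies",
    "make_all_tables",
    "annotation_coverage",
    "DEFAULT_SUFFIX_PATTERN",
]

#: strips exactly one trailing ".<digits>" isoform suffix (TAIR / Phytozome
#: gene-model convention: AT1G01010.1 -> AT1G01010)
DEFAULT_SUFFIX_PATTERN = r"\.\d+$"


def to_locus_id(subject_id: str,
                suffix_pattern: str = DEFAULT_SUFFIX_PATTERN) -> str:
    """Collapse a gene-model identifier to its locus identifier.

    Removes one trailing isoform suffix if present, else returns the id
    unchanged; idempotent for TAIR-style ids.
    """
    return re.sub(suffix_pattern, "", subject_id, count=1)


def annotate_queries(best: BestHitMap, mapping: SlimMapping,
                     level: str = "gene",
                     suffix_pattern: str = DEFAULT_SUFFIX_PATTERN,
                     ) -> dict[str, frozenset[str]]:
    """Look up each query's winning subject in the slim mapping.

    At gene level the winning ``subject_id`` is used verbatim; at locus
    level it is collapsed with :func:`to_locus_id` first.  Queries whose
    key is absent map to the empty set — they stay in the result so
    coverage statistics can count them as unannotated.
    """
    if level not in ("gene", "locus"):
        raise ValueError(f"unknown level {level!r}")
    out: dict[str, frozenset[str]] = {}
    for query, hit in best.entries.items():
        key = hit.subject_id if level == "gene" \
            else to_locus_id(hit.subject_id, suffix_pattern)
        out[query] = mapping.get(key)
    return out


def count_slims(annotations: Mapping[str, frozenset[str]]) -> dict[str, int]:
    """Tally annotation pairs per category, lexicographically ordered."""
    counts: dict[str, int] = {}
    for cats in annotations.values():
        for cat in cats:
            counts[cat] = counts.get(cat, 0) + 1
    return dict(sorted(counts.items()))


def to_frequencies(raw: Mapping[str, int]) -> dict[str, float]:
    """Normalize raw counts to fractions of total annotation pairs."""
    total = sum(raw.values())
    if total == 0:
        return {}
    return {cat: raw[cat] / total for cat in sorted(raw)}


def make_all_tables(best: BestHitMap,
                    mapping_gene: SlimMapping,
                    mapping_locus: SlimMapping,
                    n_input: int,
                    label: str = "gene_set",
                    suffix_pattern: str = DEFAULT_SUFFIX_PATTERN,
                    ) -> dict[tuple[str, str], SlimCountTable]:
    """Build the four summary tables: (gene|locus) x (raw|frequency).

    Keys of the returned dict are ``(level, kind)`` pairs.  Coverage
    metadata (input sequences, queries with a best hit, annotated
    queries) is populated on every table.
    """
    if n_input < len(best):
        raise ValueError(
            f"n_input={n_input} is less than the {len(best)} queries "
            f"holding a best hit")
    tables: dict[tuple[str, str], SlimCountTable] = {}
    for level, mapping in (("gene", mapping_gene), ("locus", mapping_locus)):
        annotations = annotate_queries(best, mapping, level, suffix_pattern)
        raw = count_slims(annotations)
        freq = to_frequencies(raw)
        n_annotated = sum(1 for cats in annotations.values() if cats)
        for kind, values in (("raw", raw), ("frequency", freq)):
            tables[(level, kind)] = SlimCountTable(
                label=label, level=level, kind=kind, values=dict(values),
                n_input_sequences=n_input,
                n_with_best_hit=len(best),
                n_annotated=n_annotated,
            )
    return tables


def annotation_coverage(table: SlimCountTable) -> float:
    """Proportion of input sequences that received >= 1 slim category."""
    if table.n_input_sequences <= 0:
        raise ValueError("table has zero input sequences")
    return table.n_annotated / table.n_input_sequences
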