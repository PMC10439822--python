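"""Synthetic inputs with planted, analytically known outcomes.

Everything the pipeline consumes — FASTA queries, 12-column hit files,
gene- and locus-level slim mappings — can be generated here with the
ground truth (best hits, filter pass/fail, all four summary tables,
annotation coverage) computed *by construction*, never by calling the
code under test.  Generation is integer/seeded and byte-deterministic.

Planted winners are strictly better than their decoys under all four
ranking metrics simultaneously, so best-hit tests are exact for any
metric; ``inject_ties`` adds metric-tied decoy pairs to exercise the
tie-break chain without disturbing the winner.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

from .formats_io import (
    HitRecord,
    SequenceRecord,
    SlimCountTable,
    write_fasta,
    write_slim_mapping,
    write_tabular_hits,
    SlimMapping,
)

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "FixtureBundle",
    "generate_fixture",
    "grid_boundary_fixture",
    "worked_example",
    "CATEGORY_POOL",
    "PRESET_THRESHOLDS",
]

# plausible plant GO-slim-flavoured labels; padded if more are requested
CATEGORY_POOL = [
    "binding", "transport", "kinase_activity", "nucleotide_binding",
    "metabolic_process", "protein_modification", "ribosome", "nucleus",
    "plasma_membrane", "cell_cycle", "response_to_stress", "translation",
    "dna_binding", "chloroplast", "mitochondrion", "cell_wall",
    "signal_transduction", "transcription_factor", "lipid_metabolism",
    "endoplasmic_reticulum", "golgi_apparatus", "cytoskeleton",
    "carbohydrate_metabolism", "transferase_activity", "hydrolase_activity",
    "oxidoreductase_activity", "transporter_activity", "vacuole",
    "cytosol", "extracellular_region", "developmental_process",
    "reproduction", "photosynthesis", "protein_folding",
    "catabolic_process", "secondary_metabolism",
]

#: (label, max_evalue, min_length, min_pident, min_bitscore) — the four
#: combined least -> most stringent filter presets
PRESET_THRESHOLDS = [
    ("combined_1_least", 1e-5, 30, 10.0, 33.0),
    ("combined_2", 1e-5, 50, 25.0, 50.0),
    ("combined_3", 1e-5, 100, 33.0, 60.0),
    ("combined_4_most", 1e-5, 150, 40.0, 75.0),
]


@dataclass
class FixtureSpec:
    """Knobs for one synthetic dataset; identical seed => identical files."""

    n_queries: int = 50
    n_subjects: int = 100
    n_categories: int = 8
    hits_per_query: tuple[int, int] = (1, 5)
    fraction_mappable: float = 0.8
    evalue_grid: tuple[float, ...] = tuple(
        float(f"1e-{e}") for e in range(60, 20, -1))
    seed: int = 0
    inject_ties: bool = False
    sequence_length: int = 90

    def __post_init__(self) -> None:
        if min(self.n_queries, self.n_subjects, self.n_categories) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.fraction_mappable <= 1:
            raise ValueError("fraction_mappable must be in [0, 1]")
        lo, hi = self.hits_per_query
        if not 1 <= lo <= hi:
            raise ValueError("invalid hits_per_query range")
        if hi > len(self.evalue_grid):
            raise ValueError(
                "hits_per_query exceeds distinct E-values available in grid")


@dataclass
class FixtureTruth:
    """Ground truth computed during generation, by construction."""

    best_hits: dict[str, str]                       # query -> winning subject
    pass_by_preset: dict[str, list[bool]]           # preset label -> per-hit-row
    preset_counts: dict[str, tuple[int, int]]       # label -> (n_hits, n_queries)
    tables: dict[tuple[str, str], dict[str, float]]  # (level, kind) -> values
    n_input_sequences: int = 0
    n_with_best_hit: int = 0
    n_annotated: int = 0
    proportion_annotated: float = 0.0
    gene_annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    locus_annotations: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass
class FixtureBundle:
    fasta_path: str
    hits_path: str
    mapping_gene_path: str
    mapping_locus_path: str
    truth: FixtureTruth


def _category_labels(n: int) -> list[str]:
    labels = list(CATEGORY_POOL)
    while len(labels) < n:
        labels.append(f"category_{len(labels):03d}")
    return labels[:n]


def _count_pairs(annotations: dict[str, frozenset[str]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for cats in annotations.values():
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
    return dict(sorted(counts.items()))


def _passes(hit: HitRecord, max_e: float, min_len: int, min_pid: float,
            min_bit: float) -> bool:
    # independent restatement of the filter contract, used only for truth
    return (hit.evalue <= max_e and hit.alignment_length >= min_len
            and hit.percent_identity >= min_pid and hit.bitscore >= min_bit)


def generate_fixture(spec: FixtureSpec,
                     out_dir: str | os.PathLike) -> FixtureBundle:
    """Write a FASTA + hits + two mappings with planted ground truth.

    The planted winner of query ``i`` is a unique subject ``S<i>.<iso>``;
    decoys use a disjoint ``D``-prefixed namespace never present in the
    mappings.  Exactly ``round(fraction_mappable * n_queries)`` winning
    subjects are mappable at both gene and locus level; every fourth
    mappable query gets one extra locus-only category so gene and locus
    tables diverge by a planted amount.
    """
    rng = random.Random(spec.seed)
    os.makedirs(out_dir, exist_ok=True)
    out_dir = str(out_dir)
    categories = _category_labels(spec.n_categories)
    grid = sorted(spec.evalue_grid)  # most significant first

    sequences: list[SequenceRecord] = []
    hits: list[HitRecord] = []
    best: dict[str, str] = {}
    gene_entries: dict[str, frozenset[str]] = {}
    locus_entries: dict[str, frozenset[str]] = {}
    gene_ann: dict[str, frozenset[str]] = {}
    locus_ann: dict[str, frozenset[str]] = {}

    n = spec.n_queries
    n_mappable = round(spec.fraction_mappable * n)
    mappable = set(rng.sample(range(n), n_mappable))

    lo, hi = spec.hits_per_query
    for i in range(n):
        qid = f"q{i:05d}"
        seq = "".join(rng.choice("ACGT") for _ in range(spec.sequence_length))
        sequences.append(SequenceRecord(qid, f"synthetic query {i}", seq))

        n_hits = rng.randint(lo, hi)
        iso = rng.choice((1, 2))
        winner_subject = f"S{i:05d}.{iso}"
        best[qid] = winner_subject
        start = rng.randrange(0, len(grid) - n_hits + 1)

        query_hits: list[HitRecord] = []
        for rank in range(n_hits):
            subject = winner_subject if rank == 0 \
                else f"D{i:05d}x{rank}.{rng.randrange(spec.n_subjects)}"
            length = 200 - 10 * rank
            pident = 95.0 - 5.0 * rank
            query_hits.append(HitRecord(
                query_id=qid, subject_id=subject,
                percent_identity=pident,
                alignment_length=length,
                mismatches=round(length * (100.0 - pident) / 100.0),
                gap_opens=0,
                q_start=1, q_end=3 * length, s_start=1, s_end=length,
                evalue=grid[start + rank],
                bitscore=480.0 - 10.0 * rank,
            ))
        if spec.inject_ties and n_hits >= 2 and rng.random() < 0.5:
            # duplicate a decoy's metrics under a new subject id: ties on
            # every metric, resolved by input order
            twin = query_hits[1]
            query_hits.append(HitRecord(
                query_id=qid, subject_id=f"T{i:05d}tie",
                percent_identity=twin.percent_identity,
                alignment_length=twin.alignment_length,
                mismatches=twin.mismatches, gap_opens=twin.gap_opens,
                q_start=twin.q_start, q_end=twin.q_end,
                s_start=twin.s_start, s_end=twin.s_end,
                evalue=twin.evalue, bitscore=twin.bitscore,
            ))
        rng.shuffle(query_hits)
        hits.extend(query_hits)

        if i in mappable:
            gene_cats = frozenset(
                rng.sample(categories, rng.randint(1, min(3, len(categories)))))
            extra = sorted(set(categories) - gene_cats)
            diverge = (sorted(mappable).index(i) % 4 == 0) and extra
            locus_cats = gene_cats | {extra[0]} if diverge else gene_cats
            gene_entries[winner_subject] = gene_cats
            locus_entries[f"S{i:05d}"] = frozenset(locus_cats)
            gene_ann[qid] = gene_cats
            locus_ann[qid] = frozenset(locus_cats)
        else:
            gene_ann[qid] = frozenset()
            locus_ann[qid] = frozenset()

    # --- truth tables, by construction -----------------------------------
    tables: dict[tuple[str, str], dict[str, float]] = {}
    for level, ann in (("gene", gene_ann), ("locus", locus_ann)):
        raw = _count_pairs(ann)
        total = sum(raw.values())
        tables[(level, "raw")] = dict(raw)
        tables[(level, "frequency")] = (
            {c: raw[c] / total for c in raw} if total else {})

    pass_by_preset: dict[str, list[bool]] = {}
    preset_counts: dict[str, tuple[int, int]] = {}
    for label, max_e, min_len, min_pid, min_bit in PRESET_THRESHOLDS:
        flags = [_passes(h, max_e, min_len, min_pid, min_bit) for h in hits]
        pass_by_preset[label] = flags
        queries = {h.query_id for h, ok in zip(hits, flags) if ok}
        preset_counts[label] = (sum(flags), len(queries))

    truth = FixtureTruth(
        best_hits=best,
        pass_by_preset=pass_by_preset,
        preset_counts=preset_counts,
        tables=tables,
        n_input_sequences=n,
        n_with_best_hit=n,
        n_annotated=n_mappable,
        proportion_annotated=n_mappable / n,
        gene_annotations=gene_ann,
        locus_annotations=locus_ann,
    )

    fasta_path = os.path.join(out_dir, "queries.fasta")
    hits_path = os.path.join(out_dir, "hits.tsv")
    gene_path = os.path.join(out_dir, "mapping_gene.tsv")
    locus_path = os.path.join(out_dir, "mapping_locus.tsv")
    write_fasta(sequences, fasta_path)
    write_tabular_hits(hits, hits_path)
    write_slim_mapping(SlimMapping(gene_entries, level_key="gene"), gene_path)
    write_slim_mapping(SlimMapping(locus_entries, level_key="locus"),
                       locus_path)
    return FixtureBundle(fasta_path, hits_path, gene_path, locus_path, truth)


def grid_boundary_fixture() -> tuple[list[HitRecord], dict[str, int]]:
    """Hits planted exactly at and around every stringency-grid value.

    Returns the hit list plus truth: for every single-metric criterion
    and every combined preset, the number of hits passing, counted by
    direct per-hit threshold comparison during construction.
    """
    # super-passing defaults so only the probed metric decides
    EASY = dict(evalue=1e-60, length=500, pident=99.0, bitscore=900.0)

    probes: list[tuple[str, float]] = []
    for c in (1e-5, 1e-10, 1e-15, 1e-20):
        probes += [("evalue", c), ("evalue", c * 0.5), ("evalue", c * 2.0)]
    for v in (30, 50, 100, 150):
        probes += [("length", v), ("length", v - 1), ("length", v + 1)]
    for v in (10.0, 25.0, 33.0, 40.0):
        probes += [("pident", v), ("pident", v - 0.5), ("pident", v + 0.5)]
    for v in (33.0, 50.0, 60.0, 75.0):
        probes += [("bitscore", v), ("bitscore", v - 1.0), ("bitscore", v + 1.0)]

    hits: list[HitRecord] = []
    for k, (metric, value) in enumerate(probes):
        fields = dict(EASY)
        fields[metric] = value
        length = int(fields["length"])
        hits.append(HitRecord(
            query_id=f"gq{k:04d}", subject_id=f"gs{k:04d}",
            percent_identity=float(fields["pident"]),
            alignment_length=length,
            mismatches=0, gap_opens=0,
            q_start=1, q_end=3 * length, s_start=1, s_end=length,
            evalue=float(fields["evalue"]),
            bitscore=float(fields["bitscore"]),
        ))

    criteria: list[tuple[str, float, int, float, float]] = []
    for c in (1e-5, 1e-10, 1e-15, 1e-20):
        criteria.append((f"evalue<={c:g}", c, 0, 0.0, 0.0))
    for v in (30, 50, 100, 150):
        criteria.append((f"length>={v}", 1e-5, v, 0.0, 0.0))
    for v in (10, 25, 33, 40):
        criteria.append((f"pident>={v}", 1e-5, 0, float(v), 0.0))
    for v in (33, 50, 60, 75):
        criteria.append((f"bitscore>={v}", 1e-5, 0, 0.0, float(v)))
    criteria.extend(PRESET_THRESHOLDS)

    truth = {
        label: sum(_passes(h, max_e, min_len, min_pid, min_bit) for h in hits)
        for label, max_e, min_len, min_pid, min_bit in criteria
    }
    return hits, truth


def worked_example() -> dict:
    """Three small gene sets with planted composition for merge/enrichment demos.

    set1 vs set2 reproduces the worked 2x2 pattern: ``binding`` is
    over-represented in set1 and ``transport`` under-represented.
    """
    counts = {
        "set1": {"binding": 40, "transport": 10},
        "set2": {"binding": 50, "transport": 100},
        "set3": {"binding": 20, "kinase_activity": 30, "transport": 10},
    }
    raw_tables = {}
    freq_tables = {}
    for label, vals in counts.items():
        total = sum(vals.values())
        n = total  # one category per query in this toy: pairs == queries
        raw_tables[label] = SlimCountTable(
            label=label, level="gene", kind="raw", values=dict(vals),
            n_input_sequences=n, n_with_best_hit=n, n_annotated=n)
        freq_tables[label] = SlimCountTable(
            label=label, level="gene", kind="frequency",
            values={c: v / total for c, v in vals.items()},
            n_input_sequences=n, n_with_best_hit=n, n_annotated=n)
    return {
        "raw_tables": raw_tables,
        "frequency_tables": freq_tables,
        "expected_union": sorted({"binding", "transport", "kinase_activity"}),
        "expected_enrichment_set1_vs_set2": {
            "binding": "over", "transport": "under"},
    }
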