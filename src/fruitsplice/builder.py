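"""High-quality transcriptome construction.

Per-stage assembled transcripts are passed through a filter cascade —
junction-read support, expression level, structural class versus the
reference annotation, unmatched single exons — and the surviving sets of the
two developmental stages are merged into one non-redundant transcriptome,
keeping the longer transcript when two stages assembled the same intron
chain.

The junction KEEP rule: a novel junction is supported iff it has >= 4 reads
in both replicates, or >= 10 reads in at least one replicate.  Expression:
a transcript must exceed 1 TPM in both replicates of its stage.  Class
codes "u" (novel intergenic), "x" (antisense exonic) and "s" (antisense
intronic) are removed; single-exon transcripts must exactly match a
reference single-exon transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import Junction, TranscriptModel, group_by_gene

logger = logging.getLogger(__name__)

REMOVAL_JUNC = "JUNC"
REMOVAL_TPM = "TPM"
REMOVAL_CLASS = "CLASS"
REMOVAL_MONO = "MONO"
REMOVAL_MERGE = "MERGE"


# ---------------------------------------------------------------------------
# classification vs reference
# ---------------------------------------------------------------------------


class _RefIndex:
    def __init__(self, reference: Iterable[TranscriptModel]):
        self.chains: set = set()
        self.mono: set = set()
        self.exons: dict[tuple[str, str], IntervalTree] = {}
        self.introns: dict[tuple[str, str], IntervalTree] = {}
        self.spans: dict[tuple[str, str], IntervalTree] = {}
        for t in reference:
            if t.is_single_exon:
                self.mono.add((t.chrom, t.strand, t.exons[0]))
            else:
                self.chains.add((t.chrom, t.strand, t.introns))
            for s, e in t.exons:
                self.exons.setdefault((t.chrom, t.strand), IntervalTree()).addi(s, e)
            for s, e in t.introns:
                self.introns.setdefault((t.chrom, t.strand), IntervalTree()).addi(s, e)
            s, e = t.span
            self.spans.setdefault((t.chrom, t.strand), IntervalTree()).addi(s, e)

    def _any(self, trees, chrom, strand, intervals) -> bool:
        tree = trees.get((chrom, strand))
        if tree is None:
            return False
        return any(tree.overlap(s, e) for s, e in intervals)


def classify_vs_reference(
    assembled: Iterable[TranscriptModel],
    reference: Iterable[TranscriptModel],
) -> dict[str, str]:
    """Assign one-character class codes against the reference annotation.

    Codes: "=" identical structure, "x" antisense exonic overlap, "s"
    antisense intronic overlap, "o" any other same-strand overlap, "u" no
    overlap.  Precedence = > x > s > o > u.
    """
    ref = _RefIndex(reference)
    anti = {"+": "-", "-": "+"}
    codes: dict[str, str] = {}
    for t in assembled:
        if t.is_single_exon:
            equal = (t.chrom, t.strand, t.exons[0]) in ref.mono
        else:
            equal = (t.chrom, t.strand, t.introns) in ref.chains
        if equal:
            code = "="
        elif ref._any(ref.exons, t.chrom, anti[t.strand], t.exons):
            code = "x"
        elif ref._any(ref.introns, t.chrom, anti[t.strand], t.exons):
            code = "s"
        elif ref._any(ref.spans, t.chrom, t.strand, [t.span]):
            code = "o"
        else:
            code = "u"
        codes[t.transcript_id] = code
    return codes


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def novel_junctions(
    assembled: Iterable[TranscriptModel],
    reference: Iterable[TranscriptModel],
) -> set[Junction]:
    """Junctions of the assembly whose intron tuple matches no reference intron."""
    known = {j for t in reference for j in t.junctions}
    return {j for t in assembled for j in t.junctions if j not in known}


def junction_supported(
    counts: tuple[int, int], min_both: int = 4, min_single: int = 10
) -> bool:
    c1, c2 = counts
    return (c1 >= min_both and c2 >= min_both) or max(c1, c2) >= min_single


def filter_by_junction_support(
    transcripts: Sequence[TranscriptModel],
    novel: set[Junction],
    support: Mapping[Junction, tuple[int, int]],
    min_both: int = 4,
    min_single: int = 10,
    ignore_strand: bool = False,
) -> tuple[list[TranscriptModel], list[str]]:
    """Drop transcripts containing an unsupported novel junction."""
    if ignore_strand:
        unstranded: dict = {}
        for (chrom, s, e, _), c in support.items():
            prev = unstranded.get((chrom, s, e), (0, 0))
            unstranded[(chrom, s, e)] = (max(prev[0], c[0]), max(prev[1], c[1]))

    def lookup(j: Junction) -> tuple[int, int]:
        if ignore_strand:
            hit = unstranded.get(j[:3])
        else:
            hit = support.get(j)
        if hit is None:
            logger.info("junction %s absent from support table; treated as 0", j)
            return (0, 0)
        return hit

    kept, removed = [], []
    for t in transcripts:
        bad = any(
            j in novel and not junction_supported(lookup(j), min_both, min_single)
            for j in t.junctions
        )
        (removed if bad else kept).append(t if not bad else t.transcript_id)
    return kept, removed


def filter_by_expression(
    transcripts: Sequence[TranscriptModel],
    expr: pd.DataFrame,
    replicate_columns: Sequence[str],
    min_tpm: float = 1.0,
) -> tuple[list[TranscriptModel], list[str]]:
    """Keep transcripts strictly above ``min_tpm`` in every stage replicate."""
    missing = [c for c in replicate_columns if c not in expr.columns]
    if missing:
        raise KeyError(f"expression table lacks replicate columns {missing}")
    kept, removed = [], []
    for t in transcripts:
        if t.transcript_id in expr.index:
            vals = expr.loc[t.transcript_id, list(replicate_columns)]
            ok = bool((vals > min_tpm).all())
        else:
            logger.info("transcript %s missing from TPM table; treated as 0",
                        t.transcript_id)
            ok = False
        (kept if ok else removed).append(t if ok else t.transcript_id)
    return kept, removed


def filter_class_codes(
    transcripts: Sequence[TranscriptModel],
    codes: Mapping[str, str],
    remove: frozenset[str] = frozenset({"u", "x", "s"}),
) -> tuple[list[TranscriptModel], list[str]]:
    kept, removed = [], []
    for t in transcripts:
        code = codes.get(t.transcript_id, "o")
        if code in remove:
            removed.append(t.transcript_id)
        else:
            kept.append(t.with_class_code(code))
    return kept, removed


def filter_single_exon(
    transcripts: Sequence[TranscriptModel],
    reference: Iterable[TranscriptModel],
) -> tuple[list[TranscriptModel], list[str]]:
    """Single-exon transcripts survive only on an exact reference match."""
    ref_mono = {
        (t.chrom, t.strand, t.exons[0]) for t in reference if t.is_single_exon
    }
    kept, removed = [], []
    for t in transcripts:
        if t.is_single_exon and (t.chrom, t.strand, t.exons[0]) not in ref_mono:
            removed.append(t.transcript_id)
        else:
            kept.append(t)
    return kept, removed


# ---------------------------------------------------------------------------
# stage merge and the full cascade
# ---------------------------------------------------------------------------


def merge_stages(
    stage_sets: Sequence[Sequence[TranscriptModel]],
) -> tuple[list[TranscriptModel], list[str]]:
    """Merge filtered per-stage sets, keeping the longest transcript (summed
    exon length) per intron chain; exact duplicates collapse to one copy."""
    groups: dict[tuple, list[TranscriptModel]] = {}
    for stage_set in stage_sets:
        for t in stage_set:
            groups.setdefault(t.intron_chain_key, []).append(t)
    merged, dropped = [], []
    for key in sorted(groups, key=repr):
        members = groups[key]
        seen: dict[str, TranscriptModel] = {}
        for t in members:
            seen.setdefault(t.transcript_id, t)
        uniq = sorted(seen.values(),
                      key=lambda t: (-t.exonic_length, t.transcript_id))
        merged.append(uniq[0])
        dropped.extend(t.transcript_id for t in uniq[1:])
    merged.sort(key=lambda t: (t.chrom, t.span, t.transcript_id))
    return merged, dropped


@dataclass
class BuildResult:
    transcripts: list[TranscriptModel]
    summary: pd.DataFrame  # stage, filter_step, n_before, n_after
    removals: list[tuple[str, str, str]]  # (stage, transcript_id, reason)
    class_codes: dict[str, str] = field(default_factory=dict)

    @property
    def expressed_genes(self) -> int:
        return len({t.gene_id for t in self.transcripts})


def build_high_quality_transcriptome(
    assembled_by_stage: Mapping[str, Sequence[TranscriptModel]],
    reference: Sequence[TranscriptModel],
    support_by_stage: Mapping[str, Mapping[Junction, tuple[int, int]]],
    expr: pd.DataFrame,
    replicate_columns: Mapping[str, Sequence[str]],
    min_tpm: float = 1.0,
    junction_thresholds: tuple[int, int] = (4, 10),
    ignore_junction_strand: bool = False,
) -> BuildResult:
    """Run the full per-stage filter cascade, then merge the stages."""
    rows = []
    removals: list[tuple[str, str, str]] = []
    all_codes: dict[str, str] = {}
    filtered_sets = []
    min_both, min_single = junction_thresholds
    for stage in assembled_by_stage:
        current = list(assembled_by_stage[stage])
        novel = novel_junctions(current, reference)
        codes = classify_vs_reference(current, reference)
        all_codes.update(codes)

        steps = [
            (
                REMOVAL_JUNC,
                lambda ts: filter_by_junction_support(
                    ts, novel, support_by_stage[stage], min_both, min_single,
                    ignore_junction_strand,
                ),
            ),
            (
                REMOVAL_TPM,
                lambda ts: filter_by_expression(
                    ts, expr, replicate_columns[stage], min_tpm
                ),
            ),
            (REMOVAL_CLASS, lambda ts: filter_class_codes(ts, codes)),
            (REMOVAL_MONO, lambda ts: filter_single_exon(ts, reference)),
        ]
        for step_name, step in steps:
            n_before = len(current)
            current, gone = step(current)
            rows.append(
                {
                    "stage": stage,
                    "filter_step": step_name,
                    "n_before": n_before,
                    "n_after": len(current),
                }
            )
            removals.extend((stage, tid, step_name) for tid in gone)
        filtered_sets.append(current)

    merged, dropped = merge_stages(filtered_sets)
    rows.append(
        {
            "stage": "merged",
            "filter_step": REMOVAL_MERGE,
            "n_before": sum(len(s) for s in filtered_sets),
            "n_after": len(merged),
        }
    )
    removals.extend(("merged", tid, REMOVAL_MERGE) for tid in dropped)
    return BuildResult(
        transcripts=merged,
        summary=pd.DataFrame(rows),
        removals=removals,
        class_codes=all_codes,
    )
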