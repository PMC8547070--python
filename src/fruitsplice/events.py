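"""AS event detection, PSI quantification, and occurrence / differential calls.

Events are local: each is defined by a small set of junction boundaries that
two transcript forms of the same gene disagree on.  Four types are handled:

* ``IR``  — intron retention: one form splices an intron, the other reads
  through it within a single exon whose outer boundaries match the spliced
  form's flanking exons.
* ``ES``  — exon skipping: a cassette exon with both flanking junctions in
  one form and the direct skipping junction in the other.
* ``A5SS`` / ``A3SS`` — two introns share one boundary and differ at the
  other; the label (donor vs acceptor side) is assigned relative to the
  transcription direction, so it is strand-aware.

PSI per sample is TPM(inclusion) / (TPM(inclusion) + TPM(exclusion)), NA
when the denominator is zero.  Inclusion conventions: IR = intron retained,
ES = exon included, A5SS/A3SS = the longer-exon (shorter-intron) form.

An event *occurs* at a stage when its stage PSI (mean of non-NA replicate
PSIs) lies in [0.05, 0.95]; a *stage-specific* event occurs at exactly one
of the two stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import ASEvent, TranscriptModel, group_by_gene, make_event

logger = logging.getLogger(__name__)

PSI_WINDOW = (0.05, 0.95)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


def _detect_gene_events(transcripts: Sequence[TranscriptModel]) -> list[ASEvent]:
    strands = {t.strand for t in transcripts}
    chroms = {t.chrom for t in transcripts}
    gene = transcripts[0].gene_id
    if len(strands) > 1 or len(chroms) > 1:
        raise ValueError(f"gene {gene}: transcripts on multiple strands/chromosomes")
    strand = strands.pop()
    chrom = chroms.pop()
    intron_sets = {t.transcript_id: set(t.introns) for t in transcripts}

    found: dict[tuple, None] = {}
    for t1 in transcripts:
        i1 = t1.introns
        for t2 in transcripts:
            if t1 is t2:
                continue
            s2 = intron_sets[t2.transcript_id]
            # --- ES: flanking introns in t1, skipping junction in t2
            for i in range(len(i1) - 1):
                (d1, s), (e, a2) = i1[i], i1[i + 1]
                if (d1, a2) in s2:
                    found[("ES", ((d1, s), (e, a2)))] = None
            # --- IR: t2 splices an intron whose flanking exon outer
            #     boundaries match a single read-through exon of t1
            for j, (d, a) in enumerate(t2.introns):
                es, ee = t2.exons[j][0], t2.exons[j + 1][1]
                for s, e in t1.exons:
                    if s == es and e == ee and s < d and a < e:
                        found[("IR", ((d, a),))] = None
            # --- A5SS / A3SS: introns sharing one boundary
            for ia, (x1, y1) in enumerate(i1):
                for (x2, y2) in s2:
                    if (x1, y1) == (x2, y2):
                        continue
                    if y1 == y2 and x1 != x2:
                        # shared high/right boundary; alt region [min_x, max_x)
                        short_t = t1 if x1 > x2 else t2
                        lo, hi = min(x1, x2), max(x1, x2)
                        if _exon_ending_at(short_t, hi, covers_from=lo):
                            etype = "A5SS" if strand == "+" else "A3SS"
                            coords = tuple(sorted([(x1, y1), (x2, y2)]))
                            found[(etype, coords)] = None
                    elif x1 == x2 and y1 != y2:
                        short_t = t1 if y1 < y2 else t2
                        lo, hi = min(y1, y2), max(y1, y2)
                        if _exon_starting_at(short_t, lo, covers_to=hi):
                            etype = "A3SS" if strand == "+" else "A5SS"
                            coords = tuple(sorted([(x1, y1), (x2, y2)]))
                            found[(etype, coords)] = None

    events = []
    for etype, coords in found:
        incl, excl = _membership(etype, coords, transcripts)
        if incl and excl:
            events.append(
                make_event(etype, gene, chrom, strand, coords, incl, excl)
            )
    events.sort(key=lambda e: e.event_id)
    return events


def _exon_ending_at(t: TranscriptModel, end: int, covers_from: int) -> bool:
    return any(e == end and s <= covers_from for s, e in t.exons)


def _exon_starting_at(t: TranscriptModel, start: int, covers_to: int) -> bool:
    return any(s == start and e >= covers_to for s, e in t.exons)


def _membership(
    etype: str,
    coords: tuple[tuple[int, int], ...],
    transcripts: Sequence[TranscriptModel],
) -> tuple[set[str], set[str]]:
    incl: set[str] = set()
    excl: set[str] = set()
    for t in transcripts:
        introns = set(t.introns)
        tid = t.transcript_id
        if etype == "ES":
            (d1, s), (e, a2) = coords
            if (d1, s) in introns and (e, a2) in introns:
                incl.add(tid)
            elif (d1, a2) in introns:
                excl.add(tid)
        elif etype == "IR":
            ((d, a),) = coords
            if any(s < d and a < e for s, e in t.exons):
                incl.add(tid)
            elif (d, a) in introns:
                excl.add(tid)
        else:  # A5SS / A3SS: inclusion = shorter intron = longer exon
            i_a, i_b = coords
            shorter = min(coords, key=lambda p: p[1] - p[0])
            longer = i_b if shorter == i_a else i_a
            if shorter in introns:
                incl.add(tid)
            elif longer in introns:
                excl.add(tid)
    return incl, excl


def detect_events(transcripts: Iterable[TranscriptModel]) -> list[ASEvent]:
    """Detect all local AS events by pairwise exon-chain comparison per gene."""
    events: list[ASEvent] = []
    for gene_id in sorted(genes := group_by_gene(transcripts)):
        txs = genes[gene_id]
        if len(txs) < 2:
            continue
        events.extend(_detect_gene_events(txs))
    return events


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


def compute_psi(events: Sequence[ASEvent], expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample PSI matrix (events x samples); NA when no member expressed."""
    rows = {}
    for ev in events:
        incl = [t for t in ev.inclusion_transcripts if t in expr.index]
        excl = [t for t in ev.exclusion_transcripts if t in expr.index]
        missing = ev.member_transcripts - set(incl) - set(excl)
        if missing:
            logger.info("event %s: members %s lack TPM rows", ev.event_id, missing)
        num = expr.loc[incl].sum(axis=0) if incl else pd.Series(0.0, index=expr.columns)
        den = num + (
            expr.loc[excl].sum(axis=0) if excl else pd.Series(0.0, index=expr.columns)
        )
        with np.errstate(invalid="ignore"):
            rows[ev.event_id] = np.where(den > 0, num / den, np.nan)
    out = pd.DataFrame(rows, index=expr.columns).T
    out.index.name = "event_id"
    return out


def stage_of_sample(sample: str) -> str:
    """Parse the stage out of a ``<species>_<stage>_rep<k>`` sample name."""
    parts = sample.rsplit("_", 2)
    if len(parts) != 3 or not parts[2].startswith("rep"):
        raise ValueError(f"cannot parse stage from sample name {sample!r}")
    return parts[1]


def stage_mean_psi(
    psi: pd.DataFrame, stage_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-stage PSI: arithmetic mean of the non-NA replicate PSIs."""
    stage_map = stage_map or {c: stage_of_sample(c) for c in psi.columns}
    return psi.T.groupby(pd.Series(stage_map)).mean().T


def call_occurrence(
    stage_psi: pd.DataFrame,
    lo: float = PSI_WINDOW[0],
    hi: float = PSI_WINDOW[1],
) -> pd.DataFrame:
    """Occurrence flags: stage PSI within [lo, hi]; NA stage PSI -> False."""
    return stage_psi.apply(lambda col: (col >= lo) & (col <= hi)).fillna(False)


def call_stage_specific(
    occurrence: pd.DataFrame,
    immature: str = "immature",
    ripe: str = "ripe",
) -> pd.Series:
    """Partition events into immature-only / ripe-only / both / neither."""
    imm = occurrence[immature].astype(bool)
    rip = occurrence[ripe].astype(bool)
    out = pd.Series("neither", index=occurrence.index, name="label")
    out[imm & rip] = "both"
    out[imm & ~rip] = "immature-only"
    out[~imm & rip] = "ripe-only"
    return out


# ---------------------------------------------------------------------------
# differential splicing
# ---------------------------------------------------------------------------


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # dpsi, pvalue, significant per testable event
    excluded: list[str]  # events with NA PSI in a required sample

    @property
    def significant_events(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def differential_splicing(
    psi: pd.DataFrame,
    events: Sequence[ASEvent],
    expr: pd.DataFrame,
    stage_map: Mapping[str, str] | None = None,
    immature: str = "immature",
    ripe: str = "ripe",
    alpha: float = 0.05,
    min_dpsi: float = 0.1,
    n_bins: int | None = None,
) -> DifferentialResult:
    """Empirical-null differential splicing between the two stages.

    dPSI = mean PSI(ripe) - mean PSI(immature).  The null distribution of
    |dPSI| is built from between-replicate |PSI| differences within each
    stage, pooled across events within total-abundance bins; the p-value is
    the +1-smoothed rank of the observed |dPSI| in its bin's null.  An event
    is significant when p < alpha and |dPSI| > min_dpsi.
    """
    stage_map = stage_map or {c: stage_of_sample(c) for c in psi.columns}
    imm_cols = [c for c in psi.columns if stage_map[c] == immature]
    ripe_cols = [c for c in psi.columns if stage_map[c] == ripe]
    if len(imm_cols) < 2 or len(ripe_cols) < 2:
        raise ValueError("differential splicing needs >= 2 replicates per stage")

    ev_by_id = {e.event_id: e for e in events}
    testable = psi.dropna(axis=0, how="any")
    excluded = [eid for eid in psi.index if eid not in testable.index]
    if excluded:
        logger.info("%d events excluded from testing (NA PSI)", len(excluded))
    if testable.empty:
        return DifferentialResult(
            pd.DataFrame(columns=["dpsi", "abundance", "pvalue", "significant"]),
            excluded,
        )

    dpsi = testable[ripe_cols].mean(axis=1) - testable[imm_cols].mean(axis=1)
    abundance = pd.Series(
        {
            eid: float(expr.reindex(sorted(ev_by_id[eid].member_transcripts))
                       .sum().sum())
            if eid in ev_by_id else 0.0
            for eid in testable.index
        }
    )
    null_parts = []
    for cols in (imm_cols, ripe_cols):
        for i in range(len(cols) - 1):
            null_parts.append((testable[cols[i]] - testable[cols[i + 1]]).abs())
    null = pd.concat(null_parts, axis=1)

    n = len(testable)
    if n_bins is None:
        n_bins = int(np.clip(n // 100, 1, 10))
    ranks = pd.qcut(abundance.rank(method="first"), n_bins, labels=False)
    pvals = pd.Series(index=testable.index, dtype=float)
    for b in range(n_bins):
        members = ranks.index[ranks == b]
        null_vals = null.loc[members].to_numpy().ravel()
        null_vals = null_vals[~np.isnan(null_vals)]
        obs = dpsi.loc[members].abs().to_numpy()
        ge = (null_vals[None, :] >= obs[:, None]).sum(axis=1)
        pvals.loc[members] = (1.0 + ge) / (1.0 + len(null_vals))

    table = pd.DataFrame(
        {
            "dpsi": dpsi,
            "abundance": abundance,
            "pvalue": pvals,
            "significant": (pvals < alpha) & (dpsi.abs() > min_dpsi),
        }
    )
    return DifferentialResult(table, excluded)


# ---------------------------------------------------------------------------
# gene-level summaries
# ---------------------------------------------------------------------------


@dataclass
class GeneLevelSummary:
    event_counts: pd.Series  # per AS type
    n_multiexon_genes: int
    n_as_multiexon_genes: int
    pct_as_genes: float
    es_ratio_by_exon_count: pd.Series
    ir_ratio_by_intron_count: pd.Series
    es_exon_corr: float
    ir_intron_corr: float


def gene_level_summary(
    events: Sequence[ASEvent], transcripts: Sequence[TranscriptModel]
) -> GeneLevelSummary:
    genes = group_by_gene(transcripts)
    max_exons = {
        g: max(len(t.exons) for t in txs) for g, txs in genes.items()
    }
    multi = {g for g, n in max_exons.items() if n >= 2}
    as_genes: dict[str, set[str]] = {}
    for ev in events:
        as_genes.setdefault(ev.etype, set()).add(ev.gene_id)
    any_as = set().union(*as_genes.values()) if as_genes else set()
    counts = pd.Series(
        {t: sum(1 for e in events if e.etype == t) for t in ("IR", "ES", "A3SS", "A5SS")}
    )

    def ratio_by_bin(target_genes: set[str], n_of_gene: Mapping[str, int]) -> pd.Series:
        df = pd.DataFrame(
            {
                "n": [n_of_gene[g] for g in multi],
                "hit": [g in target_genes for g in multi],
            }
        )
        return df.groupby("n")["hit"].mean()

    es_ratio = ratio_by_bin(as_genes.get("ES", set()), max_exons)
    ir_ratio = ratio_by_bin(
        as_genes.get("IR", set()), {g: n - 1 for g, n in max_exons.items()}
    )

    def corr(series: pd.Series) -> float:
        if len(series) < 3 or series.nunique() <= 1:
            return float("nan")
        return float(sps.pearsonr(series.index.to_numpy(float), series.to_numpy())[0])

    n_as = len(any_as & multi)
    return GeneLevelSummary(
        event_counts=counts,
        n_multiexon_genes=len(multi),
        n_as_multiexon_genes=n_as,
        pct_as_genes=100.0 * n_as / len(multi) if multi else 0.0,
        es_ratio_by_exon_count=es_ratio,
        ir_ratio_by_intron_count=ir_ratio,
        es_exon_corr=corr(es_ratio),
        ir_intron_corr=corr(ir_ratio),
    )


def intron_length_comparison(
    events: Sequence[ASEvent],
    transcripts: Sequence[TranscriptModel],
    alternative: str = "less",
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Lengths of retained introns vs all other introns + rank-sum test.

    ``alternative='less'`` tests that retained introns are shorter.
    """
    from .stats import wilcoxon_rank_sum

    retained = {
        (e.chrom, *pair) for e in events if e.etype == "IR" for pair in e.coords
    }
    if not retained:
        raise ValueError("no IR events: nothing to compare retained introns against")
    all_introns = {
        (t.chrom, s, e) for t in transcripts for s, e in t.introns
    }
    sample_a = np.array(sorted(e - s for _, s, e in all_introns & retained))
    sample_b = np.array(sorted(e - s for _, s, e in all_introns - retained))
    stat, p = wilcoxon_rank_sum(sample_a, sample_b, alternative=alternative)
    return sample_a, sample_b, stat, p
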