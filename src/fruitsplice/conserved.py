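"""Cross-species conserved AS detection via flanking-junction sequences.

Each AS event is represented by the exonic sequence flanking its
characteristic alternative splice junction(s): 30-300 bp collected outward
along the exon chain of a transcript that carries the junction, oriented in
the transcription direction.  Flanks are grouped by AS type and compared
across species with a local nucleotide aligner; two events are conserved
when their genes share an orthogroup and both flanks of one pair are
similar to the corresponding flanks of the other.  Clusters are connected
components of the resulting link graph; a cluster touching every analysed
species is *highly conserved*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align

from .models import ASEvent, TranscriptModel
from .orthology import Orthogroup
from .stats import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

TYPE_ORDER = ("IR", "A3SS", "A5SS", "ES")

_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass(frozen=True)
class FlankPair:
    """Transcription-oriented exonic flanks of one alternative junction."""

    event_id: str
    species: str
    etype: str
    junction: tuple[str, int, int, str]  # chrom, intron start/end, strand
    seq_up: str
    seq_down: str


@dataclass
class ConservedCluster:
    members: frozenset[tuple[str, str, str]]  # (species, gene_id, event_id)
    etype: str
    orthogroups: frozenset[str]
    highly_conserved: bool = False

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(sp for sp, _, _ in self.members)


# ---------------------------------------------------------------------------
# flank extraction
# ---------------------------------------------------------------------------


def _representative_junctions(event: ASEvent) -> list[tuple[int, int]]:
    if event.etype == "IR":
        return [event.coords[0]]
    if event.etype == "ES":
        (d1, _), (_, a2) = event.coords
        return [(d1, a2)]
    return list(event.coords)  # A5SS / A3SS: both alternative junctions


def _walk_flanks(
    t: TranscriptModel, junction: tuple[int, int], genome_seq: str, max_len: int
) -> tuple[str, str] | None:
    try:
        i = t.introns.index(junction)
    except ValueError:
        return None
    if junction[1] > len(genome_seq) or junction[0] < 0:
        raise ValueError(
            f"junction {junction} outside chromosome bounds for {t.transcript_id}"
        )
    left = "".join(genome_seq[s:e] for s, e in t.exons[: i + 1])[-max_len:]
    right = "".join(genome_seq[s:e] for s, e in t.exons[i + 1 :])[:max_len]
    return left, right


def extract_flanks(
    event: ASEvent,
    transcripts_by_id: Mapping[str, TranscriptModel],
    genome: Mapping[str, str],
    species: str,
    min_len: int = 30,
    max_len: int = 300,
) -> tuple[list[FlankPair], list[str]]:
    """Flank pairs for the event's representative junction(s).

    A junction yielding less than ``min_len`` exonic sequence on either side
    is un-representable; the reasons list records why.
    """
    if event.chrom not in genome:
        raise KeyError(f"no genome sequence for chromosome {event.chrom}")
    seq = genome[event.chrom]
    flanks, reasons = [], []
    for junction in _representative_junctions(event):
        carrier = None
        for tid in sorted(event.member_transcripts):
            t = transcripts_by_id.get(tid)
            if t is not None and junction in t.introns:
                carrier = t
                break
        if carrier is None:
            reasons.append(f"{event.event_id}: no member carries {junction}")
            continue
        walked = _walk_flanks(carrier, junction, seq, max_len)
        if walked is None:
            continue
        left, right = walked
        if event.strand == "+":
            up, down = left, right
        else:
            up, down = _revcomp(right), _revcomp(left)
        if len(up) < min_len or len(down) < min_len:
            reasons.append(
                f"{event.event_id}: flank below {min_len} bp at {junction}"
            )
            continue
        flanks.append(
            FlankPair(
                event_id=event.event_id,
                species=species,
                etype=event.etype,
                junction=(event.chrom, *junction, event.strand),
                seq_up=up,
                seq_down=down,
            )
        )
    return flanks, reasons


def extract_all_flanks(
    events_by_species: Mapping[str, Sequence[ASEvent]],
    transcripts_by_species: Mapping[str, Mapping[str, TranscriptModel]],
    genomes: Mapping[str, Mapping[str, str]],
    min_len: int = 30,
    max_len: int = 300,
) -> tuple[list[FlankPair], list[str]]:
    flanks, excluded = [], []
    for sp in sorted(events_by_species):
        for ev in events_by_species[sp]:
            fp, reasons = extract_flanks(
                ev, transcripts_by_species[sp], genomes[sp], sp, min_len, max_len
            )
            flanks.extend(fp)
            excluded.extend(f"{sp}: {r}" for r in reasons)
    for r in excluded:
        logger.info("flank extraction: excluded %s", r)
    return flanks, excluded


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


@dataclass
class FlankScorer:
    """Local nucleotide alignment scorer standing in for a translated search.

    A pair of flanks matches when the optimal local alignment (+1 match,
    -1 mismatch, -2 gap open, -1 gap extend) spans at least ``min_len``
    columns, at least ``min_coverage`` of the shorter sequence, with
    identity >= ``min_identity`` over its columns.  The defaults separate
    flanks that descend from a common ancestor with up to ~0.15 per-lineage
    substitutions from pairs diverged at 0.3 or more (and from unrelated
    sequence).
    """

    min_identity: float = 0.7
    min_len: int = 30
    min_coverage: float = 0.5
    _aligner: Align.PairwiseAligner = field(init=False, repr=False)

    def __post_init__(self) -> None:
        a = Align.PairwiseAligner(mode="local")
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -2
        a.extend_gap_score = -1
        self._aligner = a

    def similar(self, s1: str, s2: str) -> bool:
        if not s1 or not s2:
            return False
        alignments = self._aligner.align(s1, s2)
        try:
            best = alignments[0]
        except IndexError:
            return False
        columns = best.length
        if columns < self.min_len:
            return False
        if columns < self.min_coverage * min(len(s1), len(s2)):
            return False
        counts = best.counts()
        identity = counts.identities / columns if columns else 0.0
        return identity >= self.min_identity


@dataclass(frozen=True)
class FlankMatch:
    event_a: tuple[str, str]  # (species, event_id)
    event_b: tuple[str, str]
    etype: str


def pairwise_flank_similarity(
    flanks: Sequence[FlankPair],
    scorer: FlankScorer | None = None,
    candidate_pairs: set[frozenset[tuple[str, str]]] | None = None,
) -> list[FlankMatch]:
    """Cross-species event matches within each AS-type dataset.

    Two events match when, for some junction of each, both the upstream and
    the downstream flanks are similar.  ``candidate_pairs`` optionally
    restricts the comparison (e.g. to co-orthogroup genes) without changing
    the result for the retained pairs.
    """
    scorer = scorer or FlankScorer()
    by_type: dict[str, list[FlankPair]] = {}
    for f in flanks:
        by_type.setdefault(f.etype, []).append(f)
    matches = []
    for etype in sorted(by_type):
        group = by_type[etype]
        by_event: dict[tuple[str, str], list[FlankPair]] = {}
        for f in group:
            by_event.setdefault((f.species, f.event_id), []).append(f)
        keys = sorted(by_event)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                if ka[0] == kb[0]:
                    continue  # same species
                if candidate_pairs is not None and frozenset((ka, kb)) not in candidate_pairs:
                    continue
                hit = any(
                    scorer.similar(fa.seq_up, fb.seq_up)
                    and scorer.similar(fa.seq_down, fb.seq_down)
                    for fa in by_event[ka]
                    for fb in by_event[kb]
                )
                if hit:
                    matches.append(FlankMatch(ka, kb, etype))
    return matches


def matches_from_blast_tab(
    hits: pd.DataFrame, etype_of_event: Mapping[tuple[str, str], str]
) -> list[FlankMatch]:
    """Adapter: build event matches from an external flank-vs-flank search.

    Flank record ids must follow ``<species>|<event_id>|<up|down>``; an
    event pair matches when both the up and the down flanks hit each other.
    """
    sides: dict[frozenset, set[str]] = {}
    for q, s in zip(hits["qseqid"], hits["sseqid"]):
        qsp, qev, qside = q.split("|")
        ssp, sev, sside = s.split("|")
        if qsp == ssp or qside != sside:
            continue
        sides.setdefault(
            frozenset(((qsp, qev), (ssp, sev))), set()
        ).add(qside)
    out = []
    for pair, got in sorted(sides.items(), key=lambda kv: sorted(kv[0])):
        if {"up", "down"} <= got:
            a, b = sorted(pair)
            out.append(FlankMatch(a, b, etype_of_event[a]))
    return out


# ---------------------------------------------------------------------------
# conserved clusters and the counts matrix
# ---------------------------------------------------------------------------


@dataclass
class ConservedCountsSummary:
    counts: pd.DataFrame  # species x type
    species_totals: pd.Series
    species_pct: pd.Series
    type_totals: pd.Series
    type_pct: pd.Series
    grand_total: int

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy().astype(object)
        out["All"] = self.species_totals
        out["pct"] = self.species_pct.round(2)
        total_row = {t: self.type_totals[t] for t in self.counts.columns}
        total_row["All"] = self.grand_total
        total_row["pct"] = 100.0
        out.loc["All"] = total_row
        out.loc["pct", list(self.counts.columns)] = self.type_pct.round(2)
        return out


def summarize_counts(counts: pd.DataFrame) -> ConservedCountsSummary:
    """Row/column totals and percentages of the grand total (Table-4 shape)."""
    species_totals = counts.sum(axis=1)
    type_totals = counts.sum(axis=0)
    grand = int(counts.to_numpy().sum())
    denom = grand if grand else 1
    return ConservedCountsSummary(
        counts=counts,
        species_totals=species_totals,
        species_pct=100.0 * species_totals / denom,
        type_totals=type_totals,
        type_pct=100.0 * type_totals / denom,
        grand_total=grand,
    )


@dataclass
class ConservedResult:
    clusters: list[ConservedCluster]
    conserved_events: set[tuple[str, str]]  # (species, event_id) with >=1 link
    summary: ConservedCountsSummary
    skipped_genes: list[str]


def detect_conserved(
    events_by_species: Mapping[str, Sequence[ASEvent]],
    orthogroups: Iterable[Orthogroup],
    matches: Sequence[FlankMatch],
) -> ConservedResult:
    """Link flank-matched, co-orthogroup events and cluster them."""
    gene_og: dict[str, str] = {}
    for og in orthogroups:
        for genes in og.members.values():
            for g in genes:
                gene_og[g] = og.og_id
    ev_meta: dict[tuple[str, str], ASEvent] = {}
    skipped = []
    for sp, evs in events_by_species.items():
        for ev in evs:
            if ev.gene_id not in gene_og:
                skipped.append(f"{sp}:{ev.gene_id}")
                continue
            ev_meta[(sp, ev.event_id)] = ev
    for s in skipped:
        logger.info("conserved-AS: gene %s absent from orthogroups; skipped", s)

    graph = nx.Graph()
    for m in matches:
        ea, eb = ev_meta.get(m.event_a), ev_meta.get(m.event_b)
        if ea is None or eb is None:
            continue
        if ea.etype != eb.etype:
            continue
        if gene_og[ea.gene_id] != gene_og[eb.gene_id]:
            continue
        graph.add_edge(m.event_a, m.event_b)

    clusters = []
    for comp in nx.connected_components(graph):
        members = frozenset(
            (sp, ev_meta[(sp, eid)].gene_id, eid) for sp, eid in comp
        )
        etypes = {ev_meta[k].etype for k in comp}
        clusters.append(
            ConservedCluster(
                members=members,
                etype=etypes.pop(),
                orthogroups=frozenset(
                    gene_og[ev_meta[k].gene_id] for k in comp
                ),
            )
        )
    clusters.sort(key=lambda c: sorted(c.members))

    conserved = {node for node in graph.nodes if graph.degree(node) > 0}
    species = sorted(events_by_species)
    counts = pd.DataFrame(0, index=species, columns=list(TYPE_ORDER))
    for sp, eid in conserved:
        counts.loc[sp, ev_meta[(sp, eid)].etype] += 1
    return ConservedResult(
        clusters=clusters,
        conserved_events=conserved,
        summary=summarize_counts(counts),
        skipped_genes=skipped,
    )


def call_highly_conserved(
    clusters: Sequence[ConservedCluster], species: Iterable[str]
) -> list[ConservedCluster]:
    """Clusters whose members span every analysed species."""
    full = frozenset(species)
    out = []
    for c in clusters:
        c.highly_conserved = c.species_set == full
        if c.highly_conserved:
            out.append(c)
    return out


def conserved_psi_contrast(
    stage_psi: pd.DataFrame,
    conserved_ids: set[str],
    immature: str = "immature",
    ripe: str = "ripe",
) -> dict[str, dict]:
    """Stage-wise PSI comparison for conserved vs nonconserved events.

    Returns, per group, the two stage samples and the Wilcoxon rank-sum
    result.  The conserved contrast is omitted (with a warning) when no
    conserved event has PSI data.
    """
    out: dict[str, dict] = {}
    for name, ids in (
        ("conserved", [i for i in stage_psi.index if i in conserved_ids]),
        ("nonconserved", [i for i in stage_psi.index if i not in conserved_ids]),
    ):
        sub = stage_psi.loc[ids, [immature, ripe]].dropna()
        if sub.empty:
            logger.warning("PSI contrast: no %s events with PSI; omitted", name)
            continue
        imm = sub[immature].to_numpy()
        rip = sub[ripe].to_numpy()
        stat, p = wilcoxon_rank_sum(imm, rip, alternative="two-sided")
        out[name] = {
            "immature": imm,
            "ripe": rip,
            "statistic": stat,
            "pvalue": p,
            "n": len(sub),
        }
    return out
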