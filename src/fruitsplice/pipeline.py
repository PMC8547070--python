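"""Config-driven orchestration of the full analysis.

Each stage reads and writes declared files under the output directory, so
stages are independently re-runnable and a ``--resume`` run re-executes
only stages whose inputs (or the config) changed, tracked by content hash.

Bundle layout expected under ``input_dir`` (as written by the simulator,
or assembled from real data):

    <species>/reference.gtf, genome.fa, assembled_<stage>.gtf,
              junctions_<stage>.tsv, tpm.tsv
    orthogroups.tsv, synteny.tsv, blast_hits.tsv, homolog_map.tsv (optional)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import builder, conserved as conserved_mod, events as events_mod
from . import gtfio, orthology as ortho_mod, profiles as profiles_mod, stats
from .models import ASEvent, TranscriptModel

logger = logging.getLogger(__name__)

STAGE_NAMES = [
    "build", "events", "psi", "specific",
    "diffsplice", "orthology", "conserved", "profiles_stats",
]


class ConfigError(Exception):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(Exception):
    """Missing or malformed input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    species: list[str] | None = None
    stages: tuple[str, str] = ("immature", "ripe")
    n_replicates: int = 2
    psi_window: tuple[float, float] = (0.05, 0.95)
    tpm_min: float = 1.0
    junction_support: tuple[int, int] = (4, 10)
    dpsi_min: float = 0.1
    alpha: float = 0.05
    flank_range: tuple[int, int] = (30, 300)
    min_identity: float = 0.7
    min_match_len: int = 30
    min_coverage: float = 0.5
    linkage: str = "complete"
    orthology_mode: str = "and"
    max_evalue: float = 1e-10
    ignore_junction_strand: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.psi_window
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"psi_window {self.psi_window} not within [0, 1]")
        if self.flank_range[0] >= self.flank_range[1]:
            raise ConfigError("flank_range minimum must be below maximum")
        if self.linkage not in ("single", "average", "complete"):
            raise ConfigError(f"unsupported linkage {self.linkage!r}")
        if self.orthology_mode not in ("and", "or"):
            raise ConfigError("orthology_mode must be 'and' or 'or'")
        if self.species is None:
            root = Path(self.input_dir)
            if root.is_dir():
                self.species = sorted(
                    d.name for d in root.iterdir()
                    if d.is_dir() and (d / "reference.gtf").exists()
                )
        if not self.species:
            raise ConfigError(f"no species data found under {self.input_dir}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("stages", "psi_window", "junction_support", "flank_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def sample_columns(self, sp: str, stage: str) -> list[str]:
        return [f"{sp}_{stage}_rep{r + 1}" for r in range(self.n_replicates)]

    def in_path(self, *parts) -> Path:
        p = Path(self.input_dir).joinpath(*parts)
        if not p.exists():
            raise DataError(f"required input file missing: {p}")
        return p

    def out_path(self, *parts) -> Path:
        p = Path(self.output_dir).joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p


# ---------------------------------------------------------------------------
# event table serialization (declared stage interface)
# ---------------------------------------------------------------------------


def events_to_frame(events: Sequence[ASEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seqname": e.chrom,
                "gene_id": e.gene_id,
                "event_id": e.event_id,
                "type": e.etype,
                "strand": e.strand,
                "coords": ";".join(f"{s}-{x}" for s, x in e.coords),
                "inclusion_transcripts": ",".join(sorted(e.inclusion_transcripts)),
                "exclusion_transcripts": ",".join(sorted(e.exclusion_transcripts)),
            }
            for e in events
        ],
        columns=[
            "seqname", "gene_id", "event_id", "type", "strand", "coords",
            "inclusion_transcripts", "exclusion_transcripts",
        ],
    )


def events_from_frame(df: pd.DataFrame) -> list[ASEvent]:
    out = []
    for row in df.itertuples(index=False):
        coords = tuple(
            tuple(int(x) for x in pair.split("-")) for pair in row.coords.split(";")
        )
        out.append(
            ASEvent(
                event_id=row.event_id,
                etype=row.type,
                gene_id=row.gene_id,
                chrom=row.seqname,
                strand=row.strand,
                coords=coords,
                inclusion_transcripts=frozenset(row.inclusion_transcripts.split(",")),
                exclusion_transcripts=frozenset(row.exclusion_transcripts.split(",")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_build(cfg: PipelineConfig) -> None:
    for sp in cfg.species:
        reference = gtfio.read_gtf(cfg.in_path(sp, "reference.gtf"))
        assembled = {
            st: gtfio.read_gtf(cfg.in_path(sp, f"assembled_{st}.gtf"), stage=st)
            for st in cfg.stages
        }
        support = {
            st: gtfio.read_junction_counts(cfg.in_path(sp, f"junctions_{st}.tsv"))
            for st in cfg.stages
        }
        expr = gtfio.read_expression(cfg.in_path(sp, "tpm.tsv"))
        result = builder.build_high_quality_transcriptome(
            assembled, reference, support, expr,
            {st: cfg.sample_columns(sp, st) for st in cfg.stages},
            min_tpm=cfg.tpm_min,
            junction_thresholds=cfg.junction_support,
            ignore_junction_strand=cfg.ignore_junction_strand,
        )
        gtfio.write_gtf(cfg.out_path(sp, "transcriptome.gtf"), result.transcripts)
        result.summary.to_csv(
            cfg.out_path(sp, "build_summary.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            result.removals, columns=["stage", "transcript_id", "reason"]
        ).to_csv(cfg.out_path(sp, "build_removals.tsv"), sep="\t", index=False)


def stage_events(cfg: PipelineConfig) -> None:
    for sp in cfg.species:
        txs = gtfio.read_gtf(cfg.out_path(sp, "transcriptome.gtf"))
        events = events_mod.detect_events(txs)
        events_to_frame(events).to_csv(
            cfg.out_path(sp, "events.tsv"), sep="\t", index=False
        )


def _load_events(cfg: PipelineConfig, sp: str) -> list[ASEvent]:
    df = pd.read_csv(cfg.out_path(sp, "events.tsv"), sep="\t")
    return events_from_frame(df)


def stage_psi(cfg: PipelineConfig) -> None:
    for sp in cfg.species:
        events = _load_events(cfg, sp)
        expr = gtfio.read_expression(cfg.in_path(sp, "tpm.tsv"))
        psi = events_mod.compute_psi(events, expr)
        psi.to_csv(cfg.out_path(sp, "psi.tsv"), sep="\t", float_format="%.10g")


def stage_specific(cfg: PipelineConfig) -> None:
    lo, hi = cfg.psi_window
    for sp in cfg.species:
        psi = pd.read_csv(cfg.out_path(sp, "psi.tsv"), sep="\t", index_col="event_id")
        stage_psi = events_mod.stage_mean_psi(psi)
        occ = events_mod.call_occurrence(stage_psi, lo, hi)
        labels = events_mod.call_stage_specific(occ, *cfg.stages)
        stage_psi.to_csv(cfg.out_path(sp, "stage_psi.tsv"), sep="\t",
                         float_format="%.10g")
        occ.to_csv(cfg.out_path(sp, "occurrence.tsv"), sep="\t")
        labels.to_frame().to_csv(cfg.out_path(sp, "stage_specific.tsv"), sep="\t")


def stage_diffsplice(cfg: PipelineConfig) -> None:
    for sp in cfg.species:
        psi = pd.read_csv(cfg.out_path(sp, "psi.tsv"), sep="\t", index_col="event_id")
        events = _load_events(cfg, sp)
        expr = gtfio.read_expression(cfg.in_path(sp, "tpm.tsv"))
        res = events_mod.differential_splicing(
            psi, events, expr, alpha=cfg.alpha, min_dpsi=cfg.dpsi_min,
            immature=cfg.stages[0], ripe=cfg.stages[1],
        )
        res.table.to_csv(cfg.out_path(sp, "differential.tsv"), sep="\t",
                         float_format="%.6g")


def stage_orthology(cfg: PipelineConfig) -> None:
    ogs = ortho_mod.read_orthogroups(cfg.in_path("orthogroups.tsv"))
    hits = ortho_mod.read_blast_tab(cfg.in_path("blast_hits.tsv"))
    synteny = ortho_mod.read_synteny(cfg.in_path("synteny.tsv"))
    index = ortho_mod.resolve_one_to_one(
        ogs, hits=hits, synteny=synteny,
        max_evalue=cfg.max_evalue, mode=cfg.orthology_mode,
    )
    ortho_mod.write_orthologue_index(index, cfg.out_path("orthologue_index.tsv"))


def stage_conserved(cfg: PipelineConfig) -> None:
    events_by_sp, tx_by_sp, genomes = {}, {}, {}
    for sp in cfg.species:
        events_by_sp[sp] = _load_events(cfg, sp)
        txs = gtfio.read_gtf(cfg.out_path(sp, "transcriptome.gtf"))
        tx_by_sp[sp] = {t.transcript_id: t for t in txs}
        genomes[sp] = gtfio.read_genome_fasta(cfg.in_path(sp, "genome.fa"))
    flanks, _ = conserved_mod.extract_all_flanks(
        events_by_sp, tx_by_sp, genomes,
        min_len=cfg.flank_range[0], max_len=cfg.flank_range[1],
    )
    scorer = conserved_mod.FlankScorer(
        min_identity=cfg.min_identity,
        min_len=cfg.min_match_len,
        min_coverage=cfg.min_coverage,
    )
    matches = conserved_mod.pairwise_flank_similarity(flanks, scorer)
    ogs = ortho_mod.read_orthogroups(cfg.in_path("orthogroups.tsv"))
    result = conserved_mod.detect_conserved(events_by_sp, ogs, matches)
    conserved_mod.call_highly_conserved(result.clusters, cfg.species)
    rows = [
        {
            "cluster_id": i,
            "species": sp,
            "gene_id": g,
            "event_id": eid,
            "type": c.etype,
            "highly_conserved": c.highly_conserved,
        }
        for i, c in enumerate(result.clusters)
        for sp, g, eid in sorted(c.members)
    ]
    pd.DataFrame(
        rows,
        columns=["cluster_id", "species", "gene_id", "event_id", "type",
                 "highly_conserved"],
    ).to_csv(cfg.out_path("conserved_clusters.tsv"), sep="\t", index=False)
    result.summary.to_frame().to_csv(cfg.out_path("conserved_counts.tsv"), sep="\t")
    pd.DataFrame(
        sorted(result.conserved_events), columns=["species", "event_id"]
    ).to_csv(cfg.out_path("conserved_events.tsv"), sep="\t", index=False)


def stage_profiles_stats(cfg: PipelineConfig) -> None:
    index = pd.read_csv(
        cfg.out_path("orthologue_index.tsv"), sep="\t", index_col="orthologue"
    )
    psi_by_sp, events_by_sp = {}, {}
    for sp in cfg.species:
        psi_by_sp[sp] = pd.read_csv(
            cfg.out_path(sp, "psi.tsv"), sep="\t", index_col="event_id"
        )
        events_by_sp[sp] = _load_events(cfg, sp)
    prof = profiles_mod.build_profiles(
        psi_by_sp, events_by_sp, index, *cfg.psi_window
    )
    prof.to_csv(cfg.out_path("profiles.tsv"), sep="\t")
    dist = profiles_mod.binary_distance(prof)
    dist.to_csv(cfg.out_path("distance.tsv"), sep="\t", float_format="%.10g")
    clustering = profiles_mod.hierarchical_cluster(dist, method=cfg.linkage)
    cfg.out_path("dendrogram.nwk").write_text(clustering.newick + "\n")
    ss = profiles_mod.species_specific_as_genes(prof, index)
    pd.DataFrame(
        [
            {"species": sp, "orthologue": o, "gene_id": index.loc[o, sp]}
            for sp, orths in ss.items()
            for o in orths
        ],
        columns=["species", "orthologue", "gene_id"],
    ).to_csv(cfg.out_path("species_specific_orthologues.tsv"), sep="\t", index=False)

    # statistics report: per-species stage contrast of occurrence counts
    stat_rows = []
    for sp in cfg.species:
        occ = pd.read_csv(
            cfg.out_path(sp, "occurrence.tsv"), sep="\t", index_col="event_id"
        ).astype(bool)
        imm, rip = cfg.stages
        table = [
            [int(occ[imm].sum()), int((~occ[imm]).sum())],
            [int(occ[rip].sum()), int((~occ[rip]).sum())],
        ]
        odds, p = stats.fisher_exact_2x2(table)
        stat_rows.append(
            {
                "test": "fisher_occurrence_by_stage",
                "group": sp,
                "n": int(occ.shape[0]),
                "statistic": odds,
                "pvalue": p,
            }
        )
    conserved_ids = set()
    ce_path = Path(cfg.output_dir) / "conserved_events.tsv"
    if ce_path.exists():
        ce = pd.read_csv(ce_path, sep="\t")
        conserved_ids = set(ce["event_id"])
    stage_psi_all = pd.concat(
        [
            pd.read_csv(cfg.out_path(sp, "stage_psi.tsv"), sep="\t",
                        index_col="event_id")
            for sp in cfg.species
        ]
    )
    contrast = conserved_mod.conserved_psi_contrast(
        stage_psi_all, conserved_ids, *cfg.stages
    )
    for group, res in contrast.items():
        stat_rows.append(
            {
                "test": "wilcoxon_psi_stage_contrast",
                "group": group,
                "n": res["n"],
                "statistic": res["statistic"],
                "pvalue": res["pvalue"],
            }
        )
    pd.DataFrame(
        stat_rows, columns=["test", "group", "n", "statistic", "pvalue"]
    ).to_csv(cfg.out_path("stats_report.tsv"), sep="\t", index=False)

    hom_path = Path(cfg.input_dir) / "homolog_map.tsv"
    if hom_path.exists():
        hom = pd.read_csv(hom_path, sep="\t")
        ss_rows = []
        gene_of = {}
        for sp in cfg.species:
            for e in events_by_sp[sp]:
                gene_of[(sp, e.event_id)] = e.gene_id
            lab = pd.read_csv(
                cfg.out_path(sp, "stage_specific.tsv"), sep="\t",
                index_col="event_id",
            )["label"]
            for eid, label in lab.items():
                if label.endswith("-only"):
                    ss_rows.append(
                        {
                            "species": sp,
                            "gene_id": gene_of[(sp, eid)],
                            "stage": label.replace("-only", ""),
                        }
                    )
        ss_df = pd.DataFrame(ss_rows, columns=["species", "gene_id", "stage"])
        profiles_mod.cross_reference_gene_list(ss_df, hom).to_csv(
            cfg.out_path("ripening_stage_specific.tsv"), sep="\t", index=False
        )


_STAGE_FUNCS = {
    "build": stage_build,
    "events": stage_events,
    "psi": stage_psi,
    "specific": stage_specific,
    "diffsplice": stage_diffsplice,
    "orthology": stage_orthology,
    "conserved": stage_conserved,
    "profiles_stats": stage_profiles_stats,
}


def _stage_inputs(cfg: PipelineConfig, stage: str) -> list[Path]:
    root = Path(cfg.input_dir)
    per_sp = lambda name: [root / sp / name for sp in cfg.species]
    cross = [root / "orthogroups.tsv", root / "synteny.tsv", root / "blast_hits.tsv"]
    table = {
        "build": per_sp("reference.gtf") + per_sp("tpm.tsv")
        + [root / sp / f"assembled_{st}.gtf" for sp in cfg.species for st in cfg.stages]
        + [root / sp / f"junctions_{st}.tsv" for sp in cfg.species for st in cfg.stages],
        "events": [],
        "psi": per_sp("tpm.tsv"),
        "specific": [],
        "diffsplice": per_sp("tpm.tsv"),
        "orthology": cross,
        "conserved": per_sp("genome.fa") + [root / "orthogroups.tsv"],
        "profiles_stats": [root / "homolog_map.tsv"],
    }
    return [p for p in table[stage] if p.exists()]


def run_all(cfg: PipelineConfig, resume: bool = False) -> pd.DataFrame:
    """Execute all stages in order; returns the run report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hash_file = out / ".stage_hashes.json"
    old_hashes = {}
    if resume and hash_file.exists():
        old_hashes = json.loads(hash_file.read_text())
    new_hashes, report = {}, []
    chash = cfg.config_hash()
    for stage in STAGE_NAMES:
        h = hashlib.sha256(chash.encode())
        for p in sorted(_stage_inputs(cfg, stage)):
            h.update(p.name.encode())
            h.update(p.read_bytes())
        # downstream stages depend on upstream results through their files;
        # fold upstream hashes in so edits propagate
        for prev in report:
            h.update(prev["hash"].encode())
        digest = h.hexdigest()
        new_hashes[stage] = digest
        if resume and old_hashes.get(stage) == digest:
            status = "skipped"
        else:
            try:
                _STAGE_FUNCS[stage](cfg)
                status = "completed"
            except (ConfigError, DataError):
                raise
            except FileNotFoundError as exc:
                raise DataError(f"stage {stage}: {exc}") from exc
        logger.info("stage %s: %s", stage, status)
        report.append({"stage": stage, "status": status, "hash": digest,
                       "config_hash": chash})
    hash_file.write_text(json.dumps(new_hashes, indent=1))
    df = pd.DataFrame(report)
    df.to_csv(out / "run_report.tsv", sep="\t", index=False)
    return df
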