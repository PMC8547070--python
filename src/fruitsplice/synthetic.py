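"""Synthetic multi-species fruit-development bundle with planted ground truth.

The generator emulates the comparative study design this package analyses:
four fleshy-fruit species, two developmental stages (immature, ripe), two
replicates per stage.  For each orthogroup it draws one shared gene
architecture (4-8 exons of 120-400 bp, introns 80-2000 bp) and plants local
AS events (IR / ES / A3SS / A5SS) with known per-stage PSI, conserved events
whose flanking sequences descend from a common ancestor mutated at a
configurable divergence, assembly artefacts exercising every quality filter,
and the cross-species orthology tables (orthogroups, BLAST-style hits,
synteny pairs).

All randomness flows from one ``numpy`` generator seeded by ``config.seed``;
two runs with the same config produce byte-identical output bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gtfio
from .models import EVENT_TYPES, TranscriptModel, event_id_string

STAGES = ("immature", "ripe")
DEFAULT_SPECIES = ("cucumber", "melon", "papaya", "peach")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G on 0..3 codes


# ---------------------------------------------------------------------------
# configuration and ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic bundle.

    ``event_mix`` is the probability of each AS type for a planted event;
    the default reflects the plant-typical predominance of intron retention.
    ``flank_divergence`` is the per-site substitution probability applied,
    per species, to the ancestral sequence of a conserved-event gene.
    ``psi_noise_sd`` jitters replicate PSI on the logit scale.
    """

    n_species: int = 4
    n_orthogroups: int = 48
    genes_per_species_extra: int = 8
    event_mix: dict[str, float] = field(
        default_factory=lambda: {"IR": 0.40, "ES": 0.15, "A3SS": 0.25, "A5SS": 0.20}
    )
    frac_conserved_events: float = 0.25
    frac_as_orthogroups: float = 0.50
    frac_stage_specific: float = 0.40
    flank_divergence: float = 0.10
    n_stages: int = 2
    n_replicates: int = 2
    tpm_depth: float = 100.0
    psi_noise_sd: float = 0.05
    frac_artifact_transcripts: float = 0.10
    frac_multi_copy: float = 0.10
    n_merge_variants: int = 2
    frac_extra_as: float = 0.30
    profile_mode: str = "species"
    species_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_conserved_events",
            "frac_as_orthogroups",
            "frac_stage_specific",
            "flank_divergence",
            "frac_artifact_transcripts",
            "frac_multi_copy",
            "frac_extra_as",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event_mix must sum to 1")
        if set(self.event_mix) - set(EVENT_TYPES):
            raise ValueError(f"unknown AS types in event_mix: {self.event_mix}")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_orthogroups < 1:
            raise ValueError("n_orthogroups must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.tpm_depth <= 0:
            raise ValueError("tpm_depth must be positive")
        if self.profile_mode not in ("species", "stage"):
            raise ValueError("profile_mode must be 'species' or 'stage'")
        if self.species_names is None:
            if self.n_species <= len(DEFAULT_SPECIES):
                self.species_names = DEFAULT_SPECIES[: self.n_species]
            else:
                extra = tuple(
                    f"species{i + 1}"
                    for i in range(len(DEFAULT_SPECIES), self.n_species)
                )
                self.species_names = DEFAULT_SPECIES + extra
        self.species_names = tuple(self.species_names)
        if len(self.species_names) != self.n_species:
            raise ValueError("species_names length must equal n_species")


@dataclass(frozen=True)
class PlantedEvent:
    species: str
    gene_id: str
    etype: str
    chrom: str
    strand: str
    coords: tuple[tuple[int, int], ...]
    event_id: str
    psi: dict[str, float]  # stage -> true PSI
    conserved_cluster: int | None = None

    def label(self, lo: float = 0.05, hi: float = 0.95) -> str:
        occ = {s: lo <= p <= hi for s, p in self.psi.items()}
        if all(occ.values()):
            return "both"
        if not any(occ.values()):
            return "neither"
        on = [s for s, o in occ.items() if o][0]
        return f"{on}-only"


@dataclass
class GroundTruth:
    planted_events: list[PlantedEvent]
    conserved_clusters: list[list[tuple[str, str, str]]]
    stage_specific_labels: dict[tuple[str, str], str]
    filter_fates: dict[tuple[str, str], tuple[str, str]]
    orthologue_index: pd.DataFrame

    def __post_init__(self) -> None:
        ids = {(e.species, e.event_id) for e in self.planted_events}
        for cluster in self.conserved_clusters:
            if len({sp for sp, _, _ in cluster}) < 2:
                raise ValueError("conserved cluster spans < 2 species")
            for sp, _, eid in cluster:
                if (sp, eid) not in ids:
                    raise ValueError(f"cluster member {(sp, eid)} not planted")
        for key in self.stage_specific_labels:
            if key not in ids:
                raise ValueError(f"label for unplanted event {key}")

    def events_by_species(self) -> dict[str, list[PlantedEvent]]:
        out: dict[str, list[PlantedEvent]] = {}
        for e in self.planted_events:
            out.setdefault(e.species, []).append(e)
        return out


@dataclass
class SpeciesData:
    genome: dict[str, str]
    reference: list[TranscriptModel]
    assembled: dict[str, list[TranscriptModel]]  # stage -> transcripts
    expression: pd.DataFrame
    junctions: dict[str, dict]  # stage -> junction -> (c1, c2)


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    species: dict[str, SpeciesData]
    orthogroup_members: dict[str, dict[str, list[str]]]
    blast_hits: pd.DataFrame
    synteny: pd.DataFrame
    homolog_map: pd.DataFrame

    def sample_names(self, species: str) -> list[str]:
        return [
            f"{species}_{stage}_rep{r + 1}"
            for stage in STAGES[: self.config.n_stages]
            for r in range(self.config.n_replicates)
        ]


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    if rate <= 0:
        return out
    hit = rng.random(len(codes)) < rate
    shift = rng.integers(1, 4, int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# gene architecture in transcription space
# ---------------------------------------------------------------------------


@dataclass
class _EventPlan:
    etype: str
    k: int  # exon index (ES) or intron index (IR/A5SS/A3SS), transcription order
    delta: int  # boundary shift for A5SS/A3SS
    psi: dict[str, dict[str, float]] = field(default_factory=dict)  # sp -> stage -> psi
    species: list[str] = field(default_factory=list)
    cluster: int | None = None


@dataclass
class _Arch:
    exon_lens: np.ndarray
    intron_lens: np.ndarray

    @property
    def length(self) -> int:
        return int(self.exon_lens.sum() + self.intron_lens.sum())

    def rel_exons(self) -> list[tuple[int, int]]:
        out, pos = [], 0
        for i, el in enumerate(self.exon_lens):
            out.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(self.intron_lens):
                pos += int(self.intron_lens[i])
        return out

    def rel_intron(self, k: int) -> tuple[int, int]:
        ex = self.rel_exons()
        return (ex[k][1], ex[k + 1][0])


def _alt_rel_exons(arch: _Arch, plan: _EventPlan) -> list[tuple[int, int]]:
    ex = arch.rel_exons()
    if plan.etype == "IR":
        k = plan.k
        merged = (ex[k][0], ex[k + 1][1])
        return ex[:k] + [merged] + ex[k + 2 :]
    if plan.etype == "ES":
        return ex[: plan.k] + ex[plan.k + 1 :]
    if plan.etype == "A5SS":  # upstream exon extended delta into intron k
        k = plan.k
        out = list(ex)
        out[k] = (ex[k][0], ex[k][1] + plan.delta)
        return out
    if plan.etype == "A3SS":  # downstream exon extended delta into intron k
        k = plan.k
        out = list(ex)
        out[k + 1] = (ex[k + 1][0] - plan.delta, ex[k + 1][1])
        return out
    raise AssertionError(plan.etype)


def _map_rel(
    rel: list[tuple[int, int]], length: int, start: int, strand: str
) -> tuple[tuple[int, int], ...]:
    if strand == "+":
        return tuple((start + a, start + b) for a, b in rel)
    return tuple(sorted((start + length - b, start + length - a) for a, b in rel))


def _event_coords(
    arch: _Arch, plan: _EventPlan, start: int, strand: str
) -> tuple[tuple[int, int], ...]:
    """Genomic canonical coordinates of a planted event (detector-independent)."""
    L = arch.length

    def g(pair: tuple[int, int]) -> tuple[int, int]:
        return _map_rel([pair], L, start, strand)[0]

    if plan.etype == "IR":
        return (g(arch.rel_intron(plan.k)),)
    if plan.etype == "ES":
        return tuple(sorted([g(arch.rel_intron(plan.k - 1)), g(arch.rel_intron(plan.k))]))
    i_s, i_e = arch.rel_intron(plan.k)
    if plan.etype == "A5SS":
        alt = (i_s + plan.delta, i_e)
    else:  # A3SS
        alt = (i_s, i_e - plan.delta)
    return tuple(sorted([g((i_s, i_e)), g(alt)]))


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def _logit_jitter(rng: np.random.Generator, psi: float, sd: float) -> float:
    if sd <= 0 or psi <= 0.0 or psi >= 1.0:
        return float(psi)
    z = np.log(psi / (1 - psi)) + rng.normal(0.0, sd)
    return float(1.0 / (1.0 + np.exp(-z)))


def simulate_quantification(
    true_psi: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_replicates: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw inclusion/exclusion TPMs whose expected recomputed PSI is ``true_psi``.

    Returns arrays of length ``n_replicates`` (default ``config.n_replicates``).
    """
    if not 0.0 <= true_psi <= 1.0:
        raise ValueError(f"true_psi={true_psi} outside [0, 1]")
    if config.tpm_depth <= 0:
        raise ValueError("tpm_depth must be positive")
    rng = rng or np.random.default_rng(config.seed)
    n = n_replicates if n_replicates is not None else config.n_replicates
    incl, excl = np.empty(n), np.empty(n)
    for r in range(n):
        p = _logit_jitter(rng, true_psi, config.psi_noise_sd)
        incl[r] = config.tpm_depth * p
        excl[r] = config.tpm_depth * (1.0 - p)
    return incl, excl


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


class _GenePlanted:
    """Per-species realisation of one gene."""

    def __init__(self, gene_id, arch, strand, start, plan=None):
        self.gene_id = gene_id
        self.arch = arch
        self.strand = strand
        self.start = start
        self.plan = plan  # _EventPlan or None (only if this species is a member)


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> tuple[SimulatedBundle, GroundTruth]:
    """Generate the full multi-species bundle and its ground truth.

    When ``outdir`` is given the bundle is also written to disk in the
    documented text formats, together with a ``manifest/`` directory.
    """
    if config.n_stages != 2:
        raise ValueError("the fruit-development design has exactly 2 stages")
    if config.n_replicates != 2:
        raise ValueError("junction-support filtering assumes exactly 2 replicates")
    rng = np.random.default_rng(config.seed)
    species = list(config.species_names)
    stages = list(STAGES)
    n_og = config.n_orthogroups
    types = list(EVENT_TYPES)
    mix = np.array([config.event_mix.get(t, 0.0) for t in types])

    # ---- orthogroup-level draws (shared across species) -------------------
    n_cons = int(round(config.frac_conserved_events * n_og))
    cons_ogs = sorted(rng.choice(n_og, n_cons, replace=False).tolist())
    remaining = [i for i in range(n_og) if i not in set(cons_ogs)]
    n_as = int(round(config.frac_as_orthogroups * len(remaining)))
    as_ogs = sorted(
        rng.choice(len(remaining), n_as, replace=False).tolist()
    )
    as_ogs = [remaining[i] for i in as_ogs]
    n_ss = int(round(config.frac_stage_specific * len(as_ogs)))
    ss_ogs = set(
        as_ogs[i] for i in sorted(rng.choice(len(as_ogs), n_ss, replace=False).tolist())
    ) if as_ogs else set()

    archs: list[_Arch] = []
    for _ in range(n_og):
        ne = int(rng.integers(4, 9))
        archs.append(
            _Arch(
                exon_lens=rng.integers(120, 401, ne),
                intron_lens=rng.integers(80, 2001, ne - 1),
            )
        )

    def _draw_plan(og: int, etype: str) -> _EventPlan:
        arch = archs[og]
        n_ex = len(arch.exon_lens)
        if etype == "IR":
            k = int(np.argmin(arch.intron_lens))  # retained introns run short
            return _EventPlan(etype, k, 0)
        if etype == "ES":
            k = int(rng.integers(1, n_ex - 1))
            return _EventPlan(etype, k, 0)
        k = int(rng.integers(0, n_ex - 1))
        ilen = int(arch.intron_lens[k])
        hi = min(90, ilen - 40)
        delta = int(rng.integers(30, max(31, hi + 1)))
        return _EventPlan(etype, k, delta)

    cluster_id = 0
    plans: dict[int, _EventPlan] = {}
    for og in cons_ogs:
        etype = str(rng.choice(types, p=mix))
        plan = _draw_plan(og, etype)
        size = int(rng.integers(2, config.n_species + 1))
        members = sorted(rng.choice(config.n_species, size, replace=False).tolist())
        plan.species = [species[i] for i in members]
        plan.cluster = cluster_id
        cluster_id += 1
        p = float(rng.uniform(0.35, 0.65))  # conserved events: no stage bias
        for sp in plan.species:
            plan.psi[sp] = {st: p for st in stages}
        plans[og] = plan

    for og in as_ogs:
        etype = str(rng.choice(types, p=mix))
        plan = _draw_plan(og, etype)
        if config.profile_mode == "stage":
            plan.species = list(species)
            on = str(rng.choice(stages))
            off = 0.99 if rng.random() < 0.5 else 0.01
            for sp in plan.species:
                plan.psi[sp] = {st: (0.5 if st == on else off) for st in stages}
        else:
            plan.species = [str(rng.choice(species))]
            sp = plan.species[0]
            if og in ss_ogs:
                on = str(rng.choice(stages))
                off = 0.99 if rng.random() < 0.5 else 0.01
                plan.psi[sp] = {st: (0.5 if st == on else off) for st in stages}
            elif rng.random() < 0.5:
                p = float(rng.uniform(0.15, 0.85))
                plan.psi[sp] = {st: p for st in stages}
            else:
                plan.psi[sp] = {st: float(rng.uniform(0.15, 0.85)) for st in stages}
        plans[og] = plan

    # ancestral sequences for conserved-event genes
    ancestors: dict[int, np.ndarray] = {
        og: _random_codes(rng, archs[og].length) for og in cons_ogs
    }

    n_multi = int(round(config.frac_multi_copy * n_og))
    dup_candidates = [i for i in range(n_og) if i not in plans]
    dup_ogs = sorted(
        rng.choice(dup_candidates, min(n_multi, len(dup_candidates)), replace=False).tolist()
    )
    dup_species = {og: str(rng.choice(species)) for og in dup_ogs}

    # extra species-specific genes
    extra_archs: dict[str, list[_Arch]] = {}
    extra_plans: dict[str, list[_EventPlan | None]] = {}
    for sp in species:
        extra_archs[sp], extra_plans[sp] = [], []
        for _ in range(config.genes_per_species_extra):
            ne = int(rng.integers(4, 9))
            arch = _Arch(rng.integers(120, 401, ne), rng.integers(80, 2001, ne - 1))
            extra_archs[sp].append(arch)
            if rng.random() < config.frac_extra_as:
                etype = str(rng.choice(types, p=mix))
                n_ex = len(arch.exon_lens)
                if etype == "IR":
                    plan = _EventPlan(etype, int(np.argmin(arch.intron_lens)), 0)
                elif etype == "ES":
                    plan = _EventPlan(etype, int(rng.integers(1, n_ex - 1)), 0)
                else:
                    k = int(rng.integers(0, n_ex - 1))
                    hi = min(90, int(arch.intron_lens[k]) - 40)
                    plan = _EventPlan(etype, k, int(rng.integers(30, max(31, hi + 1))))
                plan.species = [sp]
                p = float(rng.uniform(0.15, 0.85))
                plan.psi[sp] = {st: p for st in stages}
                extra_plans[sp].append(plan)
            else:
                extra_plans[sp].append(None)

    # ---- per-species realisation ------------------------------------------
    planted: list[PlantedEvent] = []
    clusters: dict[int, list[tuple[str, str, str]]] = {}
    fates: dict[tuple[str, str], tuple[str, str]] = {}
    species_data: dict[str, SpeciesData] = {}
    chrom = "chr1"

    for sp in species:
        genes: list[_GenePlanted] = []
        segments: list[np.ndarray] = []
        cursor = 0

        def place(gene_id, arch, codes, plan=None):
            nonlocal cursor
            gap = int(rng.integers(500, 2001))
            segments.append(_random_codes(rng, gap))
            cursor += gap
            strand = "+" if rng.random() < 0.5 else "-"
            seg = codes if strand == "+" else _revcomp(codes)
            segments.append(seg)
            g = _GenePlanted(gene_id, arch, strand, cursor, plan)
            cursor += arch.length
            genes.append(g)
            return g

        for og in range(n_og):
            gid = f"{sp}_g{og:04d}"
            plan = plans.get(og)
            member = plan is not None and sp in plan.species
            if og in ancestors and member:
                codes = _mutate(rng, ancestors[og], config.flank_divergence)
            else:
                codes = _random_codes(rng, archs[og].length)
            place(gid, archs[og], codes, plan if member else None)
        for og in dup_ogs:
            if dup_species[og] == sp:
                place(f"{sp}_g{og:04d}b", archs[og], _random_codes(rng, archs[og].length))
        for j, arch in enumerate(extra_archs[sp]):
            place(f"{sp}_x{j:03d}", arch, _random_codes(rng, arch.length),
                  extra_plans[sp][j])
        segments.append(_random_codes(rng, 500))
        genome = {chrom: _codes_to_str(np.concatenate(segments))}

        # --- transcript construction ---
        reference: list[TranscriptModel] = []
        base_by_stage: dict[str, list[TranscriptModel]] = {st: [] for st in stages}

        def tmodel(tid, g, rel, stage=None):
            return TranscriptModel(
                transcript_id=tid,
                gene_id=g.gene_id,
                chrom=chrom,
                strand=g.strand,
                exons=_map_rel(rel, g.arch.length, g.start, g.strand),
                stage=stage,
            )

        event_genes: list[_GenePlanted] = []
        quiet_genes: list[_GenePlanted] = []
        for g in genes:
            rel = g.arch.rel_exons()
            reference.append(tmodel(f"{g.gene_id}.ref", g, rel))
            for st in stages:
                base_by_stage[st].append(tmodel(f"{g.gene_id}.t1", g, rel, st))
            if g.plan is not None:
                alt = _alt_rel_exons(g.arch, g.plan)
                for st in stages:
                    base_by_stage[st].append(tmodel(f"{g.gene_id}.t2", g, alt, st))
                event_genes.append(g)
                coords = _event_coords(g.arch, g.plan, g.start, g.strand)
                eid = event_id_string(g.gene_id, g.plan.etype, chrom, g.strand, coords)
                pe = PlantedEvent(
                    species=sp,
                    gene_id=g.gene_id,
                    etype=g.plan.etype,
                    chrom=chrom,
                    strand=g.strand,
                    coords=coords,
                    event_id=eid,
                    psi=dict(g.plan.psi[sp]),
                    conserved_cluster=g.plan.cluster,
                )
                planted.append(pe)
                if g.plan.cluster is not None:
                    clusters.setdefault(g.plan.cluster, []).append(
                        (sp, g.gene_id, eid)
                    )
                fates[(sp, f"{g.gene_id}.t1")] = ("kept", "")
                fates[(sp, f"{g.gene_id}.t2")] = ("kept", "")
            else:
                quiet_genes.append(g)
                fates[(sp, f"{g.gene_id}.t1")] = ("kept", "")

        # --- merge variants: same intron chain, longer terminal exon at ripe
        n_mv = min(config.n_merge_variants, len(quiet_genes))
        mv_idx = sorted(rng.choice(len(quiet_genes), n_mv, replace=False).tolist())
        mv_genes = [quiet_genes[i] for i in mv_idx]
        for g in mv_genes:
            rel = g.arch.rel_exons()
            if g.strand == "+":
                rel = rel[:-1] + [(rel[-1][0], rel[-1][1] + 30)]
                exons = _map_rel(rel, g.arch.length, g.start, g.strand)
            else:  # extend the genomically-last exon (transcription 5' end)
                exons = list(_map_rel(rel, g.arch.length, g.start, g.strand))
                exons[-1] = (exons[-1][0], exons[-1][1] + 30)
                exons = tuple(exons)
            long_t = TranscriptModel(
                transcript_id=f"{g.gene_id}.t1L",
                gene_id=g.gene_id,
                chrom=chrom,
                strand=g.strand,
                exons=exons,
                stage="ripe",
            )
            base_by_stage["ripe"] = [
                t for t in base_by_stage["ripe"]
                if t.transcript_id != f"{g.gene_id}.t1"
            ] + [long_t]
            fates[(sp, f"{g.gene_id}.t1")] = ("removed", "MERGE")
            fates[(sp, f"{g.gene_id}.t1L")] = ("kept", "")

        # --- artefacts -----------------------------------------------------
        assembled: dict[str, list[TranscriptModel]] = {
            st: list(base_by_stage[st]) for st in stages
        }
        low_junctions: dict[str, set] = {st: set() for st in stages}
        art_hosts = [g for g in quiet_genes if g not in mv_genes]
        flavours = ["JUNC", "TPM", "CLASS", "MONO"]
        class_sub = ["u", "x", "s"]
        tpm_artifacts: dict[str, list[str]] = {st: [] for st in stages}
        good_artifacts: list[str] = []
        ci = 0
        for st in stages:
            n_art = int(round(config.frac_artifact_transcripts * len(base_by_stage[st])))
            order = rng.permutation(len(art_hosts)) if art_hosts else []
            for a in range(n_art):
                if not art_hosts or a >= 4 * len(art_hosts):
                    break  # not enough event-free hosts for more artefacts
                flavour = flavours[a % 4]
                g = art_hosts[order[a % len(art_hosts)]]
                gx = list(
                    TranscriptModel(
                        "tmp", g.gene_id, chrom, g.strand,
                        _map_rel(g.arch.rel_exons(), g.arch.length, g.start, g.strand),
                    ).exons
                )
                if flavour == "JUNC":
                    k = len(gx) // 2
                    skip = gx[:k] + gx[k + 1 :]
                    tid = f"{g.gene_id}.aJ.{st}"
                    t = TranscriptModel(tid, g.gene_id, chrom, g.strand, tuple(skip), st)
                    low_junctions[st].add((chrom, gx[k - 1][1], gx[k + 1][0], g.strand))
                    good_artifacts.append(tid)
                elif flavour == "TPM":
                    ext = gx[:-1] + [(gx[-1][0], gx[-1][1] + 40)]
                    tid = f"{g.gene_id}.aT.{st}"
                    t = TranscriptModel(tid, g.gene_id, chrom, g.strand, tuple(ext), st)
                    tpm_artifacts[st].append(tid)
                elif flavour == "CLASS":
                    sub = class_sub[ci % 3]
                    ci += 1
                    anti = "-" if g.strand == "+" else "+"
                    if sub == "x":
                        tid = f"{g.gene_id}.aX.{st}"
                        t = TranscriptModel(
                            tid, f"novel_{tid}", chrom, anti, (gx[0], gx[1]), st
                        )
                    elif sub == "s":
                        introns = [
                            (gx[i][1], gx[i + 1][0]) for i in range(len(gx) - 1)
                        ]
                        wide = [iv for iv in introns if iv[1] - iv[0] >= 400]
                        if wide:
                            i_s = wide[0][0]
                            tid = f"{g.gene_id}.aS.{st}"
                            t = TranscriptModel(
                                tid, f"novel_{tid}", chrom, anti,
                                ((i_s + 50, i_s + 150), (i_s + 200, i_s + 300)), st,
                            )
                        else:
                            sub = "u"
                    if sub == "u":
                        s0 = g.start - 460
                        tid = f"{g.gene_id}.aU.{st}"
                        t = TranscriptModel(
                            tid, f"novel_{tid}", chrom, "+",
                            ((s0, s0 + 100), (s0 + 250, s0 + 350)), st,
                        )
                    good_artifacts.append(tid)
                else:  # MONO
                    s1, e1 = gx[1]
                    tid = f"{g.gene_id}.aM.{st}"
                    t = TranscriptModel(
                        tid, g.gene_id, chrom, g.strand, ((s1 + 10, e1 - 10),), st
                    )
                    good_artifacts.append(tid)
                assembled[st].append(t)
                fates[(sp, tid)] = ("removed", flavour)

        # --- junction support tables --------------------------------------
        junctions: dict[str, dict] = {}
        low_pairs = [(3, 3), (3, 9), (9, 3), (2, 7), (0, 0)]
        for st in stages:
            table = {}
            all_j = sorted({j for t in assembled[st] for j in t.junctions})
            for j in all_j:
                if j in low_junctions[st]:
                    table[j] = low_pairs[int(rng.integers(0, len(low_pairs)))]
                else:
                    table[j] = (int(rng.integers(20, 101)), int(rng.integers(20, 101)))
            junctions[st] = table

        # --- expression table ----------------------------------------------
        samples = [
            f"{sp}_{st}_rep{r + 1}" for st in stages for r in range(config.n_replicates)
        ]
        all_ids = sorted({t.transcript_id for st in stages for t in assembled[st]})
        expr = pd.DataFrame(0.0, index=pd.Index(all_ids, name="transcript_id"),
                            columns=samples)
        for g in genes:
            depth = config.tpm_depth * float(rng.lognormal(0.0, 0.4))
            if g.plan is not None:
                # inclusion-form isoform per convention: IR/A5SS/A3SS -> the
                # novel isoform (.t2); ES -> the exon-containing canonical (.t1)
                incl_id = f"{g.gene_id}.t1" if g.plan.etype == "ES" else f"{g.gene_id}.t2"
                excl_id = f"{g.gene_id}.t2" if g.plan.etype == "ES" else f"{g.gene_id}.t1"
                for st in stages:
                    for r in range(config.n_replicates):
                        col = f"{sp}_{st}_rep{r + 1}"
                        p = _logit_jitter(rng, g.plan.psi[sp][st], config.psi_noise_sd)
                        scale = float(rng.lognormal(0.0, 0.2))
                        expr.loc[incl_id, col] = depth * p * scale
                        expr.loc[excl_id, col] = depth * (1.0 - p) * scale
            else:
                row = depth * rng.lognormal(0.0, 0.2, len(samples))
                expr.loc[f"{g.gene_id}.t1", :] = row
                if f"{g.gene_id}.t1L" in expr.index:
                    expr.loc[f"{g.gene_id}.t1L", :] = row
        for tid in good_artifacts:
            expr.loc[tid, :] = 5.0
        for st in stages:
            for tid in tpm_artifacts[st]:
                for r in range(config.n_replicates):
                    expr.loc[tid, f"{sp}_{st}_rep{r + 1}"] = 0.5 + 0.3 * r

        species_data[sp] = SpeciesData(
            genome=genome,
            reference=reference,
            assembled=assembled,
            expression=expr,
            junctions=junctions,
        )

    # ---- cross-species tables ---------------------------------------------
    og_members: dict[str, dict[str, list[str]]] = {}
    for og in range(n_og):
        name = f"OG{og:04d}"
        og_members[name] = {
            sp: [f"{sp}_g{og:04d}"]
            + ([f"{sp}_g{og:04d}b"] if og in dup_ogs and dup_species[og] == sp else [])
            for sp in species
        }

    synteny_rows = []
    for og in range(n_og):
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                synteny_rows.append(
                    {
                        "gene_a": f"{a}_g{og:04d}",
                        "gene_b": f"{b}_g{og:04d}",
                        "block_id": f"blk_{a}_{b}_{og // 10}",
                    }
                )
    synteny = pd.DataFrame(synteny_rows, columns=["gene_a", "gene_b", "block_id"])

    blast_rows = []

    def _hit(q, s, bits, ev, rng):
        blast_rows.append(
            {
                "qseqid": q, "sseqid": s,
                "pident": round(float(rng.uniform(70, 95)), 2),
                "length": int(rng.integers(100, 400)),
                "mismatch": int(rng.integers(0, 40)),
                "gapopen": int(rng.integers(0, 5)),
                "qstart": 1, "qend": 300, "sstart": 1, "send": 300,
                "evalue": ev, "bitscore": round(bits, 1),
            }
        )

    for og in range(n_og):
        base = float(rng.uniform(300, 800))
        members = [(sp, g) for sp in species for g in og_members[f"OG{og:04d}"][sp]]
        for i, (sa, ga) in enumerate(members):
            for sb, gb in members:
                if sa == sb:
                    continue
                dup = ga.endswith("b") or gb.endswith("b")
                bits = base * (0.8 if dup else float(rng.uniform(0.95, 1.0)))
                ev = float(10.0 ** -rng.uniform(30, 80))
                _hit(ga, gb, bits, ev, rng)
    for _ in range(n_og):  # weak noise hits, all above the e-value cut-off
        a, b = rng.choice(species, 2, replace=False)
        ia, ib = rng.integers(0, n_og), rng.integers(0, n_og)
        _hit(f"{a}_g{ia:04d}", f"{b}_g{ib:04d}",
             float(rng.uniform(40, 60)), float(10.0 ** -rng.uniform(0, 8)), rng)
    blast = pd.DataFrame(blast_rows)

    # ripening-gene homolog map over a few AS genes per species
    ripening = [
        ("PG2a", "Cell wall structure"), ("TBG4", "Cell wall structure"),
        ("LeACS2", "Ethylene biosynthesis and signalling"),
        ("LeACS4", "Ethylene biosynthesis and signalling"),
        ("LeCTR1", "Ethylene biosynthesis and signalling"),
        ("LeETR5", "Ethylene biosynthesis and signalling"),
        ("PSY1", "Carotenoid"), ("CrtISO", "Carotenoid"),
        ("4CL", "Flavonoid/anthocyanin"),
        ("AP2a", "Transcription factor"), ("NOR", "Transcription factor"),
    ]
    hom_rows = []
    by_sp = {}
    for e in planted:
        by_sp.setdefault(e.species, []).append(e.gene_id)
    for sp in species:
        pool = sorted(set(by_sp.get(sp, [])))
        n_map = min(len(pool), 8)
        if n_map:
            idx = sorted(rng.choice(len(pool), n_map, replace=False).tolist())
            for i in idx:
                sym, path = ripening[int(rng.integers(0, len(ripening)))]
                hom_rows.append({"gene_id": pool[i], "symbol": sym, "pathway": path})
    homolog = pd.DataFrame(hom_rows, columns=["gene_id", "symbol", "pathway"])

    ortho_index = pd.DataFrame(
        {sp: [f"{sp}_g{og:04d}" for og in range(n_og)] for sp in species},
        index=pd.RangeIndex(n_og, name="orthologue"),
    )

    truth = GroundTruth(
        planted_events=planted,
        conserved_clusters=[clusters[c] for c in sorted(clusters)],
        stage_specific_labels={
            (e.species, e.event_id): e.label() for e in planted
        },
        filter_fates=fates,
        orthologue_index=ortho_index,
    )
    bundle = SimulatedBundle(
        config=config,
        species=species_data,
        orthogroup_members=og_members,
        blast_hits=blast,
        synteny=synteny,
        homolog_map=homolog,
    )
    if outdir is not None:
        write_bundle(bundle, truth, outdir)
    return bundle, truth


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------


def write_bundle(
    bundle: SimulatedBundle, truth: GroundTruth, outdir: str | Path
) -> None:
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    for sp, data in bundle.species.items():
        d = out / sp
        d.mkdir(exist_ok=True)
        gtfio.write_genome_fasta(d / "genome.fa", data.genome)
        gtfio.write_gtf(d / "reference.gtf", data.reference)
        for st, txs in data.assembled.items():
            gtfio.write_gtf(d / f"assembled_{st}.gtf", txs)
            gtfio.write_junction_counts(d / f"junctions_{st}.tsv", data.junctions[st])
        gtfio.write_expression(d / "tpm.tsv", data.expression)

    species = list(bundle.species)
    og_rows = []
    for name, members in bundle.orthogroup_members.items():
        row = {"Orthogroup": name}
        for sp in species:
            row[sp] = ", ".join(members[sp])
        og_rows.append(row)
    pd.DataFrame(og_rows).to_csv(out / "orthogroups.tsv", sep="\t", index=False)
    bundle.synteny.to_csv(out / "synteny.tsv", sep="\t", index=False)
    bundle.blast_hits.to_csv(
        out / "blast_hits.tsv", sep="\t", index=False, header=False
    )
    bundle.homolog_map.to_csv(out / "homolog_map.tsv", sep="\t", index=False)

    man = out / "manifest"
    man.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "species": e.species,
                "gene_id": e.gene_id,
                "type": e.etype,
                "chrom": e.chrom,
                "strand": e.strand,
                "coords": ";".join(f"{s}-{x}" for s, x in e.coords),
                "event_id": e.event_id,
                **{f"psi_{st}": e.psi[st] for st in sorted(e.psi)},
                "conserved_cluster": (
                    "" if e.conserved_cluster is None else e.conserved_cluster
                ),
            }
            for e in truth.planted_events
        ]
    ).to_csv(man / "planted_events.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"cluster": i, "species": sp, "gene_id": g, "event_id": eid}
            for i, cl in enumerate(truth.conserved_clusters)
            for sp, g, eid in cl
        ],
        columns=["cluster", "species", "gene_id", "event_id"],
    ).to_csv(man / "conserved_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"species": sp, "event_id": eid, "label": lab}
            for (sp, eid), lab in sorted(truth.stage_specific_labels.items())
        ],
        columns=["species", "event_id", "label"],
    ).to_csv(man / "stage_labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"species": sp, "transcript_id": tid, "fate": fate, "reason": reason}
            for (sp, tid), (fate, reason) in sorted(truth.filter_fates.items())
        ],
        columns=["species", "transcript_id", "fate", "reason"],
    ).to_csv(man / "filter_fates.tsv", sep="\t", index=False)
    truth.orthologue_index.to_csv(man / "orthologue_index.tsv", sep="\t")
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(bundle.config).items()}
    (man / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
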