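"""Resolution of one-to-one orthologue tuples across species.

Single-copy orthogroups pass through unchanged.  In multi-copy orthogroups,
cross-species gene pairs must be reciprocal best BLAST hits *and* lie in a
synteny block (strictest combination; an OR mode is available), and are then
assembled into tuples by connected components constrained to at most one
gene per species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class Orthogroup:
    og_id: str
    members: Mapping[str, tuple[str, ...]]  # species -> gene ids

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.members.values())

    @property
    def is_single_copy(self) -> bool:
        present = [g for g in self.members.values() if g]
        return len(present) >= 2 and all(len(g) == 1 for g in present)


def read_orthogroups(path: str | Path) -> list[Orthogroup]:
    """Read the tab-separated, comma-joined orthogroup membership dialect."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        og = d.pop(og_col)
        members = {
            sp: tuple(g.strip() for g in genes.split(",") if g.strip())
            for sp, genes in d.items()
        }
        out.append(Orthogroup(og, members))
    return out


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS)


def read_synteny(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def species_lookup(orthogroups: Iterable[Orthogroup]) -> dict[str, str]:
    """gene -> species map; raises if a gene is claimed by two orthogroups."""
    gene_og: dict[str, str] = {}
    gene_sp: dict[str, str] = {}
    for og in orthogroups:
        for sp, genes in og.members.items():
            for g in genes:
                if g in gene_og and gene_og[g] != og.og_id:
                    raise ValueError(
                        f"gene {g} claimed by orthogroups {gene_og[g]} and {og.og_id}"
                    )
                gene_og[g] = og.og_id
                gene_sp[g] = sp
    return gene_sp


def reciprocal_best_hits(
    hits: pd.DataFrame,
    species_of: Mapping[str, str] | Callable[[str], str],
    max_evalue: float = 1e-10,
) -> set[tuple[str, str]]:
    """Cross-species reciprocal best hit pairs, as sorted 2-tuples.

    Best = highest bit score; ties broken by lower e-value, then by
    lexicographic subject id.  Hits above ``max_evalue`` are discarded.
    """
    sp = species_of if callable(species_of) else species_of.__getitem__
    df = hits[hits["evalue"] <= max_evalue].copy()
    if df.empty:
        return set()
    df["qsp"] = df["qseqid"].map(sp)
    df["ssp"] = df["sseqid"].map(sp)
    df = df[df["qsp"] != df["ssp"]]
    df = df.sort_values(
        ["qseqid", "ssp", "bitscore", "evalue", "sseqid"],
        ascending=[True, True, False, True, True],
    )
    best = df.groupby(["qseqid", "ssp"], sort=False).first().reset_index()
    best_of = {(q, s): t for q, s, t in zip(best.qseqid, best.ssp, best.sseqid)}
    pairs = set()
    for (q, ssp), t in best_of.items():
        qsp = sp(q)
        if best_of.get((t, qsp)) == q:
            pairs.add(tuple(sorted((q, t))))
    return pairs


def resolve_one_to_one(
    orthogroups: Iterable[Orthogroup],
    rbh_pairs: set[tuple[str, str]] | None = None,
    synteny: pd.DataFrame | None = None,
    hits: pd.DataFrame | None = None,
    max_evalue: float = 1e-10,
    mode: str = "and",
) -> pd.DataFrame:
    """Orthologue index: one row per resolved tuple, one column per species.

    ``mode='and'`` (default) keeps multi-copy pairs supported by both RBH and
    synteny; ``'or'`` accepts either evidence.  Partial tuples (not all
    species present) are retained and flagged in the ``complete`` column.
    """
    orthogroups = list(orthogroups)
    gene_sp = species_lookup(orthogroups)  # also validates uniqueness
    species = sorted({sp for og in orthogroups for sp in og.members})
    if rbh_pairs is None:
        rbh_pairs = (
            reciprocal_best_hits(hits, gene_sp, max_evalue)
            if hits is not None
            else set()
        )
    syn_pairs: set[tuple[str, str]] = set()
    if synteny is not None:
        syn_pairs = {
            tuple(sorted((a, b))) for a, b in zip(synteny.gene_a, synteny.gene_b)
        }

    rows = []
    for og in sorted(orthogroups, key=lambda o: o.og_id):
        present = {sp: g for sp, g in og.members.items() if g}
        if len(present) < 2:
            continue
        if og.is_single_copy:
            rows.append({sp: g[0] for sp, g in present.items()})
            continue
        genes = [g for gs in present.values() for g in gs]
        graph = nx.Graph()
        graph.add_nodes_from(genes)
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                if gene_sp[a] == gene_sp[b]:
                    continue
                pair = tuple(sorted((a, b)))
                if mode == "and":
                    ok = pair in rbh_pairs and pair in syn_pairs
                else:
                    ok = pair in rbh_pairs or pair in syn_pairs
                if ok:
                    graph.add_edge(a, b)
        for comp in nx.connected_components(graph):
            if len(comp) < 2:
                continue
            by_sp: dict[str, list[str]] = {}
            for g in comp:
                by_sp.setdefault(gene_sp[g], []).append(g)
            if any(len(v) > 1 for v in by_sp.values()):
                logger.info(
                    "orthogroup %s: component %s has two genes in one species; "
                    "dropped", og.og_id, sorted(comp),
                )
                continue
            rows.append({sp: v[0] for sp, v in by_sp.items()})

    index = pd.DataFrame(rows, columns=species)
    index = index.sort_values(species, na_position="last").reset_index(drop=True)
    index.index.name = "orthologue"
    index["complete"] = index[species].notna().all(axis=1)
    return index


def write_orthologue_index(index: pd.DataFrame, path: str | Path) -> None:
    index.to_csv(path, sep="\t")
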