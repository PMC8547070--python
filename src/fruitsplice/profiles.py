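"""Binary AS profiles over the orthologue index, distances and clustering.

Each sample (species x stage x replicate) gets a presence/absence vector
over the one-to-one orthologue index: bit i is 1 when at least one AS event
in the i-th orthologue's gene for that species has a per-sample PSI inside
the occurrence window.  Orthologues with no AS in any sample are dropped.
Distances are binary (Jaccard) distances d = (b + c) / (a + b + c), where
a counts positions set in both vectors and b, c the discordant positions;
both-zero positions carry no information and are excluded by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .events import PSI_WINDOW
from .models import ASEvent

logger = logging.getLogger(__name__)


def species_of_sample(sample: str) -> str:
    return sample.rsplit("_", 2)[0]


def build_profiles(
    psi_by_species: Mapping[str, pd.DataFrame],
    events_by_species: Mapping[str, Sequence[ASEvent]],
    orthologue_index: pd.DataFrame,
    lo: float = PSI_WINDOW[0],
    hi: float = PSI_WINDOW[1],
) -> pd.DataFrame:
    """Profile matrix: orthologue index x samples, entries in {0, 1}.

    ``psi_by_species`` holds the per-sample PSI matrices; occurrence here is
    per sample (PSI in [lo, hi] in that very sample), not the stage mean.
    All-zero orthologue rows are dropped.
    """
    species = [c for c in orthologue_index.columns if c != "complete"]
    gene_events: dict[str, dict[str, list[str]]] = {}
    for sp in species:
        if sp not in psi_by_species:
            raise KeyError(f"no PSI data for species {sp}")
        gene_events[sp] = {}
        for ev in events_by_species.get(sp, []):
            gene_events[sp].setdefault(ev.gene_id, []).append(ev.event_id)

    columns: dict[str, np.ndarray] = {}
    for sp in species:
        psi = psi_by_species[sp]
        occ = (psi >= lo) & (psi <= hi)  # NA -> False
        for sample in psi.columns:
            bits = np.zeros(len(orthologue_index), dtype=np.int8)
            occ_events = set(occ.index[occ[sample]])
            for row_i, gene in enumerate(orthologue_index[sp]):
                if isinstance(gene, str) and any(
                    e in occ_events for e in gene_events[sp].get(gene, ())
                ):
                    bits[row_i] = 1
            columns[sample] = bits
    prof = pd.DataFrame(columns, index=orthologue_index.index)
    prof = prof.loc[prof.any(axis=1)]
    return prof


def binary_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise binary distance between sample columns of a 0/1 matrix."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 profiles")
    X = profiles.to_numpy(dtype=float).T  # samples x features
    inter = X @ X.T
    sums = X.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    zero_pairs = union == 0
    if zero_pairs.any():
        logger.info("binary_distance: %d all-zero vector pairs set to 0",
                    int(zero_pairs.sum()) - len(X))
        d[zero_pairs] = 0.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.columns, columns=profiles.columns)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    newick: str
    species_coherent: bool
    cut_assignments: pd.Series


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = TreeNode.from_linkage_matrix(Z, list(labels))
    return str(tree).strip()


def hierarchical_cluster(
    dist: pd.DataFrame,
    method: str = "complete",
    species_of: Callable[[str], str] = species_of_sample,
    n_species: int | None = None,
) -> ClusterResult:
    """Agglomerative clustering of the sample distance matrix.

    ``species_coherent`` is True iff cutting the dendrogram into one cluster
    per species reproduces exactly the species partition of the samples.
    """
    if dist.isna().to_numpy().any():
        raise ValueError("distance matrix contains NaN")
    labels = list(dist.columns)
    Z = hierarchy.linkage(squareform(dist.to_numpy(), checks=False), method=method)
    sp_of = {s: species_of(s) for s in labels}
    k = n_species if n_species is not None else len(set(sp_of.values()))
    cut = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    assign = pd.Series(cut, index=labels)
    coherent = (
        assign.groupby(pd.Series(sp_of)).nunique().eq(1).all()
        and assign.nunique() == k
    )
    return ClusterResult(
        linkage=Z,
        labels=labels,
        newick=_linkage_to_newick(Z, labels),
        species_coherent=bool(coherent),
        cut_assignments=assign,
    )


def species_specific_as_genes(
    profiles: pd.DataFrame,
    orthologue_index: pd.DataFrame,
    species_of: Callable[[str], str] = species_of_sample,
) -> dict[str, list]:
    """Orthologues AS in >= 1 sample of one species and in none of the others."""
    species = [c for c in orthologue_index.columns if c != "complete"]
    by_species = profiles.T.groupby(
        pd.Series({s: species_of(s) for s in profiles.columns})
    ).any()  # species x orthologue
    out: dict[str, list] = {sp: [] for sp in species}
    for orth in profiles.index:
        hit = by_species.index[by_species[orth]]
        if len(hit) == 1:
            out[hit[0]].append(orth)
    return out


def cross_reference_gene_list(
    stage_specific_genes: pd.DataFrame,
    homolog_map: pd.DataFrame,
) -> pd.DataFrame:
    """Join stage-specific AS genes onto a ripening-gene homolog map.

    ``stage_specific_genes`` columns: species, gene_id, stage;
    ``homolog_map`` columns: gene_id, symbol, pathway.  Returns the
    ripening-table shape: species x pathway x stage with gene symbols.
    """
    for col in ("species", "gene_id", "stage"):
        if col not in stage_specific_genes.columns:
            raise KeyError(f"stage_specific_genes lacks column {col}")
    merged = stage_specific_genes.merge(homolog_map, on="gene_id", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["species", "pathway", "stage", "symbols"])
    out = (
        merged.groupby(["species", "pathway", "stage"])["symbol"]
        .apply(lambda s: ", ".join(sorted(s)))
        .reset_index()
        .rename(columns={"symbol": "symbols"})
    )
    return out
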