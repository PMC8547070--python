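"""Binary AS profiles, distances, clustering, and the statistical tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from conftest import build_species
from fruitsplice.events import compute_psi, detect_events
from fruitsplice.models import make_event
from fruitsplice.profiles import (
    binary_distance,
    build_profiles,
    cross_reference_gene_list,
    hierarchical_cluster,
    species_specific_as_genes,
)
from fruitsplice.stats import fisher_exact_2x2, wilcoxon_rank_sum
from fruitsplice.synthetic import SimulationConfig, simulate_dataset
from oracles import fisher_two_sided, wilcoxon_exact


def _profiles_from_bundle(mode="species", seed=1, noise=0.0):
    cfg = SimulationConfig(seed=seed, psi_noise_sd=noise, profile_mode=mode)
    bundle, truth = simulate_dataset(cfg)
    psi_by_sp, ev_by_sp = {}, {}
    for sp, data in bundle.species.items():
        res = build_species(bundle, sp)
        ev_by_sp[sp] = detect_events(res.transcripts)
        psi_by_sp[sp] = compute_psi(ev_by_sp[sp], data.expression)
    prof = build_profiles(psi_by_sp, ev_by_sp, truth.orthologue_index)
    return bundle, truth, prof


class TestBuildProfiles:
    def test_profiles_match_ground_truth_bits_with_zero_noise(self):
        bundle, truth, prof = _profiles_from_bundle()
        planted = {(e.species, e.gene_id): e for e in truth.planted_events}
        idx = truth.orthologue_index
        for orth in prof.index:
            for sample in prof.columns:
                sp = sample.rsplit("_", 2)[0]
                stage = sample.rsplit("_", 2)[1]
                pe = planted.get((sp, idx.loc[orth, sp]))
                want = int(pe is not None and 0.05 <= pe.psi[stage] <= 0.95)
                assert prof.loc[orth, sample] == want, (orth, sample)

    def test_orthologues_without_as_are_dropped(self):
        bundle, truth, prof = _profiles_from_bundle()
        as_orths = set(prof.index)
        planted_genes = {(e.species, e.gene_id) for e in truth.planted_events}
        for orth in truth.orthologue_index.index:
            genes = {
                (sp, truth.orthologue_index.loc[orth, sp])
                for sp in bundle.species
            }
            if not (genes & planted_genes):
                assert orth not in as_orths

    def test_missing_species_psi_is_an_error(self):
        _, truth, _ = _profiles_from_bundle()
        with pytest.raises(KeyError, match="no PSI data"):
            build_profiles({}, {}, truth.orthologue_index)


class TestBinaryDistance:
    def test_worked_examples(self):
        prof = pd.DataFrame(
            {"x": [1, 0, 1, 0], "y": [1, 1, 0, 0], "z": [1, 0, 1, 0]}
        )
        d = binary_distance(prof)
        assert d.loc["x", "y"] == pytest.approx(2 / 3)
        assert d.loc["x", "z"] == 0.0
        disjoint = pd.DataFrame({"x": [1, 1, 0, 0], "y": [0, 0, 1, 1]})
        assert binary_distance(disjoint).loc["x", "y"] == 1.0

    def test_all_zero_pair_defined_as_zero(self):
        prof = pd.DataFrame({"x": [0, 0], "y": [0, 0], "z": [1, 0]})
        d = binary_distance(prof)
        assert d.loc["x", "y"] == 0.0 and d.loc["x", "z"] == 1.0

    def test_agrees_with_scipy_jaccard(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.integers(0, 2, (30, 8)),
                            columns=[f"s{i}" for i in range(8)])
        ours = binary_distance(prof).to_numpy()
        ref = squareform(pdist(prof.to_numpy().T.astype(bool), metric="jaccard"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            vecs = rng.integers(0, 2, (3, 12))
            while not vecs.any(axis=1).all():
                vecs = rng.integers(0, 2, (3, 12))
            prof = pd.DataFrame(vecs.T, columns=list("abc"))
            d = binary_distance(prof)
            assert np.allclose(d.to_numpy(), d.to_numpy().T)
            assert (np.diag(d.to_numpy()) == 0).all()
            for x, y, z in itertools.permutations("abc"):
                assert d.loc[x, z] <= d.loc[x, y] + d.loc[y, z] + 1e-12

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            binary_distance(pd.DataFrame({"x": [1, 0]}))


class TestClustering:
    def _dist(self, within, between, n_sp=4, reps=4):
        labels = [f"sp{i}_s_rep{r}" for i in range(n_sp) for r in range(reps)]
        n = len(labels)
        d = np.full((n, n), between, dtype=float)
        for i in range(n_sp):
            sl = slice(i * reps, (i + 1) * reps)
            d[sl, sl] = within
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=labels, columns=labels)

    def test_well_separated_species_are_coherent(self):
        res = hierarchical_cluster(self._dist(0.1, 0.8))
        assert res.species_coherent
        assert res.newick.endswith(";")

    def test_stage_dominant_profiles_break_coherence(self):
        _, _, prof = _profiles_from_bundle(mode="stage")
        res = hierarchical_cluster(binary_distance(prof))
        assert not res.species_coherent

    def test_three_samples_two_monotone_merges(self):
        d = pd.DataFrame(
            [[0, 0.2, 0.9], [0.2, 0, 0.8], [0.9, 0.8, 0]],
            index=["a_x_rep1", "a_x_rep2", "b_x_rep1"],
            columns=["a_x_rep1", "a_x_rep2", "b_x_rep1"],
        )
        res = hierarchical_cluster(d)
        assert res.linkage.shape[0] == 2
        assert res.linkage[0, 2] <= res.linkage[1, 2]

    def test_nan_distance_rejected(self):
        d = self._dist(0.1, 0.8)
        d.iloc[0, 1] = np.nan
        with pytest.raises(ValueError):
            hierarchical_cluster(d)

    def test_orthologue_permutation_invariant(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(
            rng.integers(0, 2, (40, 8)),
            columns=[f"sp{i}_s_rep{r}" for i in range(4) for r in range(2)],
        )
        perm = prof.sample(frac=1.0, random_state=7)
        a = hierarchical_cluster(binary_distance(prof))
        b = hierarchical_cluster(binary_distance(perm))
        np.testing.assert_allclose(a.linkage, b.linkage)

    def test_species_coherence_rate_under_default_noise(self):
        ok = 0
        for seed in range(30):
            cfg = SimulationConfig(
                seed=seed, genes_per_species_extra=0,
                frac_artifact_transcripts=0.0, n_merge_variants=0,
            )
            bundle, truth = simulate_dataset(cfg)
            psi_by_sp, ev_by_sp = {}, {}
            for sp, data in bundle.species.items():
                ev_by_sp[sp] = detect_events(data.assembled["immature"])
                psi_by_sp[sp] = compute_psi(ev_by_sp[sp], data.expression)
            prof = build_profiles(psi_by_sp, ev_by_sp, truth.orthologue_index)
            res = hierarchical_cluster(binary_distance(prof))
            ok += res.species_coherent
        assert ok >= 29  # >= ~95% of seeded runs


class TestSpeciesSpecific:
    def test_manifest_species_specific_orthologues_recovered(self):
        bundle, truth, prof = _profiles_from_bundle()
        got = species_specific_as_genes(prof, truth.orthologue_index)
        planted_by_orth: dict[int, set[str]] = {}
        gene_to_orth = {}
        for sp in bundle.species:
            for orth, g in truth.orthologue_index[sp].items():
                gene_to_orth[(sp, g)] = orth
        for e in truth.planted_events:
            key = gene_to_orth.get((e.species, e.gene_id))
            if key is not None and any(
                0.05 <= p <= 0.95 for p in e.psi.values()
            ):
                planted_by_orth.setdefault(key, set()).add(e.species)
        want = {
            sp: sorted(o for o, sps in planted_by_orth.items() if sps == {sp})
            for sp in bundle.species
        }
        assert {sp: sorted(v) for sp, v in got.items()} == want
        assert any(want.values())


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 1], [1, 3]], 0.4857),
            ([[5, 0], [0, 5]], 2 / 252),
            ([[2, 2], [2, 2]], 1.0),
        ],
    )
    def test_worked_examples(self, table, expected):
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(expected, abs=5e-5)

    def test_matches_enumeration_oracle_on_small_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 8, 4)
            if a + b + c + d == 0 or a + b + c + d > 20:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-10)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0.5, 2], [3, 4]])


class TestWilcoxon:
    def test_separated_triples_exact_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_shifted_normals_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-6

    def test_matches_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 11 - n))
            vals = rng.choice(1000, size=n + m, replace=False).astype(float)
            a, b = vals[:n], vals[n:]
            for alt in ("two-sided", "less", "greater"):
                _, p = wilcoxon_rank_sum(a, b, alternative=alt)
                assert p == pytest.approx(wilcoxon_exact(a, b, alt), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCrossReference:
    def _genes(self):
        return pd.DataFrame(
            {
                "species": ["cucumber", "cucumber", "melon"],
                "gene_id": ["cu_g1", "cu_g2", "me_g1"],
                "stage": ["ripe", "immature", "ripe"],
            }
        )

    def test_ripening_join_shape(self):
        hom = pd.DataFrame(
            {"gene_id": ["cu_g1"], "symbol": ["PG2a"],
             "pathway": ["Cell wall structure"]}
        )
        out = cross_reference_gene_list(self._genes(), hom)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.species, row.pathway, row.stage, row.symbols) == (
            "cucumber", "Cell wall structure", "ripe", "PG2a"
        )

    def test_empty_map_gives_empty_table(self):
        hom = pd.DataFrame(columns=["gene_id", "symbol", "pathway"])
        assert cross_reference_gene_list(self._genes(), hom).empty

    def test_unmapped_genes_absent(self):
        hom = pd.DataFrame(
            {"gene_id": ["not_there"], "symbol": ["AP2a"],
             "pathway": ["Transcription factor"]}
        )
        assert cross_reference_gene_list(self._genes(), hom).empty


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10),
       st.integers(0, 10))
def test_fisher_probability_mass_rule_property(a, b, c, d):
    if a + b + c + d == 0:
        return
    _, p = fisher_exact_2x2([[a, b], [c, d]])
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-10)
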