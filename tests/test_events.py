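"""Event detection against canonical cases and the brute-force oracle;
PSI computation, occurrence window, stage-specific and differential calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_species
from fruitsplice.events import (
    call_occurrence,
    call_stage_specific,
    compute_psi,
    detect_events,
    differential_splicing,
    gene_level_summary,
    intron_length_comparison,
    stage_mean_psi,
)
from fruitsplice.models import TranscriptModel, make_event
from oracles import oracle_events, random_gene


def tx(tid, exons, strand="+", gene="g1"):
    return TranscriptModel(tid, gene, "c1", strand, tuple(exons))


def as_tuples(events):
    return {
        (e.etype, e.coords, e.inclusion_transcripts, e.exclusion_transcripts)
        for e in events
    }


class TestDetection:
    def test_cassette_exon_yields_one_es_event(self):
        incl = tx("with_exon", [(100, 200), (300, 400), (500, 600)])
        excl = tx("skipped", [(100, 200), (500, 600)])
        events = detect_events([incl, excl])
        assert len(events) == 1
        ev = events[0]
        assert ev.etype == "ES"
        assert ev.coords == ((200, 300), (400, 500))
        assert ev.inclusion_transcripts == {"with_exon"}
        assert ev.exclusion_transcripts == {"skipped"}

    def test_sr_like_gene_retaining_third_intron(self):
        # five-exon gene; one isoform reads through intron 3
        spliced = tx("s", [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)])
        retained = tx("r", [(0, 100), (200, 300), (400, 700), (800, 900)])
        events = detect_events([spliced, retained])
        assert len(events) == 1
        ev = events[0]
        assert ev.etype == "IR" and ev.coords == ((500, 600),)
        assert ev.inclusion_transcripts == {"r"}  # retention = inclusion

    @pytest.mark.parametrize(
        "strand,expected",
        [("+", "A5SS"), ("-", "A3SS")],
    )
    def test_shared_acceptor_is_donor_shift_on_plus_strand(self, strand, expected):
        a = tx("a", [(0, 100), (300, 400)], strand)
        b = tx("b", [(0, 150), (300, 400)], strand)  # exon extended into intron
        events = detect_events([a, b])
        assert [e.etype for e in events] == [expected]
        # inclusion = longer-exon (shorter-intron) form
        assert events[0].inclusion_transcripts == {"b"}

    @pytest.mark.parametrize(
        "strand,expected",
        [("+", "A3SS"), ("-", "A5SS")],
    )
    def test_shared_donor_is_acceptor_shift_on_plus_strand(self, strand, expected):
        a = tx("a", [(0, 100), (300, 400)], strand)
        b = tx("b", [(0, 100), (250, 400)], strand)
        events = detect_events([a, b])
        assert [e.etype for e in events] == [expected]
        assert events[0].inclusion_transcripts == {"b"}

    def test_skipping_pair_not_misread_as_boundary_shift(self):
        incl = tx("i", [(100, 200), (300, 400), (500, 600)])
        excl = tx("e", [(100, 200), (500, 600)])
        types = {e.etype for e in detect_events([incl, excl])}
        assert types == {"ES"}

    def test_single_isoform_gene_has_no_events(self):
        assert detect_events([tx("a", [(0, 100), (200, 300)])]) == []

    def test_mixed_strand_gene_rejected(self):
        with pytest.raises(ValueError):
            detect_events([tx("a", [(0, 100), (200, 300)], "+"),
                           tx("b", [(0, 100), (200, 300)], "-")])

    def test_matches_bruteforce_oracle_on_random_genes(self):
        rng = np.random.default_rng(42)
        for i in range(120):
            gene = random_gene(rng, gene_id=f"g{i}")
            assert as_tuples(detect_events(gene)) == oracle_events(gene), (
                [t.exons for t in gene],
                gene[0].strand,
            )

    def test_detection_invariant_under_transcript_renaming(self):
        rng = np.random.default_rng(11)
        gene = random_gene(rng)
        renamed = [
            TranscriptModel(f"zz_{i}", t.gene_id, t.chrom, t.strand, t.exons)
            for i, t in enumerate(reversed(gene))
        ]
        assert {(e.etype, e.coords) for e in detect_events(gene)} == {
            (e.etype, e.coords) for e in detect_events(renamed)
        }


class TestPsi:
    def _event(self):
        return make_event(
            "ES", "g1", "c1", "+", ((200, 300), (400, 500)), ["i1"], ["x1"]
        )

    def test_symmetric_and_boundary_and_na(self):
        ev = self._event()
        expr = pd.DataFrame(
            {"s1": [5.0, 5.0], "s2": [3.0, 0.0], "s3": [0.0, 0.0]},
            index=["i1", "x1"],
        )
        psi = compute_psi([ev], expr)
        assert psi.loc[ev.event_id, "s1"] == 0.5
        assert psi.loc[ev.event_id, "s2"] == 1.0
        assert np.isnan(psi.loc[ev.event_id, "s3"])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=2),
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=2),
    )
    def test_label_swap_complements_psi(self, incl_tpm, excl_tpm):
        ev = self._event()
        swapped = make_event(
            "ES", "g1", "c1", "+", ((200, 300), (400, 500)), ["x1"], ["i1"]
        )
        expr = pd.DataFrame({"s1": [incl_tpm[0], excl_tpm[0]],
                             "s2": [incl_tpm[1], excl_tpm[1]]}, index=["i1", "x1"])
        p = compute_psi([ev], expr).iloc[0]
        q = compute_psi([swapped], expr).iloc[0]
        for a, b in zip(p, q):
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a + b == pytest.approx(1.0)

    def test_planted_psi_recovered_exactly(self, noiseless_bundle,
                                           built_transcriptomes):
        bundle, truth = noiseless_bundle
        for sp, planted in truth.events_by_species().items():
            res = built_transcriptomes[sp]
            events = detect_events(res.transcripts)
            by_coords = {(e.etype, e.coords): e.event_id for e in events}
            psi = compute_psi(events, bundle.species[sp].expression)
            spsi = stage_mean_psi(psi)
            for pe in planted:
                eid = by_coords[(pe.etype, pe.coords)]
                for stage, value in pe.psi.items():
                    assert spsi.loc[eid, stage] == pytest.approx(value, abs=1e-9)


class TestOccurrence:
    def test_window_bounds_inclusive(self):
        spsi = pd.DataFrame(
            {"immature": [0.05, 0.96, 0.02], "ripe": [0.95, 0.5, np.nan]},
            index=["a", "b", "c"],
        )
        occ = call_occurrence(spsi)
        assert occ.loc["a"].tolist() == [True, True]
        assert occ.loc["b"].tolist() == [False, True]
        assert occ.loc["c"].tolist() == [False, False]

    def test_stage_mean_ignores_na_replicates(self):
        psi = pd.DataFrame(
            {"x_immature_rep1": [0.02], "x_immature_rep2": [np.nan],
             "x_ripe_rep1": [0.5], "x_ripe_rep2": [0.6]},
            index=["e"],
        )
        spsi = stage_mean_psi(psi)
        assert spsi.loc["e", "immature"] == pytest.approx(0.02)
        assert not call_occurrence(spsi).loc["e", "immature"]

    def test_stage_specific_partition(self):
        occ = pd.DataFrame(
            {"immature": [True, True, False, False],
             "ripe": [False, True, True, False]},
            index=list("abcd"),
        )
        labels = call_stage_specific(occ)
        assert labels.tolist() == ["immature-only", "both", "ripe-only", "neither"]

    def test_full_window_makes_every_event_occur(self, noiseless_bundle,
                                                 built_transcriptomes):
        bundle, _ = noiseless_bundle
        res = built_transcriptomes["papaya"]
        events = detect_events(res.transcripts)
        psi = compute_psi(events, bundle.species["papaya"].expression)
        spsi = stage_mean_psi(psi)
        occ = call_occurrence(spsi, lo=0.0, hi=1.0)
        assert occ.to_numpy()[~spsi.isna().to_numpy()].all()

    def test_planted_stage_labels_recovered(self, noiseless_bundle,
                                            built_transcriptomes):
        bundle, truth = noiseless_bundle
        for sp, planted in truth.events_by_species().items():
            events = detect_events(built_transcriptomes[sp].transcripts)
            by_coords = {(e.etype, e.coords): e.event_id for e in events}
            psi = compute_psi(events, bundle.species[sp].expression)
            labels = call_stage_specific(call_occurrence(stage_mean_psi(psi)))
            for pe in planted:
                expected = truth.stage_specific_labels[(sp, pe.event_id)]
                assert labels[by_coords[(pe.etype, pe.coords)]] == expected


class TestDifferential:
    def _setup(self, n_null=100, dpsi=0.5, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        events, rows = [], {}
        for i in range(n_null + 1):
            ev = make_event(
                "IR", f"g{i}", "c1", "+", ((100 + i * 1000, 200 + i * 1000),),
                [f"g{i}.i"], [f"g{i}.x"],
            )
            events.append(ev)
            base = 0.5 if i else 0.3
            shift = 0.0 if i else dpsi
            for stage, mu in (("immature", base), ("ripe", base + shift)):
                for r in (1, 2):
                    p = np.clip(mu + rng.normal(0, noise), 0.01, 0.99)
                    rows.setdefault(f"s_{stage}_rep{r}", {})[f"g{i}.i"] = 100 * p
                    rows[f"s_{stage}_rep{r}"][f"g{i}.x"] = 100 * (1 - p)
        expr = pd.DataFrame(rows)
        psi = compute_psi(events, expr)
        return events, expr, psi

    def test_planted_large_shift_is_significant(self):
        events, expr, psi = self._setup(dpsi=0.5)
        res = differential_splicing(psi, events, expr)
        target = events[0].event_id
        assert res.table.loc[target, "significant"]
        assert res.table.loc[target, "dpsi"] == pytest.approx(0.5, abs=0.1)

    def test_small_shift_fails_dpsi_gate(self):
        events, expr, psi = self._setup(dpsi=0.08, noise=0.0)
        res = differential_splicing(psi, events, expr)
        assert not res.table.loc[events[0].event_id, "significant"]

    def test_flat_psi_not_significant(self):
        events, expr, psi = self._setup(dpsi=0.0, noise=0.0)
        res = differential_splicing(psi, events, expr)
        assert res.table.loc[events[0].event_id, "dpsi"] == 0.0
        assert not res.table["significant"].any()

    def test_na_events_excluded_and_reported(self):
        events, expr, psi = self._setup(n_null=20)
        psi.iloc[3, 0] = np.nan
        res = differential_splicing(psi, events, expr)
        assert psi.index[3] in res.excluded
        assert psi.index[3] not in res.table.index


class TestGeneLevel:
    def test_counts_match_manifest_with_artifacts_off(self):
        from fruitsplice.synthetic import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(seed=9, n_orthogroups=20,
                               frac_artifact_transcripts=0.0, psi_noise_sd=0.0)
        bundle, truth = simulate_dataset(cfg)
        for sp, planted in truth.events_by_species().items():
            res = build_species(bundle, sp)
            events = detect_events(res.transcripts)
            summary = gene_level_summary(events, res.transcripts)
            want = pd.Series(
                {t: sum(1 for e in planted if e.etype == t)
                 for t in ("IR", "ES", "A3SS", "A5SS")}
            )
            assert summary.event_counts.equals(want)

    def test_no_events_means_zero_pct(self):
        txs = [tx("a", [(0, 100), (200, 300)])]
        s = gene_level_summary([], txs)
        assert s.pct_as_genes == 0.0 and s.n_multiexon_genes == 1

    def test_as_gene_fraction_counts_multiexon_genes(self):
        genes = []
        for i in range(40):
            genes.append(tx(f"g{i}.t1", [(0, 100), (200, 300), (400, 500)],
                            gene=f"g{i}"))
        events = [
            make_event("ES", f"g{i}", "c1", "+", ((100, 200), (300, 400)),
                       [f"g{i}.t1"], [f"g{i}.skip"])
            for i in range(10)
        ]
        s = gene_level_summary(events, genes)
        assert s.pct_as_genes == pytest.approx(25.0)


class TestIntronLengths:
    def test_planted_short_retained_introns_detected(self):
        rng = np.random.default_rng(3)
        txs, events = [], []
        for i in range(30):
            base = i * 10000
            short = int(rng.integers(80, 151))
            long1 = int(rng.integers(500, 2001))
            exons = [(base, base + 100), (base + 100 + short, base + 200 + short),
                     (base + 200 + short + long1, base + 300 + short + long1)]
            spliced = tx(f"g{i}.s", exons, gene=f"g{i}")
            retained = tx(
                f"g{i}.r", [exons[0][0:2], exons[1], exons[2]], gene=f"g{i}"
            )
            txs.append(spliced)
            events.append(
                make_event("IR", f"g{i}", "c1", "+",
                           ((exons[0][1], exons[1][0]),),
                           [f"g{i}.r"], [f"g{i}.s"])
            )
        a, b, _, p = intron_length_comparison(events, txs, alternative="less")
        assert len(a) == 30
        assert p < 0.01

    def test_single_retained_intron_sample(self):
        spliced = tx("s", [(0, 100), (200, 300)])
        events = [make_event("IR", "g1", "c1", "+", ((100, 200),), ["r"], ["s"])]
        a, b, _, _ = intron_length_comparison(
            events, [spliced, tx("x", [(0, 50), (400, 500)], gene="g2")]
        )
        assert a.tolist() == [100]

    def test_no_ir_events_is_an_error(self):
        with pytest.raises(ValueError, match="no IR events"):
            intron_length_comparison([], [tx("a", [(0, 100), (200, 300)])])
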