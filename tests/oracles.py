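"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive results from first principles (exhaustive
enumeration, literal definitions, base-level sequence checks) rather than
calling the package's own code paths.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

from fruitsplice.models import TranscriptModel


# ---------------------------------------------------------------------------
# brute-force AS event detection: literal pairwise definitions
# ---------------------------------------------------------------------------


def _exonic_positions(t: TranscriptModel) -> set[int]:
    return {p for s, e in t.exons for p in range(s, e)}


def oracle_events(transcripts) -> set[tuple]:
    """All (type, coords, inclusion, exclusion) tuples by literal definition."""
    found: set[tuple[str, tuple]] = set()
    for x, y in itertools.permutations(transcripts, 2):
        # exon skipping: internal exon of x, direct junction in y
        for i in range(1, len(x.exons) - 1):
            s, e = x.exons[i]
            d1 = x.exons[i - 1][1]
            a2 = x.exons[i + 1][0]
            if (d1, a2) in y.introns:
                found.add(("ES", ((d1, s), (e, a2))))
        # intron retention: spliced in y, read through within one exon of x
        for j in range(len(y.exons) - 1):
            es, de = y.exons[j]
            ae, ee = y.exons[j + 1]
            if (es, ee) in x.exons:
                found.add(("IR", ((de, ae),)))
        # alternative donor/acceptor: introns sharing exactly one boundary,
        # with the alternative region exonic in the shorter-intron form
        for ix in x.introns:
            for iy in y.introns:
                if ix == iy:
                    continue
                shared_left = ix[0] == iy[0]
                shared_right = ix[1] == iy[1]
                if shared_left == shared_right:
                    continue
                short, owner = (ix, x) if ix[1] - ix[0] < iy[1] - iy[0] else (iy, y)
                if shared_left:
                    region = range(min(ix[1], iy[1]), max(ix[1], iy[1]))
                else:
                    region = range(min(ix[0], iy[0]), max(ix[0], iy[0]))
                if not set(region) <= _exonic_positions(owner):
                    continue
                # donor = transcription-5' side of the intron
                varies_at_donor = (
                    shared_right if x.strand == "+" else shared_left
                )
                etype = "A5SS" if varies_at_donor else "A3SS"
                found.add((etype, tuple(sorted([ix, iy]))))

    out = set()
    for etype, coords in found:
        incl, excl = set(), set()
        for t in transcripts:
            introns = set(t.introns)
            if etype == "ES":
                (d1, s), (e, a2) = coords
                if {(d1, s), (e, a2)} <= introns:
                    incl.add(t.transcript_id)
                elif (d1, a2) in introns:
                    excl.add(t.transcript_id)
            elif etype == "IR":
                ((d, a),) = coords
                if any(s < d and a < e for s, e in t.exons):
                    incl.add(t.transcript_id)
                elif (d, a) in introns:
                    excl.add(t.transcript_id)
            else:
                ia, ib = coords
                short, longi = (ia, ib) if ia[1] - ia[0] < ib[1] - ib[0] else (ib, ia)
                if short in introns:
                    incl.add(t.transcript_id)
                elif longi in introns:
                    excl.add(t.transcript_id)
        if incl and excl:
            out.add((etype, coords, frozenset(incl), frozenset(excl)))
    return out


def random_gene(
    rng: np.random.Generator,
    gene_id: str = "g",
    chrom: str = "chr",
    max_isoforms: int = 5,
    max_exons: int = 8,
) -> list[TranscriptModel]:
    """A random gene: a base exon chain plus variants with skipped exons,
    retained introns and shifted splice sites."""
    n = int(rng.integers(3, max_exons + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exons, pos = [], 100
    for i in range(n):
        length = int(rng.integers(60, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(80, 300))
    chains = {tuple(exons)}
    n_iso = int(rng.integers(2, max_isoforms + 1))
    attempts = 0
    while len(chains) < n_iso and attempts < 50:
        attempts += 1
        var = [list(e) for e in exons]
        for _ in range(int(rng.integers(1, 3))):
            op = rng.choice(["skip", "retain", "shift_end", "shift_start"])
            if op == "skip" and len(var) > 2:
                var.pop(int(rng.integers(1, len(var) - 1)))
            elif op == "retain" and len(var) > 1:
                k = int(rng.integers(0, len(var) - 1))
                var[k] = [var[k][0], var[k + 1][1]]
                var.pop(k + 1)
            elif op == "shift_end" and len(var) > 1:
                k = int(rng.integers(0, len(var) - 1))
                gap = var[k + 1][0] - var[k][1]
                if gap > 50:
                    var[k][1] += int(rng.integers(20, gap - 20))
            elif op == "shift_start" and len(var) > 1:
                k = int(rng.integers(1, len(var)))
                gap = var[k][0] - var[k - 1][1]
                if gap > 50:
                    var[k][0] -= int(rng.integers(20, gap - 20))
        chains.add(tuple(tuple(e) for e in var))
    return [
        TranscriptModel(f"{gene_id}.t{i}", gene_id, chrom, strand, chain)
        for i, chain in enumerate(sorted(chains))
    ]


# ---------------------------------------------------------------------------
# exact test oracles
# ---------------------------------------------------------------------------


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric two-sided p at fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, r1)
    probs = {k: comb(c1, k) * comb(n - c1, r1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def wilcoxon_exact(sample_a, sample_b, alternative: str = "two-sided") -> float:
    """Exact rank-sum p by full enumeration of rank assignments (no ties)."""
    a = list(sample_a)
    b = list(sample_b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n, m = len(a), len(b)
    dist = [sum(c) for c in itertools.combinations(range(1, n + m + 1), n)]
    total = len(dist)
    p_le = sum(1 for w in dist if w <= w_obs) / total
    p_ge = sum(1 for w in dist if w >= w_obs) / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def rbh_bruteforce(hits, species_of, max_evalue=1e-10) -> set[tuple[str, str]]:
    """Double-loop reciprocal best hits with the same tie-break rules."""
    rows = [
        r for r in hits.itertuples(index=False)
        if r.evalue <= max_evalue and species_of[r.qseqid] != species_of[r.sseqid]
    ]
    genes = {r.qseqid for r in rows}
    best: dict[tuple[str, str], str] = {}
    for g in genes:
        by_target_sp: dict[str, list] = {}
        for r in rows:
            if r.qseqid == g:
                by_target_sp.setdefault(species_of[r.sseqid], []).append(r)
        for tsp, cand in by_target_sp.items():
            cand.sort(key=lambda r: (-r.bitscore, r.evalue, r.sseqid))
            best[(g, tsp)] = cand[0].sseqid
    out = set()
    for (g, tsp), t in best.items():
        if best.get((t, species_of[g])) == g:
            out.add(tuple(sorted((g, t))))
    return out
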