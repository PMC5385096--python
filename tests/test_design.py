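"""Tiling, hit search, probe classification and probeset assembly."""

import numpy as np
import pandas as pd
import pytest

from pentahyb import simulate as sim
from pentahyb.design import (
    STATUS_CROSS,
    STATUS_LOW_AFFINITY,
    STATUS_NONSPECIFIC,
    STATUS_SPECIFIC,
    CandidateProbe,
    Hit,
    SeedScanBackend,
    assemble_probesets,
    classify_probe,
    design_locus,
    find_hits,
    self_affinity_filter,
    tile,
)
from pentahyb.duplex import (
    MATCH,
    DuplexAlignment,
    NoDuplexError,
    ProbeSequence,
    align_duplex,
    enumerate_vocabulary,
    extract_features,
    perfect_match_alignment,
)
from pentahyb.model import PentamerAffinityResults

from .conftest import random_seq


def uniform_results(threshold=None, pm_coef=1.0, mm_coef=-1.0):
    """A hand-built model: every PM token scores pm_coef, every MM/GAP token
    mm_coef — affinity then counts matched windows minus mispaired ones."""
    vocab = enumerate_vocabulary(25, orientations=1)
    beta = {}
    for t in vocab.tokens:
        beta[t] = pm_coef if t[0] == "PM" else mm_coef
    delta = {t: -0.5 for t in vocab.interaction_tokens}
    return (
        PentamerAffinityResults(
            model=None, beta=beta, delta=delta, lasso_penalty=0.0,
            theta=pd.DataFrame(), noise_sd=0.0, hybridization_threshold=threshold,
        ),
        vocab,
    )


class TestTile:
    def test_step1_count(self, rng):
        assert len(tile(random_seq(rng, 100), step=1)) == 76

    def test_step4_count(self, rng):
        assert len(tile(random_seq(rng, 100), step=4)) == 19

    def test_short_region_empty(self, rng):
        assert tile(random_seq(rng, 24)) == []

    def test_masked_windows_skipped(self, rng):
        region = random_seq(rng, 30)
        region = region[:10] + "N" + region[11:]
        cands = tile(region, step=1)
        assert all("N" not in c.probe.sequence for c in cands)
        assert len(cands) == 0  # every 25-mer window covers position 10

    def test_coordinates_half_open(self, rng):
        c = tile(random_seq(rng, 40), step=4)[1]
        assert (c.start, c.end) == (4, 29)
        assert c.probe.end - c.probe.start == 25

    def test_invalid_step(self, rng):
        with pytest.raises(ValueError):
            tile(random_seq(rng, 100), step=5)


class TestSelfAffinityFilter:
    def test_boundary_inclusive_and_rejection(self, rng):
        res, vocab = uniform_results(threshold=21.0)  # PM affinity == 21 exactly
        cands = tile(random_seq(rng, 60))
        kept = self_affinity_filter(cands, res, vocab)
        assert kept == cands  # every PM probe scores exactly T
        res2, _ = uniform_results(threshold=22.0)
        kept2 = self_affinity_filter(cands, res2, vocab)
        assert kept2 == []
        assert all(c.status == STATUS_LOW_AFFINITY for c in cands)

    def test_uncalibrated_model_rejected(self, rng):
        res, vocab = uniform_results(threshold=None)
        with pytest.raises(ValueError, match="calibrat"):
            self_affinity_filter(tile(random_seq(rng, 30)), res, vocab)

    def test_empty_input(self):
        res, vocab = uniform_results(threshold=1.0)
        assert self_affinity_filter([], res, vocab) == []


def brute_force_hits(probe_seq, references, max_mm, max_gaps):
    """Sliding-window scan over every start and target length."""
    found = set()
    P = len(probe_seq)
    for tid, ref in references.items():
        for start in range(len(ref)):
            for L in range(P - max_gaps, P + max_gaps + 1):
                sub = ref[start : start + L]
                if len(sub) < L:
                    continue
                try:
                    align_duplex(probe_seq, sub, max_mm, max_gaps)
                except NoDuplexError:
                    continue
                found.add((tid, start))
    return found


def cluster_starts(positions, max_gap=1):
    """Group (target, start) pairs into runs of gap-shifted starts; each run
    is one physical hit site. Yields (target, min_start, max_start)."""
    by_target = {}
    for tid, pos in sorted(positions):
        by_target.setdefault(tid, []).append(pos)
    for tid, starts in by_target.items():
        lo = prev = starts[0]
        for p in starts[1:]:
            if p - prev > max_gap:
                yield tid, lo, prev
                lo = p
            prev = p
        yield tid, lo, prev


class TestFindHits:
    def test_self_hit_always_found(self, rng):
        region = random_seq(rng, 120)
        cand = tile(region, region_id="locus1")[10]
        hits = find_hits(cand.probe, [{"locus1": region}])
        assert any(h.target_id == "locus1" and h.position == cand.start for h in hits)

    def test_planted_paralog_found_iff_budget_allows(self, rng):
        region = random_seq(rng, 80)
        probe = tile(region, region_id="locus1")[5]
        # paralog with exactly 2 substitutions inside the probe window
        par = list(region)
        for pos in (probe.start + 4, probe.start + 15):
            par[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[par[pos]]
        libs = [{"locus1": region, "locus2": "".join(par)}]
        hits2 = find_hits(probe.probe, libs, max_mm=2)
        assert {h.target_id for h in hits2} == {"locus1", "locus2"}
        hits1 = find_hits(probe.probe, libs, max_mm=1)
        assert {h.target_id for h in hits1} == {"locus1"}

    def test_duplicate_reference_merged(self, rng):
        region = random_seq(rng, 60)
        probe = tile(region, region_id="locusA")[0]
        hits = find_hits(probe.probe, [{"locusA": region}, {"locusA": region}])
        assert len([h for h in hits if h.target_id == "locusA"]) == 1

    def test_no_hit_raises(self, rng):
        probe = ProbeSequence("p", "A" * 25)
        with pytest.raises(ValueError, match="does not match"):
            find_hits(probe, [{"x": "C" * 100}])

    def test_recall_matches_brute_force(self, rng):
        """Seed-and-scan completeness: 100% recall vs the exhaustive scan."""
        n_found = n_expected = 0
        for _ in range(100):
            ref = random_seq(rng, 70)
            start = int(rng.integers(0, 70 - 25))
            var = list(ref[start : start + 25])
            for pos in rng.choice(25, size=int(rng.integers(0, 3)), replace=False):
                var[pos] = "ACGT"[int(rng.integers(4))]
            if rng.random() < 0.4:
                del var[int(rng.integers(len(var)))]
            probe_seq = "".join(var)
            refs = {"r": ref}
            oracle = brute_force_hits(probe_seq, refs, 3, 1)
            backend = SeedScanBackend(refs, 3, 1, len(probe_seq))
            got = {(h.target_id, h.position) for h in backend.find(probe_seq)}
            # the backend reports one hit per physical site; compare per
            # oracle cluster of gap-shifted starts
            for tid, lo, hi in cluster_starts(oracle, max_gap=1):
                n_expected += 1
                if any(t == tid and lo - 1 <= p <= hi + 1 for t, p in got):
                    n_found += 1
        assert n_expected > 0
        assert n_found == n_expected


class TestClassifyProbe:
    def make_candidate(self, rng, n_paralogs, divergence=0.0, seed=0):
        loci, _, _ = sim.simulate_family(n_paralogs, length=120, divergence=divergence,
                                         seed=seed)
        first = loci["locus1"]
        cand = tile(first, region_id="locus1")[3]
        cand.hits = find_hits(cand.probe, [loci])
        return cand, loci

    def test_hit_count_rules(self, rng):
        res, vocab = uniform_results(threshold=10.0)
        for n, expected in [(1, STATUS_SPECIFIC), (3, STATUS_CROSS),
                            (4, STATUS_NONSPECIFIC), (6, STATUS_NONSPECIFIC)]:
            cand, _ = self.make_candidate(rng, n)
            cand.self_affinity = 21.0
            status = classify_probe(cand, res, vocab)
            assert status == expected

    def test_two_hits_cross_hybridizing(self, rng):
        res, vocab = uniform_results(threshold=10.0)
        cand, _ = self.make_candidate(rng, 2)
        cand.self_affinity = 21.0
        assert classify_probe(cand, res, vocab) == STATUS_CROSS

    def test_lower_threshold_never_gains_specificity(self, rng):
        """Monotonicity: lowering T can only add above-threshold hits."""
        res_hi, vocab = uniform_results(threshold=15.0)
        res_lo, _ = uniform_results(threshold=-5.0)
        rank = {STATUS_SPECIFIC: 1, STATUS_CROSS: 2, STATUS_NONSPECIFIC: 3}
        for seed in range(5):
            cand, _ = self.make_candidate(rng, 4, divergence=0.15, seed=seed)
            cand.self_affinity = 21.0
            s_hi = classify_probe(cand, res_hi, vocab)
            cand2, _ = self.make_candidate(rng, 4, divergence=0.15, seed=seed)
            cand2.self_affinity = 21.0
            s_lo = classify_probe(cand2, res_lo, vocab)
            if s_hi in rank and s_lo in rank:
                assert rank[s_lo] >= rank[s_hi]


def spaced_candidates(n, spacing, status=STATUS_SPECIFIC, start0=0, affinity=21.0):
    out = []
    for k in range(n):
        s = start0 + k * spacing
        p = ProbeSequence(f"c{k}", "ACGTA" * 5, "locus", s, s + 25)
        c = CandidateProbe(p, self_affinity=affinity, status=status)
        out.append(c)
    return out


class TestAssembleProbesets:
    def test_ten_spaced_specifics_give_one_set_of_six(self):
        cands = spaced_candidates(10, 20)  # spans 0..205 within one window
        sets = assemble_probesets(cands, "locus")
        assert len(sets) == 1
        assert len(sets[0].probes) == 6

    def test_close_pair_keeps_one(self):
        cands = spaced_candidates(4, 30)
        extra = ProbeSequence("x", "ACGTA" * 5, "locus", 37, 62)
        cands.insert(2, CandidateProbe(extra, self_affinity=21.0,
                                       status=STATUS_SPECIFIC))
        sets = assemble_probesets(cands, "locus")
        starts = sorted(p.start for ps in sets for p in ps.probes)
        assert 37 not in starts  # 7 nt after the probe at 30 -> dropped
        for a, b in zip(starts, starts[1:]):
            assert b - a >= 8

    def test_no_specific_probe_no_probeset(self):
        cands = spaced_candidates(4, 30, status=STATUS_CROSS)
        for k, c in enumerate(cands):
            c.hits = [Hit(f"other{k}", 0, perfect_match_alignment(c.probe), 21.0)]
        assert assemble_probesets(cands, "locus", threshold=10.0) == []

    def test_shared_cross_partner_excluded(self):
        cands = spaced_candidates(5, 40)
        for k in (1, 3):
            cands[k].status = STATUS_CROSS
            cands[k].hits = [
                Hit("partner", 0, perfect_match_alignment(cands[k].probe), 21.0)
            ]
        sets = assemble_probesets(cands, "locus", threshold=10.0)
        assert len(sets) == 1
        cross = [p for p in sets[0].probes if p.status == STATUS_CROSS]
        assert len(cross) == 1  # the second sharer was skipped

    def test_span_restricted_to_window(self):
        cands = spaced_candidates(12, 60)  # 0..685, exceeds one 400-nt window
        sets = assemble_probesets(cands, "locus")
        for ps in sets:
            assert ps.span_end - ps.span_start <= 400
        spans = [(ps.span_start, ps.span_end) for ps in sets]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 >= e1  # emitted probesets do not overlap

    def test_too_few_probes_no_probeset(self):
        assert assemble_probesets(spaced_candidates(2, 30), "locus") == []


class TestDesignLocus:
    def test_identical_paralogs_yield_nothing(self):
        res, vocab = uniform_results(threshold=15.0)
        loci, _, _ = sim.simulate_family(4, length=150, divergence=0.0, seed=1)
        _, sets = design_locus("locus1", loci["locus1"], res, vocab, [loci], step=4)
        assert sets == []

    def test_divergent_family_yields_valid_probesets(self):
        res, vocab = uniform_results(threshold=15.0)
        loci, _, _ = sim.simulate_family(3, length=200, divergence=0.25, seed=5)
        cands, sets = design_locus("locus1", loci["locus1"], res, vocab, [loci], step=2)
        assert sets  # enough divergence for specific probes
        for ps in sets:
            ps.validate(threshold=res.hybridization_threshold)

    def test_pipeline_deterministic(self):
        res, vocab = uniform_results(threshold=15.0)
        loci, _, _ = sim.simulate_family(3, length=150, divergence=0.2, seed=9)
        out1 = design_locus("locus1", loci["locus1"], res, vocab, [loci], step=3)
        out2 = design_locus("locus1", loci["locus1"], res, vocab, [loci], step=3)
        ids1 = [[p.probe.probe_id for p in ps.probes] for ps in out1[1]]
        ids2 = [[p.probe.probe_id for p in ps.probes] for ps in out2[1]]
        assert ids1 == ids2
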