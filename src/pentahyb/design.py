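"""Three-step probe and probeset design: tiling, selection, assembly.

Candidate 25-mers are tiled over each region of interest, filtered on their
perfect-match affinity against their own target, searched against reference
libraries for every hit within a mismatch/gap budget, classified by the
number of above-threshold hits (specific / potentially cross-hybridizing /
non-specific), and finally grouped into probesets of 3-6 probes within a
400 nt window with bounded overlap, at least one specific member and
pairwise-distinct cross-hybridization partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .duplex import (
    BASES,
    DuplexAlignment,
    NoDuplexError,
    ProbeSequence,
    align_duplex,
    extract_features,
    perfect_match_alignment,
)

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGT", "TGCA")

STATUS_SPECIFIC = "specific"
STATUS_CROSS = "potentially_cross_hybridizing"
STATUS_NONSPECIFIC = "non_specific"
STATUS_LOW_AFFINITY = "rejected_low_affinity"
STATUS_UNCLASSIFIED = "unclassified"


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Hit:
    """One occurrence of a probe in a reference library."""

    target_id: str
    position: int  # 0-based start on the reference
    alignment: DuplexAlignment
    affinity: float | None = None

    @property
    def cost(self) -> float:
        return self.alignment.n_mismatches + 1.5 * self.alignment.n_gaps


@dataclass
class CandidateProbe:
    """A tiled probe with its specificity evidence."""

    probe: ProbeSequence
    self_affinity: float = float("nan")
    hits: list = field(default_factory=list)
    status: str = STATUS_UNCLASSIFIED

    @property
    def start(self) -> int:
        return self.probe.start

    @property
    def end(self) -> int:
        return self.probe.end

    def partner_loci(self, threshold: float) -> set:
        """Target ids of above-threshold hits other than the probe's own locus."""
        return {
            h.target_id
            for h in self.hits
            if h.affinity is not None
            and h.affinity >= threshold
            and h.target_id != self.probe.source_contig
        }


@dataclass
class ProbeSet:
    """3-6 probes jointly measuring one locus."""

    probeset_id: str
    locus_id: str
    probes: list  # CandidateProbe
    span_start: int
    span_end: int

    def validate(self, window: int = 400, min_probes: int = 3, max_probes: int = 6,
                 min_separation: int = 8, threshold: float | None = None) -> None:
        """Assert the structural design rules; raises AssertionError on breach."""
        n = len(self.probes)
        assert min_probes <= n <= max_probes, f"{self.probeset_id}: {n} probes"
        assert self.span_end - self.span_start <= window, f"{self.probeset_id}: span too wide"
        starts = sorted(p.start for p in self.probes)
        for a, b in zip(starts, starts[1:]):
            assert b - a >= min_separation, f"{self.probeset_id}: probes {a},{b} too close"
        assert any(p.status == STATUS_SPECIFIC for p in self.probes), (
            f"{self.probeset_id}: no specific probe"
        )
        if threshold is not None:
            seen: set = set()
            for p in self.probes:
                if p.status == STATUS_CROSS:
                    partners = p.partner_loci(threshold)
                    assert not (partners & seen), (
                        f"{self.probeset_id}: shared cross-hybridization partner"
                    )
                    seen |= partners


def tile(
    region: str,
    probe_length: int = 25,
    step: int = 1,
    region_id: str = "region",
    orientations: tuple = ("sense",),
) -> list:
    """Tile a region into candidate probes at offsets 0, step, 2*step, ...

    Regions shorter than the probe length yield an empty list (with a
    warning in the log).  ``N`` or other ambiguous symbols mask every
    candidate window they fall in.
    """
    if step < 1 or step > 4:
        raise ValueError("step must be in [1, 4]")
    region = region.upper()
    if len(region) < probe_length:
        logger.warning("region %s shorter than probe length; no candidates", region_id)
        return []
    out = []
    for off in range(0, len(region) - probe_length + 1, step):
        window = region[off : off + probe_length]
        if set(window) - set(BASES):
            continue  # masked symbols
        for orient in orientations:
            seq = window if orient == "sense" else reverse_complement(window)
            pid = f"{region_id}:{off}:{orient[0]}"
            out.append(
                CandidateProbe(
                    ProbeSequence(
                        pid, seq, source_contig=region_id, start=off,
                        end=off + probe_length, strand="+" if orient == "sense" else "-",
                        orientation=orient,
                    )
                )
            )
    return out


def self_affinity_filter(candidates: list, results, vocabulary) -> list:
    """Keep candidates whose perfect-match affinity reaches the threshold.

    The boundary is inclusive (affinity == T passes) so the calibration
    boundary case is retained.  Rejected candidates are marked
    ``rejected_low_affinity`` in place.
    """
    T = results.hybridization_threshold
    if T is None:
        raise ValueError("model threshold not calibrated; run calibrate_threshold first")
    kept = []
    for cand in candidates:
        pm = perfect_match_alignment(cand.probe)
        fv = extract_features(pm, vocabulary, cand.probe.orientation)
        cand.self_affinity = results.affinity(fv)
        if cand.self_affinity >= T:
            kept.append(cand)
        else:
            cand.status = STATUS_LOW_AFFINITY
    return kept


class SeedScanBackend:
    """Exhaustive seed-and-scan hit search, complete within budget.

    The probe is cut into ``max_mm + max_gaps + 1`` disjoint seeds; by the
    pigeonhole principle any hit within the budget leaves at least one seed
    event-free, whose exact occurrence anchors the candidate site up to a
    +-max_gaps shift.  Each candidate site is verified by optimal duplex
    alignment.  This is the built-in realization of the pluggable aligner
    contract (probe in, hit list out); genome-scale searches would swap in
    an external mapper behind the same interface.
    """

    def __init__(self, references: dict, max_mm: int = 3, max_gaps: int = 1,
                 probe_length: int = 25):
        self.references = dict(references)
        self.max_mm = max_mm
        self.max_gaps = max_gaps
        self.seed_len = max(1, probe_length // (max_mm + max_gaps + 1))
        self.index: dict = {}
        for tid, seq in self.references.items():
            seq = seq.upper()
            for pos in range(len(seq) - self.seed_len + 1):
                self.index.setdefault(seq[pos : pos + self.seed_len], []).append((tid, pos))

    def find(self, probe_seq: str) -> list:
        P = len(probe_seq)
        candidates: set = set()
        for off in range(0, P - self.seed_len + 1, self.seed_len):
            seed = probe_seq[off : off + self.seed_len]
            for tid, pos in self.index.get(seed, ()):
                anchor = pos - off
                for shift in range(-self.max_gaps, self.max_gaps + 1):
                    candidates.add((tid, anchor + shift))
        hits: dict = {}
        for tid, start in sorted(candidates):
            ref = self.references[tid].upper()
            if start < 0 or start > len(ref):
                continue
            best = None
            for L in range(P - self.max_gaps, P + self.max_gaps + 1):
                sub = ref[start : start + L]
                if len(sub) < L:
                    continue
                try:
                    aln = align_duplex(probe_seq, sub, self.max_mm, self.max_gaps)
                except NoDuplexError:
                    continue
                cost = aln.n_mismatches + 1.5 * aln.n_gaps
                if best is None or cost < best[0]:
                    best = (cost, aln)
            if best is not None:
                hits[(tid, start)] = Hit(tid, start, best[1])
        # collapse hits of the same target whose starts differ only by a gap
        # shift: cluster consecutive starts within max_gaps, keep the best
        merged: list[Hit] = []
        cluster: list[Hit] = []

        def flush():
            if cluster:
                merged.append(min(cluster, key=lambda h: (h.cost, h.position)))
                cluster.clear()

        prev: tuple | None = None
        for (tid, start), hit in sorted(hits.items()):
            if prev is not None and (tid != prev[0] or start - prev[1] > self.max_gaps):
                flush()
            cluster.append(hit)
            prev = (tid, start)
        flush()
        return merged


def find_hits(
    probe: ProbeSequence,
    libraries: list,
    max_mm: int = 3,
    max_gaps: int = 1,
    backend=None,
) -> list:
    """All occurrences of a probe in the reference libraries within budget.

    ``libraries`` is a list of id->sequence mappings (e.g. the repetitive
    fraction of a genome and its complement); results are deduplicated by
    (target, position) across libraries.  Raises if no hit is found — every
    tiled candidate must at minimum hit its own source.
    """
    if not libraries:
        raise ValueError("at least one reference library required")
    if backend is None:
        combined: dict = {}
        for lib in libraries:
            for tid, seq in lib.items():
                if tid in combined and combined[tid] != seq:
                    raise ValueError(f"conflicting sequences for reference {tid}")
                combined[tid] = seq
        backend = SeedScanBackend(combined, max_mm, max_gaps, len(probe.sequence))
    hits = backend.find(probe.sequence)
    if not hits:
        raise ValueError(f"probe {probe.probe_id} does not match its own source")
    return sorted(hits, key=lambda h: (h.target_id, h.position))


def classify_probe(candidate: CandidateProbe, results, vocabulary) -> str:
    """Count above-threshold hits: 1 -> specific, 2-3 -> potentially
    cross-hybridizing, >= 4 -> non-specific (excluded downstream)."""
    T = results.hybridization_threshold
    if T is None:
        raise ValueError("model threshold not calibrated")
    for hit in candidate.hits:
        fv = extract_features(hit.alignment, vocabulary, candidate.probe.orientation)
        hit.affinity = results.affinity(fv)
    candidate.hits.sort(key=lambda h: (-(h.affinity), h.target_id, h.position))
    n_above = sum(1 for h in candidate.hits if h.affinity >= T)
    if n_above == 0:
        if candidate.self_affinity >= T:
            raise RuntimeError(
                f"probe {candidate.probe.probe_id}: passed the self-affinity filter "
                "but no hit reaches the threshold (internal inconsistency)"
            )
        candidate.status = STATUS_LOW_AFFINITY
    elif n_above == 1:
        candidate.status = STATUS_SPECIFIC
    elif n_above <= 3:
        candidate.status = STATUS_CROSS
    else:
        candidate.status = STATUS_NONSPECIFIC
    return candidate.status


def assemble_probesets(
    candidates: list,
    locus_id: str,
    window: int = 400,
    min_probes: int = 3,
    max_probes: int = 6,
    min_separation: int = 8,
    threshold: float | None = None,
) -> list:
    """Greedy left-to-right probeset assembly under the design rules.

    Probes are admitted in position order within a 400 nt window anchored at
    the first admissible probe; a probe starting less than ``min_separation``
    after the previously admitted one is skipped (among equal starts the
    higher self-affinity, then the leftmost, wins), as is a cross-hybridizing
    probe sharing a partner locus with an already admitted one.  A window is
    emitted only with >= ``min_probes`` members including one specific probe;
    when more than ``max_probes`` qualify the highest self-affinity (then
    leftmost) are kept, never dropping the last specific member.  Emitted
    probesets are non-overlapping.
    """
    usable = [c for c in candidates if c.status in (STATUS_SPECIFIC, STATUS_CROSS)]
    usable.sort(key=lambda c: (c.start, -(c.self_affinity if c.self_affinity == c.self_affinity else 0.0)))
    # among candidates with identical start keep the best (affinity, then input order)
    dedup: list = []
    for c in usable:
        if dedup and dedup[-1].start == c.start:
            continue
        dedup.append(c)
    out: list[ProbeSet] = []
    i = 0
    n_set = 0
    while i < len(dedup):
        anchor = dedup[i]
        win_end = anchor.start + window
        admitted = [anchor]
        partners: set = anchor.partner_loci(threshold) if (
            threshold is not None and anchor.status == STATUS_CROSS
        ) else set()
        j = i + 1
        last_idx = i
        while j < len(dedup) and dedup[j].end <= win_end:
            c = dedup[j]
            if c.start - admitted[-1].start < min_separation:
                j += 1
                continue
            if threshold is not None and c.status == STATUS_CROSS:
                p = c.partner_loci(threshold)
                if p & partners:
                    j += 1
                    continue
                partners |= p
            admitted.append(c)
            last_idx = j
            j += 1
        ok = len(admitted) >= min_probes and any(
            p.status == STATUS_SPECIFIC for p in admitted
        )
        if ok and len(admitted) > max_probes:
            ranked = sorted(admitted, key=lambda c: (-c.self_affinity, c.start))
            keep = ranked[:max_probes]
            if not any(p.status == STATUS_SPECIFIC for p in keep):
                spec = next(p for p in ranked if p.status == STATUS_SPECIFIC)
                keep[-1] = spec
            admitted = sorted(keep, key=lambda c: c.start)
        if ok:
            n_set += 1
            ps = ProbeSet(
                probeset_id=f"{locus_id}.ps{n_set}",
                locus_id=locus_id,
                probes=admitted,
                span_start=admitted[0].start,
                span_end=admitted[-1].end,
            )
            ps.validate(window, min_probes, max_probes, min_separation, threshold)
            out.append(ps)
            i = last_idx + 1
        else:
            i += 1
    if not out:
        logger.info("locus %s: no probeset satisfies the design rules", locus_id)
    return out


def design_locus(
    locus_id: str,
    sequence: str,
    results,
    vocabulary,
    libraries: list,
    step: int = 1,
    probe_length: int = 25,
    max_mm: int = 3,
    max_gaps: int = 1,
    window: int = 400,
    min_probes: int = 3,
    max_probes: int = 6,
    min_separation: int = 8,
    backend=None,
) -> tuple[list, list]:
    """Full tile -> filter -> hit -> classify -> assemble pipeline for one locus.

    Returns (all candidates with their final status, emitted probesets).
    """
    candidates = tile(sequence, probe_length, step, region_id=locus_id)
    passing = self_affinity_filter(candidates, results, vocabulary)
    for cand in passing:
        cand.hits = find_hits(cand.probe, libraries, max_mm, max_gaps, backend=backend)
        classify_probe(cand, results, vocabulary)
    probesets = assemble_probesets(
        passing, locus_id, window, min_probes, max_probes, min_separation,
        threshold=results.hybridization_threshold,
    )
    return candidates, probesets
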