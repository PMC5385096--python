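"""Probe-target duplexes and their pentamer feature decomposition.

A 25-mer oligonucleotide probe hybridizing a (possibly imperfect) target is
represented as a global alignment whose columns are matches, mismatches or
gaps.  The affinity model decomposes the duplex into overlapping 5-column
windows: a clean window contributes a perfect-match (PM) pentamer token, a
window with exactly one mismatch contributes a mismatch (MM) token recording
the target context, the offset of the mispair and the offending probe base,
and a window with exactly one gap contributes a GAP token recording the
4-base context, the gap offset and which strand carries the gap.  Windows
with two or more events contribute nothing directly; their effect is carried
by interaction indicators over mismatch pairs, keyed by separation class.
Every window token is additionally tagged with one of three equal-size probe
sub-regions, which approximates a position-dependent effect at a fraction of
the parameter cost of per-position k-mers.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

BASES = "ACGT"
WINDOW = 5
N_REGIONS = 3
ORIENTATIONS = ("sense", "antisense")

#: mismatch-pair separation classes (distance in alignment columns)
INTERACTION_CLASSES = ("adjacent", "near", "far")

MATCH = "match"
MISMATCH = "mismatch"
PROBE_GAP = "probe_gap"
TARGET_GAP = "target_gap"


class NoDuplexError(ValueError):
    """No alignment exists within the mismatch/gap budget.

    Signals that a probe-target pair should be treated as non-hybridizing.
    """


@dataclass(frozen=True)
class ProbeSequence:
    """A short oligonucleotide probe, optionally anchored to a contig.

    Coordinates are 0-based half-open.  ``orientation`` records whether the
    probe was synthesized in sense or antisense relative to its source.
    """

    probe_id: str
    sequence: str
    source_contig: str = ""
    start: int = -1
    end: int = -1
    strand: str = "+"
    orientation: str = "sense"

    def __post_init__(self) -> None:
        if set(self.sequence) - set(BASES):
            bad = sorted(set(self.sequence) - set(BASES))
            raise ValueError(f"probe {self.probe_id}: non-ACGT symbols {bad}")
        if self.start >= 0 and self.end >= 0 and self.end - self.start != len(self.sequence):
            raise ValueError(
                f"probe {self.probe_id}: coordinates [{self.start},{self.end}) "
                f"inconsistent with sequence length {len(self.sequence)}"
            )
        if self.strand not in "+-":
            raise ValueError(f"probe {self.probe_id}: strand must be + or -")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"probe {self.probe_id}: orientation must be sense/antisense")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DuplexAlignment:
    """A probe aligned to a candidate target site.

    ``columns`` is the ordered list of ``(probe_symbol, target_symbol,
    state)`` triples; gap columns carry ``"-"`` on the gapped strand.
    """

    probe_id: str
    target_id: str
    columns: list[tuple[str, str, str]]
    n_mismatches: int = field(init=False)
    n_gaps: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_mismatches = sum(1 for c in self.columns if c[2] == MISMATCH)
        self.n_gaps = sum(1 for c in self.columns if c[2] in (PROBE_GAP, TARGET_GAP))

    @property
    def probe_length(self) -> int:
        return sum(1 for c in self.columns if c[2] != PROBE_GAP)

    def state_string(self) -> str:
        """Compact CIGAR-like state string (M/X/D/I per column)."""
        code = {MATCH: "M", MISMATCH: "X", PROBE_GAP: "D", TARGET_GAP: "I"}
        return "".join(code[c[2]] for c in self.columns)


def perfect_match_alignment(probe: ProbeSequence, target_id: str | None = None) -> DuplexAlignment:
    """The identity duplex of a probe with its exact complement."""
    tid = target_id if target_id is not None else f"{probe.probe_id}::self"
    cols = [(b, b, MATCH) for b in probe.sequence]
    return DuplexAlignment(probe.probe_id, tid, cols)


def align_duplex(
    probe: ProbeSequence | str,
    target: str,
    max_mm: int = 3,
    max_gaps: int = 1,
    gap_penalty: float = 1.5,
) -> DuplexAlignment:
    """Minimum-cost global alignment of a probe against a target site.

    Cost is ``n_mismatches + gap_penalty * n_gaps`` (default gap penalty 1.5,
    so one gap is dearer than one mismatch).  Ties are broken toward the
    leftmost gap placement, making the result deterministic.  Raises
    :class:`NoDuplexError` when no alignment fits the ``(max_mm, max_gaps)``
    budget.
    """
    if isinstance(probe, ProbeSequence):
        seq, pid = probe.sequence, probe.probe_id
    else:
        seq, pid = probe, "probe"
    P, T = len(seq), len(target)
    if abs(T - P) > max_gaps:
        raise NoDuplexError(f"target length {T} outside probe length {P} ± {max_gaps}")
    if max_mm > P:
        max_mm = P

    # DP over (probe prefix i, target prefix j, gaps used g); value = (n_mm,
    # gap column indices).  The column count of a state is (i + j + g) / 2,
    # so gap positions are well-defined without tracking the path length.
    # Smaller (mm, gapcols) is better at fixed g; the final pick minimizes
    # (mm + gap_penalty * g, gapcols) over feasible g.
    best: dict[tuple[int, int, int], tuple[int, tuple[int, ...]]] = {(0, 0, 0): (0, ())}
    parent: dict[tuple[int, int, int], tuple[tuple[int, int, int], str]] = {}

    def relax(key, value, par, op):
        cur = best.get(key)
        if cur is None or value < cur:
            best[key] = value
            parent[key] = (par, op)

    for i in range(P + 1):
        for j in range(T + 1):
            for g in range(max_gaps + 1):
                state = (i, j, g)
                if state not in best:
                    continue
                mm, gapcols = best[state]
                col = (i + j + g) // 2  # columns emitted so far
                if i < P and j < T:
                    dm = 0 if seq[i] == target[j] else 1
                    if mm + dm <= max_mm:
                        relax((i + 1, j + 1, g), (mm + dm, gapcols), state,
                              MATCH if dm == 0 else MISMATCH)
                if g < max_gaps:
                    if i < P:  # probe base vs gap in target
                        relax((i + 1, j, g + 1), (mm, gapcols + (col,)), state, TARGET_GAP)
                    if j < T:  # gap in probe vs target base
                        relax((i, j + 1, g + 1), (mm, gapcols + (col,)), state, PROBE_GAP)

    finals = []
    for g in range(max_gaps + 1):
        val = best.get((P, T, g))
        if val is not None and val[0] <= max_mm:
            mm, gapcols = val
            finals.append((mm + gap_penalty * g, gapcols, g))
    if not finals:
        raise NoDuplexError(
            f"no duplex for probe {pid} within budget (max_mm={max_mm}, max_gaps={max_gaps})"
        )
    _, _, g_best = min(finals)

    # traceback
    ops = []
    state = (P, T, g_best)
    while state != (0, 0, 0):
        prev, op = parent[state]
        ops.append(op)
        state = prev
    ops.reverse()

    cols: list[tuple[str, str, str]] = []
    i = j = 0
    for op in ops:
        if op in (MATCH, MISMATCH):
            cols.append((seq[i], target[j], op))
            i += 1
            j += 1
        elif op == TARGET_GAP:
            cols.append((seq[i], "-", op))
            i += 1
        else:
            cols.append(("-", target[j], op))
            j += 1
    return DuplexAlignment(pid, "target", cols)


def assign_region(position: int, probe_length: int) -> int:
    """Sub-region (1..3) of a pentamer window by its start index.

    The ``probe_length - 4`` window starts are split into three equal
    contiguous blocks; for a 25-mer the 21 windows map 7/7/7.
    """
    n_windows = probe_length - WINDOW + 1
    if not 0 <= position < n_windows:
        raise ValueError(f"window start {position} out of range for {n_windows} windows")
    return _region_of(position, n_windows)


def _region_of(window_start: int, n_windows: int) -> int:
    return 1 + min(N_REGIONS - 1, (N_REGIONS * window_start) // n_windows)


@dataclass
class FeatureVector:
    """Sparse token counts of one duplex (the affinity-model design row)."""

    pm_counts: Counter = field(default_factory=Counter)
    mm_counts: Counter = field(default_factory=Counter)
    gap_counts: Counter = field(default_factory=Counter)
    interaction_flags: dict = field(default_factory=dict)

    def items(self):
        """All (token, value) pairs, k-mer counts first then interactions."""
        yield from self.pm_counts.items()
        yield from self.mm_counts.items()
        yield from self.gap_counts.items()
        yield from self.interaction_flags.items()

    @property
    def total_pentamers(self) -> int:
        return sum(self.pm_counts.values()) + sum(self.mm_counts.values()) + sum(
            self.gap_counts.values()
        )


@dataclass
class FeatureVocabulary:
    """Deterministically ordered universe of duplex feature tokens."""

    tokens: list[tuple]
    interaction_tokens: list[tuple]
    probe_length: int = 25

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}
        base = len(self.tokens)
        for k, t in enumerate(self.interaction_tokens):
            self.index[t] = base + k
        if len(self.index) != len(self.tokens) + len(self.interaction_tokens):
            raise ValueError("vocabulary contains duplicate tokens")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token) -> bool:
        return token in self.index

    def to_frame(self):
        """Ordered token table (for TSV export; keeps coefficients reproducible)."""
        import pandas as pd

        rows = [(i, *_token_fields(t)) for i, t in enumerate(self.tokens)]
        rows += [
            (len(self.tokens) + i, *_token_fields(t))
            for i, t in enumerate(self.interaction_tokens)
        ]
        return pd.DataFrame(
            rows, columns=["index", "token_class", "orientation", "region", "payload"]
        )


def _token_fields(token: tuple) -> tuple[str, str, str, str]:
    cls = token[0]
    if cls == "IX":
        return ("IX", "", "", token[1])
    payload = "|".join(str(x) for x in token[3:])
    return (cls, token[1], str(token[2]), payload)


def enumerate_vocabulary(probe_length: int = 25, orientations: int = 2) -> FeatureVocabulary:
    """Enumerate every PM, MM and GAP pentamer token.

    Per orientation and sub-region: 4^5 = 1024 PM pentamers, 1024 x 5 offsets
    x 3 alternative probe bases = 15,360 MM tokens and 4^4 x 5 offsets x 2 gap
    strands = 2,560 GAP tokens (18,944 in all); with two orientations and
    three regions the grand total is 113,664.  Interaction indicators are
    listed separately.
    """
    if probe_length < WINDOW:
        raise ValueError("probe_length must be at least the window size (5)")
    if orientations not in (1, 2):
        raise ValueError("orientations must be 1 or 2")
    orients = ORIENTATIONS[:orientations]
    pentamers = ["".join(p) for p in itertools.product(BASES, repeat=WINDOW)]
    contexts = ["".join(p) for p in itertools.product(BASES, repeat=WINDOW - 1)]
    tokens: list[tuple] = []
    for o in orients:
        for region in range(1, N_REGIONS + 1):
            for k in pentamers:
                tokens.append(("PM", o, region, k))
            for k in pentamers:
                for off in range(WINDOW):
                    for pb in BASES:
                        if pb != k[off]:
                            tokens.append(("MM", o, region, k, off, pb))
            for ctx in contexts:
                for off in range(WINDOW):
                    for strand in ("probe", "target"):
                        tokens.append(("GAP", o, region, ctx, off, strand))
    interactions = [("IX", c) for c in INTERACTION_CLASSES]
    return FeatureVocabulary(tokens, interactions, probe_length)


def _interaction_class(distance: int) -> str:
    if distance <= 2:
        return "adjacent"
    if distance <= 7:
        return "near"
    return "far"


def extract_features(
    alignment: DuplexAlignment,
    vocabulary: FeatureVocabulary,
    orientation: str = "sense",
) -> FeatureVector:
    """Decompose a duplex into region-tagged pentamer tokens (Eq.-2 row).

    Slides a 5-column window over the alignment: 0 events -> PM token;
    exactly one mismatch -> MM token; exactly one gap -> GAP token; >= 2
    events -> nothing (multi-event windows are delegated to the interaction
    indicators).  Mismatch pairs set interaction flags keyed by separation
    class (adjacent <= 2, near 3-7, far >= 8 columns).
    """
    if orientation not in ORIENTATIONS:
        raise ValueError("orientation must be sense/antisense")
    cols = alignment.columns
    n_windows = len(cols) - WINDOW + 1
    if n_windows < 1:
        raise ValueError("alignment shorter than one pentamer window")
    fv = FeatureVector()
    for s in range(n_windows):
        win = cols[s : s + WINDOW]
        events = [(k, c) for k, c in enumerate(win) if c[2] != MATCH]
        region = _region_of(s, n_windows)
        if len(events) == 0:
            token = ("PM", orientation, region, "".join(c[1] for c in win))
            fv.pm_counts[token] += 1
        elif len(events) == 1:
            off, (psym, tsym, state) = events[0]
            if state == MISMATCH:
                token = ("MM", orientation, region, "".join(c[1] for c in win), off, psym)
                fv.mm_counts[token] += 1
            else:
                ctx = "".join(
                    (c[1] if c[1] != "-" else c[0]) for k, c in enumerate(win) if k != off
                )
                strand = "probe" if state == PROBE_GAP else "target"
                token = ("GAP", orientation, region, ctx, off, strand)
                fv.gap_counts[token] += 1
        # >= 2 events: no k-mer token (additivity breaks down; see interactions)
    mism_positions = [k for k, c in enumerate(cols) if c[2] == MISMATCH]
    for a, b in itertools.combinations(mism_positions, 2):
        token = ("IX", _interaction_class(abs(b - a)))
        fv.interaction_flags[token] = 1
    for token, _ in fv.items():
        if token not in vocabulary:
            raise KeyError(
                f"token {token} absent from vocabulary (orientation mismatch "
                "or vocabulary built for a different window size)"
            )
    return fv


def alignment_table(alignments: list[DuplexAlignment]):
    """Alignments as a TSV-ready table (probe, target, state string, counts)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "probe_id": a.probe_id,
                "target_id": a.target_id,
                "states": a.state_string(),
                "n_mm": a.n_mismatches,
                "n_gaps": a.n_gaps,
            }
            for a in alignments
        ]
    )
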