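import numpy as np
import pytest

from pentahyb.duplex import (
    MATCH,
    MISMATCH,
    PROBE_GAP,
    TARGET_GAP,
    DuplexAlignment,
    enumerate_vocabulary,
)

BASES = "ACGT"


@pytest.fixture(scope="session")
def vocab1():
    """Single-orientation vocabulary (sense), shared across the session."""
    return enumerate_vocabulary(25, orientations=1)


@pytest.fixture(scope="session")
def vocab2():
    return enumerate_vocabulary(25, orientations=2)


def random_seq(rng, n=25):
    return "".join(BASES[k] for k in rng.integers(4, size=n))


def random_duplex(rng, length=25, max_mm=2, max_gaps=1):
    """A random alignment with up to max_mm mismatches and max_gaps gaps,
    built column-by-column (independent of align_duplex)."""
    n_mm = int(rng.integers(0, max_mm + 1))
    n_gap = int(rng.integers(0, max_gaps + 1))
    positions = rng.choice(length, size=n_mm + n_gap, replace=False)
    mm_pos = set(positions[:n_mm].tolist())
    gap_pos = set(positions[n_mm:].tolist())
    cols = []
    for k in range(length):
        t = BASES[rng.integers(4)]
        if k in mm_pos:
            p = BASES[(BASES.index(t) + 1 + rng.integers(3)) % 4]
            cols.append((p, t, MISMATCH))
        elif k in gap_pos:
            if rng.random() < 0.5:
                cols.append(("-", t, PROBE_GAP))
            else:
                cols.append((BASES[rng.integers(4)], "-", TARGET_GAP))
        else:
            cols.append((t, t, MATCH))
    return DuplexAlignment("p", "t", cols)


def brute_force_features(alignment, orientation="sense"):
    """Independent window enumerator: expected token multiset of a duplex.

    Re-derives the feature definition by explicit scanning, with the region
    of a window computed from first principles (three equal blocks of
    window starts).
    """
    from collections import Counter

    cols = alignment.columns
    nw = len(cols) - 4
    pm, mm, gap = Counter(), Counter(), Counter()
    inter = {}
    for s in range(nw):
        block = nw / 3.0
        region = 1 if s < block else (2 if s < 2 * block else 3)
        win = cols[s : s + 5]
        ev = [k for k in range(5) if win[k][2] != MATCH]
        if len(ev) == 0:
            pm[("PM", orientation, region, "".join(c[1] for c in win))] += 1
        elif len(ev) == 1:
            k = ev[0]
            psym, tsym, state = win[k]
            if state == MISMATCH:
                mm[("MM", orientation, region, "".join(c[1] for c in win), k, psym)] += 1
            else:
                ctx = "".join(
                    (c[1] if c[1] != "-" else c[0]) for i, c in enumerate(win) if i != k
                )
                strand = "probe" if state == PROBE_GAP else "target"
                gap[("GAP", orientation, region, ctx, k, strand)] += 1
    mmp = [k for k, c in enumerate(cols) if c[2] == MISMATCH]
    for a in range(len(mmp)):
        for b in range(a + 1, len(mmp)):
            d = mmp[b] - mmp[a]
            cls = "adjacent" if d <= 2 else ("near" if d <= 7 else "far")
            inter[("IX", cls)] = 1
    return pm, mm, gap, inter


def brute_force_align(probe, target, max_mm, max_gaps, gap_penalty=1.5):
    """Exhaustive enumeration of all global alignments within the gap
    budget; returns (min cost, gap column tuple) with leftmost preference."""
    best = [None]

    def rec(i, j, col, mm, gaps, gapcols):
        if mm > max_mm or gaps > max_gaps:
            return
        if i == len(probe) and j == len(target):
            cand = (mm + gap_penalty * gaps, tuple(gapcols))
            if best[0] is None or cand < best[0]:
                best[0] = cand
            return
        if i < len(probe) and j < len(target):
            rec(i + 1, j + 1, col + 1, mm + (probe[i] != target[j]), gaps, gapcols)
        if i < len(probe):
            rec(i + 1, j, col + 1, mm, gaps + 1, gapcols + [col])
        if j < len(target):
            rec(i, j + 1, col + 1, mm, gaps + 1, gapcols + [col])

    rec(0, 0, 0, 0, 0, [])
    return best[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
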