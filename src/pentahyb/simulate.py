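"""Synthetic data generators: degenerate training designs, ground-truth
affinity models, intensity matrices and titration experiments.

These emulate the two experimental designs the model and the evaluation
statistics were built for: (i) a training design of probesets made of
perfect-match probes plus degenerate variants (all single mismatches, all
single-base deletions and a sample of double mismatches) hybridized across
multiple arrays, and (ii) a titration design with two pure samples A and B
and mixtures C = 0.75 A + 0.25 B and D = 0.25 A + 0.75 B in technical
triplicates.  All generators are seed-deterministic and return their ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .duplex import (
    BASES,
    MATCH,
    MISMATCH,
    PROBE_GAP,
    DuplexAlignment,
    FeatureVector,
    FeatureVocabulary,
    ProbeSequence,
    extract_features,
    perfect_match_alignment,
)

__all__ = [
    "DegenerateDesign",
    "SimTruth",
    "make_degenerate_design",
    "sample_truth",
    "simulate_intensities",
    "simulate_titration",
    "simulate_family",
    "random_probes",
]


@dataclass
class DegenerateVariant:
    probe_id: str
    parent_id: str
    kind: str  # "pm" | "single_mm" | "double_mm" | "single_gap"
    sequence: str
    alignment: DuplexAlignment  # duplex of the variant vs. the parent target


@dataclass
class DegenerateDesign:
    """A training design of PM probes plus labeled degenerate variants."""

    probes: list = field(default_factory=list)  # DegenerateVariant, PMs included
    pm_per_probeset: int = 10
    variants_per_pm: int = 180
    seed: int = 0

    @property
    def probe_ids(self):
        return [v.probe_id for v in self.probes]


def _mm_alignment(parent: str, pos: int, base: str, pid: str) -> DuplexAlignment:
    cols = [
        (base if k == pos else b, b, MISMATCH if k == pos else MATCH)
        for k, b in enumerate(parent)
    ]
    return DuplexAlignment(pid, "parent", cols)


def _double_mm_alignment(parent: str, subs: dict, pid: str) -> DuplexAlignment:
    cols = [
        (subs.get(k, b), b, MISMATCH if k in subs else MATCH)
        for k, b in enumerate(parent)
    ]
    return DuplexAlignment(pid, "parent", cols)


def _deletion_alignment(parent: str, pos: int, pid: str) -> DuplexAlignment:
    cols = [
        ("-" if k == pos else b, b, PROBE_GAP if k == pos else MATCH)
        for k, b in enumerate(parent)
    ]
    return DuplexAlignment(pid, "parent", cols)


def make_degenerate_design(
    pm_probes: list, variants_per_pm: int = 180, seed: int = 0
) -> DegenerateDesign:
    """Expand each PM probe into its degenerate variant family.

    Per PM 25-mer: all 75 single-mismatch variants (25 positions x 3
    alternative bases), all single-base-deletion variants (deduplicated by
    sequence, keeping the leftmost gap, since deleting either base of an
    adjacent repeat yields the same oligo), and enough distinct random
    double-mismatch variants to reach exactly ``variants_per_pm``.
    """
    if variants_per_pm < 100:
        raise ValueError("variants_per_pm must be >= 100 (75 single MMs + 25 gaps)")
    rng = np.random.default_rng(seed)
    probes: list[DegenerateVariant] = []
    for pm in pm_probes:
        if isinstance(pm, ProbeSequence):
            pid, seq = pm.probe_id, pm.sequence
        else:
            pid, seq = pm
        L = len(seq)
        probes.append(
            DegenerateVariant(pid, pid, "pm", seq, perfect_match_alignment(
                ProbeSequence(pid, seq), pid))
        )
        seen = {seq}
        # all single mismatches
        for pos in range(L):
            for base in BASES:
                if base == seq[pos]:
                    continue
                var = seq[:pos] + base + seq[pos + 1 :]
                vid = f"{pid}:mm{pos}{base}"
                probes.append(DegenerateVariant(vid, pid, "single_mm", var,
                                                _mm_alignment(seq, pos, base, vid)))
                seen.add(var)
        n_single = 3 * L
        # all single deletions, leftmost representative per distinct sequence
        n_del = 0
        for pos in range(L):
            var = seq[:pos] + seq[pos + 1 :]
            if var in seen:
                continue
            vid = f"{pid}:del{pos}"
            probes.append(DegenerateVariant(vid, pid, "single_gap", var,
                                            _deletion_alignment(seq, pos, vid)))
            seen.add(var)
            n_del += 1
        # distinct random double mismatches up to the requested count
        n_double = variants_per_pm - n_single - n_del
        made = 0
        while made < n_double:
            i, j = sorted(rng.choice(L, size=2, replace=False))
            bi = BASES[rng.integers(4)]
            bj = BASES[rng.integers(4)]
            if bi == seq[i] or bj == seq[j]:
                continue
            var = seq[:i] + bi + seq[i + 1 : j] + bj + seq[j + 1 :]
            if var in seen:
                continue
            vid = f"{pid}:dmm{i}{bi}{j}{bj}"
            probes.append(DegenerateVariant(vid, pid, "double_mm", var,
                                            _double_mm_alignment(seq, {i: bi, j: bj}, vid)))
            seen.add(var)
            made += 1
    pm_count = sum(1 for v in probes if v.kind == "pm")
    return DegenerateDesign(probes, pm_per_probeset=pm_count, variants_per_pm=variants_per_pm,
                            seed=seed)


@dataclass
class SimTruth:
    """Ground-truth coefficients and expression for a simulation."""

    beta: dict
    delta: dict
    theta: pd.DataFrame  # arrays x targets, constraint-renormalized
    sigma: float
    seed: int

    def affinity(self, fv: FeatureVector) -> float:
        total = 0.0
        for tok, v in fv.items():
            c = self.delta.get(tok) if tok[0] == "IX" else self.beta.get(tok)
            if c is not None:
                total += c * v
        return total


def sample_truth(
    tokens,
    n_arrays: int,
    n_targets: int,
    sparsity: float = 1.0,
    pm_effect: tuple = (0.3, 0.7),
    mm_shift: float = -0.6,
    gap_shift: float = -0.8,
    interaction_effect: tuple = (-0.8, -0.2),
    sigma: float = 0.0,
    seed: int = 0,
) -> SimTruth:
    """Draw a sparse ground-truth model over a token universe.

    PM-token coefficients are positive draws (stable stacking stabilizes the
    duplex); MM and GAP coefficients are shifted negative so that mispairing
    lowers affinity; interaction coefficients are negative.  Expression theta
    is positive, then renormalized per locus to sum-of-squares N.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    tokens = list(tokens)
    if isinstance(tokens[0], FeatureVocabulary):  # pragma: no cover - convenience
        tokens = tokens[0].tokens + tokens[0].interaction_tokens
    beta: dict = {}
    delta: dict = {}
    for tok in tokens:
        if sparsity < 1.0 and rng.random() > sparsity:
            continue
        if tok[0] == "PM":
            beta[tok] = float(rng.uniform(*pm_effect))
        elif tok[0] == "MM":
            beta[tok] = float(rng.uniform(*pm_effect) + mm_shift)
        elif tok[0] == "GAP":
            beta[tok] = float(rng.uniform(*pm_effect) + gap_shift)
        elif tok[0] == "IX":
            delta[tok] = float(rng.uniform(*interaction_effect))
    theta_raw = rng.uniform(0.5, 2.0, size=(n_arrays, n_targets))
    theta_raw *= np.sqrt(n_arrays / (theta_raw**2).sum(axis=0))
    theta = pd.DataFrame(
        theta_raw,
        index=[f"array{i+1}" for i in range(n_arrays)],
        columns=[f"target{g+1}" for g in range(n_targets)],
    )
    return SimTruth(beta=beta, delta=delta, theta=theta, sigma=float(sigma), seed=seed)


def simulate_intensities(
    truth: SimTruth,
    features: dict,
    probe_to_target: dict,
    seed: int | None = None,
) -> pd.DataFrame:
    """Intensity matrix I_ij = theta_i * phi_j + N(0, sigma^2) noise."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    probe_ids = list(features)
    phi = np.array([truth.affinity(features[p]) for p in probe_ids])
    tcol = truth.theta[pd.Index([probe_to_target[p] for p in probe_ids])].to_numpy()
    I = (tcol * phi).T
    if truth.sigma > 0:
        I = I + rng.normal(0.0, truth.sigma, size=I.shape)
    return pd.DataFrame(I, index=probe_ids, columns=truth.theta.index)


def simulate_titration(
    theta_a: pd.Series,
    theta_b: pd.Series,
    affinities: pd.DataFrame,
    fractions: dict | None = None,
    replicates: int = 3,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the four-sample titration design.

    ``theta_a`` / ``theta_b`` give per-locus expression in the two pure
    samples; ``affinities`` maps probes to loci with columns ``target_id``
    and ``affinity``.  Mixture expression is the concentration-level blend
    theta_mix = alpha * theta_A + beta * theta_B; every replicate array gets
    independent Gaussian noise.  Returns the probe x array intensity matrix
    and a sample sheet (array_id, sample, replicate).
    """
    if fractions is None:
        fractions = {"A": (1.0, 0.0), "B": (0.0, 1.0), "C": (0.75, 0.25), "D": (0.25, 0.75)}
    for s, (a, b) in fractions.items():
        if abs(a + b - 1.0) > 1e-12:
            raise ValueError(f"sample {s}: mixing fractions must sum to 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if replicates < 2:
        import warnings

        warnings.warn("replicates < 2: downstream CVs will not be computable")
    rng = np.random.default_rng(seed)
    probe_ids = list(affinities.index)
    phi = affinities["affinity"].to_numpy()
    targ = affinities["target_id"].to_numpy()
    cols, rows_sheet = [], []
    data = []
    for sample in sorted(fractions):
        alpha, beta_f = fractions[sample]
        theta_mix = alpha * theta_a + beta_f * theta_b
        th = theta_mix[pd.Index(targ)].to_numpy()
        for rep in range(1, replicates + 1):
            arr = f"{sample}{rep}"
            noise = rng.normal(0.0, sigma, size=len(probe_ids)) if sigma > 0 else 0.0
            data.append(th * phi + noise)
            cols.append(arr)
            rows_sheet.append({"array_id": arr, "sample": sample, "replicate": rep})
    I = pd.DataFrame(np.column_stack(data), index=probe_ids, columns=cols)
    sheet = pd.DataFrame(rows_sheet)
    return I, sheet


def simulate_family(
    n_loci: int,
    length: int = 400,
    divergence: float = 0.1,
    seed: int = 0,
) -> tuple[dict, str, dict]:
    """A repetitive family: one ancestor mutated into ``n_loci`` paralogs.

    Each locus substitutes bases independently at rate ``divergence``
    (0 gives identical paralogs — the worst case for cross-hybridization).
    Returns (loci dict id->sequence, ancestral sequence, dict of mutated
    positions per locus for oracle checks).
    """
    if not 0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    ancestor = "".join(BASES[k] for k in rng.integers(4, size=length))
    loci: dict[str, str] = {}
    planted: dict[str, list[int]] = {}
    for n in range(1, n_loci + 1):
        lid = f"locus{n}"
        seq = list(ancestor)
        positions = []
        for pos in range(length):
            if rng.random() < divergence:
                alts = [b for b in BASES if b != seq[pos]]
                seq[pos] = alts[rng.integers(3)]
                positions.append(pos)
        loci[lid] = "".join(seq)
        planted[lid] = positions
    return loci, ancestor, planted


def random_probes(n: int, length: int = 25, seed: int = 0, prefix: str = "p") -> list:
    """Random ACGT probes (fixture helper for model-level simulations)."""
    rng = np.random.default_rng(seed)
    return [
        ProbeSequence(f"{prefix}{k+1}", "".join(BASES[b] for b in rng.integers(4, size=length)))
        for k in range(n)
    ]


def design_features(design: DegenerateDesign, vocabulary: FeatureVocabulary,
                    orientation: str = "sense") -> dict:
    """Feature vectors for every probe of a degenerate design."""
    return {
        v.probe_id: extract_features(v.alignment, vocabulary, orientation)
        for v in design.probes
    }
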