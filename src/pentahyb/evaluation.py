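"""Platform-evaluation statistics for titration experiments.

Implements the accuracy and repeatability metrics used to benchmark an
array on the four-sample titration design (pure samples A and B plus
mixtures C = 0.75A + 0.25B and D = 0.25A + 0.75B, technical triplicates):
background estimators, replicate coefficients of variation, the monotonic
titration response and its fold-change curve, per-probeset mixture-fraction
estimation, and the differential-expression filter used to select probesets
for the mixture analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TitrationDesign",
    "ProbesetSummary",
    "background_trpn",
    "background_gcbg",
    "cv_replicates",
    "titration_monotonic",
    "titration_curve",
    "ratio_at",
    "estimate_mixture",
    "de_filter",
    "median_polish",
    "summarize_probesets",
]

NOT_ATTAINED = float("nan")


@dataclass(frozen=True)
class TitrationDesign:
    """Mixing design of the four titration samples."""

    fractions: tuple = (("A", (1.0, 0.0)), ("B", (0.0, 1.0)),
                        ("C", (0.75, 0.25)), ("D", (0.25, 0.75)))
    replicates: int = 3

    def __post_init__(self):
        for s, (a, b) in self.fractions:
            if abs(a + b - 1.0) > 1e-12:
                raise ValueError(f"sample {s}: fractions must sum to 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ProbesetSummary:
    """Replicate-level summarized intensities of one probeset."""

    probeset_id: str
    replicates: dict  # sample -> array of replicate summaries

    def mean(self, sample: str) -> float:
        return float(np.mean(self.replicates[sample]))

    def cv(self, sample: str) -> float:
        return cv_replicates(self.replicates[sample])

    @property
    def fold_change(self) -> float:
        """Symmetric A/B fold change, max(A/B, B/A)."""
        a, b = self.mean("A"), self.mean("B")
        if a <= 0 or b <= 0:
            return float("nan")
        return max(a / b, b / a)


def background_trpn(control_intensities) -> float:
    """Global background: 15th percentile of the tryptophan control probes.

    Uses the linear-interpolation quantile definition (numpy's default).
    """
    v = np.asarray(control_intensities, dtype=float)
    if v.size == 0:
        raise ValueError("empty control intensity vector")
    return float(np.percentile(v, 15, method="linear"))


def background_gcbg(antigenomic, probe_gc: int) -> float:
    """Probe-level background: median intensity of antigenomic probes with
    the same GC count; an empty GC bin falls back to the nearest populated
    bin (ties toward the lower GC)."""
    bins: dict[int, list[float]] = {}
    for gc, inten in antigenomic:
        bins.setdefault(int(gc), []).append(float(inten))
    if not bins:
        raise ValueError("empty antigenomic probe set")
    if probe_gc in bins:
        return float(np.median(bins[probe_gc]))
    nearest = min(bins, key=lambda g: (abs(g - probe_gc), g))
    return float(np.median(bins[nearest]))


def cv_replicates(values) -> float:
    """Coefficient of variation across technical replicates (linear scale):
    sample standard deviation (ddof=1) over the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    m = float(np.mean(v))
    if m <= 0:
        raise ValueError("non-positive replicate mean")
    return float(np.std(v, ddof=1) / m)


def titration_monotonic(a: float, c: float, d: float, b: float) -> bool:
    """True iff the four sample means are strictly ordered consistently with
    the mixing fractions: A > C > D > B, or B > D > C > A. Ties fail."""
    return (a > c > d > b) or (b > d > c > a)


def titration_curve(summaries: list, bins) -> pd.DataFrame:
    """Percent of probesets with a monotonic titration, per fold-change bin.

    ``bins`` are edges over the symmetric A/B fold change; bin membership is
    left-open right-closed except the first bin which includes its left
    edge.  Returns a table with bin edges, midpoints, probeset counts and
    the monotonic percentage.
    """
    edges = np.asarray(bins, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    rows = []
    fc = np.array([s.fold_change for s in summaries])
    mono = np.array(
        [titration_monotonic(s.mean("A"), s.mean("C"), s.mean("D"), s.mean("B"))
         for s in summaries]
    )
    for lo, hi in zip(edges, edges[1:]):
        if lo == edges[0]:
            mask = (fc >= lo) & (fc <= hi)
        else:
            mask = (fc > lo) & (fc <= hi)
        n = int(mask.sum())
        pct = float(100.0 * mono[mask].mean()) if n else float("nan")
        rows.append({"fc_low": lo, "fc_high": hi, "fc_mid": 0.5 * (lo + hi),
                     "n_probesets": n, "pct_monotonic": pct})
    return pd.DataFrame(rows)


def ratio_at(curve: pd.DataFrame, level: float = 75.0) -> float:
    """Smallest fold change at which the titration curve reaches ``level``
    percent, by linear interpolation between bin midpoints.

    Returns NaN ("not attained") when the curve never reaches the level.
    """
    cur = curve.dropna(subset=["pct_monotonic"])
    mids = cur["fc_mid"].to_numpy()
    pct = cur["pct_monotonic"].to_numpy()
    for k in range(len(pct)):
        if pct[k] >= level:
            if k == 0 or pct[k - 1] >= level:
                return float(mids[k])
            x0, x1 = mids[k - 1], mids[k]
            y0, y1 = pct[k - 1], pct[k]
            return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))
    return NOT_ATTAINED


def estimate_mixture(a_mean, b_mean, mix_mean, method: str = "per_probeset"):
    """Estimated mixing fractions (alpha, beta) of a titration sample.

    The default estimator solves, per probeset, the mixture identity
    mix = alpha*a + beta*b under alpha + beta = 1 (the only identifiable
    per-probeset form, one equation per probeset), giving
    beta_i = (a_i - mix_i) / (a_i - b_i); probesets with a ~= b (collinear
    predictors) are skipped with a warning, and the median (alpha, beta)
    across probesets is reported.  ``method="pooled"`` instead fits one
    unconstrained no-intercept OLS of mix on (a, b) across all probesets.
    """
    a = np.asarray(a_mean, float)
    b = np.asarray(b_mean, float)
    m = np.asarray(mix_mean, float)
    if not (len(a) == len(b) == len(m)) or len(a) < 2:
        raise ValueError("need equal-length vectors over >= 2 probesets")
    if method == "pooled":
        X = np.column_stack([a, b])
        coef, *_ = np.linalg.lstsq(X, m, rcond=None)
        return float(coef[0]), float(coef[1])
    denom = a - b
    scale = np.maximum(np.abs(a), np.abs(b))
    ok = np.abs(denom) > 1e-12 * np.maximum(scale, 1.0)
    if not ok.all():
        import warnings

        warnings.warn(f"{int((~ok).sum())} probesets with A ~= B skipped in mixture estimation")
    if not ok.any():
        raise ValueError("all probesets collinear; mixture not estimable")
    beta = (a[ok] - m[ok]) / denom[ok]
    beta_hat = float(np.median(beta))
    return 1.0 - beta_hat, beta_hat


def de_filter(
    a_reps: pd.DataFrame,
    b_reps: pd.DataFrame,
    q_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    floor: float = 16.0,
) -> pd.DataFrame:
    """Differential-expression filter between the two pure samples.

    Per probeset (rows of the replicate tables): Welch t-test between A and
    B replicates with Benjamini-Hochberg adjustment across probesets; a
    probeset is kept when q <= ``q_threshold``, the A/B fold change (either
    direction) is >= ``fc_threshold`` and the median replicate intensity is
    >= ``floor`` (default 2^4) in at least one sample.  Returns the full
    table with a boolean ``kept`` column.
    """
    if not a_reps.index.equals(b_reps.index):
        raise ValueError("replicate tables must share the probeset index")
    if a_reps.shape[1] < 2 or b_reps.shape[1] < 2:
        raise ValueError("need >= 2 replicates per sample")
    A = a_reps.to_numpy(float)
    B = b_reps.to_numpy(float)
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.maximum(mean_a / mean_b, mean_b / mean_a)
    med_ok = (np.median(A, axis=1) >= floor) | (np.median(B, axis=1) >= floor)
    kept = (q <= q_threshold) & (fc >= fc_threshold) & med_ok
    return pd.DataFrame(
        {"mean_A": mean_a, "mean_B": mean_b, "fold_change": fc, "p_value": p,
         "q_value": q, "median_ok": med_ok, "kept": kept},
        index=a_reps.index,
    )


def median_polish(matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-6):
    """Tukey's median polish of a probes x arrays block.

    Returns (overall effect, row effects, column effects, residuals); the
    summarized per-array value of a probeset is overall + column effect.
    """
    Z = np.array(matrix, dtype=float)
    nr, nc = Z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        rmed = np.median(Z, axis=1)
        Z -= rmed[:, None]
        row += rmed
        cmed = np.median(row)
        overall += cmed
        row -= cmed
        ccol = np.median(Z, axis=0)
        Z -= ccol[None, :]
        col += ccol
        rmed2 = np.median(col)
        overall += rmed2
        col -= rmed2
        if np.abs(rmed).max() < tol and np.abs(ccol).max() < tol:
            break
    return overall, row, col, Z


def summarize_probesets(
    intensities: pd.DataFrame,
    probe_to_probeset: dict,
    sample_sheet: pd.DataFrame,
) -> list:
    """Median-polish summarization of probe intensities into
    :class:`ProbesetSummary` objects.

    ``sample_sheet`` needs columns array_id, sample, replicate.  Within each
    probeset the probes x arrays block is median-polished and the per-array
    summary (overall + array effect) grouped into per-sample replicate
    vectors.
    """
    required = {"array_id", "sample", "replicate"}
    if not required <= set(sample_sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    arrays = list(intensities.columns)
    sheet = sample_sheet.set_index("array_id").loc[arrays]
    groups: dict[str, list[str]] = {}
    for p in intensities.index:
        ps = probe_to_probeset.get(p)
        if ps is not None:
            groups.setdefault(ps, []).append(p)
    out = []
    for ps_id in sorted(groups):
        block = intensities.loc[groups[ps_id]].to_numpy(float)
        overall, _, col, _ = median_polish(block)
        per_array = overall + col
        reps: dict[str, list[float]] = {}
        for val, (_, row) in zip(per_array, sheet.iterrows()):
            reps.setdefault(str(row["sample"]), []).append(float(val))
        out.append(ProbesetSummary(ps_id, {s: np.array(v) for s, v in reps.items()}))
    return out
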