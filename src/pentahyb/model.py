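"""Pentamer region-dependent hybridization affinity model.

The observed linear-scale intensity of probe j on array i is modelled as

    I_ij = theta_i(g(j)) * phi_j + eps_ij,     eps_ij ~ N(0, sigma^2)

where theta is the expression level of the targeted locus g(j) on array i
(identified up to scale by the per-locus constraint sum_i theta_i^2 = N,
N the number of arrays) and phi_j is the sequence-determined affinity

    phi_j = sum_l sum_k beta_k^l X_jk^l  +  sum_m delta_m Z_jm

a sparse linear form over region-tagged pentamer counts X and mismatch
interaction indicators Z.  Coefficients are estimated by L1-penalized
(LASSO) regression with the penalty chosen by grouped cross-validation,
alternating with closed-form least-squares updates of theta.

Organisation follows the Model/Results convention: build a
:class:`PentamerAffinityModel` from an intensity matrix plus per-probe
feature vectors, call :meth:`~PentamerAffinityModel.fit`, and work with the
returned :class:`PentamerAffinityResults`.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import Lasso, lasso_path

from .duplex import FeatureVector, FeatureVocabulary

__all__ = [
    "PentamerAffinityModel",
    "PentamerAffinityResults",
    "renormalize_theta",
    "calibrate_threshold",
    "evaluate_fit",
    "fit_affinity_model",
]


def renormalize_theta(theta_g: np.ndarray, n_arrays: int) -> np.ndarray:
    """Rescale one locus's expression vector so that sum(theta^2) == N."""
    theta_g = np.asarray(theta_g, dtype=float)
    ss = float(theta_g @ theta_g)
    if ss == 0.0:
        raise ValueError("cannot renormalize an all-zero expression vector")
    return theta_g * np.sqrt(n_arrays / ss)


class PentamerAffinityModel:
    """Intensity model binding data to the affinity decomposition.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Linear-scale intensities, probes in rows, arrays in columns.
    features : mapping of probe_id -> FeatureVector
        One duplex feature vector per probe (its perfect-match duplex for
        design training, or any degenerate duplex).
    probe_to_target : mapping of probe_id -> target_id
        The locus each probe measures (theta is per array x locus).
    vocabulary : FeatureVocabulary, optional
        Retained for provenance; the design matrix is restricted to tokens
        actually observed in ``features``.
    """

    def __init__(self, intensities: pd.DataFrame, features: dict, probe_to_target: dict,
                 vocabulary: FeatureVocabulary | None = None):
        missing = [p for p in intensities.index if p not in features]
        if missing:
            raise ValueError(f"probes without features: {missing[:5]}...")
        missing = [p for p in intensities.index if p not in probe_to_target]
        if missing:
            raise ValueError(f"probes without a target: {missing[:5]}...")
        if intensities.shape[1] < 2:
            raise ValueError("at least 2 arrays required")
        self.intensities = intensities
        self.features = features
        self.vocabulary = vocabulary
        self.probe_ids = list(intensities.index)
        self.array_ids = list(intensities.columns)
        self.targets = [probe_to_target[p] for p in self.probe_ids]
        self.target_ids = sorted(set(self.targets))
        self.probe_to_target = dict(probe_to_target)

        tokens: set = set()
        for p in self.probe_ids:
            for tok, _ in features[p].items():
                tokens.add(tok)
        self.token_list = sorted(tokens, key=repr)
        tindex = {t: k for k, t in enumerate(self.token_list)}
        rows, cols, vals = [], [], []
        for r, p in enumerate(self.probe_ids):
            for tok, v in features[p].items():
                rows.append(r)
                cols.append(tindex[tok])
                vals.append(float(v))
        self.X = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.probe_ids), len(self.token_list))
        )

    # ------------------------------------------------------------------ fit
    def _init_theta(self) -> pd.DataFrame:
        """Per-(array, locus) mean intensity, constraint-renormalized."""
        I = self.intensities
        theta = pd.DataFrame(0.0, index=self.array_ids, columns=self.target_ids)
        for g in self.target_ids:
            probes = [p for p, t in zip(self.probe_ids, self.targets) if t == g]
            means = I.loc[probes].mean(axis=0).to_numpy()
            if np.allclose(means, 0.0):
                theta[g] = 1.0  # constraint-satisfying constant; flagged later
            else:
                theta[g] = renormalize_theta(means, len(self.array_ids))
        return theta

    def _fold_assignment(self, n_folds: int, rng: np.random.Generator) -> np.ndarray:
        """Probe folds, stratified by locus (round-robin within each locus)."""
        folds = np.zeros(len(self.probe_ids), dtype=int)
        offset = 0
        for g in self.target_ids:
            idx = [k for k, t in enumerate(self.targets) if t == g]
            rng.shuffle(idx)
            for pos, k in enumerate(idx):
                folds[k] = (offset + pos) % n_folds
            offset += len(idx)
        return folds

    def _stack_design(self, theta: pd.DataFrame):
        """Observation vector and theta-scaled sparse design, array-major."""
        blocks, ys = [], []
        tcol = theta[pd.Index(self.targets)].to_numpy()  # arrays x probes
        I = self.intensities.to_numpy()
        for ai in range(len(self.array_ids)):
            scale = sp.diags(tcol[ai])
            blocks.append(scale @ self.X)
            ys.append(I[:, ai])
        return sp.vstack(blocks).tocsr(), np.concatenate(ys)

    def _select_penalty(self, A, y, folds_obs, n_folds, n_alphas=30):
        """Grouped-CV alpha path with the 1-SE rule (largest alpha within
        one standard error of the minimum mean CV error)."""
        n = A.shape[0]
        alpha_max = np.max(np.abs(A.T @ y)) / n
        if alpha_max <= 0:
            return 1e-6
        alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max) - 3, n_alphas)
        mse = np.zeros((n_folds, n_alphas))
        for f in range(n_folds):
            tr = folds_obs != f
            te = ~tr
            _, coefs, _ = lasso_path(A[tr], y[tr], alphas=alphas, max_iter=5000)
            pred = A[te] @ coefs  # n_test x n_alphas
            mse[f] = np.mean((pred - y[te][:, None]) ** 2, axis=0)
        mean = mse.mean(axis=0)
        se = mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
        k_min = int(np.argmin(mean))
        allowed = mean <= mean[k_min] + se[k_min]
        # alphas are descending; the first allowed index is the largest alpha
        k_1se = int(np.argmax(allowed))
        return float(alphas[k_1se])

    def fit(
        self,
        n_folds: int = 10,
        seed: int = 0,
        penalty: float | None = None,
        tol: float = 1e-6,
        max_iter: int = 100,
        reselect_penalty: bool = False,
    ) -> "PentamerAffinityResults":
        """Alternating LASSO / least-squares estimation of (beta, delta, theta).

        The L1 penalty is chosen by ``n_folds``-fold cross-validation over
        probes (folds stratified by locus, 1-SE rule) at the first iteration
        and then held fixed unless ``reselect_penalty`` is set.  Convergence
        is declared when the relative change in training RSS drops below
        ``tol``; theta is renormalized to the sum-of-squares constraint after
        every update.
        """
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        rng = np.random.default_rng(seed)
        theta = self._init_theta()
        folds_probe = self._fold_assignment(n_folds, rng)
        folds_obs = np.tile(folds_probe, len(self.array_ids))

        n_obs = len(self.probe_ids) * len(self.array_ids)
        I = self.intensities.to_numpy()
        rss_history: list[float] = []
        constraint_dev_history: list[float] = []
        coef = np.zeros(self.X.shape[1])
        alpha = penalty
        flagged = [
            g
            for g in self.target_ids
            if np.allclose(
                self.intensities.loc[[p for p, t in zip(self.probe_ids, self.targets) if t == g]],
                0.0,
            )
        ]
        converged = False
        for it in range(max_iter):
            A, y = self._stack_design(theta)
            if alpha is None or (reselect_penalty and it > 0):
                alpha = self._select_penalty(A, y, folds_obs, n_folds)
            lasso = Lasso(alpha=alpha, fit_intercept=False, max_iter=20000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lasso.fit(A, y)
            coef = lasso.coef_

            phi = self.X @ coef
            for g in self.target_ids:
                mask = np.array([t == g for t in self.targets])
                pg = phi[mask]
                denom = float(pg @ pg)
                if denom == 0.0 or g in flagged:
                    theta[g] = 1.0
                    continue
                raw = I[mask].T @ pg / denom  # per array
                if np.allclose(raw, 0.0):
                    theta[g] = 1.0
                else:
                    theta[g] = renormalize_theta(raw, len(self.array_ids))

            ss = (theta.to_numpy() ** 2).sum(axis=0)
            constraint_dev_history.append(
                float(np.max(np.abs(ss - len(self.array_ids))) / len(self.array_ids))
            )

            tcol = theta[pd.Index(self.targets)].to_numpy()
            resid = I - (tcol * phi).T
            rss = float(np.sum(resid**2))
            rss_history.append(rss)
            if len(rss_history) > 1:
                prev = rss_history[-2]
                if prev > 0 and abs(prev - rss) / prev < tol:
                    converged = True
                    break
                if rss == 0.0:
                    converged = True
                    break

        sigma = float(np.sqrt(rss_history[-1] / n_obs))
        beta = {t: float(c) for t, c in zip(self.token_list, coef) if c != 0 and t[0] != "IX"}
        delta = {t: float(c) for t, c in zip(self.token_list, coef) if c != 0 and t[0] == "IX"}
        return PentamerAffinityResults(
            model=self,
            beta=beta,
            delta=delta,
            lasso_penalty=float(alpha),
            theta=theta,
            noise_sd=sigma,
            rss_history=rss_history,
            constraint_dev_history=constraint_dev_history,
            converged=converged,
            seed=seed,
            flagged_targets=flagged,
        )


@dataclass
class PentamerAffinityResults:
    """Fitted affinity model: sparse coefficients, expression, diagnostics."""

    model: PentamerAffinityModel | None
    beta: dict
    delta: dict
    lasso_penalty: float
    theta: pd.DataFrame
    noise_sd: float
    rss_history: list = field(default_factory=list)
    constraint_dev_history: list = field(default_factory=list)
    converged: bool = True
    seed: int | None = None
    flagged_targets: list = field(default_factory=list)
    hybridization_threshold: float | None = None

    # ------------------------------------------------------------ prediction
    def affinity(self, features: FeatureVector) -> float:
        """phi = sum beta * count + sum delta * flag (absent coefficients are 0)."""
        total = 0.0
        for tok, v in features.items():
            c = self.delta.get(tok) if tok[0] == "IX" else self.beta.get(tok)
            if c is not None:
                total += c * v
        return total

    def predict_intensity(self, features: FeatureVector, theta: float) -> float:
        """Noiseless expectation theta * phi."""
        return theta * self.affinity(features)

    def calibrate_threshold(self, features: dict, intensities: pd.DataFrame,
                            background: float) -> float:
        """Calibrate and store the hybridization threshold (see
        :func:`calibrate_threshold`)."""
        T = calibrate_threshold(self, features, intensities, background)
        self.hybridization_threshold = T
        return T

    # ------------------------------------------------------------ reporting
    def summary(self) -> str:
        m = self.model
        lines = [
            "Pentamer hybridization affinity model",
            "=" * 53,
            f"{'No. probes:':<28}{len(m.probe_ids) if m else 'NA'}",
            f"{'No. arrays:':<28}{len(m.array_ids) if m else 'NA'}",
            f"{'No. loci:':<28}{self.theta.shape[1]}",
            f"{'Active PM/MM/GAP coefs:':<28}{len(self.beta)}",
            f"{'Active interaction coefs:':<28}{len(self.delta)}",
            f"{'LASSO penalty (alpha):':<28}{self.lasso_penalty:.6g}",
            f"{'Residual noise sd:':<28}{self.noise_sd:.6g}",
            f"{'Iterations:':<28}{len(self.rss_history)}",
            f"{'Converged:':<28}{self.converged}",
        ]
        if self.hybridization_threshold is not None:
            lines.append(f"{'Hybridization threshold:':<28}{self.hybridization_threshold:.6g}")
        if self.flagged_targets:
            lines.append(f"{'Flagged (all-zero) loci:':<28}{len(self.flagged_targets)}")
        return "\n".join(lines)

    # --------------------------------------------------------- serialization
    def save(self, path) -> None:
        """Versioned plain-text model dump (sparse coefficient triples)."""
        buf = io.StringIO()
        vocab_hash = ""
        if self.model is not None:
            h = hashlib.md5()
            for t in self.model.token_list:
                h.update(repr(t).encode())
            vocab_hash = h.hexdigest()
        thr = "NA" if self.hybridization_threshold is None else repr(self.hybridization_threshold)
        buf.write("#pentahyb-model\tv1\n")
        buf.write(f"#penalty\t{self.lasso_penalty!r}\n")
        buf.write(f"#threshold\t{thr}\n")
        buf.write(f"#sigma\t{self.noise_sd!r}\n")
        buf.write(f"#vocabulary-hash\t{vocab_hash}\n")
        for tok, c in sorted(self.beta.items(), key=lambda kv: repr(kv[0])):
            buf.write(f"{_encode_token(tok)}\t{c!r}\n")
        for tok, c in sorted(self.delta.items(), key=lambda kv: repr(kv[0])):
            buf.write(f"{_encode_token(tok)}\t{c!r}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "PentamerAffinityResults":
        beta, delta = {}, {}
        penalty = sigma = 0.0
        threshold = None
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
            if not first.startswith("#pentahyb-model\tv1"):
                raise ValueError(f"{path}: not a v1 model file")
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#penalty"):
                    penalty = float(line.split("\t")[1])
                elif line.startswith("#threshold"):
                    v = line.split("\t")[1]
                    threshold = None if v == "NA" else float(v)
                elif line.startswith("#sigma"):
                    sigma = float(line.split("\t")[1])
                elif line.startswith("#"):
                    continue
                else:
                    tok, c = _decode_token_line(line)
                    (delta if tok[0] == "IX" else beta)[tok] = c
        return cls(
            model=None,
            beta=beta,
            delta=delta,
            lasso_penalty=penalty,
            theta=pd.DataFrame(),
            noise_sd=sigma,
            hybridization_threshold=threshold,
        )


def _encode_token(tok: tuple) -> str:
    return "\x1f".join(str(x) for x in tok)


def _decode_token_line(line: str):
    payload, value = line.rsplit("\t", 1)
    parts = payload.split("\x1f")
    out = []
    for p in parts:
        out.append(int(p) if p.isdigit() else p)
    return tuple(out), float(value)


def calibrate_threshold(results: PentamerAffinityResults, features: dict,
                        intensities: pd.DataFrame, background: float) -> float:
    """Hybridization threshold: the largest affinity T such that >= 90% of
    probes with affinity < T have median intensity below ``background``.

    Candidate thresholds are the observed affinity values (no parametric
    fit); when several candidates qualify the largest is returned, and the
    scan never extends beyond observed affinities (ties resolve toward the
    smaller, more conservative T).
    """
    if not np.isfinite(background):
        raise ValueError("background must be finite")
    probes = list(intensities.index)
    phi = np.array([results.affinity(features[p]) for p in probes])
    med = intensities.median(axis=1).to_numpy()
    sub = med < background
    if not sub.any():
        raise ValueError("threshold not calibratable: no probe below background")
    best = None
    for T in np.unique(phi):
        below = phi < T
        n = int(below.sum())
        if n == 0:
            continue
        frac = float(sub[below].sum()) / n
        if frac >= 0.90:
            best = float(T)
    if best is None:
        raise ValueError("threshold not calibratable: 90% rule never satisfied")
    return best


def evaluate_fit(
    results: PentamerAffinityResults,
    intensities: pd.DataFrame,
    features: dict,
    probe_to_target: dict,
    heldout_fraction: float = 1 / 3,
    seed: int = 0,
) -> float:
    """Held-out R^2 of predicted vs observed intensities.

    Per locus, the expression level is re-estimated on roughly two-thirds of
    the probes by regressing intensities on model affinities; intensities of
    the remaining third are predicted as theta * phi.  Returns the squared
    Pearson correlation between observed and predicted held-out intensities.
    Probesets with fewer than 3 probes are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    obs_all, pred_all = [], []
    targets = sorted({probe_to_target[p] for p in intensities.index})
    for g in targets:
        probes = [p for p in intensities.index if probe_to_target[p] == g]
        if len(probes) < 3:
            warnings.warn(f"locus {g}: fewer than 3 probes, skipped in evaluation")
            continue
        phi = np.array([results.affinity(features[p]) for p in probes])
        order = rng.permutation(len(probes))
        n_test = max(1, int(round(len(probes) * heldout_fraction)))
        test = order[:n_test]
        train = order[n_test:]
        if len(train) == 0 or float(phi[train] @ phi[train]) == 0.0:
            continue
        I = intensities.loc[probes].to_numpy()
        for ai in range(I.shape[1]):
            th = float(I[train, ai] @ phi[train]) / float(phi[train] @ phi[train])
            obs_all.extend(I[test, ai])
            pred_all.extend(th * phi[test])
    obs = np.asarray(obs_all)
    pred = np.asarray(pred_all)
    if len(obs) < 2 or np.std(obs) == 0 or np.std(pred) == 0:
        return 0.0
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r * r


def fit_affinity_model(intensities, features, probe_to_target, n_folds: int = 10,
                       seed: int = 0, **kwargs) -> PentamerAffinityResults:
    """One-call convenience wrapper around Model construction + fit."""
    return PentamerAffinityModel(intensities, features, probe_to_target).fit(
        n_folds=n_folds, seed=seed, **kwargs
    )
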