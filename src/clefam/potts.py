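"""Potts (fields + pairwise couplings) model of fixed-length peptide motifs.

The model assigns each length-L sequence s a statistical energy

    E(s) = sum_i h_i(s_i) + sum_{i<j} J_ij(s_i, s_j)

with the sign convention that HIGHER energy means a MORE probable
sequence, so a deleterious substitution has a NEGATIVE energy change.
Parameters are fit by L2-regularized pseudolikelihood maximization on a
gapless motif alignment with identity-based sequence reweighting, the
standard approach for direct-coupling analysis of protein families.
Couplings are estimated asymmetrically (one conditional regression per
site) and symmetrized by averaging the two per-pair estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import scipy.optimize
import scipy.stats

from . import aa


@dataclass
class PottsModel:
    """Per-site fields and pairwise couplings over a fixed-length motif."""

    L: int
    A: int
    h: np.ndarray                      # (L, A)
    J: np.ndarray                      # (L, L, A, A); J[i,j] == J[j,i].T, J[i,i] == 0
    lambda_h: float = 0.0
    lambda_J: float = 0.0
    theta: float = 0.8
    n_eff: float = 0.0

    def check_shapes(self) -> None:
        if self.h.shape != (self.L, self.A):
            raise ValueError("field array shape mismatch")
        if self.J.shape != (self.L, self.L, self.A, self.A):
            raise ValueError("coupling array shape mismatch")
        if not np.allclose(self.J, np.transpose(self.J, (1, 0, 3, 2))):
            raise ValueError("couplings are not symmetric")
        for i in range(self.L):
            if np.any(self.J[i, i] != 0.0):
                raise ValueError("diagonal coupling blocks must be zero")

    @classmethod
    def zeros(cls, L: int, A: int = aa.A) -> "PottsModel":
        return cls(L=L, A=A, h=np.zeros((L, A)), J=np.zeros((L, L, A, A)))

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "L": self.L, "A": self.A,
            "lambda_h": self.lambda_h, "lambda_J": self.lambda_J,
            "theta": self.theta, "n_eff": self.n_eff,
            "h": self.h.tolist(), "J": self.J.ravel().tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PottsModel":
        d = json.loads(Path(path).read_text())
        L, A = d["L"], d["A"]
        return cls(
            L=L, A=A,
            h=np.asarray(d["h"], dtype=float),
            J=np.asarray(d["J"], dtype=float).reshape(L, L, A, A),
            lambda_h=d["lambda_h"], lambda_J=d["lambda_J"],
            theta=d["theta"], n_eff=d["n_eff"],
        )


@dataclass
class MutationalLandscape:
    """All single-substitution energy changes relative to a wild type.

    ``effects[i, a]`` is E(mutant) - E(wild type) for substituting residue
    ``a`` at position ``i`` (0-based internally); wild-type cells are
    exactly zero, and negative values are deleterious.
    """

    wt: str
    effects: np.ndarray                # (L, A)
    alphabet: str = dc_field(default=aa.ALPHABET)


# ---------------------------------------------------------------------------
# reweighting


def sequence_weights(msa: list[str], theta: float = 0.8) -> np.ndarray:
    """Identity-based sequence weights: 1 / (# sequences with fractional
    identity >= theta, self included).  The sum of weights is Neff."""
    if not msa:
        raise ValueError("empty alignment")
    L = len(msa[0])
    if any(len(s) != L for s in msa):
        raise ValueError("ragged alignment: all sequences must have equal length")
    X = np.array([aa.encode(s) for s in msa])
    n = len(msa)
    counts = np.zeros(n)
    for i in range(n):
        ident = (X == X[i]).mean(axis=1)
        counts[i] = np.sum(ident >= theta)
    return 1.0 / counts


# ---------------------------------------------------------------------------
# pseudolikelihood fit


def _encode_msa(msa: list[str]) -> np.ndarray:
    X = np.array([aa.encode(s) for s in msa])
    if X.ndim != 2:
        raise ValueError("ragged alignment")
    return X


def _plpl_objective(params: np.ndarray, Xoh: np.ndarray, Xflat: np.ndarray,
                    w: np.ndarray, L: int, A: int,
                    lambda_h: float, lambda_J: float,
                    diag_mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative weighted pseudolikelihood with L2 penalties and its gradient.

    Parameters are the flattened fields (L*A) followed by the asymmetric
    coupling matrix W of shape (L*A, L*A) whose diagonal A x A blocks are
    fixed at zero via ``diag_mask``.
    """
    LA = L * A
    h = params[:LA].reshape(L, A)
    W = params[LA:].reshape(LA, LA) * diag_mask
    logits = (Xflat @ W.T).reshape(-1, L, A) + h[None, :, :]
    logits -= logits.max(axis=2, keepdims=True)
    expl = np.exp(logits)
    Z = expl.sum(axis=2)
    logp_obs = np.take_along_axis(
        logits, np.argmax(Xoh, axis=2)[:, :, None], axis=2
    )[:, :, 0] - np.log(Z)
    nll = -np.sum(w[:, None] * logp_obs)

    P = expl / Z[:, :, None]
    D = w[:, None, None] * (P - Xoh)           # (N, L, A)
    Dflat = D.reshape(-1, LA)
    grad_h = D.sum(axis=0)
    grad_W = (Dflat.T @ Xflat) * diag_mask

    nll += lambda_h * np.sum(h**2) + lambda_J * np.sum(W**2)
    grad_h = grad_h + 2.0 * lambda_h * h
    grad_W = grad_W + 2.0 * lambda_J * W
    return nll, np.concatenate([grad_h.ravel(), grad_W.ravel()])


def fit_potts(msa: list[str], weights: np.ndarray | None = None,
              lambda_h: float | None = None, lambda_J: float | None = None,
              theta: float = 0.8, tol: float = 1e-6,
              max_iter: int = 500) -> PottsModel:
    """Fit fields and couplings by regularized pseudolikelihood maximization.

    ``weights`` default to identity-threshold reweighting at ``theta``.
    Regularization defaults scale with the problem size: lambda_h = 0.01*A
    and lambda_J = 0.01*A*(L-1).  The objective is convex; optimization is
    full-batch L-BFGS from zero initialization with analytic gradients,
    followed by coupling symmetrization.
    """
    X = _encode_msa(msa)
    N, L = X.shape
    if L < 2:
        raise ValueError("motif length must be >= 2")
    A = aa.A
    if weights is None:
        weights = sequence_weights(msa, theta)
    weights = np.asarray(weights, dtype=float)
    n_eff = float(weights.sum())
    if n_eff <= 0:
        raise ValueError("effective sequence count is zero")
    if lambda_h is None:
        lambda_h = 0.01 * A
    if lambda_J is None:
        lambda_J = 0.01 * A * (L - 1)

    LA = L * A
    Xoh = np.zeros((N, L, A))
    Xoh[np.arange(N)[:, None], np.arange(L)[None, :], X] = 1.0
    Xflat = Xoh.reshape(N, LA)
    diag_mask = np.ones((LA, LA))
    for i in range(L):
        diag_mask[i * A:(i + 1) * A, i * A:(i + 1) * A] = 0.0

    x0 = np.zeros(LA + LA * LA)
    res = scipy.optimize.minimize(
        _plpl_objective, x0, jac=True, method="L-BFGS-B",
        args=(Xoh, Xflat, weights, L, A, lambda_h, lambda_J, diag_mask),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"non-finite solution from optimizer: {res.message}")

    h = res.x[:LA].reshape(L, A)
    W = res.x[LA:].reshape(LA, LA) * diag_mask
    Jasym = W.reshape(L, A, L, A).transpose(0, 2, 1, 3)     # (L, L, A, A)
    J = 0.5 * (Jasym + np.transpose(Jasym, (1, 0, 3, 2)))
    for i in range(L):
        J[i, i] = 0.0
    model = PottsModel(L=L, A=A, h=h, J=J, lambda_h=lambda_h,
                       lambda_J=lambda_J, theta=theta, n_eff=n_eff)
    model.check_shapes()
    return model


def pseudolikelihood_value_and_grad(model_params: np.ndarray, msa: list[str],
                                    weights: np.ndarray, L: int, A: int,
                                    lambda_h: float, lambda_J: float):
    """Objective/gradient at an arbitrary parameter vector (fields then the
    flattened asymmetric coupling matrix).  Exposed for gradient checking."""
    X = _encode_msa(msa)
    N = X.shape[0]
    LA = L * A
    Xoh = np.zeros((N, L, A))
    Xoh[np.arange(N)[:, None], np.arange(L)[None, :], X] = 1.0
    Xflat = Xoh.reshape(N, LA)
    diag_mask = np.ones((LA, LA))
    for i in range(L):
        diag_mask[i * A:(i + 1) * A, i * A:(i + 1) * A] = 0.0
    return _plpl_objective(model_params, Xoh, Xflat, np.asarray(weights, float),
                           L, A, lambda_h, lambda_J, diag_mask)


# ---------------------------------------------------------------------------
# energies and mutational effects


def energy(model: PottsModel, s: str) -> float:
    """Statistical energy of one sequence (higher = more probable)."""
    x = aa.encode(s)
    if len(x) != model.L:
        raise ValueError(f"sequence length {len(x)} != model length {model.L}")
    e = float(model.h[np.arange(model.L), x].sum())
    for i in range(model.L):
        for j in range(i + 1, model.L):
            e += float(model.J[i, j, x[i], x[j]])
    return e


def mutational_effect(model: PottsModel, wt: str, pos: int, residue: str) -> float:
    """Energy change of a single substitution at 1-based position ``pos``.

    Computed incrementally from the field delta and the coupling deltas to
    every other position; equals the full-energy difference exactly.
    Substituting the wild-type residue itself returns exactly 0.
    """
    x = aa.encode(wt)
    if len(x) != model.L:
        raise ValueError("wild-type length does not match model")
    if not 1 <= pos <= model.L:
        raise ValueError(f"position {pos} outside 1..{model.L}")
    i = pos - 1
    b = aa.AA_INDEX.get(residue)
    if b is None:
        raise ValueError(f"invalid residue symbol {residue!r}")
    a = x[i]
    if b == a:
        return 0.0
    delta = float(model.h[i, b] - model.h[i, a])
    for j in range(model.L):
        if j == i:
            continue
        delta += float(model.J[i, j, b, x[j]] - model.J[i, j, a, x[j]])
    return delta


def mutational_landscape(model: PottsModel, wt: str) -> MutationalLandscape:
    """All L x 20 substitution effects; wild-type cells are exactly zero."""
    x = aa.encode(wt)
    if len(x) != model.L:
        raise ValueError("wild-type length does not match model")
    effects = np.zeros((model.L, model.A))
    for i in range(model.L):
        for b in range(model.A):
            if b != x[i]:
                effects[i, b] = mutational_effect(model, wt, i + 1, aa.ALPHABET[b])
    return MutationalLandscape(wt=wt, effects=effects)


# ---------------------------------------------------------------------------
# coupling maps


def zero_sum_gauge_block(block: np.ndarray) -> np.ndarray:
    """Put one A x A coupling block in the zero-sum (Ising) gauge."""
    return (block - block.mean(axis=0, keepdims=True)
            - block.mean(axis=1, keepdims=True) + block.mean())


def apc(F: np.ndarray) -> np.ndarray:
    """Average-product correction: F'_ij = F_ij - row_i * col_j / grand mean.

    Means are taken over all entries; a rank-one input maps exactly to
    zero.  Returns zero when the grand mean vanishes.
    """
    grand = F.mean()
    if grand == 0:
        return np.zeros_like(F)
    return F - np.outer(F.mean(axis=1), F.mean(axis=0)) / grand


def coupling_map(model: PottsModel) -> np.ndarray:
    """APC-corrected Frobenius norms of zero-sum-gauge coupling blocks.

    The raw map F_ij is the Frobenius norm of the gauged J_ij block; the
    average-product correction removes the site-entropy background. The
    diagonal is zero and the output is clipped below at zero.
    """
    L = model.L
    F = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            if i != j:
                F[i, j] = np.linalg.norm(zero_sum_gauge_block(model.J[i, j]))
    out = apc(F)
    np.fill_diagonal(out, 0.0)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# validation regressions


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    r2: float
    mse: float
    spearman: float


def _ols_report(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, RegressionReport]:
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) predictor")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    resid = y - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean())**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rho = scipy.stats.spearmanr(x, y).statistic
    report = RegressionReport(slope=float(slope), intercept=float(intercept),
                              r2=r2, mse=ss_res / len(y), spearman=float(rho))
    return resid, report


def residualize_blosum(landscape: MutationalLandscape,
                       blosum: np.ndarray | None = None):
    """Regress substitution effects on BLOSUM62(wt -> mutant) scores.

    Ordinary least squares over all non-wild-type landscape cells; returns
    ``(residuals, scores, report)`` where residuals/scores are flat arrays
    aligned with the non-wild-type (position, mutant) cells in row-major
    order, and the report carries slope, intercept, R^2, MSE and Spearman.
    """
    if blosum is None:
        blosum = aa.blosum62()
    x = aa.encode(landscape.wt)
    xs, ys = [], []
    for i in range(len(x)):
        for b in range(aa.A):
            if b == x[i]:
                continue
            xs.append(blosum[x[i], b])
            ys.append(landscape.effects[i, b])
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    resid, report = _ols_report(xs, ys)
    return resid, xs, report


def sneath_correlation(residuals: np.ndarray, wt: str,
                       table: np.ndarray | None = None) -> RegressionReport:
    """Correlate BLOSUM-residualized effects with biochemical dissimilarity
    of each (wild-type, mutant) residue pair.

    ``table`` is a 20 x 20 dissimilarity matrix (defaults to the packaged
    property-derived stand-in for Sneath's index); residual order must
    match :func:`residualize_blosum`'s non-wild-type cell order.
    """
    if table is None:
        table = aa.biochemical_dissimilarity()
    if table.shape != (aa.A, aa.A) or not np.all(np.isfinite(table)):
        raise ValueError("dissimilarity table must define all 20x20 pairs")
    x = aa.encode(wt)
    diss = []
    for i in range(len(x)):
        for b in range(aa.A):
            if b != x[i]:
                diss.append(table[x[i], b])
    diss = np.asarray(diss, dtype=float)
    if len(diss) != len(residuals):
        raise ValueError("residual vector does not match the landscape shape")
    _, report = _ols_report(diss, np.asarray(residuals, dtype=float))
    return report


# ---------------------------------------------------------------------------
# conservation aggregation


def conservation_score(site_values: list[float], threshold: float = 0.6) -> float:
    """Proportion of positions whose site-level value exceeds the threshold."""
    if len(site_values) == 0:
        raise ValueError("empty site-value list")
    v = np.asarray(site_values, dtype=float)
    return float(np.mean(v > threshold))
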