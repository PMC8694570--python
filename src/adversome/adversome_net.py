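"""Estimating the Adversome: a sparse Ising network over co-reported events.

Events (primary HLTs with at least ``min_cases`` cohort reports) become the
binary variables of a pairwise Markov random field

    P(x) ∝ exp( Σ_i tau_i x_i + Σ_{i<j} W_ij x_i x_j ),   x ∈ {0,1}^p,

whose conditional distributions are logistic regressions.  The network is
estimated by the eLASSO procedure: each node is regressed on all others
with an L1 penalty along a decreasing lambda grid, the extended BIC

    EBIC_gamma = -2 * loglik + k * ln(n) + 2 * gamma * k * ln(p - 1)

selects the per-node model (k = number of nonzero neighbours, loglik the
logistic log-pseudolikelihood at the penalized estimates), and the nodewise
estimates are combined by an AND rule (edge kept only when both regressions
retain it; weight = mean of the two coefficients) or an OR rule (either
regression suffices; a missing coefficient counts as 0 in the mean).

A single-site Gibbs sampler for the same model serves as simulation
ground truth for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse
from sklearn.linear_model import LogisticRegression

from .faers_io import ReportRecord
from .meddra import MedDRAHierarchy, SOCExclusionList
from .dispro import project_cohort


class DegenerateColumnError(ValueError):
    """A column is constant (or the matrix is empty) and cannot be fit."""


@dataclass
class EventMatrix:
    """Reports x events binary matrix feeding the Ising fit."""

    row_ids: list[str]
    columns: list[str]
    X: np.ndarray  # (n, p) with entries in {0, 1}

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.size and not np.isin(self.X, (0, 1)).all():
            raise TypeError("event matrix entries must be binary 0/1")
        self.X = self.X.astype(np.int8)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_counts(self) -> dict[str, int]:
        return dict(zip(self.columns, self.X.sum(axis=0).astype(int)))


@dataclass
class IsingNetwork:
    """Node thresholds and symmetric edge-weight matrix (the Adversome)."""

    nodes: list[str]
    tau: np.ndarray  # (p,) node thresholds (selected intercepts)
    W: np.ndarray  # (p, p) symmetric, zero diagonal; edge iff W[i,j] != 0
    fit_meta: dict = field(default_factory=dict)
    node_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if not np.allclose(self.W, self.W.T):
            raise ValueError("edge-weight matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("edge-weight matrix must have a zero diagonal")

    @property
    def p(self) -> int:
        return len(self.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.W[i, j] != 0:
                    out.append((self.nodes[i], self.nodes[j], float(self.W[i, j])))
        return out

    def n_edges(self) -> int:
        return len(self.edges())

    def degrees(self) -> dict[str, int]:
        adj = (self.W != 0).astype(int)
        return dict(zip(self.nodes, adj.sum(axis=1).astype(int)))


def binarize(
    cohort: list[ReportRecord],
    hierarchy: MedDRAHierarchy,
    exclusions: SOCExclusionList | None = None,
    min_cases: int = 10,
) -> EventMatrix:
    """Build the reports x HLT presence/absence matrix.

    Columns are HLTs reported in at least ``min_cases`` cohort reports
    (after projection and SOC exclusion), sorted by descending count then
    name.  Raises :class:`DegenerateColumnError` with the observed count
    distribution when no event survives the filter.
    """
    projected = project_cohort(cohort, hierarchy, exclusions)
    counts: dict[str, int] = {}
    for events in projected:
        for h in events:
            counts[h] = counts.get(h, 0) + 1
    keep = sorted(
        (h for h, c in counts.items() if c >= min_cases),
        key=lambda h: (-counts[h], h),
    )
    if not keep:
        dist = sorted(counts.items(), key=lambda kv: -kv[1])[:20]
        raise DegenerateColumnError(
            f"no event reaches min_cases={min_cases}; top counts: {dist}"
        )
    idx = {h: j for j, h in enumerate(keep)}
    X = np.zeros((len(cohort), len(keep)), dtype=np.int8)
    for i, events in enumerate(projected):
        for h in events:
            j = idx.get(h)
            if j is not None:
                X[i, j] = 1
    return EventMatrix([r.report_id for r in cohort], keep, X)


def _logistic_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log P(y | eta) for Bernoulli with logit link, numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_node(
    X: np.ndarray,
    j: int,
    n_lambda: int,
    lambda_min_ratio: float,
    gamma: float,
    tol: float = 1e-8,
    fdev: float = 1e-5,
) -> tuple[np.ndarray, float, float]:
    """eLASSO fit of column j on the rest; returns (coefs, intercept, lambda).

    Candidate neighbourhoods come from the L1 path (predictors standardized
    inside the fit, as path solvers conventionally do; the path is cut
    short once the deviance explained stops improving by more than ``fdev``
    per step).  Each distinct support is then refit without penalty and
    scored by EBIC on the refit log-likelihood: comparing unshrunk
    likelihoods keeps the comparison calibrated across penalty levels —
    scoring at the shrunk estimates rewards larger models merely for
    un-shrinking the strong true coefficients.
    """
    n, p = X.shape
    y = X[:, j].astype(float)
    Z = np.delete(X, j, axis=1).astype(float)
    sd = Z.std(axis=0)
    Zs = Z / sd

    # smallest lambda that zeroes every coefficient of the penalized
    # logistic problem (1/n)*NLL + lambda*||beta||_1
    lam_max = float(np.max(np.abs(Zs.T @ (y - y.mean()))) / n)
    if lam_max <= 0:
        lam_max = 1e-4
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    ybar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    b0 = float(np.log(ybar / (1 - ybar)))
    ll0 = _logistic_loglik(y, np.full(n, b0))
    null_dev = -2.0 * ll0

    # walk the path collecting distinct supports (the empty model included)
    supports: dict[tuple[int, ...], float] = {(): float(lam_max)}
    prev_dev_ratio = 0.0
    for lam in lambdas:
        # liblinear penalizes the intercept; a large intercept_scaling makes
        # that penalty negligible so the lambda grid stays calibrated
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
            tol=tol, max_iter=2000, fit_intercept=True, intercept_scaling=1000.0,
            random_state=0,
        )
        clf.fit(Zs, y)
        coef = clf.coef_[0]
        k = int(np.count_nonzero(coef))
        supports.setdefault(tuple(np.flatnonzero(coef)), float(lam))
        ll = _logistic_loglik(y, float(clf.intercept_[0]) + Zs @ coef)
        dev_ratio = 1.0 - (-2.0 * ll) / null_dev if null_dev > 0 else 1.0
        if k > 0 and (dev_ratio - prev_dev_ratio < fdev or dev_ratio > 0.999):
            break
        prev_dev_ratio = dev_ratio

    log_pen = np.log(n) + 2.0 * gamma * np.log(max(p - 1, 1))
    best: tuple[float, tuple] | None = None
    for support, lam in supports.items():
        if support:
            refit = LogisticRegression(C=np.inf, solver="lbfgs", tol=tol, max_iter=5000)
            refit.fit(Z[:, list(support)], y)
            coef = np.zeros(Z.shape[1])
            coef[list(support)] = refit.coef_[0]
            intercept = float(refit.intercept_[0])
            ll = _logistic_loglik(y, intercept + Z @ coef)
        else:
            coef, intercept, ll = np.zeros(Z.shape[1]), b0, ll0
        ebic = -2.0 * ll + len(support) * log_pen
        if best is None or ebic < best[0] - 1e-12:
            best = (ebic, (coef, intercept, lam))
    coef, intercept, lam = best[1]
    return coef, intercept, lam


def fit_ising(
    matrix: EventMatrix,
    gamma: float = 0.25,
    rule: str = "AND",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> IsingNetwork:
    """Estimate the Ising network by nodewise L1 logistic regression + EBIC.

    Parameters
    ----------
    gamma
        EBIC hyperparameter in [0, 1]; 0 recovers plain BIC, larger values
        give sparser graphs with fewer false edges.
    rule
        ``"AND"`` keeps an edge only when both nodewise regressions retain
        it; ``"OR"`` when either does.  Weights are the mean of the two
        coefficients (one treated as 0 under OR).
    """
    if rule not in ("AND", "OR"):
        raise ValueError(f"rule must be 'AND' or 'OR', got {rule!r}")
    X = np.asarray(matrix.X, dtype=np.int8)
    n, p = X.shape
    if n < 2 or p < 2:
        raise DegenerateColumnError(f"need at least 2 rows and 2 columns, got {X.shape}")
    if not np.isin(X, (0, 1)).all():
        raise TypeError("fit_ising requires a binary matrix")
    col_means = X.mean(axis=0)
    constant = [matrix.columns[j] for j in range(p) if col_means[j] in (0.0, 1.0)]
    if constant:
        raise DegenerateColumnError(f"constant columns cannot be fit: {constant}")

    B = np.zeros((p, p))  # B[j, i]: coefficient of node i in node j's regression
    tau = np.zeros(p)
    sel_lambda = []
    for j in range(p):
        coef, intercept, lam = _fit_node(X, j, n_lambda, lambda_min_ratio, gamma)
        others = [i for i in range(p) if i != j]
        B[j, others] = coef
        tau[j] = intercept
        sel_lambda.append(lam)

    both = (B != 0) & (B.T != 0)
    either = (B != 0) | (B.T != 0)
    keep = both if rule == "AND" else either
    W = np.where(keep, (B + B.T) / 2.0, 0.0)
    np.fill_diagonal(W, 0.0)

    return IsingNetwork(
        nodes=list(matrix.columns),
        tau=tau,
        W=W,
        fit_meta={
            "gamma": gamma, "rule": rule, "n_lambda": n_lambda,
            "lambda_min_ratio": lambda_min_ratio,
            "selected_lambda": sel_lambda, "n": n,
        },
        node_counts=matrix.column_counts(),
    )


def gibbs_sample(
    tau: np.ndarray,
    W: np.ndarray,
    n: int,
    burn_in: int = 200,
    thin: int = 1,
    seed: int | np.random.Generator = 0,
    columns: list[str] | None = None,
) -> EventMatrix:
    """Draw n samples from the Ising model by single-site Gibbs updates.

    One sweep updates every site in index order with conditional
    P(x_i = 1 | rest) = logistic(tau_i + Σ_j W_ij x_j); the chain discards
    ``burn_in`` sweeps, then records one sample every ``thin`` sweeps.
    Deterministic for a fixed seed.
    """
    tau = np.asarray(tau, dtype=float)
    W = np.asarray(W, dtype=float)
    p = len(tau)
    if W.shape != (p, p):
        raise ValueError(f"W must be ({p},{p}), got {W.shape}")
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric with zero diagonal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    x = (rng.random(p) < 0.5).astype(np.int8)
    out = np.empty((n, p), dtype=np.int8)

    def sweep() -> None:
        for i in range(p):
            eta = tau[i] + W[i] @ x
            x[i] = rng.random() < 1.0 / (1.0 + np.exp(-eta))

    for _ in range(burn_in):
        sweep()
    for s in range(n):
        for _ in range(thin):
            sweep()
        out[s] = x

    cols = columns if columns is not None else [f"V{i}" for i in range(p)]
    return EventMatrix([f"s{k}" for k in range(n)], cols, out)


def positive_subnetwork(net: IsingNetwork) -> IsingNetwork:
    """Zero out negative edge weights; node set and thresholds unchanged."""
    W = np.where(net.W > 0, net.W, 0.0)
    return IsingNetwork(
        nodes=list(net.nodes), tau=net.tau.copy(), W=W,
        fit_meta={**net.fit_meta, "subnetwork": "positive"},
        node_counts=dict(net.node_counts),
    )


# ---------------------------------------------------------------------------
# Exports


def to_networkx(net: IsingNetwork):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_weighted_edges_from(net.edges())
    return g


def write_event_matrix(matrix: EventMatrix, out_dir: str | Path, prefix: str = "event_matrix") -> None:
    """MatrixMarket sparse export plus row/column label files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(out / f"{prefix}.mtx", sparse.csr_matrix(matrix.X))
    (out / f"{prefix}.rows.txt").write_text("\n".join(matrix.row_ids) + "\n")
    (out / f"{prefix}.cols.txt").write_text("\n".join(matrix.columns) + "\n")


def write_network(net: IsingNetwork, out_dir: str | Path, prefix: str = "adversome") -> None:
    """GraphML + TSV edge list + node table."""
    import networkx as nx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(to_networkx(net), out / f"{prefix}.graphml")
    pd.DataFrame(net.edges(), columns=["node_i", "node_j", "weight"]).to_csv(
        out / f"{prefix}_edges.tsv", sep="\t", index=False, float_format="%.12g"
    )
    deg = net.degrees()
    pd.DataFrame(
        [
            {"hlt": h, "count": net.node_counts.get(h, 0),
             "tau": net.tau[i], "degree": deg[h]}
            for i, h in enumerate(net.nodes)
        ]
    ).to_csv(out / f"{prefix}_nodes.tsv", sep="\t", index=False, float_format="%.12g")
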