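"""Sparse Laguerre-basis GLM for directed functional connectivity.

Each neuron's binned train is regressed, one output neuron at a time, on
the recent history of every neuron in the population.  Temporal kernels
``k^(n)(tau)`` are expanded on a discrete Laguerre basis, which reduces
the parameter count from ``N*(M+1)+1`` to ``N*J+1`` and enforces smooth
exponential decay.  Because binned binary rates are treated as Gaussian,
the fit is an L1-penalized least squares (lasso); the penalty prunes
inputs, and surviving input groups become directed edges.

The lasso penalty ``zeta`` follows the per-sample convention
``(1/2T)*RSS + zeta*sum|c|`` so that the useful range is independent of
recording length; it is selected, jointly with the Laguerre decay
``alpha``, by minimizing out-of-sample deviance (residual sum of squares
for a Gaussian model) over contiguous time-block cross-validation folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.linear_model import Lasso, lasso_path

from .io import AnalysisConfig, FunctionalNetwork, SpikeTrainSet


@dataclass
class LaguerreBasis:
    """Discrete Laguerre functions ``b_j(tau)``, ``j=0..J-1``, ``tau=0..M-1``.

    ``alpha`` in (0,1) sets the decay: smaller alpha, faster decay.  Rows
    are orthonormal over the infinite lag axis; for M large relative to
    alpha the truncated rows are orthonormal to high accuracy.
    """

    alpha: float
    order: int
    memory: int
    values: np.ndarray

    @property
    def time_constant_bins(self) -> float:
        """Lag scale ``-1/ln(alpha)`` of the zeroth-order function."""
        return -1.0 / np.log(self.alpha)


def laguerre_basis(alpha: float, order: int, memory: int) -> LaguerreBasis:
    """Build the discrete Laguerre basis by the standard two-term recursion.

    ``b_0(tau) = sqrt(1-alpha) * alpha^(tau/2)`` and, for ``j >= 1``,

        b_j(0)   = sqrt(alpha) * b_{j-1}(0)
        b_j(tau) = sqrt(alpha) * b_j(tau-1)
                   + sqrt(alpha) * b_{j-1}(tau) - b_{j-1}(tau-1)
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if order < 1:
        raise ValueError("order must be >= 1")
    if memory < order:
        raise ValueError("memory must be >= order")
    sa = np.sqrt(alpha)
    b = np.zeros((order, memory))
    tau = np.arange(memory)
    b[0] = np.sqrt(1 - alpha) * sa**tau
    for j in range(1, order):
        b[j, 0] = sa * b[j - 1, 0]
        for t in range(1, memory):
            b[j, t] = sa * b[j, t - 1] + sa * b[j - 1, t] - b[j - 1, t - 1]
    return LaguerreBasis(alpha=alpha, order=order, memory=memory, values=b)


def convolve_inputs(sts: SpikeTrainSet | np.ndarray, basis: LaguerreBasis) -> np.ndarray:
    """Convolve every input train with every basis function.

    Returns the ``(T, N*J)`` matrix with columns ordered input-major,
    basis-order-minor: column ``n*J + j`` is
    ``v_j^(n)(t) = sum_tau b_j(tau) x_n(t - tau)`` with ``x = 0`` for
    negative times (zero-padded start).
    """
    x = sts.binned() if isinstance(sts, SpikeTrainSet) else np.asarray(sts)
    n, t = x.shape
    j = basis.order
    if basis.memory > t:
        raise ValueError("basis memory exceeds number of bins")
    v = np.empty((t, n * j))
    for i in range(n):
        xi = x[i].astype(float)
        for q in range(j):
            v[:, i * j + q] = np.convolve(xi, basis.values[q])[:t]
    return v


def design_matrix(
    sts: SpikeTrainSet | np.ndarray, basis: LaguerreBasis, lag: int = 1
) -> np.ndarray:
    """Convolved design shifted so that row ``t`` only sees bins ``< t``.

    The one-bin lag keeps the regression strictly causal (in particular
    the output neuron's own current bin never predicts itself).
    """
    v = convolve_inputs(sts, basis)
    if lag == 0:
        return v
    out = np.zeros_like(v)
    out[lag:] = v[:-lag]
    return out


@dataclass
class GlmModel:
    """Fitted single-output model.

    ``coef`` has shape ``(N_inputs, J)``; row n holds the Laguerre
    coefficients of kernel ``k^(n)``.  ``output_index`` marks which input
    is the neuron's own history (self-kernel; never a graph edge).
    """

    output_index: int
    intercept: float
    coef: np.ndarray
    zeta: float
    basis: LaguerreBasis
    cv_deviance: np.ndarray | None = None
    zeta_grid: np.ndarray | None = None

    def kernels(self) -> np.ndarray:
        """Reconstruct ``(N, M)`` kernels ``k^(n)(tau) = sum_j c_j b_j``."""
        return kernels_from_coefficients(self.coef, self.basis)

    def predict(self, design: np.ndarray) -> np.ndarray:
        """Predicted per-bin intensity ``k_0 + v @ c``."""
        return self.intercept + design @ self.coef.ravel()

    def input_groups_nonzero(self) -> np.ndarray:
        """Boolean mask over inputs: any nonzero coefficient in the group."""
        return np.any(self.coef != 0, axis=1)


def kernels_from_coefficients(coef: np.ndarray, basis: LaguerreBasis) -> np.ndarray:
    """Expand Laguerre coefficients ``(..., J)`` into kernels ``(..., M)``."""
    coef = np.asarray(coef, dtype=float)
    return coef @ basis.values


def _contiguous_folds(t: int, folds: int) -> list[np.ndarray]:
    """Contiguous time blocks (time series CV: no shuffling across time)."""
    edges = np.linspace(0, t, folds + 1).astype(int)
    return [np.arange(edges[k], edges[k + 1]) for k in range(folds)]


def fit_sparse_glm(
    design: np.ndarray,
    target: np.ndarray,
    zeta_grid: np.ndarray | tuple[float, ...] | None = None,
    folds: int = 5,
    seed: int | None = None,
    output_index: int = -1,
    basis: LaguerreBasis | None = None,
    selection: str = "min",
    prune_alpha: float | None = 0.01,
) -> GlmModel:
    """Lasso fit with penalty chosen by blocked cross-validated deviance.

    For each penalty on the grid, Gaussian deviance (held-out residual sum
    of squares) is accumulated over contiguous time folds.  With
    ``selection="min"`` (default) the smallest-deviance penalty wins,
    exact ties going to the larger (sparser) penalty; ``"1se"`` applies
    the paired one-standard-error rule instead.  The final model is refit
    on all data at the selected penalty.

    The CV deviance curve is nearly flat around its minimum, so the
    prediction-optimal penalty routinely drags in inputs whose
    contribution is noise.  Because an edge is declared for *any* nonzero
    input group, significance of the surviving groups is then enforced
    directly: an OLS refit on the selected columns scores each input
    group with a partial F-test, and groups failing the level
    ``prune_alpha`` Bonferroni-corrected over *all* candidate inputs have
    their coefficients zeroed (``prune_alpha=None`` disables pruning).
    Correcting over all inputs rather than only the selected ones
    compensates for the selection step having already scanned every
    candidate.

    ``seed`` is accepted for interface symmetry; the blocked-CV fit is
    deterministic.
    """
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float).ravel()
    t, p = design.shape
    if zeta_grid is None:
        zeta_grid = np.logspace(-5, -1, 20)
    zetas = np.sort(np.asarray(list(zeta_grid), dtype=float))[::-1]  # descending
    if basis is None:
        # columns are treated as one group each when no basis is attached
        basis = laguerre_basis(0.5, 1, min(50, t))
    nj = basis.order
    if p % nj:
        raise ValueError("design width is not a multiple of the basis order")
    n_inputs = p // nj

    if np.allclose(design.std(axis=0), 0):
        warnings.warn("degenerate design (zero variance); returning empty model")
        return GlmModel(
            output_index=output_index,
            intercept=float(target.mean()),
            coef=np.zeros((n_inputs, nj)),
            zeta=float(zetas[0]),
            basis=basis,
            cv_deviance=np.full(zetas.size, np.nan),
            zeta_grid=zetas,
        )

    fold_dev = np.zeros((folds, zetas.size))
    blocks = _contiguous_folds(t, folds)
    for k, test_idx in enumerate(blocks):
        train_idx = np.concatenate([b for q, b in enumerate(blocks) if q != k])
        xtr, ytr = design[train_idx], target[train_idx]
        xte, yte = design[test_idx], target[test_idx]
        xm, ym = xtr.mean(axis=0), ytr.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(xtr - xm, ytr - ym, alphas=zetas)
        pred = (xte - xm) @ coefs + ym  # (n_test, n_zeta)
        fold_dev[k] = ((pred - yte[:, None]) ** 2).mean(axis=0)
    deviance = fold_dev.mean(axis=0)
    # zetas are descending, so argmin picks the largest zeta on exact ties
    best = int(np.argmin(deviance))
    if selection == "1se":
        # paired one-SE rule: fold-level variance is shared across the
        # penalty path, so compare each zeta to the minimizer fold by fold
        diff = fold_dev - fold_dev[:, [best]]
        se = diff.std(axis=0, ddof=1) / np.sqrt(folds)
        within = np.flatnonzero(diff.mean(axis=0) <= se)
        best = int(within.min())  # largest zeta within one SE of the minimum
    elif selection != "min":
        raise ValueError("selection must be '1se' or 'min'")
    zeta = float(zetas[best])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = Lasso(alpha=zeta, fit_intercept=True, max_iter=5000)
        model.fit(design, target)
    coef = model.coef_.reshape(n_inputs, nj)
    intercept = float(model.intercept_)
    if prune_alpha is not None:
        coef = _prune_insignificant_groups(design, target, coef, nj, prune_alpha)
        intercept = float(np.mean(target - design @ coef.ravel()))
    return GlmModel(
        output_index=output_index,
        intercept=intercept,
        coef=coef,
        zeta=zeta,
        basis=basis,
        cv_deviance=deviance,
        zeta_grid=zetas,
    )


def _prune_insignificant_groups(
    design: np.ndarray,
    target: np.ndarray,
    coef: np.ndarray,
    group_size: int,
    alpha: float,
) -> np.ndarray:
    """Zero input groups whose selected columns fail a partial F-test.

    OLS is refit on the union of lasso-selected columns; each group's
    columns are then dropped in turn and the nested-model F statistic
    compared against ``alpha`` Bonferroni-corrected over the total number
    of candidate groups.  Failing groups are zeroed in the lasso
    coefficient matrix (the surviving values stay the lasso estimates).
    """
    from scipy import stats

    groups = np.flatnonzero(np.any(coef != 0, axis=1))
    if groups.size == 0:
        return coef
    cols = np.flatnonzero(coef.ravel() != 0)
    t = design.shape[0]
    x_full = np.column_stack([np.ones(t), design[:, cols]])
    beta, *_ = np.linalg.lstsq(x_full, target, rcond=None)
    rss_full = float(np.sum((target - x_full @ beta) ** 2))
    df_resid = t - x_full.shape[1]
    if df_resid <= 0 or rss_full <= 0:
        return coef
    level = alpha / coef.shape[0]
    pruned = coef.copy()
    for g in groups:
        in_group = (cols // group_size) == g
        m = int(in_group.sum())
        x_red = np.column_stack([np.ones(t), design[:, cols[~in_group]]])
        beta_r, *_ = np.linalg.lstsq(x_red, target, rcond=None)
        rss_red = float(np.sum((target - x_red @ beta_r) ** 2))
        f = ((rss_red - rss_full) / m) / (rss_full / df_resid)
        if stats.f.sf(f, m, df_resid) >= level:
            pruned[g] = 0.0
    return pruned


def fit_neuron(
    sts: SpikeTrainSet, output: int, config: AnalysisConfig
) -> GlmModel:
    """Fit one output neuron, selecting ``alpha`` and ``zeta`` jointly.

    Every basis decay on ``config.alpha_grid`` gets its own design matrix
    and CV sweep over the penalty grid; the (alpha, zeta) pair with the
    lowest cross-validated deviance wins.
    """
    x = sts.binned()
    target = x[output].astype(float)
    best: GlmModel | None = None
    best_dev = np.inf
    for alpha in config.alpha_grid:
        basis = laguerre_basis(alpha, config.basis_order, config.memory_bins)
        design = design_matrix(x, basis, lag=1)
        m = fit_sparse_glm(
            design,
            target,
            zeta_grid=config.zeta_grid,
            folds=config.cv_folds,
            output_index=output,
            basis=basis,
        )
        dev = float(np.nanmin(m.cv_deviance))
        if dev < best_dev:
            best, best_dev = m, dev
    assert best is not None
    return best


def build_functional_network(
    models: list[GlmModel],
    neuron_ids: list[str] | None = None,
    drop_isolates: bool = True,
) -> FunctionalNetwork:
    """Assemble the directed graph from per-neuron fitted models.

    Edge ``n -> i`` exists iff any Laguerre coefficient of input ``n`` in
    neuron ``i``'s model is nonzero.  Self-kernels never produce edges,
    and isolated nodes are removed by default (they carry no functional
    statement).
    """
    n = len(models)
    if neuron_ids is None:
        neuron_ids = [str(i) for i in range(n)]
    g = nx.DiGraph()
    g.add_nodes_from(neuron_ids)
    for m in models:
        i = m.output_index
        mask = m.input_groups_nonzero()
        for src in np.flatnonzero(mask):
            if src == i:
                continue
            g.add_edge(neuron_ids[src], neuron_ids[i])
    if drop_isolates:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


def reconstruct_network(
    sts: SpikeTrainSet, config: AnalysisConfig
) -> tuple[list[GlmModel], FunctionalNetwork]:
    """Full pipeline: rate filter -> per-neuron sparse GLM -> directed graph."""
    from .io import filter_by_rate

    kept_sts = filter_by_rate(sts, config.rate_floor_hz)
    models = [fit_neuron(kept_sts, i, config) for i in range(kept_sts.n_neurons)]
    net = build_functional_network(models, kept_sts.neuron_ids)
    return models, net
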