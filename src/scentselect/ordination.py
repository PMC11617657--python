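"""Constrained analysis of principal coordinates on Bray-Curtis distances.

The multivariate plasticity analysis: compute Bray-Curtis dissimilarities
among plant emission profiles, embed them by principal coordinates
analysis (Gower double-centering, negative-eigenvalue axes discarded and
counted), regress the eigenvalue-scaled coordinates on a sequential model
matrix, and test each term by free permutation of the response rows.

Permutations are unrestricted: the split-plot structure is instead honored
by the companion mixed models, since constrained ordination does not admit
random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "CAPModel",
    "PermTestResult",
    "bray_curtis",
    "pcoa",
    "cap_fit",
    "sequential_perm_test",
    "percent_inertia",
]


@dataclass
class DistanceMatrix:
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # n x k, columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all signed eigenvalues, descending
    total_inertia: float  # sum of positive eigenvalues
    n_negative_discarded: int
    labels: list[str]


@dataclass
class CAPModel:
    terms: list[str]
    term_dfs: dict[str, int]
    term_inertia: dict[str, float]
    constrained_inertia: float
    residual_inertia: float
    total_inertia: float
    residual_df: int
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame | None
    env_arrows: pd.DataFrame | None
    # internals reused by the permutation test
    _Y: np.ndarray = field(repr=False, default=None)
    _q_blocks: list[np.ndarray] = field(repr=False, default_factory=list)

    def pseudo_f(self, term: str) -> float:
        if self.residual_df < 1:
            raise ValueError("saturated model: pseudo-F undefined (no residual df)")
        ms_term = self.term_inertia[term] / self.term_dfs[term]
        ms_resid = self.residual_inertia / self.residual_df
        return ms_term / ms_resid


@dataclass
class PermTestResult:
    term: str
    df: int
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    X = np.asarray(matrix, float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative values")
    row_sums = X.sum(axis=1)
    labels = [str(i) for i in matrix.index]
    zero_rows = [labels[i] for i in np.flatnonzero(row_sums == 0)]
    if zero_rows:
        raise ValueError(
            f"all-zero emission row(s) make Bray-Curtis undefined: {zero_rows}"
        )
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = row_sums[:, None] + row_sums[None, :]
    d = num / den
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, labels)


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Classical scaling: Gower-center -0.5*D^2 and eigendecompose.

    Coordinates are scaled by sqrt(eigenvalue); axes with negative
    eigenvalues are discarded and counted (no correction applied).
    """
    n = dist.n
    if n < 3:
        raise ValueError("PCoA needs at least 3 objects")
    A = -0.5 * dist.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # tiny eigenvalues are numerically zero, not signal
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    positive = eigvals > tol
    negative = eigvals < -tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigvals,
        total_inertia=float(eigvals[positive].sum()),
        n_negative_discarded=int(negative.sum()),
        labels=dist.labels,
    )


def _encode_term(term: str, design: pd.DataFrame) -> np.ndarray:
    """Columns for one model term: treatment contrasts for factors,
    the column itself for numerics, elementwise products for interactions."""
    parts = [p.strip() for p in term.split(":")]
    blocks = []
    for p in parts:
        if p not in design.columns:
            raise KeyError(f"model term component {p!r} not in design table")
        col = design[p]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            # drop the first level: treatment contrasts
            blocks.append(
                np.column_stack(
                    [(col.astype(str) == lev).to_numpy(float) for lev in levels[1:]]
                )
                if len(levels) > 1
                else np.empty((len(col), 0))
            )
        else:
            blocks.append(col.to_numpy(float)[:, None])
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(len(design), -1)
    return out


def cap_fit(
    pcoa_result: PCoAResult,
    design: pd.DataFrame,
    terms: list[str],
    species: pd.DataFrame | None = None,
) -> CAPModel:
    """Sequential multivariate least squares of the coordinates on model terms.

    Each term's inertia is the increment in fitted sum of squares when the
    term is added, in the stated order (sequential, order-of-entry
    decomposition).  Rank-deficient (aliased) terms raise.
    """
    Y = pcoa_result.coordinates
    n = Y.shape[0]
    if len(design) != n:
        raise ValueError("design rows do not align with distance labels")
    total = pcoa_result.total_inertia

    q_blocks: list[np.ndarray] = []
    basis: np.ndarray | None = None
    term_dfs: dict[str, int] = {}
    term_inertia: dict[str, float] = {}
    for term in terms:
        X = _encode_term(term, design)
        X = X - X.mean(axis=0)  # orthogonal to the implicit intercept
        # project out all earlier blocks
        if basis is not None:
            X = X - basis @ (basis.T @ X)
        Q, R = np.linalg.qr(X)
        keep = np.abs(np.diag(R)) > 1e-8 * max(1.0, np.abs(np.diag(R)).max(initial=1.0))
        if keep.sum() < X.shape[1]:
            raise ValueError(
                f"term {term!r} is aliased with earlier terms (rank deficiency)"
            )
        Qk = Q[:, keep]
        q_blocks.append(Qk)
        basis = Qk if basis is None else np.column_stack([basis, Qk])
        proj = Qk.T @ Y
        term_dfs[term] = int(Qk.shape[1])
        term_inertia[term] = float((proj**2).sum())

    constrained = float(sum(term_inertia.values()))
    residual = total - constrained
    model_df = sum(term_dfs.values())
    residual_df = n - 1 - model_df
    if residual_df < 0:
        raise ValueError("more model dimensions than data; fit is overdetermined")

    # constrained axes: SVD of fitted values
    if basis is not None and basis.shape[1] > 0:
        Yhat = basis @ (basis.T @ Y)
        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        k = min(int((s > 1e-10).sum()), model_df)
        site = pd.DataFrame(
            U[:, :k] * s[:k],
            index=pcoa_result.labels,
            columns=[f"CAP{i + 1}" for i in range(k)],
        )
    else:
        site = pd.DataFrame(index=pcoa_result.labels)

    species_scores = None
    if species is not None and site.shape[1] > 0:
        sp = species.to_numpy(float)
        spc = sp - sp.mean(axis=0)
        axes = site.to_numpy()
        axes_unit = axes / np.linalg.norm(axes, axis=0)
        species_scores = pd.DataFrame(
            spc.T @ axes_unit, index=species.columns, columns=site.columns
        )

    env_arrows = None
    numeric = design.select_dtypes("number")
    if not numeric.empty and site.shape[1] > 0:
        arrows = {}
        for colname in numeric.columns:
            v = numeric[colname].to_numpy(float)
            if np.std(v) == 0:
                continue
            arrows[colname] = [
                float(np.corrcoef(v, site[a])[0, 1]) for a in site.columns
            ]
        if arrows:
            env_arrows = pd.DataFrame(arrows, index=site.columns).T

    return CAPModel(
        terms=list(terms),
        term_dfs=term_dfs,
        term_inertia=term_inertia,
        constrained_inertia=constrained,
        residual_inertia=residual,
        total_inertia=total,
        residual_df=residual_df,
        site_scores=site,
        species_scores=species_scores,
        env_arrows=env_arrows,
        _Y=Y,
        _q_blocks=q_blocks,
    )


def sequential_perm_test(
    model: CAPModel,
    n_perm: int = 999,
    seed: int = 0,
    interaction_block: bool = False,
) -> list[PermTestResult]:
    """Permutation tests of each term's sequential pseudo-F.

    Response rows are permuted freely; for each permutation the full
    sequential decomposition is recomputed against the fixed model matrix.
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  With
    ``interaction_block`` set, all ':' terms are pooled into one
    jointly-after-main-effects test.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    Y = model._Y
    n = Y.shape[0]
    rng = np.random.default_rng(seed)

    blocks = model._q_blocks
    terms = model.terms
    dfs = np.array([model.term_dfs[t] for t in terms], float)
    Qall = np.column_stack(blocks)
    splits = np.cumsum([b.shape[1] for b in blocks])[:-1]
    ms_resid_obs = model.residual_inertia / model.residual_df

    if interaction_block:
        is_int = np.array([":" in t for t in terms])
        if not is_int.any():
            raise ValueError("interaction_block requested but no ':' terms in model")
        group_terms = [t for t in terms if ":" not in t] + ["interactions"]
    else:
        is_int = None
        group_terms = list(terms)

    def term_stats(ss_terms: np.ndarray, ms_resid: float) -> np.ndarray:
        if interaction_block:
            main_ss = ss_terms[~is_int]
            main_df = dfs[~is_int]
            int_ss = ss_terms[is_int].sum()
            int_df = dfs[is_int].sum()
            ss = np.append(main_ss, int_ss)
            df = np.append(main_df, int_df)
        else:
            ss, df = ss_terms, dfs
        return (ss / df) / ms_resid

    ss_obs = np.array([model.term_inertia[t] for t in terms])
    f_obs = term_stats(ss_obs, ms_resid_obs)

    exceed = np.zeros_like(f_obs)
    total = model.total_inertia
    for _ in range(n_perm):
        perm = rng.permutation(n)
        B = Qall.T @ Y[perm]
        sq = (B**2).sum(axis=1)
        ss_terms = np.add.reduceat(sq, np.r_[0, splits])
        ms_resid = (total - sq.sum()) / model.residual_df
        f_perm = term_stats(ss_terms, ms_resid)
        exceed += f_perm >= f_obs

    pvals = (1.0 + exceed) / (1.0 + n_perm)
    results = []
    for i, term in enumerate(group_terms):
        df_i = int(dfs[is_int].sum()) if (interaction_block and term == "interactions") else model.term_dfs[term]
        results.append(
            PermTestResult(
                term=term,
                df=df_i,
                pseudo_f=float(f_obs[i]),
                p_value=float(pvals[i]),
                n_permutations=n_perm,
                seed=seed,
            )
        )
    return results


def percent_inertia(model: CAPModel) -> float:
    """Constrained / total inertia as a percentage."""
    if model.total_inertia <= 0:
        raise ValueError("total inertia must be positive")
    return 100.0 * model.constrained_inertia / model.total_inertia
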