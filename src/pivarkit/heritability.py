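"""Pedigree relationship matrices, REML heritability and permutation nulls.

The additive relationship matrix is built with the tabular method.
Heritability per cluster comes from a spectral REML fit of
y = X beta + u + e with u ~ (0, sigma_a^2 A): A is eigendecomposed once and
the REML log-likelihood profiled over lambda = sigma_a^2 / sigma_e^2 by
bounded scalar optimization on log(lambda).  Significance uses a stratified
permutation null (shuffling phenotype-to-individual assignment within
generation x pedigree-set strata) with add-one empirical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .expression_analysis import adjust_bh

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "H2Estimate",
    "PermutationResult",
    "read_pedigree",
    "build_relationship_matrix",
    "estimate_h2",
    "permute_pedigree_labels",
    "empirical_significance",
]

PEDIGREE_COLUMNS = ["individual_id", "sire_id", "dam_id", "generation", "pedigree_set"]


@dataclass
class Pedigree:
    """Directed ancestry records; unknown parents are None (founders)."""

    frame: pd.DataFrame  # PEDIGREE_COLUMNS

    def __post_init__(self):
        missing = [c for c in PEDIGREE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        df = self.frame.copy()
        for col in ("sire_id", "dam_id"):
            df[col] = df[col].replace({"0": None, 0: None, "": None, float("nan"): None})
            df[col] = df[col].where(pd.notna(df[col]), None)
        if df["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        ids = set(df["individual_id"])
        gen = dict(zip(df["individual_id"], df["generation"]))
        for _, row in df.iterrows():
            for parent in (row["sire_id"], row["dam_id"]):
                if parent is None:
                    continue
                if parent not in ids:
                    raise ValueError(f"parent {parent!r} not declared in pedigree")
                if gen[parent] >= row["generation"]:
                    raise ValueError(
                        f"parent {parent!r} does not precede {row['individual_id']!r} "
                        "in generation order"
                    )
        self.frame = df

    @property
    def individuals(self) -> list:
        return list(self.frame["individual_id"])

    def strata(self) -> pd.Series:
        """(generation, pedigree_set) stratum label per individual."""
        return pd.Series(
            list(zip(self.frame["generation"], self.frame["pedigree_set"])),
            index=self.frame["individual_id"],
        )


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"individual_id": str, "sire_id": str, "dam_id": str, "pedigree_set": str},
    )
    return Pedigree(df)


def write_pedigree(path, ped: Pedigree) -> None:
    out = ped.frame.copy()
    for col in ("sire_id", "dam_id"):
        out[col] = out[col].fillna("0").replace({None: "0"})
    out.to_csv(path, sep="\t", index=False)


@dataclass
class RelationshipMatrix:
    individuals: list
    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.individuals)
        if self.A.shape != (n, n):
            raise ValueError("A shape does not match individual list")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("A must be symmetric")

    def submatrix(self, ids) -> "RelationshipMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        idx = np.array([pos[i] for i in ids])
        return RelationshipMatrix(list(ids), self.A[np.ix_(idx, idx)])


def build_relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix via the tabular method.

    Individuals are processed parents-first (sorted by generation):
    A[i,i] = 1 + 0.5 * A[sire, dam], and A[i,j] = 0.5 * (A[j,sire] + A[j,dam])
    for previously processed j, with unknown-parent terms equal to 0.
    """
    df = pedigree.frame.sort_values("generation", kind="stable")
    order = list(df["individual_id"])
    pos = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    sires = list(df["sire_id"])
    dams = list(df["dam_id"])
    for i in range(n):
        s = pos.get(sires[i]) if sires[i] is not None else None
        d = pos.get(dams[i]) if dams[i] is not None else None
        if (s is not None and s >= i) or (d is not None and d >= i):
            raise ValueError("pedigree not sorted parents-first (cycle?)")
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * A[j, s]
            if d is not None:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(order, A)


@dataclass
class H2Estimate:
    cluster_id: str
    sigma_a2: float
    sigma_e2: float
    h2: float
    loglik: float
    converged: bool


class REMLWorkspace:
    """Eigendecomposition of (A, X) reused across clusters and permutations."""

    def __init__(self, A: np.ndarray, X: np.ndarray):
        self.n, self.p = X.shape
        vals, vecs = np.linalg.eigh(A)
        self.d = np.maximum(vals, 0.0)  # clip tiny negative eigenvalues
        self.U = vecs
        self.Xt = vecs.T @ X

    def _profile(self, yt: np.ndarray, log_lam: float):
        lam = np.exp(log_lam)
        w = 1.0 / (lam * self.d + 1.0)
        XtW = self.Xt * w[:, None]
        xtx = self.Xt.T @ XtW
        xty = XtW.T @ yt
        beta = np.linalg.solve(xtx, xty)
        resid = yt - self.Xt @ beta
        rss = float(np.sum(w * resid**2))
        nf = self.n - self.p
        sigma_e2 = rss / nf
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        ll = -0.5 * (
            nf * np.log(sigma_e2)
            + np.sum(np.log(lam * self.d + 1.0))
            + logdet_xtx
            + nf
        )
        return ll, sigma_e2, beta

    def fit(self, y: np.ndarray, bounds=(-10.0, 10.0), tol=1e-6):
        yt = self.U.T @ y
        res = minimize_scalar(
            lambda ll: -self._profile(yt, ll)[0],
            bounds=bounds, method="bounded",
            options={"xatol": tol},
        )
        log_lam = float(res.x)
        ll, sigma_e2, _ = self._profile(yt, log_lam)
        lam = np.exp(log_lam)
        sigma_a2 = lam * sigma_e2
        h2 = sigma_a2 / (sigma_a2 + sigma_e2)
        return sigma_a2, sigma_e2, float(np.clip(h2, 0.0, 1.0)), ll, bool(res.success)


def _design_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        for col in covariates.columns:
            dummies = pd.get_dummies(covariates[col], drop_first=True)
            if len(dummies.columns):
                X = np.hstack([X, dummies.to_numpy(dtype=float)])
    return X


def estimate_h2(
    expression: np.ndarray,
    A_sub: RelationshipMatrix | np.ndarray,
    fixed_covariates: pd.DataFrame | None = None,
    cluster_id: str = "",
    workspace: REMLWorkspace | None = None,
) -> H2Estimate:
    """REML heritability of one cluster's expression over recorded individuals.

    ``fixed_covariates`` (e.g. pedigree_set, batch) enter as categorical
    fixed effects alongside the intercept.  When A is (numerically) the
    identity the additive and residual components are confounded and the
    estimate is flagged non-converged.
    """
    y = np.asarray(expression, dtype=float)
    A = A_sub.A if isinstance(A_sub, RelationshipMatrix) else np.asarray(A_sub)
    if workspace is None:
        X = _design_matrix(fixed_covariates, len(y))
        workspace = REMLWorkspace(A, X)
    sigma_a2, sigma_e2, h2, ll, success = workspace.fit(y)
    identifiable = not np.allclose(A, np.eye(len(y)), atol=1e-10)
    return H2Estimate(cluster_id, float(sigma_a2), float(sigma_e2), h2, float(ll),
                      success and identifiable)


def permute_pedigree_labels(
    individuals: list,
    strata: dict,
    seed: int,
    n_perm: int = 100,
) -> list[list]:
    """Stratified permutations of the phenotype-to-individual assignment.

    Each permutation shuffles individuals uniformly at random within each
    (generation, pedigree_set) stratum; singleton strata are fixed points.
    Returns ``n_perm`` permuted orderings of ``individuals``.
    """
    rng = np.random.default_rng(seed)
    individuals = list(individuals)
    index_by_stratum: dict = {}
    for i, ind in enumerate(individuals):
        index_by_stratum.setdefault(strata[ind], []).append(i)
    perms = []
    for _ in range(n_perm):
        arr = list(individuals)
        for idxs in index_by_stratum.values():
            if len(idxs) < 2:
                continue
            shuffled = rng.permutation(idxs)
            for src, dst in zip(idxs, shuffled):
                arr[dst] = individuals[src]
        perms.append(arr)
    return perms


@dataclass
class PermutationResult:
    cluster_id: str
    observed_h2: float
    permuted_h2: np.ndarray
    empirical_p: float
    padj: float = np.nan
    significant: bool = False


def empirical_significance(
    observed: dict[str, float],
    permuted: dict[str, np.ndarray],
    h2_floor: float = 0.5,
    alpha: float = 0.05,
) -> list[PermutationResult]:
    """Add-one empirical p-values with BH adjustment across clusters.

    empirical_p = (1 + #{permuted >= observed}) / (1 + n_perm); a cluster is
    significant iff padj < alpha and observed h2 >= h2_floor.
    """
    ids = list(observed)
    results = []
    for cid in ids:
        perm = np.asarray(permuted[cid], dtype=float)
        obs = observed[cid]
        p = (1.0 + np.sum(perm >= obs)) / (1.0 + perm.size)
        results.append(PermutationResult(cid, obs, perm, float(p)))
    padj = adjust_bh([r.empirical_p for r in results])
    for r, q in zip(results, padj):
        r.padj = float(q)
        r.significant = bool(q < alpha and r.observed_h2 >= h2_floor)
    return results


def heritability_scan(
    expression: pd.DataFrame,
    A: RelationshipMatrix,
    individual_of_sample: dict,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 100,
    seed: int = 0,
    strata: dict | None = None,
    h2_floor: float = 0.5,
    alpha: float = 0.05,
) -> tuple[list[H2Estimate], list[PermutationResult]]:
    """Observed + permuted heritability for every cluster in a matrix.

    ``expression`` is clusters x samples; samples map to pedigree
    individuals via ``individual_of_sample``.  One REML workspace is shared
    across clusters; permutation streams are derived from ``seed`` and are
    common to all clusters (the pedigree is permuted, not the cluster).
    """
    sample_ids = list(expression.columns)
    inds = [individual_of_sample[s] for s in sample_ids]
    A_sub = A.submatrix(inds)
    X = _design_matrix(covariates, len(inds))
    ws = REMLWorkspace(A_sub.A, X)

    estimates = []
    observed = {}
    for cid, row in expression.iterrows():
        est = estimate_h2(row.to_numpy(), A_sub, cluster_id=str(cid), workspace=ws)
        estimates.append(est)
        observed[str(cid)] = est.h2

    permuted: dict[str, list[float]] = {str(cid): [] for cid in expression.index}
    if n_perm > 0:
        if strata is None:
            strata = {i: (0, 0) for i in inds}
        perms = permute_pedigree_labels(inds, strata, seed=seed, n_perm=n_perm)
        pos = {ind: k for k, ind in enumerate(inds)}
        for perm in perms:
            # permuting individuals within strata == permuting phenotype slots
            take = np.array([pos[ind] for ind in perm])
            ws_p = ws  # A fixed; reorder phenotypes instead
            for cid, row in expression.iterrows():
                y = row.to_numpy()[take]
                est = ws_p.fit(y)
                permuted[str(cid)].append(est[2])
    perm_results = empirical_significance(
        observed, {k: np.asarray(v) for k, v in permuted.items()},
        h2_floor=h2_floor, alpha=alpha,
    ) if n_perm > 0 else []
    return estimates, perm_results
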