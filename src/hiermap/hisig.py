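"""Selective-pressure scoring of systems from gene-level signals.

Fits y = I·w + H·v with a nonnegative lasso along a 500-value λ path, where
I is the gene identity design and H the binary gene x system membership
matrix of a hierarchy.  Each system's selective pressure S(c) is the maximum
fraction of total weight it ever captures along the path; significance comes
from permuting the rows of H, with Benjamini-Hochberg FDR control.

The coordinate-descent solver runs on the Gram matrix (a numba kernel), so
permutation replicates only rebuild the identity-H cross block: H^T H is
invariant under row permutations of H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from numba import njit

from .treeops import Hierarchy

FLOAT_FMT = "%.12g"
_PERM_SLACK = 1e-9  # tolerance for S_perm >= S_obs comparisons


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OmicsZTable:
    """Per-gene z-scores over K platforms; NaN marks a missing entry."""

    gene_ids: tuple[str, ...]
    z: np.ndarray  # (n, K)
    platforms: tuple[str, ...] = ("cnv", "expression", "methylation", "mutation")

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != len(self.gene_ids):
            raise ValueError("z must be (n_genes, K)")
        if z.shape[1] < 1:
            raise ValueError("at least one platform required")
        if np.any(np.isinf(z)):
            raise ValueError("infinite z-score")
        z.setflags(write=False)
        object.__setattr__(self, "z", z)


@dataclass(frozen=True)
class SignalTrack:
    """Named gene-level signal with a declared sign-handling transform."""

    name: str
    values: Mapping[str, float]
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.transform not in ("none", "abs", "relu"):
            raise ValueError(f"unknown transform {self.transform!r}")
        vals = dict(self.values)
        for g, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite signal for gene {g!r}")
        object.__setattr__(self, "values", vals)

    def transformed(self) -> dict[str, float]:
        """Apply the transform; the result is guaranteed nonnegative."""
        if self.transform == "abs":
            out = {g: abs(v) for g, v in self.values.items()}
        elif self.transform == "relu":
            out = {g: max(v, 0.0) for g, v in self.values.items()}
        else:
            neg = [g for g, v in self.values.items() if v < 0]
            if neg:
                raise ValueError(
                    f"track {self.name!r} has negative values (e.g. {neg[0]!r}) "
                    "with transform='none'; use 'abs' or 'relu'"
                )
            out = dict(self.values)
        return out


def meta_z(ztable: OmicsZTable) -> SignalTrack:
    """Combine platform z-scores per gene: sum / sqrt(#non-missing).

    Genes with every platform missing are excluded with a warning.
    """
    out: dict[str, float] = {}
    dropped = []
    for gid, row in zip(ztable.gene_ids, ztable.z):
        present = ~np.isnan(row)
        k = int(present.sum())
        if k == 0:
            dropped.append(gid)
            continue
        out[gid] = float(row[present].sum() / np.sqrt(k))
    if dropped:
        warnings.warn(
            f"meta_z: {len(dropped)} gene(s) with all platforms missing excluded "
            f"(e.g. {dropped[0]!r})"
        )
    return SignalTrack(name="meta_z", values=out, transform="abs")


@dataclass(frozen=True)
class MembershipMatrix:
    """Binary genes x systems matrix; column c marks the gene set of c."""

    gene_ids: tuple[str, ...]
    system_ids: tuple[str, ...]
    matrix: np.ndarray  # (n, m) float {0,1}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.gene_ids), len(self.system_ids)):
            raise ValueError("matrix shape mismatch")
        if not np.all((m == 0) | (m == 1)):
            raise ValueError("membership entries must be 0/1")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)


def membership_matrix(hierarchy: Hierarchy) -> MembershipMatrix:
    """Column c has 1 exactly for the genes under system c (descendant leaves)."""
    genes = tuple(sorted(hierarchy.genes))
    systems = tuple(sorted(hierarchy.children))
    gidx = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(systems)))
    for j, s in enumerate(systems):
        for g in hierarchy.gene_set(s):
            mat[gidx[g], j] = 1.0
    return MembershipMatrix(gene_ids=genes, system_ids=systems, matrix=mat)


@dataclass(frozen=True)
class LassoPath:
    """Nonnegative coefficient paths over a descending λ grid."""

    lambdas: np.ndarray  # (L,) descending
    W: np.ndarray  # (n_genes, L)
    V: np.ndarray  # (n_systems, L)
    zero_signal: bool = False

    def __post_init__(self) -> None:
        for name in ("lambdas", "W", "V"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if np.any(self.W < 0) or np.any(self.V < 0):
            raise ValueError("negative coefficient in path")
        if np.any(np.diff(self.lambdas) > 0):
            raise ValueError("lambda grid must be descending")


@dataclass(frozen=True)
class PressureResult:
    system_ids: tuple[str, ...]
    n_genes: np.ndarray
    S: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    metadata: dict = field(default_factory=dict)

    def significant_ids(self) -> set[str]:
        return {s for s, flag in zip(self.system_ids, self.significant) if flag}

    def as_rows(self) -> list[dict]:
        return [
            {
                "system_id": s,
                "n_genes": int(self.n_genes[i]),
                "S": float(self.S[i]),
                "p": float(self.p[i]),
                "q": float(self.q[i]),
                "significant": bool(self.significant[i]),
            }
            for i, s in enumerate(self.system_ids)
        ]


def write_pressure_result(result: PressureResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("system_id\tn_genes\tS\tp\tq\tsignificant\n")
        for row in result.as_rows():
            fh.write(
                "\t".join(
                    [
                        row["system_id"],
                        str(row["n_genes"]),
                        FLOAT_FMT % row["S"],
                        FLOAT_FMT % row["p"],
                        FLOAT_FMT % row["q"],
                        str(row["significant"]),
                    ]
                )
                + "\n"
            )


def read_pressure_result(path) -> PressureResult:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"system_id": str})
    return PressureResult(
        system_ids=tuple(df["system_id"]),
        n_genes=df["n_genes"].to_numpy(),
        S=df["S"].to_numpy(dtype=float),
        p=df["p"].to_numpy(dtype=float),
        q=df["q"].to_numpy(dtype=float),
        significant=df["significant"].astype(str).str.lower().isin(["true", "1"]).to_numpy(),
    )


# ---------------------------------------------------------------------------
# nonnegative lasso path
# ---------------------------------------------------------------------------


@njit(cache=False)
def _cd_path_kernel(indptr, indices, y, lambdas, tol, max_passes):  # pragma: no cover
    """Nonnegative lasso path for the design X = [I | H].

    H is given column-wise (CSC-style indptr/indices into the gene axis).
    The identity block's columns are mutually orthogonal, so the whole
    w-block minimizes in closed form given v: w = max(0, y - Hv - nλ).
    The v coordinates are updated by coordinate descent on the residual.
    Returns B of shape (L, n + m): w then v per grid λ.
    """
    n = y.shape[0]
    m = indptr.shape[0] - 1
    L = lambdas.shape[0]
    B = np.zeros((L, n + m))
    w = np.zeros(n)
    v = np.zeros(m)
    Hv = np.zeros(n)
    for li in range(L):
        lam_n = lambdas[li] * n
        for _ in range(max_passes):
            # exact w-block update given v
            for i in range(n):
                wi = y[i] - Hv[i] - lam_n
                if wi < 0.0:
                    wi = 0.0
                w[i] = wi
            # one coordinate-descent pass over the system weights
            for c in range(m):
                lo, hi = indptr[c], indptr[c + 1]
                size = hi - lo
                if size == 0:
                    continue
                grad = 0.0  # x_c^T r = sum over support of (y - w - Hv)
                for t in range(lo, hi):
                    g = indices[t]
                    grad += y[g] - w[g] - Hv[g]
                new = v[c] + (grad - lam_n) / size
                if new < 0.0:
                    new = 0.0
                delta = new - v[c]
                if delta != 0.0:
                    v[c] = new
                    for t in range(lo, hi):
                        Hv[indices[t]] += delta
            # KKT stationarity over all coordinates
            maxviol = 0.0
            for i in range(n):
                g_over_n = (y[i] - w[i] - Hv[i]) / n
                if w[i] > 0.0:
                    viol = abs(g_over_n - lambdas[li])
                else:
                    viol = g_over_n - lambdas[li]
                    if viol < 0.0:
                        viol = 0.0
                if viol > maxviol:
                    maxviol = viol
            for c in range(m):
                lo, hi = indptr[c], indptr[c + 1]
                grad = 0.0
                for t in range(lo, hi):
                    g = indices[t]
                    grad += y[g] - w[g] - Hv[g]
                g_over_n = grad / n
                if v[c] > 0.0:
                    viol = abs(g_over_n - lambdas[li])
                else:
                    viol = g_over_n - lambdas[li]
                    if viol < 0.0:
                        viol = 0.0
                if viol > maxviol:
                    maxviol = viol
            if maxviol <= tol:
                break
        for i in range(n):
            B[li, i] = w[i]
        for c in range(m):
            B[li, n + c] = v[c]
    return B


def _csc_columns(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column supports of a binary matrix as CSC-style (indptr, indices)."""
    n, m = H.shape
    cols = [np.nonzero(H[:, c] > 0)[0] for c in range(m)]
    indptr = np.zeros(m + 1, dtype=np.int64)
    for c, idx in enumerate(cols):
        indptr[c + 1] = indptr[c] + idx.shape[0]
    indices = (
        np.concatenate(cols).astype(np.int64) if m else np.empty(0, dtype=np.int64)
    )
    return indptr, indices


def lambda_grid(
    y: np.ndarray, H: np.ndarray, n_lambda: int, lambda_min_ratio: float
) -> np.ndarray:
    """Log-spaced descending grid from λ_max (smallest all-zero λ) down to
    λ_max * lambda_min_ratio."""
    n = y.shape[0]
    corr_genes = float(y.max(initial=0.0))
    corr_systems = float((H.T @ y).max(initial=0.0)) if H.size else 0.0
    lam_max = max(corr_genes, corr_systems) / n
    if lam_max <= 0:
        lam_max = 1.0  # degenerate all-zero signal; any grid gives zero paths
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _solve_path(
    y: np.ndarray,
    H: np.ndarray,
    lambdas: np.ndarray,
    csc: Optional[tuple[np.ndarray, np.ndarray]] = None,
    tol: float = 1e-10,
    max_passes: int = 100000,
) -> tuple[np.ndarray, np.ndarray]:
    n, m = H.shape
    indptr, indices = csc if csc is not None else _csc_columns(H)
    B = _cd_path_kernel(
        indptr, indices, np.ascontiguousarray(y), np.ascontiguousarray(lambdas), tol, max_passes
    )
    B[B < 1e-12] = 0.0  # KKT-equality coordinates can leave float-eps residue
    W = B[:, :n].T.copy()
    V = B[:, n:].T.copy()
    return W, V


def lasso_path(
    y: SignalTrack | np.ndarray,
    H: MembershipMatrix,
    n_lambda: int = 500,
    lambda_min_ratio: float = 1e-3,
) -> LassoPath:
    """Nonnegative lasso path of (1/(2n))·||y - Iw - Hv||² + λ·(Σw + Σv).

    KKT residuals are driven below 1e-8 at every grid λ; at the largest λ the
    solution is exactly zero.
    """
    if isinstance(y, SignalTrack):
        vals = y.transformed()
        yvec = np.array([vals.get(g, 0.0) for g in H.gene_ids])
    else:
        yvec = np.asarray(y, dtype=float)
    if yvec.shape[0] != len(H.gene_ids):
        raise ValueError("y length does not match membership gene count")
    if np.any(yvec < 0):
        raise ValueError("y must be nonnegative after transform")
    zero = not np.any(yvec > 0)
    lambdas = lambda_grid(yvec, H.matrix, n_lambda, lambda_min_ratio)
    if zero:
        return LassoPath(
            lambdas=lambdas,
            W=np.zeros((len(H.gene_ids), n_lambda)),
            V=np.zeros((len(H.system_ids), n_lambda)),
            zero_signal=True,
        )
    W, V = _solve_path(yvec, H.matrix, lambdas)
    return LassoPath(lambdas=lambdas, W=W, V=V)


def kkt_residual(path: LassoPath, y: np.ndarray, H: MembershipMatrix) -> float:
    """Largest KKT violation across the whole path (diagnostic)."""
    n = len(H.gene_ids)
    X = np.hstack([np.eye(n), H.matrix])
    worst = 0.0
    for li, lam in enumerate(path.lambdas):
        beta = np.concatenate([path.W[:, li], path.V[:, li]])
        grad = X.T @ (y - X @ beta) / n
        active = beta > 0
        if active.any():
            worst = max(worst, float(np.abs(grad[active] - lam).max()))
        if (~active).any():
            worst = max(worst, float(np.maximum(grad[~active] - lam, 0.0).max()))
    return worst


def selective_pressure(path: LassoPath) -> np.ndarray:
    """S(c) = max over λ (with positive total weight) of system c's share of
    the total weight; 0 for systems never active."""
    totals = path.W.sum(axis=0) + path.V.sum(axis=0)
    S = np.zeros(path.V.shape[0])
    pos = totals > 0
    if pos.any():
        frac = path.V[:, pos] / totals[pos]
        S = frac.max(axis=1)
    return S


def permutation_pvalues(
    y: SignalTrack | np.ndarray,
    H: MembershipMatrix,
    n_perm: int = 10000,
    seed: int = 0,
    n_lambda: int = 500,
    lambda_min_ratio: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical p-values for S(c) against row-permuted H.

    Returns (S_observed, p).  p(c) = (1 + #{perm: S_perm(c) >= S_obs(c)}) /
    (1 + n_perm), so p is never 0 and equals 1 when n_perm = 0.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    if isinstance(y, SignalTrack):
        vals = y.transformed()
        yvec = np.array([vals.get(g, 0.0) for g in H.gene_ids])
    else:
        yvec = np.asarray(y, dtype=float)
    obs_path = lasso_path(yvec, H, n_lambda, lambda_min_ratio)
    S_obs = selective_pressure(obs_path)
    m = len(H.system_ids)
    counts = np.zeros(m)
    if n_perm > 0 and not obs_path.zero_signal:
        n = len(H.gene_ids)
        rng = np.random.default_rng(seed)
        lambdas = obs_path.lambdas  # grid depends on y and column sums only;
        # both are invariant under row permutation of H, so reuse it
        indptr, indices = _csc_columns(H.matrix)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            # row i of permuted H equals row perm[i] of H, so column supports
            # map through the inverse permutation
            inv = np.empty(n, dtype=np.int64)
            inv[perm] = np.arange(n)
            Wp, Vp = _solve_path(
                yvec, H.matrix, lambdas, csc=(indptr, inv[indices])
            )
            totals = Wp.sum(axis=0) + Vp.sum(axis=0)
            pos = totals > 0
            S_perm = np.zeros(m)
            if pos.any():
                S_perm = (Vp[:, pos] / totals[pos]).max(axis=1)
            counts += S_perm >= S_obs - _PERM_SLACK
    elif n_perm > 0 and obs_path.zero_signal:
        counts[:] = n_perm  # all-zero signal: every permutation ties at S = 0
    p = (1.0 + counts) / (1.0 + n_perm)
    return S_obs, p


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class HisigConfig:
    n_lambda: int = 500
    lambda_min_ratio: float = 1e-3
    n_perm: int = 10000
    seed: int = 0
    fdr_cutoff: float = 0.25
    transform: str = "none"

    def as_dict(self) -> dict:
        return {
            "n_lambda": self.n_lambda,
            "lambda_min_ratio": self.lambda_min_ratio,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "fdr_cutoff": self.fdr_cutoff,
            "transform": self.transform,
        }


def run_hisig(
    track: SignalTrack, hierarchy: Hierarchy, config: HisigConfig = HisigConfig()
) -> PressureResult:
    """transform -> lasso path -> S(c) -> permutation p -> BH q -> flags."""
    H = membership_matrix(hierarchy)
    track = SignalTrack(name=track.name, values=track.values, transform=config.transform)
    missing = set(track.values) - set(H.gene_ids)
    if missing:
        warnings.warn(
            f"{len(missing)} track gene(s) absent from the hierarchy are ignored"
        )
    absent = set(H.gene_ids) - set(track.values)
    if absent:
        warnings.warn(
            f"{len(absent)} hierarchy gene(s) missing from track {track.name!r}; y = 0"
        )
    S_obs, p = permutation_pvalues(
        track,
        H,
        n_perm=config.n_perm,
        seed=config.seed,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    q = bh_adjust(p)
    sizes = H.matrix.sum(axis=0)
    return PressureResult(
        system_ids=H.system_ids,
        n_genes=sizes.astype(int),
        S=S_obs,
        p=p,
        q=q,
        significant=q < config.fdr_cutoff,
        metadata={"track": track.name, **config.as_dict()},
    )


def intersect_hotspots(results: Sequence[PressureResult]) -> dict[str, dict[str, float]]:
    """Intersection of significant systems across runs on the same hierarchy.

    Returns system id -> per-track q values.
    """
    if len(results) < 2:
        raise ValueError("need at least two result tables")
    base = set(results[0].system_ids)
    for r in results[1:]:
        if set(r.system_ids) != base:
            raise ValueError("results come from different hierarchies")
    common = set.intersection(*(r.significant_ids() for r in results))
    out: dict[str, dict[str, float]] = {}
    for sys_id in sorted(common):
        out[sys_id] = {}
        for i, r in enumerate(results):
            track = str(r.metadata.get("track", f"track{i}"))
            out[sys_id][track] = float(r.q[r.system_ids.index(sys_id)])
    return out
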