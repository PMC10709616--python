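"""Probe-level PCA of multidimensional experience sampling (mDES) data.

mDES probes ask participants to rate 13 aspects of ongoing thought on a
1-10 scale.  Concatenating every probe row-wise gives an observations x 13
matrix; a correlation-matrix PCA with varimax rotation summarizes it as a
small number of "thought patterns" (three in the analyses this package
targets).  Per-probe component scores are the dot product of the
standardized item ratings with the rotated loadings, and the same loadings
can project an external dataset into the trained space -- scaled by the
*training* item means and standard deviations, never the external set's.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pingouin as pg
from sklearn.base import BaseEstimator, TransformerMixin

N_ITEMS = 13
ITEM_COLUMNS = tuple(f"item_{i}" for i in range(1, N_ITEMS + 1))
KEY_COLUMNS = ("participant", "run", "probe_index")

logger = logging.getLogger(__name__)

__all__ = [
    "ThoughtPCA",
    "fit_pca_varimax",
    "score_probes",
    "project_external",
    "participant_means",
    "icc_consistency",
    "tucker_congruence",
    "kaiser_count",
]


def _varimax(
    loadings: np.ndarray, tol: float = 1e-6, max_iter: int = 100, kaiser: bool = True
) -> np.ndarray:
    """Varimax rotation with Kaiser row-normalization.

    Classic pairwise-free SVD formulation; returns the rotated loading
    matrix.  Rotation is orthogonal, so per-item communalities and total
    retained variance are preserved.
    """
    L = loadings.copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt((L**2).sum(axis=1)) if kaiser else np.ones(p)
    h[h == 0] = 1.0
    L = L / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return (L @ R) * h[:, None]


def _item_matrix(probes: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ITEM_COLUMNS if c in probes.columns]
    if len(cols) != N_ITEMS:
        missing = sorted(set(ITEM_COLUMNS) - set(cols))
        raise ValueError(f"probe table lacks item columns {missing}")
    return probes[list(ITEM_COLUMNS)]


class ThoughtPCA(BaseEstimator, TransformerMixin):
    """Correlation-matrix PCA with varimax rotation over mDES items.

    Parameters
    ----------
    n_components : int in [1, 13]
        Components to retain (no automated eigenvalue rule is applied; see
        :func:`kaiser_count` for an eigenvalue>1 helper).
    rotate : bool
        Apply varimax (identity when ``n_components == 1``).
    tol, max_iter
        Varimax convergence settings.

    Attributes
    ----------
    item_means_, item_sds_ : Series (13,)
        Training standardization (sd with ddof=1).
    loadings_ : DataFrame (13, k)
        Rotated loadings, columns ordered by descending rotated variance,
        each signed so its largest-|loading| item is positive.
    variance_explained_ : Series (k,)
        Percent variance per component, post-rotation.
    total_variance_explained_ : float
        Percent of total item variance retained (rotation-invariant).

    ``transform`` returns per-row component scores: standardized items
    (training scaling) dotted with the loadings.
    """

    def __init__(self, n_components: int = 3, rotate: bool = True,
                 tol: float = 1e-6, max_iter: int = 100):
        self.n_components = n_components
        self.rotate = rotate
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None) -> "ThoughtPCA":
        if not 1 <= self.n_components <= N_ITEMS:
            raise ValueError(f"n_components must be in [1, {N_ITEMS}]")
        items = _item_matrix(X) if X.shape[1] != N_ITEMS else pd.DataFrame(X).set_axis(
            list(ITEM_COLUMNS), axis=1
        )
        n_before = len(items)
        items = items.dropna()
        if n_before - len(items):
            logger.info("dropped %d probe rows with missing items", n_before - len(items))
        if len(items) < N_ITEMS:
            raise ValueError(f"need >= {N_ITEMS} complete probe rows, have {len(items)}")
        means = items.mean()
        sds = items.std(ddof=1)
        dead = sds.index[sds == 0].tolist()
        if dead:
            raise ValueError(f"zero-variance items: {dead}")
        Z = (items - means) / sds
        corr = np.corrcoef(Z.to_numpy(), rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        k = self.n_components
        L = eigvec[:, :k] * np.sqrt(eigval[:k])
        if self.rotate and k > 1:
            L = _varimax(L, tol=self.tol, max_iter=self.max_iter)
        # order by rotated variance, fix sign of the dominant item
        ssl = (L**2).sum(axis=0)
        L = L[:, np.argsort(ssl)[::-1]]
        for j in range(k):
            top = np.abs(L[:, j]).argmax()
            if L[top, j] < 0:
                L[:, j] = -L[:, j]
        self.item_means_ = means
        self.item_sds_ = sds
        self.eigenvalues_ = pd.Series(eigval, index=range(1, N_ITEMS + 1))
        self.loadings_ = pd.DataFrame(
            L, index=list(ITEM_COLUMNS), columns=[f"component_{j + 1}" for j in range(k)]
        )
        self.variance_explained_ = pd.Series(
            (L**2).sum(axis=0) / N_ITEMS * 100, index=self.loadings_.columns
        )
        self.total_variance_explained_ = float(eigval[:k].sum() / N_ITEMS * 100)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "loadings_"):
            raise RuntimeError("ThoughtPCA is not fitted")
        items = _item_matrix(X)
        Z = (items - self.item_means_) / self.item_sds_
        scores = Z.to_numpy() @ self.loadings_.to_numpy()
        return pd.DataFrame(
            scores,
            index=X.index,
            columns=[f"score_{j + 1}" for j in range(self.loadings_.shape[1])],
        )


def fit_pca_varimax(probes: pd.DataFrame, k: int = 3) -> ThoughtPCA:
    """Fit the probe-level varimax PCA (thin wrapper over ThoughtPCA)."""
    return ThoughtPCA(n_components=k).fit(probes)


def _with_keys(probes: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in probes.columns if not c.startswith("item_")]
    return pd.concat([probes[keys].reset_index(drop=True),
                      scores.reset_index(drop=True)], axis=1)


def score_probes(model: ThoughtPCA, probes: pd.DataFrame) -> pd.DataFrame:
    """Per-probe component scores, keyed like the input probe table."""
    return _with_keys(probes, model.transform(probes))


def project_external(model: ThoughtPCA, external: pd.DataFrame) -> pd.DataFrame:
    """Project an external 13-item dataset into the trained component space.

    Identical arithmetic to :func:`score_probes`, but validates the item
    set explicitly: the external table must carry exactly the training
    items.  Scaling always uses the training means/sds.
    """
    ext_items = [c for c in external.columns if c.startswith("item_")]
    mismatch = sorted(set(ext_items) ^ set(ITEM_COLUMNS))
    if mismatch:
        raise ValueError(f"external items do not align with the model: {mismatch}")
    return _with_keys(external, model.transform(external))


def participant_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean of each component score across all probes."""
    score_cols = [c for c in scores.columns if c.startswith("score_")]
    if scores.empty:
        return pd.DataFrame(columns=score_cols)
    return scores.groupby("participant")[score_cols].mean()


def icc_consistency(scores: pd.DataFrame, component: int = 1) -> float:
    """Run-wise consistency of a component: ICC(3,1) on per-run means.

    Per-run participant means are computed first; participants missing any
    run are excluded (count logged).  The statistic is the two-way mixed
    effects, consistency-type, single-measure intraclass correlation
    (ICC3), which rewards stable participant ordering across runs.
    """
    col = f"score_{component}"
    per_run = scores.groupby(["participant", "run"])[col].mean().unstack("run")
    complete = per_run.dropna()
    if len(complete) < len(per_run):
        logger.info(
            "excluding %d participants with missing runs", len(per_run) - len(complete)
        )
    if len(complete) < 2:
        raise ValueError("ICC undefined with fewer than 2 complete participants")
    long = complete.reset_index().melt(
        id_vars="participant", var_name="run", value_name=col
    )
    icc = pg.intraclass_corr(
        data=long, targets="participant", raters="run", ratings=col
    )
    # pingouin labels the consistency/single-measure row ICC3 or ICC(C,1)
    # depending on version
    mask = icc["Type"].isin(["ICC3", "ICC(C,1)"])
    return float(icc.loc[mask, "ICC"].iloc[0])


def tucker_congruence(A: np.ndarray | pd.DataFrame, B: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Tucker congruence of each column of A with its best |phi| match in B.

    Used to compare recovered loadings against planted ones (or solutions
    across sessions); returns one |phi| per column of A.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    An = A / np.linalg.norm(A, axis=0)
    Bn = B / np.linalg.norm(B, axis=0)
    phi = An.T @ Bn
    return np.abs(phi).max(axis=1)


def kaiser_count(probes: pd.DataFrame) -> int:
    """Number of correlation-matrix eigenvalues above 1 (retention helper)."""
    items = _item_matrix(probes).dropna()
    Z = (items - items.mean()) / items.std(ddof=1)
    eig = np.linalg.eigvalsh(np.corrcoef(Z.to_numpy(), rowvar=False))
    return int((eig > 1).sum())
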