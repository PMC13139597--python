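"""Henderson's mixed-model equations (MME) and pedigree machinery.

Shared by the test-day residual model and the population-scale model.  The
MME for y = Xb + Z1 u1 + ... + e with u_r ~ N(0, G_r) and e ~ N(0, I s2e)
are, after multiplying through by s2e:

    [ X'X    X'Z ] [ b ]   [ X'y ]
    [ Z'X  Z'Z + s2e * blockdiag(G_r^{-1}) ] [ u ] = [ Z'y ]

The additive-genetic covariance across animals is structured by the pedigree
numerator relationship matrix A; its sparse inverse is assembled directly by
Henderson's rules (inbreeding ignored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["a_inverse", "RandomTerm", "solve_mme", "MmeSolution"]

#: above this equation count the solver switches from dense to sparse LU
DENSE_LIMIT = 2000

UNKNOWN_PARENT = 0


def a_inverse(pedigree: pd.DataFrame) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix A.

    Henderson's rules ignoring inbreeding.  ``pedigree`` must have columns
    ``animal``, ``sire``, ``dam`` with 0 (or NaN) meaning unknown, and be
    topologically ordered: every known parent appears in an earlier row.

    Row/column order of the result follows the pedigree row order.
    """
    animals = pedigree["animal"].tolist()
    index = {a: i for i, a in enumerate(animals)}
    if len(index) != len(animals):
        raise ValueError("duplicate animal ids in pedigree")
    n = len(animals)
    rows, cols, vals = [], [], []

    def _parent(v):
        if pd.isna(v) or v == UNKNOWN_PARENT or v in ("0", ""):
            return None
        return v

    for i, (a, s, d) in enumerate(
        pedigree[["animal", "sire", "dam"]].itertuples(index=False)
    ):
        s, d = _parent(s), _parent(d)
        parents = []
        for p in (s, d):
            if p is not None:
                if p not in index:
                    raise ValueError(f"parent {p!r} of {a!r} not in pedigree")
                j = index[p]
                if j >= i:
                    raise ValueError(
                        f"animal {a!r} listed before its parent {p!r}; "
                        "pedigree must be topologically ordered"
                    )
                parents.append(j)
        # Mendelian sampling variance (no inbreeding): 1, 3/4, or 1/2
        w = 4.0 / (4.0 - len(parents) * 1.0) if parents else 1.0
        # len 0 -> 1, len 1 -> 4/3, len 2 -> 2
        rows.append(i); cols.append(i); vals.append(w)
        for j in parents:
            rows.extend((i, j)); cols.extend((j, i)); vals.extend((-w / 2, -w / 2))
            for k in parents:
                rows.append(j); cols.append(k); vals.append(w / 4)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


@dataclass
class RandomTerm:
    """One random effect block of the MME.

    ``design`` is the n x q incidence/covariate matrix; ``ginv`` the q x q
    inverse covariance of the effect (already including any Kronecker
    structure, e.g. kron(Ainv, inv(G_a)) for random-regression coefficients
    nested in a pedigree), scaled so that the MME addition is
    ``sigma2_e * ginv``.
    """

    name: str
    design: sp.spmatrix
    ginv: sp.spmatrix


@dataclass
class MmeSolution:
    fixed: np.ndarray
    random: dict = field(default_factory=dict)
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None


def solve_mme(X: sp.spmatrix, terms: list[RandomTerm], y: np.ndarray,
              sigma2_e: float) -> MmeSolution:
    """Solve Henderson's MME for one trait.

    Dense Cholesky-style solve below ``DENSE_LIMIT`` equations, sparse LU
    above.  Raises ``ValueError`` if the system is singular (confounded
    fixed-effect levels).
    """
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    y = np.asarray(y, dtype=float)
    X = sp.csr_matrix(X)
    Zs = [sp.csr_matrix(t.design) for t in terms]
    blocks = [X] + Zs
    W = sp.hstack(blocks, format="csr")
    shrink = sp.block_diag(
        [sp.csr_matrix((X.shape[1], X.shape[1]))]
        + [sigma2_e * sp.csr_matrix(t.ginv) for t in terms]
    )
    C = ((W.T @ W) + shrink).tocsc()
    rhs = W.T @ y
    n_eq = C.shape[0]
    if n_eq <= DENSE_LIMIT:
        Cd = C.toarray()
        try:
            sol = np.linalg.solve(Cd, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular mixed-model equations: confounded fixed-effect "
                "levels (check herd-year / month / class factors)"
            ) from exc
        # np.linalg.solve can succeed on nearly singular systems; verify
        if not np.all(np.isfinite(sol)):
            raise ValueError("singular mixed-model equations")
    else:
        lu = spla.splu(C)
        sol = lu.solve(rhs)
        if not np.all(np.isfinite(sol)):
            raise ValueError("singular mixed-model equations")
    out = MmeSolution(fixed=sol[: X.shape[1]])
    offset = X.shape[1]
    for t, Z in zip(terms, Zs):
        q = Z.shape[1]
        out.random[t.name] = sol[offset:offset + q]
        offset += q
    out.fitted = W @ sol
    out.residuals = y - out.fitted
    return out
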