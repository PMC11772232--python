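"""Group-wise behavioral partial least squares correlation (PLSC).

The method: within each group, z-score the volumetric matrix X and the
behavioral matrix Y, form the per-group cross-correlation blocks
``R_g = Y_g' X_g / (n_g - 1)``, stack them vertically (VPT block first),
and take the SVD of the stacked matrix.  Each latent component pairs a
common volumetric salience vector (right singular vector) with
group-specific behavioral salience blocks (slices of the left singular
vector).  Component significance comes from permuting the rows of Y
across the whole sample; salience stability from resampling subjects
with replacement within each group, with Procrustes re-alignment of
every bootstrap solution to the reference before accumulating
standard deviations.  The bootstrap ratio (BSR) is the reference
salience divided by its bootstrap SD; |BSR| >= 3 flags a robust
contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateColumnError, ValidationError

log = logging.getLogger(__name__)


def _groups_in_order(groups, group_order):
    groups = np.asarray(groups)
    if group_order is None:
        # fixed stacking order: order of first appearance
        _, idx = np.unique(groups, return_index=True)
        group_order = list(groups[np.sort(idx)])
    missing = set(group_order) - set(groups)
    if missing:
        raise ValidationError(f"groups {missing} absent from data")
    return groups, list(group_order)


def _zscore_block(M: np.ndarray, group: str, names) -> np.ndarray:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise DegenerateColumnError(group, str(names[zero[0]]))
    return (M - mean) / sd


def stacked_cross_covariance(
    X,
    Y,
    groups,
    group_order=None,
    zscore: bool = True,
):
    """Stacked per-group cross-covariance matrix R of shape (G*B, V).

    With ``zscore`` (default) each group's X and Y columns are z-scored
    first, so each block is that group's Pearson correlation matrix
    between behavior (rows) and volumes (columns).  With
    ``zscore=False`` columns are centered only (literal covariance).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y must be row-aligned 2-D arrays")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValidationError("X and Y must be free of missing values")
    groups, order = _groups_in_order(groups, group_order)
    x_names = list(range(X.shape[1]))
    y_names = list(range(Y.shape[1]))
    blocks = []
    for g in order:
        sel = groups == g
        if sel.sum() < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 subjects")
        Xg, Yg = X[sel], Y[sel]
        if zscore:
            Xg = _zscore_block(Xg, g, x_names)
            Yg = _zscore_block(Yg, g, y_names)
        else:
            Xg = Xg - Xg.mean(axis=0)
            Yg = Yg - Yg.mean(axis=0)
        blocks.append(Yg.T @ Xg / (sel.sum() - 1))
    return np.vstack(blocks)


def svd_components(R: np.ndarray):
    """SVD of R with deterministic ordering and sign convention.

    Returns ``(s, U, V)`` with components ordered by decreasing
    singular value and each component's sign fixed so that the
    volumetric salience entry of largest magnitude is positive.
    """
    R = np.asarray(R, dtype=float)
    if not np.isfinite(R).all():
        raise ValidationError("R contains non-finite entries")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for k in range(len(s)):
        lead = np.argmax(np.abs(V[:, k]))
        if V[lead, k] < 0:
            V[:, k] *= -1.0
            U[:, k] *= -1.0
    return s, U, V


def _procrustes_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Orthogonal W minimizing ||A W - B||_F (A, B column-matched)."""
    P, _, Qt = np.linalg.svd(A.T @ B)
    return P @ Qt


def permutation_test(
    X,
    Y,
    groups,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    group_order=None,
    zscore: bool = True,
    procrustes: bool = False,
):
    """Permutation p-value per latent component.

    Rows of Y are permuted across the whole sample while X and the
    group labels stay fixed; the stacked matrix and its singular values
    are recomputed per permutation and compared rank-for-rank (or,
    with ``procrustes``, after rotating the permuted solution onto the
    reference).  ``p_k = (1 + #{s_perm >= s_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    R_obs = stacked_cross_covariance(X, Y, groups, group_order, zscore)
    s_obs, _, V_ref = svd_components(R_obs)
    n = X.shape[0]
    exceed = np.zeros(len(s_obs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        R_p = stacked_cross_covariance(
            X, Y[perm], groups, group_order, zscore
        )
        if procrustes:
            s_p, _, V_p = svd_components(R_p)
            Q = _procrustes_rotation(V_p, V_ref)
            s_p = np.linalg.norm(np.diag(s_p) @ Q, axis=0)
        else:
            s_p = np.linalg.svd(R_p, compute_uv=False)
        exceed += s_p[: len(s_obs)] >= s_obs
    return (1.0 + exceed) / (1.0 + n_perm)


def bootstrap_stability(
    X,
    Y,
    groups,
    reference,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
    group_order=None,
    zscore: bool = True,
    max_redraws: int = 100,
):
    """Bootstrap SDs of the saliences, aligned to a reference solution.

    ``reference`` is the ``(s, U, V)`` triple from
    :func:`svd_components` on the observed data.  Subjects are
    resampled with replacement within each group (group sizes
    preserved); each resample's singular vectors are rotated onto the
    reference by orthogonal Procrustes (on the stacked
    behavioral+volumetric saliences) before accumulating.  Resamples
    that produce a zero-variance column are redrawn (logged, bounded).

    Returns ``(sd_U, sd_V)`` elementwise bootstrap standard deviations.
    """
    if n_boot < 2:
        raise ConfigurationError("n_boot must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    _, U_ref, V_ref = reference
    groups_arr, order = _groups_in_order(groups, group_order)
    group_idx = [np.flatnonzero(groups_arr == g) for g in order]

    U_samples = np.empty((n_boot,) + U_ref.shape)
    V_samples = np.empty((n_boot,) + V_ref.shape)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = np.concatenate(
                [rng.choice(gi, size=len(gi), replace=True)
                 for gi in group_idx]
            )
            try:
                R_b = stacked_cross_covariance(
                    X[idx], Y[idx], groups_arr[idx], order, zscore
                )
            except DegenerateColumnError:
                redraws += 1
                if redraws > max_redraws:
                    raise
                continue
            break
        _, U_b, V_b = svd_components(R_b)
        K = U_ref.shape[1]
        W = _procrustes_rotation(
            np.vstack([U_b[:, :K], V_b[:, :K]]),
            np.vstack([U_ref, V_ref]),
        )
        U_samples[b] = U_b[:, :K] @ W
        V_samples[b] = V_b[:, :K] @ W
    if redraws:
        log.info("bootstrap_stability: redrew %d degenerate resamples",
                 redraws)
    return U_samples.std(axis=0, ddof=1), V_samples.std(axis=0, ddof=1)


@dataclass
class PlscResult:
    """Full output of one group-wise PLSC analysis."""

    group_order: list
    measure_names: list
    behavior_names: list
    singular_values: np.ndarray  # (K,)
    perm_p: np.ndarray  # (K,)
    volumetric_saliences: np.ndarray  # (V, K)
    behavior_saliences: np.ndarray  # (G*B, K), VPT block first
    boot_sd_volumetric: np.ndarray
    boot_sd_behavior: np.ndarray
    bsr_volumetric: np.ndarray
    bsr_behavior: np.ndarray
    robust_volumetric: np.ndarray  # bool (V, K)
    robust_behavior: np.ndarray  # bool (G*B, K)
    significant: np.ndarray  # bool (K,)
    scores_x: np.ndarray  # (n, K) latent scores X_z . v_k
    scores_y: np.ndarray  # (n, K) per-group Y_gz . u_k(g)
    r_matrix: np.ndarray
    n_perm: int = 1000
    n_boot: int = 500
    alpha_component: float = 0.01
    bsr_threshold: float = 3.0
    config: dict = field(default_factory=dict)

    @property
    def frobenius_sq(self) -> float:
        return float(np.sum(self.r_matrix**2))

    def behavior_salience_block(self, group) -> np.ndarray:
        """Behavioral saliences (B, K) for one group."""
        g = self.group_order.index(group)
        B = len(self.behavior_names)
        return self.behavior_saliences[g * B: (g + 1) * B]

    def components_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.singular_values) + 1),
                "singular_value": self.singular_values,
                "perm_p": self.perm_p,
                "significant": self.significant,
                "explained_covariance": self.singular_values**2
                / self.frobenius_sq,
            }
        )

    def volumetric_salience_table(self) -> pd.DataFrame:
        rows = []
        for k in range(len(self.singular_values)):
            for j, m in enumerate(self.measure_names):
                rows.append(
                    {
                        "component": k + 1,
                        "measure": m,
                        "salience": self.volumetric_saliences[j, k],
                        "boot_sd": self.boot_sd_volumetric[j, k],
                        "bsr": self.bsr_volumetric[j, k],
                        "robust": bool(self.robust_volumetric[j, k]),
                    }
                )
        return pd.DataFrame(rows)

    def behavior_salience_table(self) -> pd.DataFrame:
        B = len(self.behavior_names)
        rows = []
        for k in range(len(self.singular_values)):
            for i in range(self.behavior_saliences.shape[0]):
                rows.append(
                    {
                        "component": k + 1,
                        "group": self.group_order[i // B],
                        "behavior": self.behavior_names[i % B],
                        "salience": self.behavior_saliences[i, k],
                        "boot_sd": self.boot_sd_behavior[i, k],
                        "bsr": self.bsr_behavior[i, k],
                        "robust": bool(self.robust_behavior[i, k]),
                    }
                )
        return pd.DataFrame(rows)


def _bsr(salience: np.ndarray, sd: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(sd > 0, salience / np.where(sd > 0, sd, 1.0),
                       np.inf * np.sign(salience))
    return bsr


def run_plsc(
    X,
    Y,
    groups,
    *,
    group_order=None,
    n_perm: int = 1000,
    n_boot: int = 500,
    seed: int = 0,
    alpha_component: float = 0.01,
    bsr_threshold: float = 3.0,
    zscore: bool = True,
    perm_procrustes: bool = False,
    measure_names=None,
    behavior_names=None,
) -> PlscResult:
    """Full group-wise PLSC: SVD + permutation + bootstrap.

    ``X``/``Y`` may be DataFrames (column names become measure/behavior
    names) or arrays.  Permutation and bootstrap draw from independent
    streams spawned from ``seed``.
    """
    if isinstance(X, pd.DataFrame):
        measure_names = measure_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    if isinstance(Y, pd.DataFrame):
        behavior_names = behavior_names or list(Y.columns)
        Y = Y.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    measure_names = list(measure_names or range(X.shape[1]))
    behavior_names = list(behavior_names or range(Y.shape[1]))

    groups_arr, order = _groups_in_order(groups, group_order)
    R = stacked_cross_covariance(X, Y, groups_arr, order, zscore)
    s, U, V = svd_components(R)

    ss_perm, ss_boot = np.random.SeedSequence(seed).spawn(2)
    perm_p = permutation_test(
        X,
        Y,
        groups_arr,
        n_perm=n_perm,
        seed=np.random.default_rng(ss_perm),
        group_order=order,
        zscore=zscore,
        procrustes=perm_procrustes,
    )
    sd_U, sd_V = bootstrap_stability(
        X,
        Y,
        groups_arr,
        (s, U, V),
        n_boot=n_boot,
        seed=np.random.default_rng(ss_boot),
        group_order=order,
        zscore=zscore,
    )
    bsr_U = _bsr(U, sd_U)
    bsr_V = _bsr(V, sd_V)

    # subject-level latent scores on the (per-group standardized) data
    n = X.shape[0]
    K = len(s)
    scores_x = np.empty((n, K))
    scores_y = np.empty((n, K))
    B = Y.shape[1]
    for g_i, g in enumerate(order):
        sel = groups_arr == g
        Xg = _zscore_block(X[sel], g, measure_names) if zscore else (
            X[sel] - X[sel].mean(axis=0)
        )
        Yg = _zscore_block(Y[sel], g, behavior_names) if zscore else (
            Y[sel] - Y[sel].mean(axis=0)
        )
        scores_x[sel] = Xg @ V
        scores_y[sel] = Yg @ U[g_i * B: (g_i + 1) * B]

    return PlscResult(
        group_order=order,
        measure_names=measure_names,
        behavior_names=behavior_names,
        singular_values=s,
        perm_p=perm_p,
        volumetric_saliences=V,
        behavior_saliences=U,
        boot_sd_volumetric=sd_V,
        boot_sd_behavior=sd_U,
        bsr_volumetric=bsr_V,
        bsr_behavior=bsr_U,
        robust_volumetric=np.abs(bsr_V) >= bsr_threshold,
        robust_behavior=np.abs(bsr_U) >= bsr_threshold,
        significant=perm_p < alpha_component,
        scores_x=scores_x,
        scores_y=scores_y,
        r_matrix=R,
        n_perm=n_perm,
        n_boot=n_boot,
        alpha_component=alpha_component,
        bsr_threshold=bsr_threshold,
        config={
            "seed": seed,
            "zscore": zscore,
            "perm_procrustes": perm_procrustes,
        },
    )
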