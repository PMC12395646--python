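"""Multiple Factor Analysis (MFA) for the condition-blocked sway battery.

MFA is a weighted PCA for data whose variables come in blocks — here the
four sensory conditions, each contributing the same six sway metrics. A
standardized PCA is run inside each block; every variable of block *b* is
then weighted by ``1/sqrt(lambda_1^b)``, the inverse square root of that
block's first eigenvalue, so each block's leading inertia becomes exactly
1 and no single condition dominates; a global PCA of the weighted,
concatenated matrix yields the common dimensions, onto which the
individual blocks can be projected (partial scores).

Adequacy is checked with the Kaiser-Meyer-Olkin measure and Bartlett's
sphericity test, the number of interpretable dimensions with Horn's
parallel analysis, and the retained loadings are varimax-rotated before
thresholding (|loading| >= 0.40 substantial, > 0.32 on several dimensions
flagged as cross-loading).

Everything is implemented directly on top of the SVD so each step is
auditable; tests hold the whole model to an independent SVD oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import significance_code

__all__ = [
    "MFA",
    "MFAResults",
    "RetentionDiagnostics",
    "fit_mfa",
    "kmo",
    "bartlett_sphericity",
    "varimax",
    "horn_parallel",
    "interpret_loadings",
    "group_variance_share",
    "dimension_group_test",
]


# ---------------------------------------------------------------------------
# adequacy diagnostics
# ---------------------------------------------------------------------------

def kmo(data) -> tuple[pd.Series, float]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Compares simple correlations ``r`` with anti-image partial
    correlations ``q``: MSA = sum r^2 / (sum r^2 + sum q^2) over the
    off-diagonal entries (per-variable over each row, overall over all).
    Values near 1 mean variables share common factors; below ~0.6 the
    data are a poor candidate for factor analysis.
    """
    X = _as_matrix(data)
    if X.shape[1] < 3:
        raise ValueError("KMO needs at least 3 variables")
    R = np.corrcoef(X, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; using pseudo-inverse", stacklevel=2)
        Rinv = np.linalg.pinv(R)
    diag = np.clip(np.diag(Rinv), 1e-12, None)  # pinv can leave tiny negatives
    d = np.sqrt(np.outer(diag, diag))
    partial = -Rinv / d
    np.fill_diagonal(partial, 0.0)
    r2 = R**2
    np.fill_diagonal(r2, 0.0)
    q2 = partial**2
    per_var = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    names = data.columns if isinstance(data, pd.DataFrame) else range(X.shape[1])
    return pd.Series(per_var, index=names, name="kmo"), overall


def bartlett_sphericity(data) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2, upper-tail
    p from the chi-square distribution.
    """
    X = _as_matrix(data)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def _as_matrix(data) -> np.ndarray:
    X = data.to_numpy(float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D observations x variables table")
    return X


# ---------------------------------------------------------------------------
# varimax rotation
# ---------------------------------------------------------------------------

def _varimax_criterion(L: np.ndarray) -> float:
    # sum over factors of the variance of squared loadings
    L2 = L**2
    return float(np.sum(L2**2) - np.sum(L2.sum(axis=0) ** 2) / L.shape[0])


def varimax(
    loadings,
    *,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Orthogonal rotation maximising the variance of squared loadings per
    factor, with Kaiser row-normalisation by default (rows scaled to unit
    communality during the search, restored afterwards — so row
    communalities are preserved exactly). Iterates until the criterion
    gain drops below ``tol``. A single-column matrix is returned
    unchanged. Returns ``(rotated, rotation_matrix)``.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        safe = np.where(h > 0, h, 1.0)
        L = L / safe[:, None]

    # Kaiser's pairwise planar rotations: for each factor pair the optimal
    # angle has a closed form, phi = atan2(D - 2AB/p, C - (A^2 - B^2)/p) / 4
    # with u = x^2 - y^2, v = 2xy, A = sum u, B = sum v, C = sum(u^2 - v^2),
    # D = sum 2uv; sweeps repeat until the criterion stops improving.
    R = np.eye(k)
    Lr = L.copy()
    crit = _varimax_criterion(Lr)
    converged = False
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = Lr[:, i], Lr[:, j]
                u = x * x - y * y
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C, D = (u * u - v * v).sum(), 2.0 * (u * v).sum()
                num = D - 2.0 * A * B / p
                den = C - (A * A - B * B) / p
                if num == 0.0 and den == 0.0:
                    continue
                phi = 0.25 * np.arctan2(num, den)
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                Lr[:, [i, j]] = Lr[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        new_crit = _varimax_criterion(Lr)
        if new_crit - crit < tol:
            converged = True
            break
        crit = new_crit
    if not converged:
        warnings.warn("varimax did not converge; returning last iterate", stacklevel=2)
    rotated = Lr
    if kaiser_normalize:
        rotated = rotated * np.where(h > 0, h, 1.0)[:, None]
    rotated, flips = _fix_signs(rotated)
    R = R * flips[None, :]
    return rotated, R


def _fix_signs(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip columns so the entry of largest magnitude is positive."""
    idx = np.argmax(np.abs(L), axis=0)
    flips = np.sign(L[idx, np.arange(L.shape[1])])
    flips[flips == 0] = 1.0
    return L * flips[None, :], flips


# ---------------------------------------------------------------------------
# Horn's parallel analysis
# ---------------------------------------------------------------------------

def _weighted_eigenvalues(X: np.ndarray, blocks: list[np.ndarray] | None) -> np.ndarray:
    """Eigenvalues of the (block-weighted) standardized covariance."""
    Z = _standardize(X)
    if blocks is not None:
        Z = Z.copy()
        for cols in blocks:
            lam1 = _block_lambda1(Z[:, cols])
            Z[:, cols] /= np.sqrt(lam1)
    n = Z.shape[0]
    s = np.linalg.svd(Z, compute_uv=False)
    eig = np.zeros(Z.shape[1])
    eig[: len(s)] = s**2 / (n - 1)
    return eig


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance variable at column {j}")
    return (X - mu) / sd


def _block_lambda1(Z: np.ndarray) -> float:
    n = Z.shape[0]
    s1 = np.linalg.svd(Z, compute_uv=False)[0]
    return float(s1**2 / (n - 1))


def horn_parallel(
    data,
    *,
    blocks: list[np.ndarray] | None = None,
    n_iter: int = 500,
    quantile: float = 0.95,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Horn's parallel analysis on the (optionally block-weighted) matrix.

    Observed eigenvalues are compared rank-by-rank against the chosen
    quantile of eigenvalues from ``n_iter`` standard-normal datasets of
    identical shape pushed through the same standardize-and-weight
    pipeline; the retained count is the number of *leading consecutive*
    observed eigenvalues exceeding their noise threshold. Deterministic
    under ``seed``. Returns ``(retained, thresholds)``.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100 for stable quantiles")
    X = _as_matrix(data)
    n, p = X.shape
    observed = _weighted_eigenvalues(X, blocks)
    rng = np.random.default_rng(seed)
    noise_eigs = np.empty((n_iter, p))
    for i in range(n_iter):
        noise_eigs[i] = _weighted_eigenvalues(rng.standard_normal((n, p)), blocks)
    thresholds = np.quantile(noise_eigs, quantile, axis=0)
    exceed = observed > thresholds
    retained = 0
    for flag in exceed:
        if not flag:
            break
        retained += 1
    return retained, thresholds


# ---------------------------------------------------------------------------
# the MFA model
# ---------------------------------------------------------------------------

@dataclass
class RetentionDiagnostics:
    """Adequacy and dimensionality diagnostics for an MFA fit."""

    kmo_per_variable: pd.Series
    kmo_overall: float
    kmo_per_block: dict[str, float]
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    horn_retained: int | None = None
    horn_thresholds: np.ndarray | None = None


class MFA:
    """Multiple Factor Analysis model over condition blocks of variables.

    Parameters
    ----------
    data : DataFrame
        Observations x variables table (complete cases). Non-numeric
        columns are treated as metadata and ignored.
    blocks : mapping, optional
        ``{block_name: [column, ...]}``. When omitted, columns named
        ``metric@BLOCK`` are grouped by their suffix.
    n_dims : int or None
        Dimensions to retain for rotation/interpretation. ``None``
        (default) lets Horn's parallel analysis decide (minimum 1).
    rotate : bool
        Varimax-rotate the retained loadings (identity when 1 dim).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        blocks: dict[str, list[str]] | None = None,
        *,
        n_dims: int | None = None,
        rotate: bool = True,
        horn_iter: int = 500,
        horn_quantile: float = 0.95,
        seed: int = 0,
        diagnostics: bool = True,
    ):
        numeric = data.select_dtypes(include=[np.number])
        if blocks is None:
            blocks = {}
            for col in numeric.columns:
                if "@" in col:
                    blocks.setdefault(col.split("@", 1)[1], []).append(col)
            if not blocks:
                blocks = {"all": list(numeric.columns)}
        ordered_cols = [c for cols in blocks.values() for c in cols]
        self.data = numeric[ordered_cols]
        if self.data.isna().any().any():
            raise ValueError("MFA requires complete cases; drop or impute NaNs first")
        if len(self.data) < 3:
            raise ValueError("MFA needs at least 3 observations")
        self.blocks = {name: list(cols) for name, cols in blocks.items()}
        self.n_dims = n_dims
        self.rotate = rotate
        self.horn_iter = horn_iter
        self.horn_quantile = horn_quantile
        self.seed = seed
        self.diagnostics = diagnostics

    @classmethod
    def from_metrics_table(cls, table: pd.DataFrame, **kwargs) -> "MFA":
        """Build from the long metrics table (pivots to participants x 24)."""
        from .battery import to_wide

        return cls(to_wide(table), **kwargs)

    def _block_indices(self) -> list[np.ndarray]:
        cols = list(self.data.columns)
        return [
            np.array([cols.index(c) for c in block_cols])
            for block_cols in self.blocks.values()
        ]

    def fit(self) -> "MFAResults":
        X = self.data.to_numpy(float)
        n, p = X.shape
        cols = list(self.data.columns)

        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [cols[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance variables: {bad}")
        Z = (X - mu) / sd

        block_weights = {}
        Zw = Z.copy()
        idx_blocks = self._block_indices()
        for name, idx in zip(self.blocks, idx_blocks):
            lam1 = _block_lambda1(Z[:, idx])
            block_weights[name] = 1.0 / lam1
            Zw[:, idx] /= np.sqrt(lam1)

        U, s, Vt = np.linalg.svd(Zw, full_matrices=False)
        eigenvalues = s**2 / (n - 1)
        variance_explained = 100.0 * eigenvalues / eigenvalues.sum()
        scores_full = U * s  # participant coordinates on all dimensions
        V = Vt.T

        # diagnostics on the standardized (unweighted) variables
        if self.diagnostics:
            try:
                kmo_pv, kmo_all = kmo(self.data)
                kmo_blocks = {
                    name: kmo(self.data[colnames])[1]
                    for name, colnames in self.blocks.items()
                }
            except (np.linalg.LinAlgError, ValueError) as exc:
                warnings.warn(f"KMO unavailable: {exc}", stacklevel=2)
                kmo_pv, kmo_all, kmo_blocks = pd.Series(dtype=float), np.nan, {}
            try:
                chi2, df, bart_p = bartlett_sphericity(self.data)
            except np.linalg.LinAlgError as exc:
                warnings.warn(f"Bartlett test unavailable: {exc}", stacklevel=2)
                chi2, df, bart_p = np.nan, p * (p - 1) // 2, np.nan
            horn_retained, horn_thr = horn_parallel(
                self.data,
                blocks=idx_blocks,
                n_iter=self.horn_iter,
                quantile=self.horn_quantile,
                seed=self.seed,
            )
        else:
            kmo_pv, kmo_all, kmo_blocks = pd.Series(dtype=float), np.nan, {}
            chi2, df, bart_p = np.nan, p * (p - 1) // 2, np.nan
            horn_retained, horn_thr = None, None
        diagnostics = RetentionDiagnostics(
            kmo_per_variable=kmo_pv,
            kmo_overall=kmo_all,
            kmo_per_block=kmo_blocks,
            bartlett_chi2=chi2,
            bartlett_df=df,
            bartlett_p=bart_p,
            horn_retained=horn_retained,
            horn_thresholds=horn_thr,
        )

        if self.n_dims is not None:
            n_keep = self.n_dims
        elif horn_retained is not None:
            n_keep = max(horn_retained, 1)
        else:
            n_keep = min(2, len(eigenvalues))
        n_keep = min(n_keep, len(eigenvalues))
        dims = [f"Dim{k + 1}" for k in range(len(eigenvalues))]
        kept = dims[:n_keep]

        # loadings = correlations of the original variables with the scores
        loadings_full = np.empty((p, len(eigenvalues)))
        Fc = scores_full - scores_full.mean(axis=0)
        for k in range(len(eigenvalues)):
            fk = Fc[:, k]
            denom = np.sqrt((Z**2).sum(axis=0) * (fk @ fk))
            with np.errstate(invalid="ignore", divide="ignore"):
                loadings_full[:, k] = np.where(denom > 0, Z.T @ fk / denom, 0.0)
        loadings_full, flips = _fix_signs(loadings_full)
        scores_full = scores_full * flips[None, :]
        V = V * flips[None, :]

        contrib = 100.0 * V**2  # per-dimension contributions, sum to 100

        rotated = None
        rotation = None
        if self.rotate:
            rot_mat, rotation = varimax(loadings_full[:, :n_keep])
            rotated = pd.DataFrame(rot_mat, index=cols, columns=kept)

        return MFAResults(
            model=self,
            block_weights=block_weights,
            eigenvalues=eigenvalues,
            variance_explained=pd.Series(variance_explained, index=dims),
            loadings=pd.DataFrame(loadings_full, index=cols, columns=dims),
            rotated_loadings=rotated,
            rotation=rotation,
            contrib=pd.DataFrame(contrib, index=cols, columns=dims),
            scores=pd.DataFrame(scores_full, index=self.data.index, columns=dims),
            standardization=pd.DataFrame({"mean": mu, "sd": sd}, index=cols),
            diagnostics=diagnostics,
            n_retained=n_keep,
        )


@dataclass
class MFAResults:
    """Fitted MFA: eigenstructure, loadings, scores and diagnostics."""

    model: MFA
    block_weights: dict[str, float]
    eigenvalues: np.ndarray
    variance_explained: pd.Series
    loadings: pd.DataFrame
    rotated_loadings: pd.DataFrame | None
    rotation: np.ndarray | None
    contrib: pd.DataFrame
    scores: pd.DataFrame
    standardization: pd.DataFrame
    diagnostics: RetentionDiagnostics
    n_retained: int

    def summary(self) -> str:
        d = self.diagnostics
        ve = self.variance_explained
        lines = [
            "Multiple Factor Analysis",
            f"  {self.scores.shape[0]} observations, "
            f"{self.loadings.shape[0]} variables in {len(self.block_weights)} blocks",
            f"  KMO overall: {d.kmo_overall:.3f}   "
            f"Bartlett chi2({d.bartlett_df}) = {d.bartlett_chi2:.1f}, "
            f"p = {d.bartlett_p:.3g} {significance_code(d.bartlett_p)}",
            f"  Horn's parallel analysis retains {d.horn_retained} dimension(s); "
            f"{self.n_retained} kept for interpretation",
            "  Variance explained (%): "
            + ", ".join(f"{dim} {v:.1f}" for dim, v in ve.head(4).items()),
        ]
        if self.rotated_loadings is not None:
            lines += ["", "Varimax-rotated loadings:", self.rotated_loadings.round(3).to_string()]
        return "\n".join(lines)

    def partial_scores(self, block: str) -> pd.DataFrame:
        """Projection of one condition block onto the global dimensions.

        The standard MFA partial-cloud coordinates: the block's weighted
        columns projected on the global axes, scaled by the number of
        blocks so the mean of partial points equals the global score.
        """
        mfa = self.model
        cols = mfa.blocks[block]
        Z = (mfa.data - self.standardization["mean"]) / self.standardization["sd"]
        Zb = Z[cols].to_numpy(float) * np.sqrt(self.block_weights[block])
        # right singular vectors recovered from Zw = F V^T
        Vt, *_ = np.linalg.lstsq(
            self.scores.to_numpy(), _zw(mfa, self.standardization), rcond=None
        )
        all_cols = list(mfa.data.columns)
        idx = [all_cols.index(c) for c in cols]
        Vb = Vt.T[idx]
        proj = len(mfa.blocks) * Zb @ Vb
        return pd.DataFrame(proj, index=mfa.data.index, columns=self.scores.columns)

    def plot_loadings(self, dims=("Dim1", "Dim2"), rotated: bool = True, ax=None):
        """Loading biplot (arrows coloured by contribution)."""
        import matplotlib.pyplot as plt

        L = self.rotated_loadings if (rotated and self.rotated_loadings is not None) else self.loadings
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        c = self.contrib[dims[0]] + self.contrib[dims[1]]
        cmap = plt.get_cmap("coolwarm")
        cn = (c - c.min()) / max(c.max() - c.min(), 1e-12)
        for var in L.index:
            x, y = L.loc[var, dims[0]], L.loc[var, dims[1]]
            ax.annotate(
                "", xy=(x, y), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color=cmap(cn[var])),
            )
            ax.text(x, y, var, fontsize=6)
        theta = np.linspace(0, 2 * np.pi, 200)
        ax.plot(np.cos(theta), np.sin(theta), lw=0.5, color="grey")
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel(dims[0])
        ax.set_ylabel(dims[1])
        ax.set_aspect("equal")
        return ax

    def loadings_table(self) -> pd.DataFrame:
        """Tidy per-variable table: loading, rotated loading, contrib."""
        rows = []
        for block, cols in self.model.blocks.items():
            for col in cols:
                metric = col.split("@", 1)[0]
                for dim in self.loadings.columns[: self.n_retained]:
                    rows.append(
                        {
                            "variable": col,
                            "metric": metric,
                            "block": block,
                            "dim": dim,
                            "loading": self.loadings.loc[col, dim],
                            "rotated_loading": (
                                self.rotated_loadings.loc[col, dim]
                                if self.rotated_loadings is not None
                                and dim in self.rotated_loadings.columns
                                else np.nan
                            ),
                            "contrib": self.contrib.loc[col, dim],
                        }
                    )
        return pd.DataFrame(rows)


def _zw(mfa: MFA, standardization: pd.DataFrame) -> np.ndarray:
    Z = (mfa.data.to_numpy(float) - standardization["mean"].to_numpy()) / standardization[
        "sd"
    ].to_numpy()
    for name, idx in zip(mfa.blocks, mfa._block_indices()):
        lam1 = _block_lambda1(Z[:, idx])
        Z[:, idx] /= np.sqrt(lam1)
    return Z


def fit_mfa(data_or_table: pd.DataFrame, blocks=None, **kwargs) -> MFAResults:
    """Fit an MFA from a wide table (or long metrics table with 'metric')."""
    if {"metric", "condition", "value"}.issubset(data_or_table.columns):
        return MFA.from_metrics_table(data_or_table, **kwargs).fit()
    return MFA(data_or_table, blocks, **kwargs).fit()


# ---------------------------------------------------------------------------
# interpretation and group comparisons
# ---------------------------------------------------------------------------

def interpret_loadings(
    rotated_loadings: pd.DataFrame,
    substantial: float = 0.40,
    crossload: float = 0.32,
) -> pd.DataFrame:
    """Classify variables by their rotated loadings.

    A variable is *substantial* on every dimension where
    ``|loading| >= substantial``; it is *flagged cross-loading* when more
    than one dimension exceeds ``crossload`` in magnitude; with no
    substantial loading and no cross-loading it is *negligible*.
    """
    if not (0 < crossload < 1 and 0 < substantial < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    rows = []
    for var, lds in rotated_loadings.iterrows():
        absl = lds.abs()
        subs = list(lds.index[absl >= substantial])
        crossing = int((absl > crossload).sum()) >= 2
        if subs:
            label = "substantial"
        elif crossing:
            label = "cross-loading"
        else:
            label = "negligible"
        rows.append(
            {
                "variable": var,
                "label": label,
                "substantial_dims": ",".join(subs),
                "primary_dim": absl.idxmax(),
                "cross_loading": crossing,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def group_variance_share(
    data: pd.DataFrame,
    groups: pd.Series,
    *,
    n_dims: int = 2,
    **mfa_kwargs,
) -> pd.DataFrame:
    """Per-group MFA variance shares for the leading dimensions.

    Fits a separate MFA inside each group and reports each group's
    percentage of variance on Dim1..Dim``n_dims``.
    """
    groups = groups.loc[data.index]
    mfa_kwargs.setdefault("diagnostics", False)
    rows = []
    for level in sorted(groups.unique()):
        sub = data.loc[groups == level]
        res = MFA(sub, n_dims=n_dims, **mfa_kwargs).fit()
        row = {"group": level, "n": len(sub)}
        for k in range(n_dims):
            row[f"dim{k + 1}_share"] = float(res.variance_explained.iloc[k])
        rows.append(row)
    return pd.DataFrame(rows)


def dimension_group_test(
    scores: pd.Series,
    groups: pd.Series,
    *,
    method: str = "anova",
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Test whether dimension scores differ by group.

    ``method="anova"`` runs a one-way ANOVA of the scores on group
    (reporting F, df, p and eta-squared); ``method="permutation"``
    replaces the p-value by a label-permutation null of the F statistic.
    """
    scores = np.asarray(scores, float)
    glabels = np.asarray(groups)
    levels = np.unique(glabels)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [scores[glabels == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least 2 observations per group")
    grand = scores.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_total = float(((scores - grand) ** 2).sum())
    df1 = len(levels) - 1
    df2 = len(scores) - len(levels)
    ss_within = ss_total - ss_between
    if ss_within <= 0:
        F, p = (0.0, 1.0) if ss_between <= 1e-300 else (np.inf, 0.0)
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(F, df1, df2))
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(glabels)
            psamples = [scores[perm == g] for g in levels]
            ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in psamples)
            ssw = ss_total - ssb
            Fp = (ssb / df1) / (ssw / df2) if ssw > 0 else np.inf
            count += Fp >= F
        p = (count + 1) / (n_perm + 1)
    elif method != "anova":
        raise ValueError(f"unknown method {method!r}")
    return {"F": float(F), "df1": df1, "df2": df2, "p": float(p), "eta2": float(eta2)}
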