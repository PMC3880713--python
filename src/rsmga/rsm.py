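"""Second-order response-surface fitting and inference.

Fits the full quadratic polynomial in coded units

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j + e

by ordinary least squares and provides the standard design-of-experiments
inference outputs: coefficient table (SE, t, two-sided p), R^2 and adjusted
R^2, sequential (type-I) ANOVA with the residual split into lack-of-fit and
pure error from replicated runs, externally studentized residuals, and
prediction grids for surface plots.

Model-matrix column order (for k factors): intercept, the k linear terms,
the k pure quadratic terms, then the k(k-1)/2 pairwise interactions in
lexicographic order (1,2), (1,3), ..., (k-1,k).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .doe import DesignTable, FactorSpace, ReplicateGrouping, find_replicate_groups

__all__ = [
    "QuadraticSurface",
    "FitResult",
    "AnovaReport",
    "build_quadratic_matrix",
    "term_names",
    "fit_quadratic",
    "anova_sequential",
    "studentized_residuals",
    "surface_grid",
    "published_surface",
]


def _n_terms(k: int) -> int:
    return 1 + 2 * k + k * (k - 1) // 2


def term_names(names: Sequence[str]) -> list[str]:
    """Model-matrix column labels in the canonical order."""
    k = len(names)
    out = ["Intercept"] + list(names) + [f"{n}^2" for n in names]
    out += [f"{names[i]}*{names[j]}" for i, j in itertools.combinations(range(k), 2)]
    return out


@dataclass(frozen=True)
class QuadraticSurface:
    """Full second-order polynomial in coded units.

    ``interaction[(i, j)]`` (i < j, zero-based) holds the coefficient of
    ``x_i x_j``.  Evaluation at the coded origin returns the intercept.
    """

    intercept: float
    linear: tuple[float, ...]
    square: tuple[float, ...]
    interaction: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        k = len(self.linear)
        if len(self.square) != k:
            raise ValueError("linear and square coefficient counts differ")
        expected = set(itertools.combinations(range(k), 2))
        if set(self.interaction) != expected:
            raise ValueError(
                f"interaction keys must be exactly the {len(expected)} pairs i<j"
            )

    @property
    def k(self) -> int:
        return len(self.linear)

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients in model-matrix column order (length 1+2k+k(k-1)/2)."""
        pairs = itertools.combinations(range(self.k), 2)
        return np.array(
            [self.intercept, *self.linear, *self.square]
            + [self.interaction[p] for p in pairs]
        )

    @classmethod
    def from_coefficients(cls, beta: np.ndarray, k: int) -> "QuadraticSurface":
        beta = np.asarray(beta, dtype=float)
        if beta.size != _n_terms(k):
            raise ValueError(f"expected {_n_terms(k)} coefficients, got {beta.size}")
        pairs = list(itertools.combinations(range(k), 2))
        return cls(
            intercept=float(beta[0]),
            linear=tuple(beta[1 : 1 + k]),
            square=tuple(beta[1 + k : 1 + 2 * k]),
            interaction={p: float(b) for p, b in zip(pairs, beta[1 + 2 * k :])},
        )

    def predict(self, coded: np.ndarray) -> np.ndarray | float:
        """Evaluate the polynomial at coded point(s) of shape (k,) or (n, k)."""
        coded = np.asarray(coded, dtype=float)
        scalar = coded.ndim == 1
        pts = np.atleast_2d(coded)
        if pts.shape[1] != self.k:
            raise ValueError(f"expected {self.k} coordinates, got {pts.shape[1]}")
        M = build_quadratic_matrix(pts)
        out = M @ self.coefficients
        return float(out[0]) if scalar else out

    def predict_natural(self, space: FactorSpace, natural: np.ndarray):
        """Evaluate at natural-unit point(s), coding internally."""
        return self.predict(space.code(np.asarray(natural, dtype=float)))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "linear": list(self.linear),
            "square": list(self.square),
            "interaction": {f"{i},{j}": v for (i, j), v in self.interaction.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "QuadraticSurface":
        d = json.loads(Path(path).read_text())
        inter = {
            tuple(int(x) for x in key.split(",")): float(v)
            for key, v in d["interaction"].items()
        }
        return cls(d["intercept"], tuple(d["linear"]), tuple(d["square"]), inter)


def build_quadratic_matrix(coded: np.ndarray | DesignTable) -> np.ndarray:
    """Build the n x (1+2k+k(k-1)/2) full-quadratic model matrix."""
    if isinstance(coded, DesignTable):
        coded = coded.coded
    X = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(k)]
    cols += [X[:, i] ** 2 for i in range(k)]
    cols += [X[:, i] * X[:, j] for i, j in itertools.combinations(range(k), 2)]
    return np.column_stack(cols)


@dataclass
class FitResult:
    """OLS fit of the full quadratic with the usual inference quantities."""

    surface: QuadraticSurface
    design: DesignTable = field(repr=False)
    coef: np.ndarray = field(repr=False)
    coef_se: np.ndarray = field(repr=False)
    t_stat: np.ndarray = field(repr=False)
    p_value: np.ndarray = field(repr=False)
    r2: float
    r2_adj: float
    residuals: np.ndarray = field(repr=False)
    leverage: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    sse: float
    sst: float
    residual_df: int
    sigma2: float

    @property
    def n(self) -> int:
        return len(self.residuals)

    def coefficient_table(self) -> pd.DataFrame:
        """Term / Coef / SE Coef / T / P table in model-matrix order."""
        return pd.DataFrame(
            {
                "Term": term_names(self.design.space.names),
                "Coef": self.coef,
                "SE Coef": self.coef_se,
                "T": self.t_stat,
                "P": self.p_value,
            }
        )

    def to_json(self, path: str | Path) -> None:
        tab = self.coefficient_table()
        payload = {
            "terms": tab.to_dict(orient="records"),
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "sse": self.sse,
            "sst": self.sst,
            "residual_df": self.residual_df,
            "sigma2": self.sigma2,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def fit_quadratic(design: DesignTable, response: np.ndarray | None = None) -> FitResult:
    """Fit the full second-order model by OLS in coded units.

    Uses a QR-based least-squares solve; standard errors come from the
    diagonal of ``sigma2 * (X'X)^-1`` and p-values are two-sided t on the
    residual degrees of freedom.
    """
    X = build_quadratic_matrix(design)
    y = design.response if response is None else np.asarray(response, dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} runs to fit {p} terms, have {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns to make the error actionable
        names = term_names(design.space.names)
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(p) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {bad or 'undetermined'}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    residual_df = n - p
    sigma2 = sse / residual_df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), residual_df)
    hat = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    k = design.space.k
    return FitResult(
        surface=QuadraticSurface.from_coefficients(beta, k),
        design=design,
        coef=beta,
        coef_se=se,
        t_stat=tstat,
        p_value=pval,
        r2=1.0 - sse / sst,
        r2_adj=1.0 - (sse / residual_df) / (sst / (n - 1)),
        residuals=resid,
        leverage=hat,
        fitted=fitted,
        sse=sse,
        sst=sst,
        residual_df=residual_df,
        sigma2=sigma2,
    )


@dataclass
class AnovaReport:
    """Sequential-SS ANOVA table with lack-of-fit / pure-error split."""

    table: pd.DataFrame = field(repr=False)

    ROW_ORDER = (
        "Regression",
        "Linear",
        "Square",
        "Interaction",
        "Residual error",
        "Lack-of-fit",
        "Pure error",
        "Total",
    )

    def row(self, source: str) -> pd.Series:
        return self.table.loc[source]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            self.table.reset_index().to_json(orient="records", indent=2) + "\n"
        )

    def __str__(self) -> str:
        with pd.option_context("display.float_format", "{:0.4f}".format):
            return self.table.to_string()


def _sse_of(X: np.ndarray, y: np.ndarray, cols: slice) -> float:
    sub = X[:, cols]
    beta, _, _, _ = np.linalg.lstsq(sub, y, rcond=None)
    r = y - sub @ beta
    return float(r @ r)


def anova_sequential(
    fit: FitResult, grouping: ReplicateGrouping | None = None
) -> AnovaReport:
    """Sequential (type-I) ANOVA adding blocks Linear -> Square -> Interaction.

    Each block's sequential SS is the drop in error SS when it is added on
    top of the previous blocks; the adjusted SS is the drop when the block is
    removed from the full model.  Pure-error SS is the within-group squared
    deviation over replicate groups; lack-of-fit is the remainder of the
    residual.  Block F statistics use the full-model residual mean square;
    lack-of-fit is tested against pure error.  When there are no replicates
    the lack-of-fit rows are reported as NaN (undefined), not zero.
    """
    design = fit.design
    if grouping is None:
        grouping = find_replicate_groups(design)
    X = build_quadratic_matrix(design)
    y = design.response
    n, k = len(y), design.space.k
    sst = fit.sst
    # column blocks in the canonical order
    lin_end, sq_end = 1 + k, 1 + 2 * k
    sse_lin = _sse_of(X, y, slice(0, lin_end))
    sse_sq = _sse_of(X, y, slice(0, sq_end))
    sse_full = fit.sse
    seq = {
        "Linear": sst - sse_lin,
        "Square": sse_lin - sse_sq,
        "Interaction": sse_sq - sse_full,
    }
    # adjusted SS: drop each block from the full model
    cols = np.arange(X.shape[1])
    blocks = {
        "Linear": (cols >= 1) & (cols < lin_end),
        "Square": (cols >= lin_end) & (cols < sq_end),
        "Interaction": cols >= sq_end,
    }
    adj = {}
    for name, mask in blocks.items():
        keep = X[:, ~mask]
        beta, _, _, _ = np.linalg.lstsq(keep, y, rcond=None)
        r = y - keep @ beta
        adj[name] = float(r @ r) - sse_full

    df_blocks = {"Linear": k, "Square": k, "Interaction": k * (k - 1) // 2}
    df_reg = sum(df_blocks.values())
    df_res = fit.residual_df
    ms_res = fit.sigma2

    # pure error from replicate groups
    run_pos = {int(r): i for i, r in enumerate(design.data.index)}
    ss_pe = 0.0
    for group in grouping.replicated:
        vals = y[[run_pos[r] for r in group]]
        ss_pe += float(((vals - vals.mean()) ** 2).sum())
    df_pe = grouping.pure_error_df
    df_lof = df_res - df_pe
    ss_lof = sse_full - ss_pe

    ss_reg = sst - sse_full
    rows = {}

    def add(source, df, seq_ss, adj_ss, f=np.nan, p=np.nan):
        ms = seq_ss / df if df > 0 else np.nan
        rows[source] = {
            "DF": df, "Seq SS": seq_ss, "Adj SS": adj_ss, "MS": ms, "F": f, "P": p,
        }

    f_reg = (ss_reg / df_reg) / ms_res
    add("Regression", df_reg, ss_reg, ss_reg, f_reg,
        stats.f.sf(f_reg, df_reg, df_res))
    for name in ("Linear", "Square", "Interaction"):
        f_b = (seq[name] / df_blocks[name]) / ms_res
        add(name, df_blocks[name], seq[name], adj[name], f_b,
            stats.f.sf(f_b, df_blocks[name], df_res))
    add("Residual error", df_res, sse_full, sse_full)
    if df_pe > 0 and df_lof > 0:
        f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
        add("Lack-of-fit", df_lof, ss_lof, ss_lof, f_lof,
            stats.f.sf(f_lof, df_lof, df_pe))
        add("Pure error", df_pe, ss_pe, ss_pe)
    else:
        add("Lack-of-fit", df_lof, np.nan, np.nan)
        add("Pure error", df_pe, ss_pe if df_pe else np.nan, np.nan)
    add("Total", n - 1, sst, sst)

    table = pd.DataFrame.from_dict(rows, orient="index").reindex(
        list(AnovaReport.ROW_ORDER)
    )
    table.index.name = "Source"
    return AnovaReport(table)


def studentized_residuals(fit: FitResult) -> np.ndarray:
    """Externally (R-) studentized residuals.

    Each residual is scaled by the leave-one-out error estimate:
    ``e_i / sqrt(s2_(-i) * (1 - h_i))`` with
    ``s2_(-i) = (SSE - e_i^2/(1-h_i)) / (df - 1)``.  Runs with leverage
    numerically equal to 1 get NaN (the statistic is undefined there).
    """
    if fit.residual_df <= 1:
        raise ValueError("externally studentized residuals need residual df > 1")
    e, h = fit.residuals, fit.leverage
    out = np.full_like(e, np.nan)
    ok = 1.0 - h > 1e-12
    s2_loo = (fit.sse - e[ok] ** 2 / (1.0 - h[ok])) / (fit.residual_df - 1)
    s2_loo = np.maximum(s2_loo, 0.0)  # guard rounding on near-perfect fits
    with np.errstate(invalid="ignore", divide="ignore"):
        out[ok] = e[ok] / np.sqrt(s2_loo * (1.0 - h[ok]))
    return out


def surface_grid(
    surface: QuadraticSurface,
    pair: tuple[int, int],
    resolution: int = 21,
    fixed: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate predictions over a coded [-1,1]^2 grid for one factor pair.

    Remaining factors are held at ``fixed`` (default: the coded centre).
    Returns a tidy (x, y, z) frame of ``resolution**2`` rows, ready for CSV
    export and external contour/surface plotting.
    """
    i, j = pair
    if i == j:
        raise ValueError("pair must name two distinct factors")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    base = np.zeros(surface.k) if fixed is None else np.asarray(fixed, dtype=float)
    if base.size != surface.k:
        raise ValueError(f"fixed vector must have length {surface.k}")
    axis = np.linspace(-1.0, 1.0, resolution)
    xx, yy = np.meshgrid(axis, axis)
    pts = np.tile(base, (resolution * resolution, 1))
    pts[:, i] = xx.ravel()
    pts[:, j] = yy.ravel()
    return pd.DataFrame({"x": pts[:, i], "y": pts[:, j], "z": surface.predict(pts)})


def published_surface() -> QuadraticSurface:
    """The published second-order lipase-activity model (coded units, U/mL).

    These are the printed coefficients of the study's regression equation;
    they are kept verbatim as a reference surface for the optimization stage.
    Note that refitting the shipped design table does *not* reproduce them —
    see the package methods note on fixture inconsistencies.
    """
    return QuadraticSurface(
        intercept=3.52179,
        linear=(-0.01167, 0.11833, -0.10222, 0.51389, 0.01222),
        square=(-0.07564, 1.57436, -0.70064, 0.48436, -0.56064),
        interaction={
            (0, 1): -0.18187,
            (0, 2): -0.28062,
            (0, 3): 0.04188,
            (0, 4): 0.04188,
            (1, 2): 0.32312,
            (1, 3): 0.08312,
            (1, 4): 0.10313,
            (2, 3): -0.01062,
            (2, 4): -0.03562,
            (3, 4): -0.15813,
        },
    )
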