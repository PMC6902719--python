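"""Missing-value handling and variance-stabilizing normalization.

Targeted mediator panels are left-censored: concentrations below a species'
analytical limit of detection (LOD) are reported as not detected.  For each
pairwise comparison the pipeline applies two heuristics before testing:

1. species missing in *more than half* of the comparison's samples are
   removed (:func:`filter_missing`);
2. remaining missing cells are substituted with the species' LOD
   (:func:`substitute_lod`).

The complete matrix is then variance-stabilized with a generalized-log
(arsinh) transform calibrated per sample,

    h_s(x) = arsinh(a_s + b_s * x) / ln 2,

fitted by iterative robust (least-trimmed-squares) profile maximum
likelihood under the model h_s(x_si) = mu_i + eps, eps ~ N(0, sigma^2).
Under additive-plus-multiplicative measurement error this transform is
approximately linear near zero and log2-like at high intensity, so the
transformed replicate spread is flat across the intensity range.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)

#: Columns a sample-design table must carry.
DESIGN_COLUMNS = ("subject", "arm", "phase", "tissue", "uvr_time")


@dataclass
class ConcentrationMatrix:
    """Samples x species concentrations tied to a sample design.

    ``values`` holds positive concentrations with ``NaN`` marking cells
    below the LOD (not detected); zeros in input files are coerced to
    missing on load.  ``design`` is indexed like ``values`` and carries the
    subject/arm/phase/tissue/uvr_time metadata used to form paired
    comparisons.  ``lod`` is the per-species detection limit in ``unit``.
    """

    design: pd.DataFrame
    values: pd.DataFrame
    lod: pd.Series
    unit: str

    def __post_init__(self) -> None:
        if not self.design.index.equals(self.values.index):
            raise ValueError("design and values must share the same sample index")
        missing_cols = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing_cols:
            raise ValueError(f"design lacks columns {missing_cols}")
        unknown = [c for c in self.values.columns if c not in self.lod.index]
        if unknown:
            raise ValueError(f"species without an LOD entry: {unknown}")
        self.lod = self.lod.loc[self.values.columns].astype(float)
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() <= 0).any():
                raise ValueError("present concentrations must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    def is_complete(self) -> bool:
        return not self.values.isna().to_numpy().any()

    def restrict(self, mask: pd.Series | np.ndarray | Sequence[bool]) -> "ConcentrationMatrix":
        """Row subset preserving design/values alignment."""
        mask = np.asarray(mask, dtype=bool)
        return replace(self, design=self.design.loc[mask], values=self.values.loc[mask])

    def select_species(self, names: Sequence[str]) -> "ConcentrationMatrix":
        return replace(self, values=self.values.loc[:, list(names)], lod=self.lod.loc[list(names)])

    def write_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)


def read_concentrations(
    path: str | Path,
    design: pd.DataFrame,
    lod: pd.Series,
    unit: str,
) -> ConcentrationMatrix:
    """Read a samples x species CSV; blanks and zeros become missing."""
    values = pd.read_csv(path, index_col=0)
    values = values.where(values > 0)
    return ConcentrationMatrix(design=design.loc[values.index], values=values, lod=lod, unit=unit)


# ---------------------------------------------------------------------------
# Missing-value heuristics
# ---------------------------------------------------------------------------


def filter_missing(
    matrix: ConcentrationMatrix, comparison=None
) -> tuple[ConcentrationMatrix, list[str]]:
    """Drop species missing in more than half of the comparison's samples.

    ``comparison`` (anything with a ``select(design)`` method, e.g.
    :class:`lipidiga.difftest.PairwiseComparison`) restricts the matrix to
    the relevant samples first; pass ``None`` when the matrix is already
    restricted.  The boundary is strict: a species missing in exactly half
    of the samples is retained.

    Returns the filtered matrix and the removal log (dropped species names).
    """
    if comparison is not None:
        mask = comparison.select(matrix.design)
        matrix = matrix.restrict(mask)
    if matrix.n_samples == 0:
        raise ValueError("comparison selects zero samples")
    n = matrix.n_samples
    n_missing = matrix.values.isna().sum(axis=0)
    dropped = list(matrix.values.columns[n_missing > n / 2])
    if dropped:
        logger.info("filter_missing removed %d species: %s", len(dropped), dropped)
    kept = [c for c in matrix.values.columns if c not in set(dropped)]
    return matrix.select_species(kept), dropped


def substitute_lod(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Replace every remaining missing cell with that species' LOD.

    Must run after :func:`filter_missing`; observed values are never
    altered.  A species with missing cells but a non-positive LOD is an
    error, since the substitute would violate positivity.
    """
    has_missing = matrix.values.isna().any(axis=0)
    bad = matrix.lod[has_missing & ~(matrix.lod > 0)].index.tolist()
    if bad:
        raise ValueError(f"species with missing cells but no positive LOD: {bad}")
    filled = matrix.values.fillna(matrix.lod)
    out = replace(matrix, values=filled)
    assert out.is_complete()
    return out


# ---------------------------------------------------------------------------
# glog / VSN
# ---------------------------------------------------------------------------


@dataclass
class VSNFit:
    """Per-sample calibration of the arsinh (glog2) transform.

    ``offsets`` (a_s) and ``scales`` (b_s > 0) parameterize
    h_s(x) = arsinh(a_s + b_s x)/ln2.  ``species_means`` are the fitted
    per-species transformed means, ``sigma`` the residual spread on the
    trimmed set.  ``method`` is ``"glog-ml"`` for the maximum-likelihood
    fit or ``"log-fallback"`` when the caller replaced a non-converged fit
    with the deterministic log2(x + LOD/2) transform.
    """

    sample_index: pd.Index
    species_index: pd.Index
    offsets: np.ndarray
    scales: np.ndarray
    species_means: np.ndarray
    sigma: float
    converged: bool
    n_iter: int
    trim_fraction: float
    method: str = "glog-ml"
    fallback_lod: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method == "glog-ml" and not (np.asarray(self.scales) > 0).all():
            raise ValueError("scales must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "samples": list(map(str, self.sample_index)),
            "species": list(map(str, self.species_index)),
            "offsets": np.asarray(self.offsets).tolist(),
            "scales": np.asarray(self.scales).tolist(),
            "species_means": np.asarray(self.species_means).tolist(),
            "sigma": float(self.sigma),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "trim_fraction": float(self.trim_fraction),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _nll_and_grad(params: np.ndarray, x: np.ndarray, kept: np.ndarray):
    """Profile negative log-likelihood and gradient for the glog model.

    x: (n_samples, m) positive matrix; kept: boolean species mask (LTS).
    params: [a_1..a_n, beta_1..beta_n] with b = exp(beta).
    """
    n, m = x.shape
    a = params[:n, None]
    beta = params[n:, None]
    b = np.exp(beta)
    z = a + b * x
    s = np.sqrt(1.0 + z * z)
    y = np.arcsinh(z) / _LN2
    yk = y[:, kept]
    mu = yk.mean(axis=0)
    r = yk - mu
    # floor keeps the profile likelihood finite for degenerate (replicated)
    # data where the residual sum of squares would be exactly zero
    rss = max(float((r * r).sum()), 1e-12 * yk.size)
    mk = int(kept.sum())
    # transform derivative h'(x) = b / (s * ln2); Jacobian over kept cells
    log_jac = (beta.ravel() * mk).sum() - 0.5 * np.log1p(z[:, kept] ** 2).sum() - mk * n * np.log(_LN2)
    nll = 0.5 * n * mk * np.log(rss) - log_jac

    inv_s = 1.0 / s[:, kept]
    zk = z[:, kept]
    xk = x[:, kept]
    # dY/da = 1/(s ln2); dY/dbeta = b x /(s ln2)
    dy_da = inv_s / _LN2
    dy_dbeta = (b * xk) * inv_s / _LN2
    c = n * mk / rss
    # (z/s) and (b x/s) are each bounded, so this association cannot overflow
    grad_a = c * (r * dy_da).sum(axis=1) + (zk * inv_s * inv_s).sum(axis=1)
    grad_beta = c * (r * dy_dbeta).sum(axis=1) - (
        mk - ((zk * inv_s) * (b * xk * inv_s)).sum(axis=1)
    )
    return nll, np.concatenate([grad_a, grad_beta])


def _initial_params(x: np.ndarray) -> np.ndarray:
    """Moment-based start: b ~ multiplicative CV / additive noise scale."""
    n, m = x.shape
    col_mean = x.mean(axis=0)
    order = np.argsort(col_mean)
    lo = order[: max(2, m // 3)]
    hi = order[-max(2, m // 3):]
    sd_lo = float(np.median(x[:, lo].std(axis=0, ddof=1))) if n > 1 else 1.0
    with np.errstate(divide="ignore"):
        sd_hi_log = float(np.median(np.log(x[:, hi]).std(axis=0, ddof=1))) if n > 1 else 0.3
    sd_lo = max(sd_lo, 1e-8)
    sd_hi_log = min(max(sd_hi_log, 1e-3), 2.0)
    b0 = sd_hi_log / sd_lo
    return np.concatenate([np.zeros(n), np.full(n, np.log(b0))])


def fit_glog_normalization(
    matrix: ConcentrationMatrix,
    trim_fraction: float = 0.9,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> VSNFit:
    """Fit the per-sample arsinh calibration by robust profile ML.

    The least-trimmed step alternates between (i) optimizing (a_s, b_s) on
    the currently kept species and (ii) keeping the ``trim_fraction`` of
    species with the smallest residual sum of squares, until the parameter
    change drops below ``tol`` or ``max_iter`` total iterations elapse.
    Requires a complete matrix with at least 2 samples and 2 species.
    """
    if not matrix.is_complete():
        raise ValueError("matrix must be complete; run substitute_lod first")
    x = matrix.values.to_numpy(dtype=float)
    n, m = x.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 samples and 2 species")
    params = _initial_params(x)
    kept = np.ones(m, dtype=bool)
    m_keep = max(2, int(np.ceil(trim_fraction * m)))
    total_iter = 0
    converged = False
    prev_nll = np.inf
    for _ in range(max_iter):
        # wide box bounds only guard against overflow in the line search
        bounds = [(-1e12, 1e12)] * n + [(-60.0, 60.0)] * n
        res = optimize.minimize(
            _nll_and_grad,
            params,
            args=(x, kept),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        total_iter += 1
        delta = float(np.max(np.abs(res.x - params)))
        # restarts of the inner optimizer jitter parameters at the ftol
        # floor along near-flat directions; a stalled objective counts as
        # converged even when the raw parameter change does not reach tol
        nll_delta = abs(prev_nll - res.fun) / max(abs(res.fun), 1.0)
        prev_nll = res.fun
        params = res.x
        # LTS step: rank species by residual SS under current params
        a = params[:n, None]
        b = np.exp(params[n:, None])
        y = np.arcsinh(a + b * x) / _LN2
        r = y - y.mean(axis=0)
        ss = (r * r).sum(axis=0)
        new_kept = np.zeros(m, dtype=bool)
        new_kept[np.argsort(ss)[:m_keep]] = True
        if (delta < tol or nll_delta < 1e-10) and (new_kept == kept).all():
            converged = True
            kept = new_kept
            break
        kept = new_kept
        if total_iter >= max_iter:
            break
    a = params[:n]
    b = np.exp(params[n:])
    y = np.arcsinh(a[:, None] + b[:, None] * x) / _LN2
    mu = y.mean(axis=0)
    resid = (y - mu)[:, kept]
    dof = max(resid.size - n * 2 - kept.sum(), 1)
    sigma = float(np.sqrt((resid**2).sum() / dof))
    if not converged:
        logger.warning("glog normalization did not converge after %d iterations", total_iter)
    return VSNFit(
        sample_index=matrix.values.index,
        species_index=matrix.values.columns,
        offsets=a,
        scales=b,
        species_means=mu,
        sigma=sigma,
        converged=converged,
        n_iter=total_iter,
        trim_fraction=trim_fraction,
    )


def log_fallback_fit(matrix: ConcentrationMatrix) -> VSNFit:
    """Deterministic fallback transform log2(x + LOD/2), per species.

    Used when the ML calibration fails to converge; monotone, log2-like at
    high intensity, and recorded as such in the fit metadata.
    """
    y = np.log2(matrix.values.to_numpy(dtype=float) + matrix.lod.to_numpy() / 2.0)
    return VSNFit(
        sample_index=matrix.values.index,
        species_index=matrix.values.columns,
        offsets=np.zeros(matrix.n_samples),
        scales=np.ones(matrix.n_samples),
        species_means=y.mean(axis=0),
        sigma=float(y.std()),
        converged=True,
        n_iter=0,
        trim_fraction=1.0,
        method="log-fallback",
        fallback_lod=matrix.lod.copy(),
    )


def apply_transform(matrix: ConcentrationMatrix, fit: VSNFit) -> pd.DataFrame:
    """Transform concentrations onto the calibrated glog2 scale."""
    if not matrix.values.index.equals(fit.sample_index):
        raise ValueError("sample index mismatch between matrix and fit")
    if not matrix.values.columns.equals(fit.species_index):
        raise ValueError("species mismatch between matrix and fit")
    x = matrix.values.to_numpy(dtype=float)
    if fit.method == "log-fallback":
        y = np.log2(x + fit.fallback_lod.to_numpy() / 2.0)
    else:
        y = np.arcsinh(fit.offsets[:, None] + fit.scales[:, None] * x) / _LN2
    return pd.DataFrame(y, index=matrix.values.index, columns=matrix.values.columns)


def inverse_transform(transformed: pd.DataFrame, fit: VSNFit) -> pd.DataFrame:
    """Map glog2-scale values back to concentrations (exact inverse)."""
    y = transformed.to_numpy(dtype=float)
    if fit.method == "log-fallback":
        x = 2.0**y - fit.fallback_lod.to_numpy() / 2.0
    else:
        x = (np.sinh(y * _LN2) - fit.offsets[:, None]) / fit.scales[:, None]
    return pd.DataFrame(x, index=transformed.index, columns=transformed.columns)
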