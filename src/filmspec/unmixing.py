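"""Spectral unmixing: augmented MCR-ALS reference refinement + non-negative LASSO.

Measured organelle spectra rarely match pure-standard references exactly
(matrix effects, peak shifts, unmodelled constituents). The decomposition
therefore runs in two stages:

1. *Augmented MCR-ALS*: the M x N matrix of calibrated organelle spectra is
   augmented with (replicated) reference rows and factorized as D' ~ C S
   under non-negativity on both factors, initialized at S = S0. The
   appended reference rows anchor the refined components so they stay
   interpretable, while the data rows pull them toward the in-situ spectra.
   Each alternating step is an exact non-negative least-squares solve, so
   the Frobenius residual is non-increasing by construction.
2. *Non-negative LASSO*: each spectrum y is decomposed against the refined
   references by minimizing 1/2 ||y - S^T c||^2 + lambda ||c||_1 with
   c >= 0, via cyclic coordinate descent with soft thresholding. The L1
   penalty yields sparse abundance vectors; "auto" selects lambda by
   generalized cross-validation on a 20-point log grid spanning
   [1e-4, 1] x lambda_max.

All fits run on unmasked bins only; abundances are reported both raw and as
fractions of their sum (references are AUC-normalized, so fractions are
relative contributions to spectral area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .datatypes import ReferenceLibrary, Spectrum, SpectrumTable

__all__ = [
    "ReferenceMatrix",
    "McrConfig",
    "McrResult",
    "ConcentrationTable",
    "augmented_mcr",
    "lasso_unmix",
    "lasso_lambda_max",
    "mcr_lasso",
    "fit_metrics",
]


def _trapezoid_area(rows: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    return np.trapezoid(rows, wavenumbers, axis=-1)


@dataclass
class ReferenceMatrix:
    """K x N non-negative reference spectra on a shared wavenumber grid."""

    names: list[str]
    S: np.ndarray
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.S.shape != (len(self.names), self.wavenumbers.size):
            raise ValueError("S shape does not match names/wavenumbers")
        if np.any(self.S < 0):
            raise ValueError("reference spectra must be non-negative")
        if np.any(~self.S.any(axis=1)):
            raise ValueError("reference matrix has an all-zero row")

    @property
    def n_components(self) -> int:
        return len(self.names)

    def normalized_auc(self) -> "ReferenceMatrix":
        areas = _trapezoid_area(self.S, self.wavenumbers)
        if np.any(areas <= 0):
            raise ValueError("cannot AUC-normalize a zero-area reference")
        return ReferenceMatrix(list(self.names), self.S / areas[:, None], self.wavenumbers)

    @classmethod
    def from_library(
        cls,
        library: ReferenceLibrary,
        bin_mask: np.ndarray | None = None,
        normalize: bool = True,
    ) -> "ReferenceMatrix":
        """Build from a :class:`ReferenceLibrary`, optionally dropping
        excluded bins (bin_mask True = excluded) and AUC-normalizing rows."""
        keep = (
            np.ones(library.axis.n_frames, dtype=bool)
            if bin_mask is None
            else ~np.asarray(bin_mask, dtype=bool)
        )
        ref = cls(
            names=list(library.names),
            S=library.spectra[:, keep],
            wavenumbers=library.axis.values[keep],
        )
        return ref.normalized_auc() if normalize else ref


@dataclass(frozen=True)
class McrConfig:
    """Augmented MCR-ALS settings.

    ``augmentation_weight`` is the replication count of the reference rows
    appended to the data matrix; ``anchor`` adds an optional ridge penalty
    pulling the refined spectra toward their initial estimates (off by
    default, exposed because ALS can over-adjust references on small noisy
    datasets). ``residual_flag`` marks fits whose final relative residual
    stays above this fraction (model misspecification indicator).
    """

    max_iter: int = 50
    tol: float = 1e-6
    augmentation_weight: int = 1
    anchor: float = 0.0
    residual_flag: float = 0.05

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.augmentation_weight < 0:
            raise ValueError("augmentation_weight must be >= 0")
        if self.anchor < 0:
            raise ValueError("anchor must be >= 0")


@dataclass
class McrResult:
    refined: ReferenceMatrix
    residuals: list[float]
    converged: bool
    relative_residual: float
    flagged: bool


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x - b||, x >= 0 for every column b of B; returns
    (A.shape[1], B.shape[1])."""
    out = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        out[:, j], _ = nnls(A, B[:, j])
    return out


def augmented_mcr(
    D: np.ndarray, S0: ReferenceMatrix, config: McrConfig | None = None
) -> McrResult:
    """Refine reference spectra by alternating non-negative least squares on
    the reference-augmented data matrix D' = [D; w copies of S0]."""
    config = config or McrConfig()
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if D.shape[1] != S0.wavenumbers.size:
        raise ValueError("data matrix width does not match the reference grid")
    k = S0.n_components
    augmented = np.vstack([D] + [S0.S] * config.augmentation_weight)
    S = S0.S.copy()
    residuals: list[float] = []
    converged = False
    sqrt_anchor = np.sqrt(config.anchor)
    for _ in range(config.max_iter):
        # C-step: rows of D' against fixed S
        C = _nnls_rows(S.T, augmented.T).T  # (M', K)
        # S-step: columns of D' against fixed C, optional anchor to S0
        if config.anchor > 0:
            A = np.vstack([C, sqrt_anchor * np.eye(k)])
            B = np.vstack([augmented, sqrt_anchor * S0.S])
            S = _nnls_rows(A, B)
        else:
            S = _nnls_rows(C, augmented)
        residual = float(np.linalg.norm(augmented - C @ S))
        residuals.append(residual)
        dead = ~S.any(axis=1)
        if dead.any():
            # exact ALS keeps the recorded residual monotone; the reset (rare,
            # only without augmentation rows) perturbs the next iterate
            warnings.warn(
                "rank-deficient MCR step: resetting unused component(s) "
                f"{[S0.names[i] for i in np.flatnonzero(dead)]} to their initial spectra",
                stacklevel=2,
            )
            S[dead] = S0.S[dead]
        if len(residuals) >= 2:
            prev = residuals[-2]
            if prev > 0 and (prev - residual) / prev < config.tol:
                converged = True
                break
    relative = residuals[-1] / float(np.linalg.norm(augmented))
    refined = ReferenceMatrix(list(S0.names), S, S0.wavenumbers).normalized_auc()
    flagged = (not converged) or relative > config.residual_flag
    if not converged:
        warnings.warn("augmented MCR did not reach tol within max_iter", stacklevel=2)
    return McrResult(
        refined=refined,
        residuals=residuals,
        converged=converged,
        relative_residual=relative,
        flagged=flagged,
    )


def lasso_lambda_max(y: np.ndarray, S: np.ndarray) -> float:
    """Smallest penalty at which the non-negative LASSO solution is all-zero."""
    return float(np.max(S @ y))


def _cd_lasso(
    y: np.ndarray, S: np.ndarray, lam: float, tol: float = 1e-8, max_iter: int = 10000
) -> np.ndarray:
    gram = S @ S.T
    b = S @ y
    k = S.shape[0]
    c = np.zeros(k)
    diag = np.diag(gram).copy()
    diag[diag == 0] = 1.0
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(k):
            residual_j = b[j] - gram[j] @ c + gram[j, j] * c[j]
            new = max(0.0, (residual_j - lam) / diag[j])
            delta = abs(new - c[j])
            if delta > max_delta:
                max_delta = delta
            c[j] = new
        if max_delta < tol:
            break
    return c


def lasso_unmix(
    y: Spectrum | np.ndarray,
    S: ReferenceMatrix | np.ndarray,
    lam: float | Literal["auto"] = "auto",
    full_output: bool = False,
):
    """Non-negative LASSO decomposition of one spectrum.

    Minimizes 1/2 ||y - S^T c||^2 + lam ||c||_1 subject to c >= 0 by cyclic
    coordinate descent with soft thresholding. ``lam="auto"`` picks the
    penalty by generalized cross-validation over a log grid.
    """
    if isinstance(y, Spectrum):
        mask = y.mask
        y_vec = y.intensities[~mask]
        if isinstance(S, ReferenceMatrix) and S.wavenumbers.size != y_vec.size:
            raise ValueError("reference grid does not match the spectrum's unmasked bins")
    else:
        y_vec = np.asarray(y, dtype=float)
    S_mat = S.S if isinstance(S, ReferenceMatrix) else np.atleast_2d(np.asarray(S, dtype=float))
    if y_vec.size == 0:
        raise ValueError("all bins of the input spectrum are masked")
    if y_vec.size < S_mat.shape[0]:
        raise ValueError("need at least K unmasked bins for a K-component fit")
    if S_mat.shape[1] != y_vec.size:
        raise ValueError("reference matrix width does not match the spectrum")

    if lam == "auto":
        lam_max = lasso_lambda_max(y_vec, S_mat)
        if lam_max <= 0:
            c = np.zeros(S_mat.shape[0])
            return (c, 0.0) if full_output else c
        n = y_vec.size
        best = (np.inf, 0.0, None)
        for factor in np.logspace(-4, 0, 20):
            candidate = factor * lam_max
            c = _cd_lasso(y_vec, S_mat, candidate)
            rss = float(np.sum((y_vec - S_mat.T @ c) ** 2))
            df = int(np.count_nonzero(c))
            if df >= n:
                continue
            gcv = rss / (n * (1.0 - df / n) ** 2)
            if gcv < best[0]:
                best = (gcv, candidate, c)
        _, lam_used, c = best
        if c is None:
            c = np.zeros(S_mat.shape[0])
        return (c, float(lam_used)) if full_output else c

    lam = float(lam)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    c = _cd_lasso(y_vec, S_mat, lam)
    return (c, lam) if full_output else c


def fit_metrics(
    y: Spectrum | np.ndarray, y_hat: Spectrum | np.ndarray
) -> tuple[float, float]:
    """Cosine similarity and Euclidean distance over unmasked bins."""
    if isinstance(y, Spectrum):
        keep = y.unmasked
        a = y.intensities[keep]
        b = y_hat.intensities[keep] if isinstance(y_hat, Spectrum) else np.asarray(y_hat)[keep]
    else:
        a = np.asarray(y, dtype=float)
        b = y_hat.intensities if isinstance(y_hat, Spectrum) else np.asarray(y_hat, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("spectra must share one axis with >= 1 unmasked bin")
    euclid = float(np.linalg.norm(a - b))
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-norm spectrum: cosine similarity undefined", stacklevel=2)
        return float("nan"), euclid
    return float(a @ b / (na * nb)), euclid


@dataclass
class ConcentrationTable:
    """Per-organelle non-negative component abundances with fit metrics."""

    ids: list[str]
    component_names: list[str]
    abundances: np.ndarray  # (M, K), raw LASSO coefficients
    fractions: np.ndarray  # (M, K), rows normalized to sum 1 (or 0 if empty)
    cosine_sim: np.ndarray  # (M,)
    euclid_dist: np.ndarray  # (M,)
    lambda_used: np.ndarray  # (M,)
    wavenumbers: np.ndarray  # unmasked grid used for the fits
    reconstructions: np.ndarray  # (M, n_unmasked)
    references: ReferenceMatrix
    mcr: McrResult | None = None
    group_label: list[str | None] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.fractions, columns=self.component_names)
        frame.insert(0, "organelle_id", self.ids)
        frame["cosine_sim"] = self.cosine_sim
        frame["euclid_dist"] = self.euclid_dist
        frame["lambda"] = self.lambda_used
        if self.group_label:
            frame["group_label"] = self.group_label
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def mcr_lasso(
    table: SpectrumTable,
    references: ReferenceLibrary | ReferenceMatrix,
    mcr_config: McrConfig | None = None,
    lam: float | Literal["auto"] = "auto",
    refine: bool = True,
) -> ConcentrationTable:
    """Refine references on the table's spectra (augmented MCR), then unmix
    every row with the non-negative LASSO.

    ``refine=False`` skips the MCR stage (plain LASSO against the initial
    references), which is the baseline the refined fit is compared to.
    """
    if len(table) == 0:
        raise ValueError("empty spectrum table")
    keep = ~table.mask
    D = table.intensities[:, keep]
    if isinstance(references, ReferenceLibrary):
        S0 = ReferenceMatrix.from_library(references, bin_mask=table.mask)
    else:
        S0 = references.normalized_auc()
    if S0.wavenumbers.size != int(keep.sum()):
        raise ValueError("reference grid does not match the table's unmasked bins")

    mcr_result = None
    refs = S0
    if refine:
        mcr_result = augmented_mcr(D, S0, mcr_config)
        refs = mcr_result.refined

    m, k = D.shape[0], refs.n_components
    abundances = np.zeros((m, k))
    lambdas = np.zeros(m)
    recon = np.zeros_like(D)
    cosine = np.zeros(m)
    euclid = np.zeros(m)
    for i in range(m):
        c, lam_used = lasso_unmix(D[i], refs, lam, full_output=True)
        abundances[i] = c
        lambdas[i] = lam_used
        recon[i] = refs.S.T @ c
        cosine[i], euclid[i] = fit_metrics(D[i], recon[i])
    sums = abundances.sum(axis=1)
    fractions = np.divide(
        abundances, sums[:, None], out=np.zeros_like(abundances), where=sums[:, None] > 0
    )
    return ConcentrationTable(
        ids=list(table.ids),
        component_names=list(refs.names),
        abundances=abundances,
        fractions=fractions,
        cosine_sim=cosine,
        euclid_dist=euclid,
        lambda_used=lambdas,
        wavenumbers=refs.wavenumbers.copy(),
        reconstructions=recon,
        references=refs,
        mcr=mcr_result,
        group_label=list(table.group_label),
    )
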