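"""Pathway activity levels (PAL) by singular value decomposition.

A pathway's row-normalized gene x sample submatrix X (k genes, t samples) is
decomposed as X = U S V'.  The first right singular vector V'(1,:) is the
pathway activity level — the single sample-space profile that captures the
dominant coordinated expression pattern — and the first left singular vector
U(:,1) holds the per-gene weights (signed contributions).  The variance
fraction

    f_P = sigma_1^2 / sum_g sigma_g^2

measures how much of the pathway's total (normalized) variance that single
component explains; its statistical calibration lives in
:mod:`circapal.significance`.

Singular vectors are sign-ambiguous; :func:`compute_pal` canonicalizes so the
gene with the largest |weight| has a positive weight, and :func:`fix_sign`
re-aligns against a reference profile when needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .data_io import PathwayExpressionMatrix, TimeDesign

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """A gene row is constant and cannot be z-scored."""


@dataclass
class PALResult:
    """First singular component of a row-normalized pathway submatrix."""

    pathway_name: str
    activity: np.ndarray          # length t, unit norm
    weights: np.ndarray           # length k, unit norm
    singular_values: np.ndarray   # non-increasing, >= 0
    variance_fraction: float      # f_P in [0, 1]
    sign_convention: str          # "as_computed" | "flipped"
    design: TimeDesign
    gene_ids: list[str] | None = None
    #: full right singular matrix as computed (one component per row), kept
    #: read-only for diagnostics; row 0 equals `activity` up to the sign
    #: canonicalization, and higher rows are never fed into clustering
    activity_components: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise ValueError("singular values must be non-increasing")
        if not (-1e-9 <= self.variance_fraction <= 1 + 1e-9):
            raise ValueError("variance_fraction outside [0, 1]")


def normalize_rows(
    matrix: PathwayExpressionMatrix,
    *,
    policy: str = "error",
    ddof: int = 1,
) -> PathwayExpressionMatrix:
    """Z-score each gene row to mean 0, standard deviation 1.

    ``policy`` decides what happens to constant rows: ``"error"`` (default)
    raises :class:`ZeroVarianceError` naming the gene, ``"drop-constant"``
    removes them (logged).  ``ddof=1`` uses the sample standard deviation.
    """
    values = matrix.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    gene_ids = list(matrix.gene_ids)
    if constant.any():
        bad = [g for g, c in zip(gene_ids, constant) if c]
        if policy == "drop-constant":
            logger.info(
                "pathway %s: dropping %d constant gene row(s): %s",
                matrix.pathway.name, len(bad), bad,
            )
            keep = ~constant
            values, mean, sd = values[keep], mean[keep], sd[keep]
            gene_ids = [g for g, c in zip(gene_ids, constant) if not c]
        else:
            raise ZeroVarianceError(
                f"gene {bad[0]!r} has zero variance in pathway "
                f"{matrix.pathway.name!r}"
            )
    return PathwayExpressionMatrix(
        pathway=matrix.pathway,
        gene_ids=gene_ids,
        values=(values - mean) / sd,
        design=matrix.design,
    )


def compute_pal(
    matrix: PathwayExpressionMatrix,
    *,
    canonical_sign: bool = True,
) -> PALResult:
    """Decompose a (row-normalized) pathway submatrix into its PAL.

    Returns the first right singular vector as the activity profile, the
    first left singular vector as gene weights, and f_P = sigma_1^2 over the
    sum of all squared singular values.  With ``canonical_sign`` the result
    is flipped so the top-|weight| gene has a positive weight (ties broken by
    lowest row index), making the otherwise arbitrary SVD sign reproducible.
    """
    X = np.asarray(matrix.values, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(
            f"need at least 2 genes and 2 samples, got {X.shape}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total == 0:
        raise ValueError("all-zero matrix has no activity profile")
    result = PALResult(
        pathway_name=matrix.pathway.name,
        activity=Vt[0].copy(),
        weights=U[:, 0].copy(),
        singular_values=s.copy(),
        variance_fraction=float(s[0] ** 2 / total),
        sign_convention="as_computed",
        design=matrix.design,
        gene_ids=list(matrix.gene_ids),
        activity_components=Vt.copy(),
    )
    if canonical_sign:
        result = fix_sign(result, mode="top_weight_positive")
    return result


def _flipped(pal: PALResult) -> PALResult:
    flipped = "flipped" if pal.sign_convention == "as_computed" else "as_computed"
    return replace(
        pal,
        activity=-pal.activity,
        weights=-pal.weights,
        sign_convention=flipped,
    )


def fix_sign(
    pal: PALResult,
    *,
    mode: str = "top_weight_positive",
    reference: np.ndarray | None = None,
) -> PALResult:
    """Resolve the PAL's sign ambiguity (weights and activity flip together).

    ``top_weight_positive`` flips when the largest-|weight| gene is negative;
    ``reference_correlation`` flips when the activity is anticorrelated with
    ``reference``.
    """
    if mode == "top_weight_positive":
        if reference is not None:
            raise ValueError("reference is only used with reference_correlation")
        top = int(np.argmax(np.abs(pal.weights)))  # argmax: lowest index wins ties
        return _flipped(pal) if pal.weights[top] < 0 else pal
    if mode == "reference_correlation":
        if reference is None:
            raise ValueError("reference_correlation mode needs a reference")
        ref = np.asarray(reference, dtype=float)
        if ref.shape != pal.activity.shape:
            raise ValueError("reference length does not match activity")
        a = pal.activity - pal.activity.mean()
        r = ref - ref.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(r)
        corr = float(a @ r / denom) if denom > 0 else 0.0
        if abs(corr) < 1e-12:
            logger.warning(
                "pathway %s: activity uncorrelated with reference; sign kept",
                pal.pathway_name,
            )
            return pal
        return _flipped(pal) if corr < 0 else pal
    raise ValueError(f"unknown sign mode {mode!r}")


def variance_fraction(matrix_values: np.ndarray) -> float:
    """f_P of an already-normalized matrix, without keeping the vectors."""
    s = np.linalg.svd(np.asarray(matrix_values, dtype=float), compute_uv=False)
    total = float(np.sum(s ** 2))
    if total == 0:
        raise ValueError("all-zero matrix")
    return float(s[0] ** 2 / total)
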