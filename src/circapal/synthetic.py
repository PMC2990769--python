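"""Synthetic noisy-pathway generator and the two Monte-Carlo noise studies.

A hypothetical pathway of ``n_genes`` genes is simulated over the 18-point,
3-replicate (54-sample) time grid from the periodic expression model

    g(t) = beta * cos(omega * t + phi) + eps ,

with eps drawn independently per gene and sample, uniform on [0, 50 * i] for
integer noise level i (a zero-centered variant is available; every
downstream criterion is offset-invariant, so the choice is cosmetic).  At
i = 0 all genes carry the identical clean circadian signal; increasing i
buries the signal in noise.

Two event probabilities are estimated over replicate simulations:

* gene events — the probability that at least a fraction q of the genes are
  individually classified circadian (p = share of replicates falling below
  q, significance = 1 - p);
* the PAL event — the probability that the pathway activity level (the SVD
  summary across all genes) is classified circadian.

Because the PAL pools 45 genes, its circadian call survives noise levels at
which nearly all individual genes have dropped below the correlation
threshold — the motivating robustness property, quantified by
:func:`pal_significance_curve` together with the permutation significance of
f_P against a pure-noise background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import (
    ExpressionMatrix,
    PathwayExpressionMatrix,
    PathwayGeneSet,
    TimeDesign,
    rat_liver_design,
)
from .pal import compute_pal, normalize_rows
from .rhythm import (
    DEFAULT_BAND,
    DEFAULT_CORR_THRESHOLD,
    average_replicates,
    classify_circadian_genes,
    fit_sinusoid,
)

logger = logging.getLogger(__name__)

#: Signal amplitude calibrated so that, with uniform [0, 50*i] noise, the
#: per-gene circadian call crosses 50% near noise level i ~ 17 while the
#: 45-gene PAL remains circadian far beyond i = 30.
DEFAULT_BETA = 450.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the periodic-expression simulator."""

    n_genes: int = 45
    design: TimeDesign = field(default_factory=rat_liver_design)
    beta: float = DEFAULT_BETA
    omega: float = 2 * math.pi / 24       # rad/h; 24-h period
    phi: float = 0.0
    noise_level: int = 0
    noise_scale_per_level: float = 50.0
    centered_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.omega < math.pi:
            raise ValueError("omega must lie in (0, pi)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class NoiseCurvePoint:
    """One point of a significance-versus-noise curve."""

    noise_level: int
    event: str
    p_value: float
    significance: float
    n_reps: int
    samples: np.ndarray | None = None   # per-replicate statistic, for diagnostics

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if abs(self.significance - (1.0 - self.p_value)) > 1e-12:
            raise ValueError("significance must equal 1 - p_value")


def generate_pathway(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> PathwayExpressionMatrix:
    """Simulate one noisy pathway (n_genes x n_samples).

    Every gene shares the cosine signal; noise is independent per gene and
    sample.  Reproducible from ``config.seed`` when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = config.design.sample_times()
    signal = config.beta * np.cos(config.omega * t + config.phi)
    hi = config.noise_scale_per_level * config.noise_level
    if hi > 0:
        lo, up = (-hi / 2, hi / 2) if config.centered_noise else (0.0, hi)
        noise = rng.uniform(lo, up, size=(config.n_genes, t.size))
    else:
        noise = np.zeros((config.n_genes, t.size))
    gene_ids = [f"SYN{g + 1:03d}" for g in range(config.n_genes)]
    pathway = PathwayGeneSet(
        name="synthetic_circadian_pathway",
        description=f"simulated cosine pathway, noise level {config.noise_level}",
        members=frozenset(gene_ids),
    )
    return PathwayExpressionMatrix(
        pathway=pathway,
        gene_ids=gene_ids,
        values=signal[None, :] + noise,
        design=config.design,
    )


def generate_background(
    n_genes: int,
    design: TimeDesign,
    noise_level: int = 1,
    noise_scale_per_level: float = 50.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Pure-noise expression matrix (no signal), for permutation nulls.

    After row normalization f_P of a random subset is scale-invariant, so a
    single background serves every noise level.
    """
    if noise_level < 1:
        raise ValueError("background needs noise_level >= 1 (pure zeros are degenerate)")
    rng = np.random.default_rng(seed)
    hi = noise_scale_per_level * noise_level
    values = rng.uniform(0.0, hi, size=(n_genes, design.n_samples))
    return ExpressionMatrix(
        [f"BG{g + 1:05d}" for g in range(n_genes)], values, design
    )


def circadian_fraction(
    matrix: PathwayExpressionMatrix,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Fraction of the pathway's genes individually classified circadian."""
    fits = classify_circadian_genes(matrix, corr_threshold, band)
    return float(np.mean([f.is_circadian for f in fits]))


def pal_is_circadian(
    matrix: PathwayExpressionMatrix,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[bool, float]:
    """Circadian call for the pathway's activity level.

    The PAL is computed from the row-normalized matrix, averaged over
    replicates, and sinusoid-fitted.  Returns (is_circadian, f_P).
    """
    pal = compute_pal(normalize_rows(matrix, policy="drop-constant"))
    profile = average_replicates(pal.activity, matrix.design, pal.pathway_name)
    fit = fit_sinusoid(profile, corr_threshold, band)
    return fit.is_circadian, pal.variance_fraction


def _rep_rngs(seed: int, n_reps: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n_reps)]


def gene_event_pvalue(
    config: SyntheticConfig,
    q: float,
    n_reps: int = 1000,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    band: tuple[float, float] = DEFAULT_BAND,
) -> NoiseCurvePoint:
    """Monte-Carlo p-value of the event "at least q of the genes are circadian".

    p = fraction of simulated pathways whose circadian gene fraction falls
    strictly below q; significance = 1 - p.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fractions = np.empty(n_reps)
    for r, rng in enumerate(_rep_rngs(config.seed, n_reps)):
        matrix = generate_pathway(config, rng)
        fractions[r] = circadian_fraction(matrix, corr_threshold, band)
    p = float(np.count_nonzero(fractions < q)) / n_reps
    return NoiseCurvePoint(
        noise_level=config.noise_level,
        event=f"frac_circadian >= {q:g}",
        p_value=p,
        significance=1.0 - p,
        n_reps=n_reps,
        samples=fractions,
    )


def pal_event_pvalue(
    config: SyntheticConfig,
    n_reps: int = 1000,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    band: tuple[float, float] = DEFAULT_BAND,
) -> NoiseCurvePoint:
    """Monte-Carlo p-value of the event "the PAL is NOT circadian"."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    failed = np.empty(n_reps, dtype=bool)
    for r, rng in enumerate(_rep_rngs(config.seed, n_reps)):
        matrix = generate_pathway(config, rng)
        circadian, _ = pal_is_circadian(matrix, corr_threshold, band)
        failed[r] = not circadian
    p = float(np.count_nonzero(failed)) / n_reps
    return NoiseCurvePoint(
        noise_level=config.noise_level,
        event="PAL circadian",
        p_value=p,
        significance=1.0 - p,
        n_reps=n_reps,
        samples=failed.astype(float),
    )


def pal_significance_curve(
    noise_levels: list[int],
    config: SyntheticConfig = SyntheticConfig(),
    n_reps: int = 1000,
    background: ExpressionMatrix | None = None,
    n_perm: int = 1000,
) -> list[tuple[NoiseCurvePoint, NoiseCurvePoint]]:
    """PAL circadian significance and f_P permutation significance per level.

    For each noise level the pathway is simulated ``n_reps`` times; the first
    curve is the circadian-detection significance of the PAL, the second the
    significance of its median f_P against random same-size gene sets drawn
    from a pure-noise ``background`` matrix (generated on demand).
    """
    if background is None:
        background = generate_background(
            1000, config.design, seed=config.seed + 1
        )
    from .significance import null_variance_fractions

    rng = np.random.default_rng(config.seed + 2)
    null = null_variance_fractions(
        background, config.n_genes, n_perm, rng
    )
    out: list[tuple[NoiseCurvePoint, NoiseCurvePoint]] = []
    for i in noise_levels:
        cfg = replace(config, noise_level=int(i))
        fps = np.empty(n_reps)
        failed = np.empty(n_reps, dtype=bool)
        for r, rep_rng in enumerate(_rep_rngs(cfg.seed, n_reps)):
            matrix = generate_pathway(cfg, rep_rng)
            circadian, fp = pal_is_circadian(matrix)
            failed[r] = not circadian
            fps[r] = fp
        p_circ = float(np.count_nonzero(failed)) / n_reps
        f_med = float(np.median(fps))
        p_fp = float(np.count_nonzero(null >= f_med)) / n_perm
        out.append((
            NoiseCurvePoint(int(i), "PAL circadian", p_circ, 1 - p_circ,
                            n_reps, failed.astype(float)),
            NoiseCurvePoint(int(i), "f_P vs random gene sets", p_fp, 1 - p_fp,
                            n_reps, fps),
        ))
    return out
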