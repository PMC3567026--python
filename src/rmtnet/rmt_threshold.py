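"""Random-matrix-theory threshold selection (the ``rmm`` step).

The similarity matrix is pruned at successively lower correlation thresholds.
At each level the eigenvalue spectrum of the pruned matrix is *unfolded* —
rescaled through a smooth spline fit of eigenvalue against rank so the mean
nearest-neighbor spacing is 1 — and the spacing distribution (NNSD) is
compared to the unit-mean exponential expected of uncorrelated (Poisson)
levels with a chi-square statistic over 60 bins on [0, 3] (59 degrees of
freedom). While the pruned matrix contains only genuine co-expression
structure, independent blocks superpose their spectra and the NNSD stays
Poisson (low chi-square). Once the threshold descends into the noise floor
the matrix behaves like a random symmetric matrix, level repulsion of the
Gaussian orthogonal ensemble sets in, and the chi-square explodes. The scan
flags the first threshold whose chi-square reaches the significance level
(default 100, p ~ 0.001 at df 59) and confirms it by continuing down until
the statistic reaches a confirmation level (default 200) without ever
dropping back below the significance level — a drop-back marks the candidate
as a local maximum and resets it. The reported network threshold is one step
*above* the confirmed divergence point: the last level at which the spectrum
was still noise-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.linalg import eigvalsh
from scipy.stats import chi2 as chi2_dist

from .errors import (
    AsymmetricMatrix,
    InsufficientEigenvalues,
    InvalidParameter,
    ThresholdNotFound,
)
from .similarity import SimilarityMatrix

#: Fewer unique eigenvalues than this and the chi-square of a scan level is
#: recorded as undefined (fewer than two spacings per histogram bin carries
#: no distributional information).
MIN_UNIQUE_EIGENVALUES = 120

#: Absolute tolerance under which adjacent sorted eigenvalues are collapsed
#: to a single representative before unfolding.
DEDUP_TOL = 1e-6


class UnstableHistogramWarning(UserWarning):
    """Raised when a spacing histogram has fewer than 10 counts per bin."""


@dataclass
class ScanRecord:
    """One level of the threshold scan."""

    threshold: float
    n_genes_retained: int
    n_unique_eigs: int
    chi2: float | None


@dataclass
class RMTResult:
    """Outcome of a confirmed threshold scan.

    ``final_threshold`` is ``divergence_threshold + step``: the lowest level
    whose spacing distribution was still Poisson.
    """

    final_threshold: float | None
    divergence_threshold: float | None
    confirmed: bool
    trace: list[ScanRecord] = field(repr=False)
    params: tuple[float, float, float, float] = (0.92, 0.001, 100.0, 200.0)


@dataclass
class SpacingSet:
    """Nearest-neighbor spacings of an unfolded spectrum (mean ~ 1)."""

    spacings: np.ndarray = field(repr=False)
    mean_spacing: float = 1.0

    @classmethod
    def from_spacings(cls, s) -> "SpacingSet":
        s = np.asarray(s, dtype=float)
        return cls(s, float(s.mean()) if s.size else float("nan"))


def prune_at_threshold(
    sm: SimilarityMatrix, t: float
) -> tuple[np.ndarray, list[str]]:
    """Zero entries with \\|corr\\| < t and drop genes left with no partner.

    Thresholding is on absolute correlation (negative co-expression counts);
    retained entries keep their sign, the diagonal stays 1. Returns the
    pruned dense matrix and the retained gene identifiers in original order.
    """
    if not 0.0 < t <= 1.0:
        raise InvalidParameter(f"threshold must lie in (0, 1], got {t}")
    A = np.where(np.abs(sm.corr) >= t, sm.corr, 0.0)
    np.fill_diagonal(A, 1.0)
    off = A - np.diag(np.diag(A))
    keep = np.flatnonzero(np.any(off != 0.0, axis=1))
    pruned = A[np.ix_(keep, keep)]
    return pruned, [sm.gene_ids[i] for i in keep]


def eigenvalues_symmetric(M: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of a symmetric real matrix (LAPACK syevr)."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise AsymmetricMatrix(f"matrix is not square: shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-8, rtol=0.0):
        raise AsymmetricMatrix("matrix is not symmetric within 1e-8")
    return np.sort(eigvalsh(M))


def _dedup(eigs: np.ndarray, tol: float) -> np.ndarray:
    """Collapse sorted values lying within ``tol`` of the kept representative."""
    out = [eigs[0]]
    for v in eigs[1:]:
        if v - out[-1] > tol:
            out.append(v)
    return np.asarray(out)


def unfold_eigenvalues(
    eigs,
    dedup_tol: float = DEDUP_TOL,
    n_anchors: int | None = None,
    min_unique: int = 10,
) -> SpacingSet:
    """Unfold a sorted spectrum to unit mean spacing via a monotone spline.

    Duplicates are collapsed at ``dedup_tol``; a monotone (PCHIP) cubic
    spline is fit through (eigenvalue, rank) at ``n_anchors`` evenly spaced
    rank anchors — default ``max(5, ceil(u/20))`` for ``u`` unique values,
    always including the first and last — and each unique eigenvalue is
    mapped through it. Spacings are first differences of the mapped values;
    monotonicity of the spline keeps them non-negative, and interpolation of
    the endpoints makes the mean spacing exactly 1.
    """
    eigs = np.sort(np.asarray(eigs, dtype=float))
    if eigs.size == 0:
        raise InsufficientEigenvalues("empty spectrum")
    uniq = _dedup(eigs, dedup_tol)
    u = uniq.size
    if u < max(min_unique, 4):
        raise InsufficientEigenvalues(
            f"{u} unique eigenvalues after deduplication; need at least {max(min_unique, 4)}"
        )
    if n_anchors is None:
        n_anchors = max(5, int(np.ceil(u / 20)))
    n_anchors = min(max(n_anchors, 2), u)
    anchor_ranks = np.unique(np.round(np.linspace(0, u - 1, n_anchors)).astype(int))
    spline = PchipInterpolator(uniq[anchor_ranks], anchor_ranks.astype(float))
    unfolded = spline(uniq)
    spacings = np.diff(unfolded)
    return SpacingSet(spacings, float(spacings.mean()))


def count_unique_eigenvalues(eigs, dedup_tol: float = DEDUP_TOL) -> int:
    eigs = np.sort(np.asarray(eigs, dtype=float))
    if eigs.size == 0:
        return 0
    return _dedup(eigs, dedup_tol).size


def nnsd_chi_square(
    sp: SpacingSet, n_bins: int = 60, s_max: float = 3.0
) -> float:
    """Chi-square of an observed NNSD against the Poisson (exponential) law.

    Observed counts are histogrammed over ``n_bins`` equal-width bins on
    [0, s_max] (spacings beyond ``s_max`` are discarded); expected counts are
    the unit-mean exponential probabilities renormalized over [0, s_max] so
    the expected total matches the retained count.
    """
    s = np.asarray(sp.spacings, dtype=float)
    if s.size == 0:
        raise InvalidParameter("empty spacing set")
    if n_bins < 2 or s_max <= 0:
        raise InvalidParameter("need n_bins >= 2 and s_max > 0")
    s = s[s <= s_max]
    N = s.size
    if N == 0:
        raise InvalidParameter("all spacings exceed s_max")
    if N < 10 * n_bins:
        warnings.warn(
            f"only {N} spacings for {n_bins} bins; chi-square is unstable",
            UnstableHistogramWarning,
            stacklevel=2,
        )
    edges = np.linspace(0.0, s_max, n_bins + 1)
    observed, _ = np.histogram(s, bins=edges)
    probs = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    expected = N * probs / (1.0 - np.exp(-s_max))
    return float(((observed - expected) ** 2 / expected).sum())


def chi2_pvalue(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability P(X >= chi2) at ``df`` degrees."""
    if df <= 0:
        raise InvalidParameter(f"df must be positive, got {df}")
    if chi2 < 0:
        raise InvalidParameter(f"chi-square statistic must be >= 0, got {chi2}")
    return float(chi2_dist.sf(chi2, df))


def find_threshold(
    sm: SimilarityMatrix,
    start: float = 0.92,
    step: float = 0.001,
    chi_signif: float = 100.0,
    chi_confirm: float = 200.0,
    t_min: float = 0.5,
    n_bins: int = 60,
    s_max: float = 3.0,
    dedup_tol: float = DEDUP_TOL,
    min_unique: int = MIN_UNIQUE_EIGENVALUES,
) -> RMTResult:
    """Scan thresholds downward and locate the Poisson-to-GOE transition.

    Raises :class:`ThresholdNotFound` (carrying the full trace) when the scan
    reaches ``t_min`` unconfirmed; the exception's ``homogeneous`` flag is set
    when every computable chi-square already exceeded the significance level,
    the signature of near-uniformly high correlations.
    """
    if not (0.0 < t_min < start <= 1.0):
        raise InvalidParameter(f"need 0 < t_min < start <= 1, got t_min={t_min} start={start}")
    if step <= 0:
        raise InvalidParameter(f"step must be positive, got {step}")

    n = sm.n_genes
    absA = np.abs(sm.corr).copy()
    np.fill_diagonal(absA, 0.0)
    # sorted off-diagonal magnitudes let each level check cheaply whether any
    # new entry crossed the threshold since the previous level; if none did,
    # the pruned matrix and hence the chi-square are unchanged.
    tri_sorted = np.sort(absA[np.triu_indices(n, 1)])

    trace: list[ScanRecord] = []
    candidate: float | None = None
    prev_edge_count = -1
    prev_rec: ScanRecord | None = None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UnstableHistogramWarning)
        k = 0
        while True:
            t = round(start - k * step, 10)
            if t < t_min - 1e-12:
                break
            k += 1
            edge_count = tri_sorted.size - int(np.searchsorted(tri_sorted, t, side="left"))
            if prev_rec is not None and edge_count == prev_edge_count:
                rec = ScanRecord(t, prev_rec.n_genes_retained, prev_rec.n_unique_eigs, prev_rec.chi2)
            else:
                pruned, kept = prune_at_threshold(sm, t)
                if len(kept) == 0:
                    rec = ScanRecord(t, 0, 0, None)
                else:
                    eigs = eigenvalues_symmetric(pruned)
                    u = count_unique_eigenvalues(eigs, dedup_tol)
                    if u < min_unique:
                        rec = ScanRecord(t, len(kept), u, None)
                    else:
                        sp = unfold_eigenvalues(eigs, dedup_tol=dedup_tol)
                        rec = ScanRecord(t, len(kept), u, nnsd_chi_square(sp, n_bins, s_max))
            prev_edge_count = edge_count
            prev_rec = rec
            trace.append(rec)

            if rec.chi2 is None:
                continue
            if rec.chi2 < chi_signif:
                candidate = None  # dropped back: previous rise was a local maximum
                continue
            if candidate is None:
                candidate = t
            if rec.chi2 >= chi_confirm:
                return RMTResult(
                    final_threshold=round(candidate + step, 10),
                    divergence_threshold=candidate,
                    confirmed=True,
                    trace=trace,
                    params=(start, step, chi_signif, chi_confirm),
                )

    defined = [r.chi2 for r in trace if r.chi2 is not None]
    homogeneous = bool(defined) and all(c >= chi_signif for c in defined)
    raise ThresholdNotFound(
        "no Poisson-to-GOE transition confirmed before t_min="
        f"{t_min}" + ("; chi-square was high at every level — correlations appear "
                      "homogeneously high across the matrix" if homogeneous else ""),
        trace=trace,
        homogeneous=homogeneous,
    )
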