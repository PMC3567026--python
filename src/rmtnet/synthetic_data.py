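"""Synthetic expression matrices with planted co-expression modules.

The generator emulates a normalized microarray expression matrix: blocks of
co-expressed genes embedded in uncorrelated background noise. Each module m
gets an independent standard-normal latent factor f_m over samples, and a
module gene's profile is

    loading * f_m + sqrt(1 - loading^2) * eps,    eps ~ N(0, 1) i.i.d.,

scaled by ``noise_sd``; background genes are pure scaled noise. The expected
Pearson correlation is ``loading**2`` within a module and 0 across modules
or against background, which gives closed-form oracles for every downstream
stage. The single-factor construction guarantees a positive-definite
population covariance at any size.

All randomness flows from one seed through independent spawned streams per
purpose, so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import InvalidParameter
from .expression_io import ExpressionMatrix
from .functional_similarity import AnnotationSet
from .network_topology import Network
from .rmt_threshold import SpacingSet, unfold_eigenvalues


@dataclass
class SyntheticTruth:
    """Planted module structure behind a generated matrix."""

    assignment: dict[str, int]  # module genes only; background genes absent
    loading: float
    noise_sd: float
    params: dict = field(default_factory=dict)

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, m in self.assignment.items():
            out.setdefault(m, []).append(g)
        return out

    def true_pairs(self) -> set[tuple[str, str]]:
        """Every within-module gene pair, canonically ordered."""
        pairs: set[tuple[str, str]] = set()
        for genes in self.modules().values():
            for a, b in combinations(sorted(genes), 2):
                pairs.add((a, b))
        return pairs


def generate_modular_expression(
    n_genes: int = 600,
    n_samples: int = 100,
    n_modules: int = 5,
    module_size: int = 20,
    loading: float = 0.92,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression matrix with ``n_modules`` planted blocks of co-expression.

    The first ``n_modules * module_size`` genes are module genes (grouped
    contiguously); the rest are background noise. ``loading`` in (0, 1)
    controls within-module correlation (expected r = loading^2).
    """
    if n_modules * module_size > n_genes:
        raise InvalidParameter(
            f"{n_modules} modules x {module_size} genes exceed n_genes={n_genes}"
        )
    if not 0.0 <= loading < 1.0 or noise_sd <= 0:
        raise InvalidParameter("need 0 <= loading < 1 and noise_sd > 0")
    ss = np.random.SeedSequence(seed)
    rng_factors, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    factors = rng_factors.standard_normal((n_modules, n_samples))
    eps = rng_noise.standard_normal((n_genes, n_samples))
    values = noise_sd * eps
    assignment: dict[str, int] = {}
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    for m in range(n_modules):
        lo, hi = m * module_size, (m + 1) * module_size
        values[lo:hi] = noise_sd * (
            loading * factors[m] + np.sqrt(1.0 - loading**2) * eps[lo:hi]
        )
        for g in gene_ids[lo:hi]:
            assignment[g] = m
    sample_ids = [f"s{j:04d}" for j in range(n_samples)]
    em = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = SyntheticTruth(
        assignment,
        loading,
        noise_sd,
        params=dict(
            n_genes=n_genes,
            n_samples=n_samples,
            n_modules=n_modules,
            module_size=module_size,
            loading=loading,
            noise_sd=noise_sd,
            seed=seed,
        ),
    )
    return em, truth


def generate_spacing_ensemble(kind: str, n: int, seed: int = 0) -> np.ndarray:
    """Reference nearest-neighbor spacing samples.

    ``"GOE"``: unfolded spacings of an n x n symmetric Gaussian matrix
    (level repulsion, Wigner-surmise shaped). ``"Poisson"``: spacings of n
    i.i.d. uniform points, normalized to unit mean (exponential law).
    """
    if n < 100:
        raise InvalidParameter(f"need n >= 100, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if kind == "GOE":
        A = rng.standard_normal((n, n))
        M = (A + A.T) / np.sqrt(2.0)
        eigs = np.linalg.eigvalsh(M)
        sp: SpacingSet = unfold_eigenvalues(eigs)
        return sp.spacings
    if kind == "Poisson":
        pts = np.sort(rng.uniform(0.0, 1.0, size=n))
        s = np.diff(pts)
        return s / s.mean()
    raise InvalidParameter(f"unknown ensemble kind {kind!r}; use 'GOE' or 'Poisson'")


def planted_edge_precision_recall(
    net: Network, truth: SyntheticTruth
) -> tuple[float | None, float]:
    """Precision/recall of network edges against planted within-module pairs."""
    true_pairs = truth.true_pairs()
    found = net.edge_set()
    if not found:
        return None, 0.0
    tp = len(found & true_pairs)
    precision = tp / len(found)
    recall = tp / len(true_pairs) if true_pairs else 0.0
    return precision, recall


def generate_module_annotations(
    truth: SyntheticTruth,
    terms_per_module: int = 3,
    n_generic_terms: int = 10,
    seed: int = 0,
) -> AnnotationSet:
    """Annotation fixture: distinctive terms per planted module.

    Every gene of module m carries terms ``M{m}:T{j}``; in addition every
    gene (module or background) draws one of ``n_generic_terms`` broad terms
    uniformly, so the background universe covers all genes and broad terms
    are never enriched in any specific module.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gene_ids = [f"g{i:04d}" for i in range(truth.params.get("n_genes", 0))] or sorted(
        truth.assignment
    )
    terms: dict[str, set[str]] = {g: set() for g in gene_ids}
    for g, m in truth.assignment.items():
        terms.setdefault(g, set()).update(
            f"M{m}:T{j}" for j in range(terms_per_module)
        )
    generic = rng.integers(0, n_generic_terms, size=len(gene_ids))
    for g, j in zip(gene_ids, generic):
        terms[g].add(f"GEN:T{j}")
    return AnnotationSet(terms)


def write_truth(truth: SyntheticTruth, path) -> None:
    """TSV ``gene<TAB>module_id`` of planted module genes."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(truth.assignment):
            fh.write(f"{g}\t{truth.assignment[g]}\n")


def write_annotations(ann: AnnotationSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(ann.terms_by_gene):
            for t in sorted(ann.terms_by_gene[g]):
                fh.write(f"{g}\t{t}\n")
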