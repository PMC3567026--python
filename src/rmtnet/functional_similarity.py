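"""Module term enrichment and chance-corrected functional similarity.

Modules are tested for annotation-term enrichment with the upper-tail
hypergeometric law (raw p <= 0.001 retained, no multiple-testing
correction). Two networks' module sets are then compared with Cohen's
kappa: each module with at least one enriched term becomes a binary
incidence vector over the union of enriched terms, every perturbed module
is matched to the global module maximizing kappa, and the mean of those
best-match kappas is the functional-similarity score. Kappa of 1 means a
module's enriched-term profile is perfectly reproduced; 0.6 is the
conventional cutoff for a meaningful match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import hypergeom

from .errors import (
    DimensionMismatch,
    InvalidBackground,
    NoComparableModules,
)

DEFAULT_ALPHA = 0.001
MEANINGFUL_KAPPA = 0.6


@dataclass
class AnnotationSet:
    """Flat gene -> annotation-term mapping over a gene universe.

    Terms may come from any vocabulary (GO, InterPro, KEGG, Pfam, ...);
    the ontology structure is not used. Every annotated gene must belong to
    the background universe.
    """

    terms_by_gene: dict[str, set[str]]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.background:
            self.background = set(self.terms_by_gene)
        stray = set(self.terms_by_gene) - self.background
        if stray:
            raise InvalidBackground(
                f"annotated genes outside the background: {sorted(stray)[:5]}"
            )

    def genes_by_term(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, terms in self.terms_by_gene.items():
            for t in terms:
                out.setdefault(t, set()).add(g)
        return out

    def restricted_to(self, genes: Iterable[str]) -> "AnnotationSet":
        """Annotation set over a sub-universe, e.g. the genes of one network."""
        genes = set(genes)
        return AnnotationSet(
            {g: set(ts) for g, ts in self.terms_by_gene.items() if g in genes},
        )


@dataclass
class EnrichmentProfile:
    """Enriched terms (term -> p-value) per module, at significance alpha."""

    per_module: dict[object, dict[str, float]]
    alpha: float = DEFAULT_ALPHA

    def nonempty(self) -> dict[object, set[str]]:
        return {m: set(tp) for m, tp in self.per_module.items() if tp}


@dataclass
class KappaResult:
    """Best-match kappa per perturbed module and their average."""

    per_module: dict[object, float]
    average_kappa: float


def hypergeometric_enrichment(module_genes, term_genes, background) -> float:
    """P(X >= observed overlap) for drawing a module from the background."""
    background = set(background)
    if not background:
        raise InvalidBackground("empty background universe")
    module_genes = set(module_genes) & background
    term_genes = set(term_genes) & background
    k = len(module_genes & term_genes)
    return float(
        hypergeom.sf(k - 1, len(background), len(term_genes), len(module_genes))
    )


def enrichment_profile(
    modules: Mapping[object, Iterable[str]],
    ann: AnnotationSet,
    alpha: float = DEFAULT_ALPHA,
) -> EnrichmentProfile:
    """Hypergeometric enrichment of every module x overlapping term.

    The background is the annotation set's universe; restrict the annotation
    set to the network's genes first (``ann.restricted_to``) to test against
    a network-relative background. Modules may come out with empty profiles.
    """
    by_term = ann.genes_by_term()
    per_module: dict[object, dict[str, float]] = {}
    for mid, genes in modules.items():
        genes = set(genes) & ann.background
        hits: dict[str, float] = {}
        candidate_terms = {t for g in genes for t in ann.terms_by_gene.get(g, ())}
        for t in candidate_terms:
            p = hypergeometric_enrichment(genes, by_term[t], ann.background)
            if p <= alpha:
                hits[t] = p
        per_module[mid] = hits
    return EnrichmentProfile(per_module, alpha)


def cohen_kappa(x, y) -> float:
    """Cohen's kappa of two equal-length binary vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise DimensionMismatch(f"binary vectors must align: {x.shape} vs {y.shape}")
    po = float((x == y).mean())
    px, py = float(x.mean()), float(y.mean())
    pe = px * py + (1.0 - px) * (1.0 - py)
    if pe >= 1.0:
        return 1.0  # both constant in the same class => identical vectors
    return (po - pe) / (1.0 - pe)


def average_module_kappa(
    perturbed: EnrichmentProfile, reference: EnrichmentProfile
) -> KappaResult:
    """Mean best-match kappa of perturbed modules against reference modules.

    Vectors are term-incidence over the union of terms enriched in either
    profile; modules with no enriched term are excluded on both sides.
    """
    pert = perturbed.nonempty()
    ref = reference.nonempty()
    if not pert or not ref:
        raise NoComparableModules(
            "need at least one module with enriched terms on each side"
        )
    universe = sorted(set().union(*pert.values(), *ref.values()))
    t_index = {t: i for i, t in enumerate(universe)}

    def vec(terms: set[str]) -> np.ndarray:
        v = np.zeros(len(universe))
        for t in terms:
            v[t_index[t]] = 1.0
        return v

    ref_vecs = {m: vec(ts) for m, ts in ref.items()}
    per_module: dict[object, float] = {}
    for m, ts in pert.items():
        v = vec(ts)
        per_module[m] = max(cohen_kappa(v, rv) for rv in ref_vecs.values())
    return KappaResult(per_module, float(np.mean(list(per_module.values()))))


def read_annotations(path, background: Iterable[str] | None = None) -> AnnotationSet:
    """Read a 2-column TSV ``gene<TAB>term_id`` (one pair per line)."""
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            g, t = ln.split("\t")
            terms.setdefault(g, set()).add(t)
    return AnnotationSet(terms, set(background) if background is not None else set())


def write_enrichment(profile: EnrichmentProfile, path) -> None:
    """TSV ``module<TAB>term<TAB>p_value``."""
    with open(path, "w", encoding="utf-8") as fh:
        for mid in sorted(profile.per_module, key=str):
            for t, p in sorted(profile.per_module[mid].items()):
                fh.write(f"{mid}\t{t}\t{p:.3e}\n")
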