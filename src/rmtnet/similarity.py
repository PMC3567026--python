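"""All-pairs Pearson similarity of expression profiles and its binary store.

This is the correlation-matrix construction step of the pipeline. Missing
values are handled pairwise-complete: each gene pair is correlated over the
samples where both are observed, and a pair whose complete-observation count
falls below ``min_obs`` (or whose variance is zero over those samples) is
*undefined*. Undefined correlations are stored as 0 so they can never seed a
network edge, and counted in ``n_missing_pairs``.

The on-disk format exploits symmetry: only the lower triangle (including the
unit diagonal) is stored, as little-endian float32, behind a 9-byte header —
magic ``RMTB``, version byte ``0x01``, and an unsigned 32-bit little-endian
gene count. Gene identifiers live in a plain-text sidecar ``<path>.genes``,
one per line.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionMismatch, FormatError, InsufficientData
from .expression_io import ExpressionMatrix

MAGIC = b"RMTB"
VERSION = 1
DEFAULT_MIN_OBS = 30


@dataclass
class SimilarityMatrix:
    """Symmetric Pearson correlation matrix over a fixed gene order."""

    gene_ids: list[str]
    corr: np.ndarray = field(repr=False)
    min_obs: int = DEFAULT_MIN_OBS
    n_missing_pairs: int = 0

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        n = len(self.gene_ids)
        if self.corr.shape != (n, n):
            raise DimensionMismatch(
                f"{n} gene ids but correlation matrix of shape {self.corr.shape}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def pearson(x, y, min_obs: int = DEFAULT_MIN_OBS) -> float | None:
    """Pairwise-complete Pearson correlation of two profiles.

    Returns ``None`` (undefined) when fewer than ``min_obs`` positions are
    jointly observed or when either profile is constant over them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DimensionMismatch(f"profile lengths differ: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    if int(ok.sum()) < min_obs:
        return None
    xv, yv = x[ok], y[ok]
    xd, yd = xv - xv.mean(), yv - yv.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        return None
    r = float((xd * yd).sum() / denom)
    return min(1.0, max(-1.0, r))


def build_similarity_matrix(
    em: ExpressionMatrix, min_obs: int = DEFAULT_MIN_OBS
) -> SimilarityMatrix:
    """Correlate every gene pair of an expression matrix (the ``ccm`` step).

    Delegates the pairwise-complete computation to pandas' C implementation;
    undefined pairs come back as NaN, are stored as 0, and counted.
    """
    if em.n_probes < 2:
        raise InsufficientData("need at least 2 probes to build a similarity matrix")
    if em.n_samples < min_obs:
        raise InsufficientData(
            f"{em.n_samples} samples is below min_obs={min_obs}"
        )
    corr = pd.DataFrame(em.values.T).corr(min_periods=min_obs).to_numpy()
    iu = np.triu_indices(em.n_probes, 1)
    n_missing = int(np.isnan(corr[iu]).sum())
    corr = np.nan_to_num(corr, nan=0.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix(list(em.probe_ids), corr, min_obs, n_missing)


def _tril_order(n: int) -> tuple[np.ndarray, np.ndarray]:
    # row-major lower triangle: (0,0), (1,0), (1,1), (2,0), ...
    return np.tril_indices(n)


def write_similarity_binary(sm: SimilarityMatrix, path) -> None:
    """Serialize the lower triangle as float32 plus a ``.genes`` sidecar."""
    path = Path(path)
    n = sm.n_genes
    tri = sm.corr[_tril_order(n)].astype("<f4")
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<B", VERSION))
        fh.write(struct.pack("<I", n))
        fh.write(tri.tobytes())
    with open(str(path) + ".genes", "w", encoding="utf-8") as fh:
        fh.write("\n".join(sm.gene_ids) + "\n")


def read_similarity_binary(path) -> SimilarityMatrix:
    """Reconstruct the full symmetric matrix from the triangular store.

    Values round-trip bit-exactly at float32 precision. ``min_obs`` and the
    missing-pair count are construction-time metadata and are not persisted;
    the returned object records ``min_obs=1`` and ``n_missing_pairs=0``.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(9)
        if len(head) < 9 or head[:4] != MAGIC:
            raise FormatError(f"{path}: bad magic bytes (not a similarity file)")
        if head[4] != VERSION:
            raise FormatError(f"{path}: unsupported version {head[4]}")
        n = struct.unpack("<I", head[5:9])[0]
        payload = fh.read()
    expected = n * (n + 1) // 2 * 4
    if len(payload) != expected:
        raise FormatError(
            f"{path}: truncated or padded payload ({len(payload)} bytes, expected {expected})"
        )
    tri = np.frombuffer(payload, dtype="<f4").astype(float)
    corr = np.zeros((n, n))
    rows, cols = _tril_order(n)
    corr[rows, cols] = tri
    corr[cols, rows] = tri
    genes_path = Path(str(path) + ".genes")
    if genes_path.exists():
        with open(genes_path, encoding="utf-8") as fh:
            gene_ids = [ln.strip() for ln in fh if ln.strip()]
        if len(gene_ids) != n:
            raise FormatError(
                f"{genes_path}: {len(gene_ids)} gene ids for a {n}-gene matrix"
            )
    else:
        gene_ids = [f"g{i}" for i in range(n)]
    return SimilarityMatrix(gene_ids, corr, min_obs=1, n_missing_pairs=0)
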