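"""Genomic relationship matrices: additive (G), dominance (D), epistatic.

The additive matrix follows the standard centered-dosage construction
G = MM' / (2 Σ p_i q_i), where column i of M holds (0-2p_i), (1-2p_i) or
(2-2p_i) for genotypes A1A1, A1A2 and A2A2.

The dominance matrix uses the centered heterozygosity coding: column i of H
is (1 - 2 p_i q_i) for a heterozygote and (-2 p_i q_i) for either homozygote,
and D = HH' / Σ 2 p_i q_i (1 - 2 p_i q_i).  Under Hardy-Weinberg equilibrium
the per-locus variance of the centered coefficient is 2 p q (1 - 2 p q), so
this scaling gives D a diagonal expectation of one for non-inbred individuals
and an off-diagonal expectation of zero for unrelated individuals.

Epistatic relationship matrices are Hadamard (elementwise) products of
lower-order matrices: G#G for additive-by-additive, G#G#G for third order,
G#G#D for additive-by-additive-by-dominance, and so on.  No rescaling is
applied after the product.

Missing genotypes contribute 0 to both codings (the expected centered
coefficient); the scale sums run over all retained loci regardless of
missingness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import AlleleFrequencies, GenotypeMatrix

__all__ = [
    "CenteredAdditiveCoding",
    "CenteredDominanceCoding",
    "RelationshipMatrix",
    "build_additive_coding",
    "build_G",
    "build_dominance_coding",
    "build_D",
    "hadamard_epistatic",
    "write_grm",
    "read_grm",
]


@dataclass
class CenteredAdditiveCoding:
    individual_ids: list[str]
    locus_ids: list[str]
    M: np.ndarray
    scale: float  # 2 * sum(p_i q_i)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("additive scale must be positive")


@dataclass
class CenteredDominanceCoding:
    individual_ids: list[str]
    locus_ids: list[str]
    H: np.ndarray
    scale: float  # sum(2 p_i q_i (1 - 2 p_i q_i))

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("dominance scale must be positive")


@dataclass
class RelationshipMatrix:
    """Symmetric individuals x individuals relationship matrix.

    ``kind`` is one of additive / dominance / epistatic (free-form on read),
    ``recipe`` records the construction, e.g. "A", "D", "A#A" or "A#A#D".
    """

    individual_ids: list[str]
    K: np.ndarray
    kind: str
    recipe: str
    scale: float | None = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.individual_ids)
        if self.K.shape != (n, n):
            raise ValueError(f"K shape {self.K.shape} != ({n}, {n})")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def submatrix(self, idx: np.ndarray) -> "RelationshipMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return RelationshipMatrix(
            [self.individual_ids[i] for i in idx],
            self.K[np.ix_(idx, idx)],
            self.kind,
            self.recipe,
            self.scale,
        )


def _check_segregating(f: AlleleFrequencies) -> None:
    fixed = (f.p <= 0) | (f.p >= 1)
    if fixed.any():
        bad = f.locus_ids[int(np.argmax(fixed))]
        raise ValueError(f"locus {bad!r} is fixed (p = 0 or 1); run QC first")


def build_additive_coding(g: GenotypeMatrix, f: AlleleFrequencies) -> CenteredAdditiveCoding:
    """Centered dosage matrix M with entries dosage - 2p (0 where missing)."""
    if list(f.locus_ids) != list(g.locus_ids):
        raise ValueError("allele frequencies do not match the genotype loci")
    _check_segregating(f)
    M = g.dosages.astype(float) - 2.0 * f.p
    M[g.missing_mask] = 0.0
    return CenteredAdditiveCoding(
        list(g.individual_ids), list(g.locus_ids), M, float(2.0 * f.pq.sum())
    )


def build_G(c: CenteredAdditiveCoding) -> RelationshipMatrix:
    """Additive genomic relationship matrix G = MM' / (2 Σ p_i q_i)."""
    K = c.M @ c.M.T / c.scale
    K = (K + K.T) / 2.0
    return RelationshipMatrix(list(c.individual_ids), K, "additive", "A", c.scale)


def build_dominance_coding(g: GenotypeMatrix, f: AlleleFrequencies) -> CenteredDominanceCoding:
    """Centered heterozygosity matrix H: het -> 1-2pq, hom -> -2pq, missing -> 0."""
    if list(f.locus_ids) != list(g.locus_ids):
        raise ValueError("allele frequencies do not match the genotype loci")
    _check_segregating(f)
    two_pq = 2.0 * f.pq
    H = np.where(g.dosages == 1, 1.0 - two_pq, -two_pq)
    H[g.missing_mask] = 0.0
    scale = float((two_pq * (1.0 - two_pq)).sum())
    return CenteredDominanceCoding(list(g.individual_ids), list(g.locus_ids), H, scale)


def build_D(c: CenteredDominanceCoding) -> RelationshipMatrix:
    """Dominance genomic relationship matrix D = HH' / Σ 2pq(1 - 2pq)."""
    K = c.H @ c.H.T / c.scale
    K = (K + K.T) / 2.0
    return RelationshipMatrix(list(c.individual_ids), K, "dominance", "D", c.scale)


def hadamard_epistatic(parts: Sequence[RelationshipMatrix]) -> RelationshipMatrix:
    """Elementwise product of relationship matrices, e.g. G#G or G#G#D.

    All parts must be over the same individuals in the same order.  The
    product is not rescaled (inbreeding is ignored, matching the usual
    Hadamard approximation for epistatic covariance).
    """
    if len(parts) < 2:
        raise ValueError("need at least two matrices for an epistatic product")
    ids = parts[0].individual_ids
    for part in parts[1:]:
        if part.individual_ids != ids:
            raise ValueError("relationship matrices cover different individuals")
    K = parts[0].K.copy()
    for part in parts[1:]:
        K *= part.K
    recipe = "#".join(p.recipe for p in parts)
    return RelationshipMatrix(list(ids), K, "epistatic", recipe)


# ---------------------------------------------------------------------------
# persistence: full-matrix TSV or the GCTA binary GRM triplet


def write_grm(
    K: RelationshipMatrix,
    path: str | Path,
    format: str = "tsv",
    n_markers: int | None = None,
) -> None:
    """Write a relationship matrix.

    ``tsv``: full symmetric matrix with an id header and a metadata comment
    line.  ``gcta_bin``: the GCTA triplet <prefix>.grm.bin (float32 lower
    triangle, row-major), <prefix>.grm.id, and <prefix>.grm.N.bin when
    ``n_markers`` is given.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            scale = "" if K.scale is None else f";scale={K.scale!r}"
            fh.write(f"#kind={K.kind};recipe={K.recipe}{scale}\n")
            pd.DataFrame(K.K, index=K.individual_ids, columns=K.individual_ids).to_csv(
                fh, sep="\t", index_label="id", float_format="%.12g"
            )
        return
    if format == "gcta_bin":
        prefix = str(path)
        tril = K.K[np.tril_indices(K.n)].astype("<f4")
        tril.tofile(prefix + ".grm.bin")
        with open(prefix + ".grm.id", "w") as fh:
            for iid in K.individual_ids:
                fh.write(f"{iid}\t{iid}\n")
        if n_markers is not None:
            np.full(tril.size, float(n_markers), dtype="<f4").tofile(prefix + ".grm.N.bin")
        return
    raise ValueError(f"unknown GRM format {format!r}")


def read_grm(path: str | Path, format: str = "tsv") -> RelationshipMatrix:
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            first = fh.readline()
            kind, recipe, scale = "unknown", "unknown", None
            if first.startswith("#"):
                meta = dict(
                    item.split("=", 1) for item in first[1:].strip().split(";") if "=" in item
                )
                kind = meta.get("kind", kind)
                recipe = meta.get("recipe", recipe)
                scale = float(meta["scale"]) if "scale" in meta else None
                body = fh
            else:
                fh.seek(0)
                body = fh
            df = pd.read_csv(body, sep="\t", index_col=0)
        return RelationshipMatrix(list(df.index.astype(str)), df.to_numpy(), kind, recipe, scale)
    if format == "gcta_bin":
        prefix = str(path)
        with open(prefix + ".grm.id") as fh:
            ids = [line.split()[1] for line in fh if line.strip()]
        n = len(ids)
        tril = np.fromfile(prefix + ".grm.bin", dtype="<f4")
        expected = n * (n + 1) // 2
        if tril.size != expected:
            raise ValueError(
                f"{prefix}.grm.bin holds {tril.size} values, expected {expected} for {n} ids"
            )
        K = np.zeros((n, n))
        K[np.tril_indices(n)] = tril
        K = K + np.tril(K, -1).T
        return RelationshipMatrix(ids, K, "unknown", "unknown")
    raise ValueError(f"unknown GRM format {format!r}")
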