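"""Synthetic genotypes and phenotypes with known genetic architecture.

The generator emulates a genotyped pig population with litter structure:
founders are drawn in Hardy-Weinberg equilibrium at allele frequencies
sampled uniformly above the QC threshold, reference individuals are full-sib
litters produced by Mendelian gamete sampling from randomly mated founders,
and test individuals form a second generation bred from the reference
animals.  The split into reference and test is therefore by generation, the
analogue of a birth-date cut-off.

Phenotypes follow the full additive + epistatic + dominance + litter +
residual decomposition.  Two effect modes are provided:

* ``mvn`` — genetic components are drawn multivariate normal with
  covariances proportional to the realized G, G#G and D matrices.  This is
  an exact match to the fitted model's assumptions and is the mode used for
  parameter-recovery checks.
* ``locus`` — per-locus additive effects, dominance values and
  additive-by-additive pair effects are drawn iid normal and scaled so the
  expected component variances hit their targets, giving genotype-anchored
  phenotypes that do not assume the model's covariance form.

Default variance magnitudes (2000 / 500 / 300 / 500 / 2200 for additive,
epistatic, dominance, litter, residual) mirror a corrected daily-gain
analysis in pigs, with a phenotype mean of 1134 g/day.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype_io import GenotypeMatrix, allele_frequencies, write_genotypes_tsv
from .relationship import (
    RelationshipMatrix,
    build_additive_coding,
    build_D,
    build_dominance_coding,
    build_G,
    hadamard_epistatic,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "draw_hwe_genotypes",
    "simulate_genotypes",
    "simulate_phenotypes",
    "build_relationship_matrices",
    "make_benchmark",
]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


@dataclass
class SimulationConfig:
    n_ref: int = 1000
    n_test: int = 200
    m: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.95
    n_founders: int = 200
    litter_size: int = 5
    var_additive: float = 2000.0
    var_epistatic: float = 500.0
    var_dominance: float = 300.0
    var_litter: float = 500.0
    var_residual: float = 2200.0
    mean: float = 1134.0
    effect_mode: str = "mvn"
    n_epistatic_pairs: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ref", "n_test", "m", "n_founders", "litter_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("var_additive", "var_epistatic", "var_dominance",
                     "var_litter", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_mode not in ("mvn", "locus"):
            raise ValueError("effect_mode must be 'mvn' or 'locus'")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders to mate")
        if not 0 < self.maf_low < self.maf_high < 1:
            raise ValueError("require 0 < maf_low < maf_high < 1")


@dataclass
class TruthSet:
    """Per-individual true genetic components and the generating config."""

    table: pd.DataFrame  # individual_id, litter, generation, is_reference,
    # additive, epistatic, dominance, litter_effect, residual, phenotype
    realized_variances: dict[str, float]
    config: SimulationConfig

    def __post_init__(self) -> None:
        comp = (
            self.table[["additive", "epistatic", "dominance", "litter_effect", "residual"]]
            .sum(axis=1)
            .to_numpy()
        )
        recon = self.config.mean + comp
        if not np.allclose(recon, self.table["phenotype"].to_numpy(), atol=1e-8):
            raise ValueError("phenotype does not reconstruct from its components")


def draw_hwe_genotypes(rng: np.random.Generator, n: int, p: np.ndarray) -> np.ndarray:
    """n individuals at len(p) loci, genotypes binomial(2, p) per locus (HWE)."""
    return rng.binomial(2, p, size=(n, p.size)).astype(np.int8)


def _gametes(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele count per locus from each parent row."""
    het = dosages == 1
    return (dosages == 2).astype(np.int8) + (het & (rng.random(dosages.shape) < 0.5))


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotypes plus a metadata table (litter, generation, reference flag).

    Founders are HWE draws; each litter is a full-sib family from a randomly
    chosen founder pair; the test generation is bred the same way from
    randomly chosen reference parents.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.m)
    founders = draw_hwe_genotypes(rng, cfg.n_founders, p)

    def breed(parents: np.ndarray, n_offspring: int, litter_prefix: str, start: int):
        n_litters = int(np.ceil(n_offspring / cfg.litter_size))
        rows, litters = [], []
        produced = 0
        for t in range(n_litters):
            sire, dam = rng.choice(parents.shape[0], size=2, replace=False)
            size = min(cfg.litter_size, n_offspring - produced)
            for _ in range(size):
                child = _gametes(parents[sire], rng) + _gametes(parents[dam], rng)
                rows.append(child)
                litters.append(f"{litter_prefix}{start + t}")
            produced += size
        return np.array(rows, dtype=np.int8), litters, start + n_litters

    ref_geno, ref_litters, next_litter = breed(founders, cfg.n_ref, "L", 0)
    test_geno, test_litters, _ = breed(ref_geno, cfg.n_test, "L", next_litter)

    dosages = np.vstack([ref_geno, test_geno])
    ids = [f"ref{i}" for i in range(cfg.n_ref)] + [f"test{i}" for i in range(cfg.n_test)]
    g = GenotypeMatrix(
        ids,
        [f"snp{j}" for j in range(cfg.m)],
        dosages,
        np.zeros(dosages.shape, dtype=bool),
    )
    meta = pd.DataFrame(
        {
            "individual_id": ids,
            "litter": ref_litters + test_litters,
            "generation": [1] * cfg.n_ref + [2] * cfg.n_test,
            "is_reference": [True] * cfg.n_ref + [False] * cfg.n_test,
        }
    )
    return g, meta


def build_relationship_matrices(
    g: GenotypeMatrix,
) -> dict[str, RelationshipMatrix]:
    """G, G#G and D from a genotype matrix, frequencies from the sample.

    Loci fixed in the sample (drift can fix loci in small simulated
    populations) carry no relationship information and are dropped.
    """
    f = allele_frequencies(g)
    segregating = (f.p > 0) & (f.p < 1)
    if not segregating.all():
        g = g.subset(cols=segregating)
        f = allele_frequencies(g)
    G = build_G(build_additive_coding(g, f))
    D = build_D(build_dominance_coding(g, f))
    Gaa = hadamard_epistatic([G, G])
    return {"additive": G, "epistatic": Gaa, "dominance": D}


def _mvn_component(
    K: np.ndarray, variance: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(0, K * variance) via Cholesky with jitter escalation."""
    n = K.shape[0]
    if variance == 0:
        return np.zeros(n)
    for jit in _JITTERS:
        try:
            L = np.linalg.cholesky(K + jit * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError("relationship matrix not PSD after jitter escalation")
    return np.sqrt(variance) * (L @ rng.standard_normal(n))


def simulate_phenotypes(
    g: GenotypeMatrix, meta: pd.DataFrame, cfg: SimulationConfig
) -> TruthSet:
    """True genetic components and phenotypes for the simulated individuals.

    The component-effect stream is seeded from ``cfg.seed`` offset by one so
    genotype and phenotype randomness never interleave.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = g.n_individuals

    if cfg.effect_mode == "mvn":
        mats = build_relationship_matrices(g)
        a = _mvn_component(mats["additive"].K, cfg.var_additive, rng)
        i = _mvn_component(mats["epistatic"].K, cfg.var_epistatic, rng)
        d = _mvn_component(mats["dominance"].K, cfg.var_dominance, rng)
    else:  # locus mode
        f = allele_frequencies(g)
        coding_a = build_additive_coding(g, f)
        coding_d = build_dominance_coding(g, f)
        alpha = rng.standard_normal(g.n_loci) * np.sqrt(cfg.var_additive / coding_a.scale)
        a = coding_a.M @ alpha
        delta = rng.standard_normal(g.n_loci) * np.sqrt(cfg.var_dominance / coding_d.scale)
        d = coding_d.H @ delta
        if cfg.var_epistatic > 0:
            max_pairs = g.n_loci * (g.n_loci - 1) // 2
            n_pairs = min(cfg.n_epistatic_pairs, max_pairs)
            loci = np.array(
                [rng.choice(g.n_loci, size=2, replace=False) for _ in range(n_pairs)]
            )
            pq2 = 2.0 * f.pq
            pair_scale = float((pq2[loci[:, 0]] * pq2[loci[:, 1]]).sum())
            w = rng.standard_normal(n_pairs) * np.sqrt(cfg.var_epistatic / pair_scale)
            i = (coding_a.M[:, loci[:, 0]] * coding_a.M[:, loci[:, 1]]) @ w
        else:
            i = np.zeros(n)

    litters = meta["litter"].to_numpy()
    codes, uniques = pd.factorize(litters)
    litter_values = rng.standard_normal(len(uniques)) * np.sqrt(cfg.var_litter)
    litter_effect = litter_values[codes]
    e = rng.standard_normal(n) * np.sqrt(cfg.var_residual)
    y = cfg.mean + a + i + d + litter_effect + e

    table = meta.copy()
    table["additive"] = a
    table["epistatic"] = i
    table["dominance"] = d
    table["litter_effect"] = litter_effect
    table["residual"] = e
    table["phenotype"] = y
    realized = {
        "additive": float(np.var(a, ddof=1)),
        "epistatic": float(np.var(i, ddof=1)),
        "dominance": float(np.var(d, ddof=1)),
        "litter": float(np.var(litter_effect, ddof=1)),
        "residual": float(np.var(e, ddof=1)),
    }
    return TruthSet(table=table, realized_variances=realized, config=cfg)


def make_benchmark(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete desk-scale fixture: genotypes, phenotypes, truth.

    The phenotype table carries exactly what the fitting pipeline consumes
    (individual_id, dgc, litter, is_reference); the truth table keeps the
    per-individual components, and the manifest records the configuration and
    realized variances.  Identical config and seed reproduce the bundle
    byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, meta = simulate_genotypes(cfg)
    truth = simulate_phenotypes(g, meta, cfg)

    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.yaml",
    }
    write_genotypes_tsv(g, paths["genotypes"])
    pheno = truth.table[["individual_id", "phenotype", "litter", "is_reference"]].rename(
        columns={"phenotype": "dgc"}
    )
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.10g")
    truth.table.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    manifest = {
        "generator": "nagblup.simulate.make_benchmark",
        "config": asdict(cfg),
        "realized_variances": truth.realized_variances,
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths
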