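"""Synthetic landscape-genomics datasets with known truth.

Generates spatially clustered samples, neutral SNPs with Balding-Nichols
population-structured allele frequencies, and optional "adaptive" SNPs whose
genotype-class presence follows a logistic link to one environmental
gradient — exactly the model class the scoring engine fits, so planted
effects are a fair recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from geascan.env_data import EnvTable
from geascan.genotype_io import MISSING, GenotypeMatrix


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; ``seed`` is mandatory and drives every draw."""

    n_samples: int = 300
    n_neutral_snps: int = 100
    n_adaptive_snps: int = 0
    demes: int = 1
    fst: float = 0.0  # Balding-Nichols divergence F in [0, 1)
    env_noise_sd: float = 0.3
    beta1: float = 2.0  # adaptive log-odds slope on the (z-scored) gradient
    beta0: float = 0.0
    missing_rate: float = 0.0
    bbox: tuple = (-5.0, 40.0, 5.0, 50.0)  # lon_min, lat_min, lon_max, lat_max
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise SimulationError("n_samples must be positive")
        if self.n_neutral_snps < 0 or self.n_adaptive_snps < 0:
            raise SimulationError("SNP counts must be nonnegative")
        if self.n_neutral_snps + self.n_adaptive_snps == 0:
            raise SimulationError("need at least one SNP")
        if not 0.0 <= self.fst < 1.0:
            raise SimulationError("fst must be in [0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise SimulationError("missing_rate must be in [0, 1]")
        if self.demes < 1:
            raise SimulationError("demes must be >= 1")


@dataclass
class SimDataset:
    genotypes: GenotypeMatrix
    env: EnvTable
    truth: pd.DataFrame  # columns: snp, beta1, genotype_class
    deme: np.ndarray


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Draw one complete dataset.

    Coordinates: deme centers uniform in the bounding box, samples scattered
    around their deme center.  Environment: ``env1`` is a linear lon/lat
    gradient plus Gaussian noise, z-scored.  Neutral SNP j: ancestral
    frequency p_j ~ U(0.05, 0.95), per-deme frequencies Beta-distributed with
    mean p_j and variance F p_j (1 - p_j) (Balding-Nichols), calls
    Binomial(2, p_deme).  Adaptive SNPs plant homAlt presence
    ~ Bernoulli(expit(beta0 + beta1 * env1)); non-carriers split evenly
    between homRef and het.  Missing calls are dropped out at
    ``missing_rate``.  Identical config (same seed) gives identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    lon_min, lat_min, lon_max, lat_max = cfg.bbox

    deme_of = rng.integers(0, cfg.demes, size=n)
    centers_lon = rng.uniform(lon_min, lon_max, size=cfg.demes)
    centers_lat = rng.uniform(lat_min, lat_max, size=cfg.demes)
    spread_lon = 0.1 * (lon_max - lon_min)
    spread_lat = 0.1 * (lat_max - lat_min)
    lon = np.clip(centers_lon[deme_of] + rng.normal(0, spread_lon, n), lon_min, lon_max)
    lat = np.clip(centers_lat[deme_of] + rng.normal(0, spread_lat, n), lat_min, lat_max)

    raw = (lon - lon_min) / (lon_max - lon_min) + (lat - lat_min) / (lat_max - lat_min)
    raw = raw + rng.normal(0.0, cfg.env_noise_sd, n)
    env1 = (raw - raw.mean()) / raw.std(ddof=0)

    n_snps = cfg.n_neutral_snps + cfg.n_adaptive_snps
    calls = np.empty((n, n_snps), dtype=np.int8)
    adaptive_idx = set(
        rng.choice(n_snps, size=cfg.n_adaptive_snps, replace=False).tolist()
    )
    truth_rows = []
    for j in range(n_snps):
        if j in adaptive_idx:
            prob = 1.0 / (1.0 + np.exp(-(cfg.beta0 + cfg.beta1 * env1)))
            carrier = rng.random(n) < prob
            rest = rng.integers(0, 2, size=n)  # homRef or het for non-carriers
            calls[:, j] = np.where(carrier, 2, rest).astype(np.int8)
            truth_rows.append(
                {"snp": f"snp{j + 1}", "beta1": cfg.beta1, "genotype_class": "homAlt"}
            )
        else:
            p_anc = rng.uniform(0.05, 0.95)
            if cfg.fst > 0 and cfg.demes > 1:
                a = p_anc * (1 - cfg.fst) / cfg.fst
                b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
                p_deme = rng.beta(a, b, size=cfg.demes)
            else:
                p_deme = np.full(cfg.demes, p_anc)
            calls[:, j] = rng.binomial(2, p_deme[deme_of]).astype(np.int8)
    if cfg.missing_rate > 0:
        drop = rng.random(calls.shape) < cfg.missing_rate
        calls[drop] = MISSING

    samples = [f"ind{i + 1}" for i in range(n)]
    snps = pd.DataFrame(
        {
            "name": [f"snp{j + 1}" for j in range(n_snps)],
            "chrom": ["1"] * n_snps,
            "pos": np.arange(1, n_snps + 1) * 1000,
            "ref": ["A"] * n_snps,
            "alt": ["G"] * n_snps,
        }
    )
    g = GenotypeMatrix(samples=samples, snps=snps, calls=calls)
    env = EnvTable(
        samples=samples,
        coordinates=np.column_stack([lon, lat]),
        data=pd.DataFrame({"env1": env1}),
    )
    truth = pd.DataFrame(truth_rows, columns=["snp", "beta1", "genotype_class"])
    return SimDataset(genotypes=g, env=env, truth=truth, deme=deme_of)


PRESETS = {
    "null": dict(n_samples=300, n_neutral_snps=2000, n_adaptive_snps=0,
                 demes=1, fst=0.0),
    "adaptive": dict(n_samples=500, n_neutral_snps=500, n_adaptive_snps=1,
                     demes=1, fst=0.0, beta1=2.0),
    "structured": dict(n_samples=300, n_neutral_snps=500, n_adaptive_snps=0,
                       demes=2, fst=0.2),
}


def preset_config(name: str, seed: int, **overrides) -> SimConfig:
    if name not in PRESETS:
        raise SimulationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal plain-text VCF 4.2 with GT-only genotype fields."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.samples)
            + "\n"
        )
        for j in range(g.n_snps):
            snp = g.snps.iloc[j]
            gts = "\t".join(gt_of[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{snp['chrom']}\t{snp['pos']}\t{snp['name']}\t{snp['ref']}\t"
                f"{snp['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_dataset(ds: SimDataset, outdir) -> dict:
    """Write VCF + samples CSV + env CSV + truth TSV; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "samples": os.path.join(outdir, "samples.csv"),
        "env": os.path.join(outdir, "env.csv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_vcf(ds.genotypes, paths["vcf"])
    pd.DataFrame(
        {
            "ID": ds.env.samples,
            "lon": ds.env.coordinates[:, 0],
            "lat": ds.env.coordinates[:, 1],
            "epsg": 4326,
        }
    ).to_csv(paths["samples"], index=False)
    from geascan.env_data import write_env_csv

    write_env_csv(ds.env, paths["env"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
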