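import numpy as np
import pandas as pd
import pytest

from geascan import env_data as ed
from geascan import genotype_io as gio
from geascan import simulate as sim


def make_vcf(path, records, samples=("s1", "s2")):
    """Write a minimal VCF; records = (chrom, pos, id, ref, alt, gts)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        for chrom in dict.fromkeys(r[0] for r in records):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, vid, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


def matrix_from_calls(calls, chrom=None, pos=None):
    """GenotypeMatrix straight from a calls array (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snps = pd.DataFrame({
        "name": [f"snp{j+1}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
        "ref": ["A"] * m,
        "alt": ["G"] * m,
    })
    return gio.GenotypeMatrix(samples=[f"i{k+1}" for k in range(n)],
                              snps=snps, calls=calls)


@pytest.fixture
def small_dataset():
    cfg = sim.SimConfig(n_samples=120, n_neutral_snps=40, n_adaptive_snps=1,
                        seed=11, missing_rate=0.02)
    return sim.simulate_dataset(cfg)


@pytest.fixture
def env_table():
    rng = np.random.default_rng(5)
    n = 60
    data = pd.DataFrame({
        "bio1": rng.normal(10, 3, n),
        "bio12": rng.normal(800, 100, n),
        "alt": rng.normal(500, 200, n),
    })
    coords = np.column_stack([rng.uniform(-5, 5, n), rng.uniform(42, 48, n)])
    return ed.EnvTable(samples=[f"i{k}" for k in range(n)],
                       coordinates=coords, data=data)
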