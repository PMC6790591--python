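# geascan

Genome–environment association (GEA) scanning for landscape genomics, as one
package: genotype QC and binary genotype-indicator encoding, environmental
table construction from rasters and coordinates, population-structure
covariates, per-genotype logistic association models scored by likelihood-ratio
(G) and Wald statistics, multiple-testing correction (Storey q-values,
Bonferroni), spatial-autocorrelation diagnostics, and offline nearest-gene
annotation from a GFF3.

## Pipeline (CLI)

```bash
# synthetic dataset with a planted adaptive SNP
geascan simulate --preset adaptive --seed 1 --out data/

# genotype QC (MAF, missingness, optional LD pruning) + indicator encoding
geascan prepare-geno --in data/genotypes.vcf --format vcf \
    --maf 0.05 --miss 0.1 --ld-r2 off --out geno.txt --report qc.json

# environmental table: raster extraction + correlation pruning (r^2 > 0.9)
geascan prepare-env --samples loc.csv --epsg 4326 --rasters rasters/ \
    --r2 0.9 --out env.csv

# optional population-structure covariates (PCA scores or memberships)
geascan structure --geno geno.txt --env env.csv --npc 2 --out env_pop.csv

# logistic G / Wald scan (null = intercept + pop vars; full adds env var)
geascan run --geno geno.txt --env env.csv --chunks 8 --workers 4 \
    --out scores.tsv

# p-values (upper-tail chi-squared), Storey q-values, Bonferroni
geascan postprocess --scores scores.tsv --out results.tsv

# Manhattan plot of models with G or Wald score > 6
geascan plot manhattan --results results.tsv --snps geno.txt.snps.csv \
    --env-var env1 --value q_G --threshold 0.05 --out manhattan.png

# offline gene annotation of significant SNPs
geascan annotate --results results.tsv --snps geno.txt.snps.csv \
    --gff genes.gff3 --q-max 0.05 --out annotation.tsv
```

Library API mirrors the CLI: `geascan.genotype_io`, `geascan.env_data`,
`geascan.popstructure`, `geascan.gea_core`, `geascan.stats_post`,
`geascan.spatial_viz`, `geascan.annotate`, `geascan.simulate`.

Notes:

- Each biallelic SNP is expanded into 3 binary presence/absence indicators
  (homRef/het/homAlt); each indicator × environmental variable pair is one
  logistic model. G = 2(LL_full − LL_null), Wald = β̂ᵀV̂⁻¹β̂ over the
  environmental coefficients; both are χ²(df = #env vars) under the null.
- Coordinate projection supports EPSG:4326 and WGS84 UTM zones
  (EPSG:326xx/327xx) without external GIS dependencies. Rasters: ESRI ASCII
  grid and GeoTIFF.
- PED/MAP input: the first allele encountered per SNP in file order is taken
  as the reference allele (PED carries no ref designation).
- The scan output is byte-identical regardless of `--chunks`/`--workers`.

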