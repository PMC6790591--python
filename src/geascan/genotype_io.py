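"""Genotype input, quality control and presence/absence indicator encoding.

Genotypes are stored as diploid alt-allele dosages in ``{0, 1, 2}`` with
``-1`` marking a missing call.  Each retained biallelic SNP is expanded into
three binary indicator variables (homRef / het / homAlt presence), the unit
of association testing downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: genotype-class index -> dosage value it indicates
GENOTYPE_CLASSES = ("homRef", "het", "homAlt")

_SNP_COLUMNS = ["name", "chrom", "pos", "ref", "alt"]


class GenotypeError(ValueError):
    """Fatal genotype input/QC error."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid dosage matrix with per-SNP metadata.

    Attributes
    ----------
    samples : list of str
        Ordered unique sample identifiers.
    snps : pandas.DataFrame
        One row per SNP with columns ``name, chrom, pos, ref, alt``.
    calls : numpy.ndarray of int8, shape (n_samples, n_snps)
        Alt-allele dosage per call; ``-1`` is missing.
    """

    samples: list
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.snps.shape[0] != self.calls.shape[1]:
            raise GenotypeError(
                f"snps table has {self.snps.shape[0]} rows but calls has "
                f"{self.calls.shape[1]} columns"
            )
        if len(self.samples) != self.calls.shape[0]:
            raise GenotypeError("sample count does not match calls rows")
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeError("duplicate sample IDs")
        if self.snps["name"].duplicated().any():
            dup = self.snps.loc[self.snps["name"].duplicated(), "name"].iloc[0]
            raise GenotypeError(f"duplicate SNP name: {dup}")
        if (self.snps["pos"].to_numpy() < 0).any():
            raise GenotypeError("negative SNP position")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeError(f"illegal call value {self.calls[bad][0]}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.snps.shape[0]

    def take_snps(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the SNPs selected by ``index``."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
        )


@dataclass(frozen=True)
class QCThresholds:
    """QC thresholds: SNPs with MAF below ``maf_min`` or missing-call
    proportion above ``missing_max`` are removed, then LD pruning at
    ``ld_r2_max`` (``None`` disables it) within ``ld_window``-SNP windows."""

    maf_min: float = 0.05
    missing_max: float = 0.1
    ld_r2_max: float | None = None
    ld_window: int = 50

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise GenotypeError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.missing_max <= 1.0:
            raise GenotypeError(f"missing_max must be in [0, 1], got {self.missing_max}")
        if self.ld_r2_max is not None and not 0.0 <= self.ld_r2_max <= 1.0:
            raise GenotypeError(f"ld_r2_max must be in [0, 1], got {self.ld_r2_max}")
        if self.ld_window < 2:
            raise GenotypeError("ld_window must be >= 2")


@dataclass
class IndicatorSet:
    """Binary presence/absence variables, three per SNP.

    ``indicators`` is a DataFrame with columns ``snp, genotype_class, label``
    (label = ``"<snp>_<alleles>"``); ``values`` is samples x indicators in
    ``{0, 1}`` with ``-1`` missing.
    """

    samples: list
    indicators: pd.DataFrame
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), self.indicators.shape[0]):
            raise GenotypeError("values shape does not match samples x indicators")

    @property
    def n_indicators(self) -> int:
        return self.indicators.shape[0]

    def __eq__(self, other):
        if not isinstance(other, IndicatorSet):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.indicators.reset_index(drop=True).equals(
                other.indicators.reset_index(drop=True)
            )
            and np.array_equal(self.values, other.values)
        )


def indicator_count(n_snps: int) -> int:
    """Number of indicator variables the encoder produces for ``n_snps``
    biallelic SNPs: one per genotype class, i.e. ``3 * n_snps``."""
    if n_snps < 0:
        raise GenotypeError("n_snps must be nonnegative")
    return len(GENOTYPE_CLASSES) * n_snps


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_BASES = frozenset("ACGT")


def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Read a genotype file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"vcf", "ped"}
        ``"ped"`` expects a companion ``.map`` file next to the ``.ped``.

    Only biallelic SNP records are kept; multi-allelic and non-SNP records
    are skipped (counts logged).  Zero retained SNPs is fatal.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "ped":
        return _read_ped(path)
    raise GenotypeError(f"unknown genotype format: {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise GenotypeError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    names, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1 or var.REF not in _BASES or var.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        name = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        names.append(name)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(remap[np.asarray(var.gt_types)])
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", n_skipped)
    if not names:
        raise GenotypeError(f"no biallelic SNPs found in {path}")
    snps = pd.DataFrame(
        {"name": names, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def _read_ped(path) -> GenotypeMatrix:
    """PLINK text PED + MAP.  PED carries no ref/alt designation: the first
    allele encountered in file order at each SNP becomes the ref allele."""
    import os

    path = str(path)
    map_path = os.path.splitext(path)[0] + ".map"
    try:
        map_df = pd.read_csv(
            map_path,
            sep=r"\s+",
            header=None,
            names=["chrom", "name", "cm", "pos"],
            dtype={"chrom": str, "name": str},
        )
    except OSError as exc:
        raise GenotypeError(f"cannot read MAP file {map_path}: {exc}") from exc
    n_snps = map_df.shape[0]

    samples = []
    allele_rows = []
    try:
        fh = open(path)
    except OSError as exc:
        raise GenotypeError(f"cannot read PED file {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise GenotypeError(
                    f"{path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(fields)}"
                )
            samples.append(fields[1])
            allele_rows.append(fields[6:])
    if not samples:
        raise GenotypeError(f"empty PED file {path}")

    alleles = np.array(allele_rows, dtype=object).reshape(len(samples), n_snps, 2)
    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    refs, alts, keep = [], [], []
    n_skipped = 0
    for j in range(n_snps):
        a = alleles[:, j, :]
        obs = [x for x in a.ravel() if x not in ("0", ".")]
        uniq = list(dict.fromkeys(obs))  # first-encountered order
        if len(uniq) == 0 or len(uniq) > 2 or any(u not in _BASES for u in uniq):
            n_skipped += 1
            continue
        ref = uniq[0]
        alt = uniq[1] if len(uniq) > 1 else ("A" if ref != "A" else "G")
        missing_mask = (a[:, 0] == "0") | (a[:, 1] == "0") | (a[:, 0] == ".") | (a[:, 1] == ".")
        dosage = (a[:, 0] == alt).astype(np.int8) + (a[:, 1] == alt).astype(np.int8)
        dosage[missing_mask] = MISSING
        calls[:, j] = dosage
        refs.append(ref)
        alts.append(alt)
        keep.append(j)
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP PED columns", n_skipped)
    if not keep:
        raise GenotypeError(f"no biallelic SNPs found in {path}")
    snps = map_df.iloc[keep][["name", "chrom", "pos"]].reset_index(drop=True)
    snps["ref"] = refs
    snps["alt"] = alts
    return GenotypeMatrix(
        samples=samples, snps=snps[_SNP_COLUMNS], calls=calls[:, keep]
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency ``min(p, 1-p)`` with
    ``p = sum(dosage) / (2 * n_nonmissing)``; NaN when all calls missing."""
    calls = g.calls.astype(float)
    calls[g.calls == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0) / (2.0 * np.sum(~np.isnan(calls), axis=0))
    return np.minimum(p, 1.0 - p)


def compute_missingness(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP proportion of missing calls."""
    return (g.calls == MISSING).mean(axis=0)


def apply_qc(g: GenotypeMatrix, t: QCThresholds):
    """Filter SNPs on MAF and missingness, then LD-prune.

    Returns ``(filtered GenotypeMatrix, report dict)``.  The report holds
    20-bin histograms of MAF/missingness/LD-r2 and per-criterion discard
    counts.  Removing every SNP is fatal.
    """
    maf = compute_maf(g)
    miss = compute_missingness(g)
    with np.errstate(invalid="ignore"):
        pass_maf = np.nan_to_num(maf, nan=-1.0) >= t.maf_min
        pass_miss = miss <= t.missing_max
    keep = pass_maf & pass_miss
    report = {
        "n_input": g.n_snps,
        "maf_hist": _hist(maf[~np.isnan(maf)], 0.0, 0.5),
        "missingness_hist": _hist(miss, 0.0, 1.0),
        "n_discarded_maf": int((~pass_maf).sum()),
        "n_discarded_missingness": int((~pass_miss).sum()),
    }
    filtered = g.take_snps(np.where(keep)[0])
    if t.ld_r2_max is not None and filtered.n_snps:
        pruned, r2_values = _ld_prune_impl(filtered, t.ld_r2_max, t.ld_window)
        report["ld_r2_hist"] = _hist(r2_values, 0.0, 1.0)
        report["n_discarded_ld"] = filtered.n_snps - pruned.n_snps
        filtered = pruned
    else:
        report["ld_r2_hist"] = _hist(np.array([]), 0.0, 1.0)
        report["n_discarded_ld"] = 0
    report["n_retained"] = filtered.n_snps
    if filtered.n_snps == 0:
        raise GenotypeError(f"QC removed all SNPs; report: {report}")
    return filtered, report


def _hist(x, lo, hi, bins=20):
    counts, edges = np.histogram(np.asarray(x, float), bins=bins, range=(lo, hi))
    return {"counts": counts.tolist(), "edges": edges.tolist()}


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over their shared
    non-missing samples.  Undefined (constant vector or <2 shared) -> 0."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def _ld_prune_impl(g: GenotypeMatrix, r2_max: float, window: int):
    order = np.lexsort((g.snps["pos"].to_numpy(), g.snps["chrom"].to_numpy()))
    gs = g.take_snps(order)
    kept: list[int] = []
    kept_chrom: list = []
    chroms = gs.snps["chrom"].to_numpy()
    r2_seen = []
    for j in range(gs.n_snps):
        drop = False
        # compare against previous window-1 retained SNPs on the same chromosome
        for i in reversed(kept[-(window - 1):] if window > 1 else []):
            if chroms[i] != chroms[j]:
                break
            r2 = _pairwise_r2(gs.calls[:, i], gs.calls[:, j])
            r2_seen.append(r2)
            if r2 > r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
            kept_chrom.append(chroms[j])
    return gs.take_snps(kept), np.array(r2_seen)


def ld_prune(g: GenotypeMatrix, r2_max: float, window: int = 50) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning.

    SNPs are scanned in (chromosome, position) order; a SNP whose dosage
    vector has squared Pearson correlation above ``r2_max`` with any retained
    SNP among the previous ``window - 1`` retained SNPs on the same
    chromosome is dropped (the later/higher-position SNP of the pair).
    """
    pruned, _ = _ld_prune_impl(g, r2_max, window)
    return pruned


# ---------------------------------------------------------------------------
# Indicator encoding
# ---------------------------------------------------------------------------


def encode_indicators(g: GenotypeMatrix) -> IndicatorSet:
    """Expand each SNP into 3 binary genotype-presence indicators.

    Labels use allele letters: homRef ``<snp>_<ref><ref>``, het
    ``<snp>_<ref><alt>``, homAlt ``<snp>_<alt><alt>``.  A missing call gives
    missing (-1) in all three indicators of that SNP.
    """
    if g.n_snps == 0:
        raise GenotypeError("cannot encode an empty GenotypeMatrix")
    n = g.n_snps
    labels = np.empty(indicator_count(n), dtype=object)
    snp_names = np.empty(indicator_count(n), dtype=object)
    classes = np.empty(indicator_count(n), dtype=object)
    refs = g.snps["ref"].to_numpy()
    alts = g.snps["alt"].to_numpy()
    names = g.snps["name"].to_numpy()
    for j in range(n):
        pairs = (refs[j] + refs[j], refs[j] + alts[j], alts[j] + alts[j])
        for c, (cls, pair) in enumerate(zip(GENOTYPE_CLASSES, pairs)):
            k = 3 * j + c
            labels[k] = f"{names[j]}_{pair}"
            snp_names[k] = names[j]
            classes[k] = cls
    values = np.full((g.n_samples, indicator_count(n)), MISSING, dtype=np.int8)
    for c in range(3):
        present = g.calls == c
        nonmissing = g.calls != MISSING
        values[:, c::3][nonmissing] = present[nonmissing].astype(np.int8)
    indicators = pd.DataFrame(
        {"snp": snp_names, "genotype_class": classes, "label": labels}
    )
    return IndicatorSet(samples=list(g.samples), indicators=indicators, values=values)


# ---------------------------------------------------------------------------
# Interchange text format
# ---------------------------------------------------------------------------

_MISSING_TOKEN = "NaN"


def write_sambada_format(ind: IndicatorSet, path) -> None:
    """Write the whitespace-separated interchange table: header row of
    indicator labels after an ``ID`` column, missing written as ``NaN``."""
    with open(path, "w") as fh:
        fh.write(" ".join(["ID"] + list(ind.indicators["label"])) + "\n")
        for i, sample in enumerate(ind.samples):
            row = [
                _MISSING_TOKEN if v == MISSING else str(int(v))
                for v in ind.values[i]
            ]
            fh.write(" ".join([str(sample)] + row) + "\n")


def read_sambada_format(path) -> IndicatorSet:
    """Inverse of :func:`write_sambada_format` (round-trip identity).

    Tolerates runs of spaces/tabs; a row whose length disagrees with the
    header is fatal, naming the line number.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "ID":
            raise GenotypeError(f"{path}:1: expected header starting with 'ID'")
        labels = header[1:]
        n_ind = len(labels)
        samples, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != n_ind + 1:
                raise GenotypeError(
                    f"{path}:{lineno}: expected {n_ind + 1} fields, got {len(fields)}"
                )
            samples.append(fields[0])
            rows.append(
                [MISSING if f == _MISSING_TOKEN else int(f) for f in fields[1:]]
            )
    values = np.array(rows, dtype=np.int8) if rows else np.empty((0, n_ind), np.int8)
    snp_names = [lab.rsplit("_", 1)[0] for lab in labels]
    # genotype class recovered positionally: indicators come in triples
    classes = [GENOTYPE_CLASSES[i % 3] for i in range(n_ind)]
    indicators = pd.DataFrame(
        {"snp": snp_names, "genotype_class": classes, "label": labels}
    )
    return IndicatorSet(samples=samples, indicators=indicators, values=values)
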