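"""PLINK-dialect genotype I/O, quality control and genotyping statistics.

Genotypes are held as a dense ``int8`` matrix of shape (n_samples, n_markers)
with four codes: homozygous for the first allele, heterozygous, homozygous for
the second allele, and missing.  Runs-of-homozygosity detection only ever needs
homozygous / heterozygous / missing status, but both homozygous codes are kept
so that files round-trip exactly.

The binary dialect round-trips genotype codes exactly (allele order is
recorded in the .bim).  The text dialect carries no allele-order metadata, so
on re-read the observed alleles are assigned in sorted order: at markers where
the original first allele is unobserved the two homozygous codes swap labels,
while homozygous/heterozygous/missing status — all that ROH detection uses —
is always preserved.

Supported dialects are the two classic PLINK layouts:

* text: ``.ped`` + ``.map`` (whitespace separated, two allele columns per
  marker, ``0`` for a missing allele);
* binary: ``.bed`` + ``.bim`` + ``.fam`` (SNP-major, magic bytes
  ``0x6c 0x1b 0x01``, two bits per genotype).

Population labels are taken from the family-id column, or from an optional
two-column ``sample<TAB>population`` sidecar file which takes precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Genotype codes.  HOM_A1/HOM_A2 refer to the first/second allele of the
# marker as listed in the .bim / inferred from the .ped.
HOM_A1 = 0
HET = 1
HOM_A2 = 2
MISSING = 3

_VALID_CODES = frozenset({HOM_A1, HET, HOM_A2, MISSING})

# PLINK .bed 2-bit values -> internal codes (00 hom A1, 01 missing, 10 het,
# 11 hom A2) and the inverse.
_BED_TO_CODE = np.array([HOM_A1, MISSING, HET, HOM_A2], dtype=np.int8)
_CODE_TO_BED = np.array([0b00, 0b10, 0b11, 0b01], dtype=np.uint8)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class PlinkFormatError(ValueError):
    """Raised when a PLINK file cannot be parsed."""


class QcError(ValueError):
    """Raised when quality control empties the dataset."""


@dataclass
class GenotypeDataset:
    """SNP map + sample metadata + genotype-code matrix.

    Parameters
    ----------
    snp_map
        One row per marker with columns ``chrom`` (str), ``snp`` (str),
        ``cm`` (float), ``pos`` (int, 1-based bp), ``a1``, ``a2`` (str).
        Markers must be grouped by chromosome and strictly increasing in
        position within each chromosome.
    samples
        One row per sample with columns ``fid``, ``sample``, ``father``,
        ``mother``, ``sex``, ``phenotype``, ``population``.
    genotypes
        ``int8`` array of shape (n_samples, n_markers) with the four codes.
    """

    snp_map: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self._validate()

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        m, s = self.snp_map, self.samples
        if self.genotypes.shape != (len(s), len(m)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"({len(s)} samples x {len(m)} markers)"
            )
        bad = set(np.unique(self.genotypes)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes present: {sorted(bad)}")
        if m["snp"].duplicated().any():
            dup = m.loc[m["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        if s["sample"].duplicated().any():
            dup = s.loc[s["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if s["population"].isna().any() or (s["population"] == "").any():
            raise ValueError("every sample needs a population label")
        # chromosomes must form contiguous blocks, positions strictly increasing
        chrom = m["chrom"].to_numpy()
        seen: set[str] = set()
        prev = None
        for c in chrom:
            if c != prev:
                if c in seen:
                    raise ValueError(f"markers of chromosome {c!r} are not contiguous")
                seen.add(c)
                prev = c
        for c, grp in m.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) and not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions on chromosome {c!r} are not strictly increasing"
                )

    # -- basic accessors ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.snp_map)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.snp_map["chrom"]))

    def autosomes(self) -> list[str]:
        """Chromosome labels parseable as positive integers (sex chromosomes
        and unplaced contigs are excluded from ROH scans)."""
        out = []
        for c in self.chromosomes:
            try:
                if int(c) > 0:
                    out.append(c)
            except ValueError:
                continue
        return out

    def marker_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.snp_map["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no markers on chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, sample_mask=None, marker_mask=None) -> "GenotypeDataset":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        mm = np.ones(self.n_markers, bool) if marker_mask is None else np.asarray(marker_mask, bool)
        return GenotypeDataset(
            snp_map=self.snp_map.loc[mm].copy(),
            samples=self.samples.loc[sm].copy(),
            genotypes=self.genotypes[np.ix_(sm, mm)].copy(),
        )

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))


@dataclass
class QcReport:
    """Before/after bookkeeping for the missingness filters."""

    markers_before: int
    markers_after: int
    samples_before: int
    samples_after: int
    marker_missing_fraction: pd.Series
    sample_missing_fraction: pd.Series
    genotyping_rate: float

    def __post_init__(self) -> None:
        if self.markers_after > self.markers_before or self.samples_after > self.samples_before:
            raise ValueError("after-counts cannot exceed before-counts")
        if not 0.0 <= self.genotyping_rate <= 1.0:
            raise ValueError("genotyping rate must be in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": [
                    "markers_before", "markers_after",
                    "samples_before", "samples_after",
                    "genotyping_rate",
                ],
                "value": [
                    self.markers_before, self.markers_after,
                    self.samples_before, self.samples_after,
                    self.genotyping_rate,
                ],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_map_like(path: Path, n_cols: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != n_cols:
                raise PlinkFormatError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(tok)}"
                )
            try:
                int(tok[3])
            except ValueError:
                raise PlinkFormatError(
                    f"{path}:{lineno}: position {tok[3]!r} is not an integer"
                ) from None
            rows.append(tok)
    if not rows:
        raise PlinkFormatError(f"{path}: no markers")
    cols = ["chrom", "snp", "cm", "pos"] + (["a1", "a2"] if n_cols == 6 else [])
    df = pd.DataFrame(rows, columns=cols)
    df["pos"] = df["pos"].astype(np.int64)
    df["cm"] = pd.to_numeric(df["cm"], errors="coerce").fillna(0.0)
    return df


def _sort_map(snp_map: pd.DataFrame, genotypes: np.ndarray):
    """Ensure per-chromosome ascending positions; warn if re-sorting."""
    order = np.arange(len(snp_map))
    pieces = []
    resorted = False
    for _, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        if (np.diff(pos) <= 0).any():
            if pd.Series(pos).duplicated().any():
                c = grp["chrom"].iloc[0]
                raise PlinkFormatError(f"duplicate bp position on chromosome {c!r}")
            idx = idx[np.argsort(pos, kind="stable")]
            resorted = True
        pieces.append(idx)
    order = np.concatenate(pieces)
    if resorted:
        warnings.warn("map positions out of order; markers re-sorted by position")
        snp_map = snp_map.iloc[order].reset_index(drop=True)
        genotypes = genotypes[:, order]
    return snp_map, genotypes


def _attach_populations(samples: pd.DataFrame, population_file) -> pd.DataFrame:
    samples = samples.copy()
    samples["population"] = samples["fid"].astype(str)
    if population_file is not None:
        tbl = pd.read_csv(population_file, sep=r"\s+", header=None,
                          names=["sample", "population"], dtype=str)
        mapping = dict(zip(tbl["sample"], tbl["population"]))
        missing = [s for s in samples["sample"] if s not in mapping]
        if missing:
            raise PlinkFormatError(
                f"population sidecar lacks {len(missing)} samples (e.g. {missing[0]!r})"
            )
        samples["population"] = [mapping[s] for s in samples["sample"]]
    return samples


def _read_ped_map(prefix: Path, population_file) -> GenotypeDataset:
    snp_map = _read_map_like(Path(f"{prefix}.map"), 4)
    m = len(snp_map)
    fam_rows, geno_rows = [], []
    ped = Path(f"{prefix}.ped")
    with open(ped) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped}:{lineno}: expected {6 + 2 * m} fields, got {len(tok)}"
                )
            fam_rows.append(tok[:6])
            geno_rows.append(tok[6:])
    if not fam_rows:
        raise PlinkFormatError(f"{ped}: no samples")
    alleles = np.array(geno_rows, dtype="U8").reshape(len(fam_rows), m, 2)

    a1_list, a2_list = [], []
    codes = np.empty((len(fam_rows), m), dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        obs = [a for a in np.unique(col) if a != "0"]
        if len(obs) > 2:
            raise PlinkFormatError(
                f"{ped}: marker {snp_map['snp'][j]!r} has {len(obs)} alleles"
            )
        a1 = obs[0] if obs else "0"
        a2 = obs[1] if len(obs) > 1 else "0"
        miss = (col[:, 0] == "0") | (col[:, 1] == "0")
        het = col[:, 0] != col[:, 1]
        hom1 = col[:, 0] == a1
        codes[:, j] = np.where(miss, MISSING, np.where(het, HET, np.where(hom1, HOM_A1, HOM_A2)))
        a1_list.append(a1)
        a2_list.append(a2)
    snp_map = snp_map.assign(a1=a1_list, a2=a2_list)

    samples = pd.DataFrame(fam_rows, columns=["fid", "sample", "father", "mother", "sex", "phenotype"])
    samples = _attach_populations(samples, population_file)
    snp_map, codes = _sort_map(snp_map, codes)
    return GenotypeDataset(snp_map, samples, codes)


def _read_bed(prefix: Path, population_file) -> GenotypeDataset:
    snp_map = _read_map_like(Path(f"{prefix}.bim"), 6)
    fam = Path(f"{prefix}.fam")
    fam_rows = []
    with open(fam) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6:
                raise PlinkFormatError(f"{fam}:{lineno}: expected 6 fields")
            fam_rows.append(tok)
    samples = pd.DataFrame(fam_rows, columns=["fid", "sample", "father", "mother", "sex", "phenotype"])
    samples = _attach_populations(samples, population_file)

    n, m = len(samples), len(snp_map)
    bed = Path(f"{prefix}.bed")
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes (not SNP-major PLINK .bed)")
    nb = (n + 3) // 4
    body = raw[3:]
    if body.size != m * nb:
        raise PlinkFormatError(
            f"{bed}: size mismatch ({body.size} bytes for {m} markers x {nb} bytes)"
        )
    body = body.reshape(m, nb)
    two_bit = np.empty((m, nb * 4), dtype=np.uint8)
    for k in range(4):
        two_bit[:, k::4] = (body >> (2 * k)) & 0b11
    codes = _BED_TO_CODE[two_bit[:, :n]].T.copy()

    snp_map, codes = _sort_map(snp_map, codes)
    return GenotypeDataset(snp_map, samples, codes)


def read_plink(path_prefix, dialect: str | None = None,
               population_file=None) -> GenotypeDataset:
    """Read a PLINK fileset into a :class:`GenotypeDataset`.

    ``dialect`` is ``"ped"`` (text) or ``"bed"`` (binary); when ``None`` it is
    auto-detected from which files exist (binary preferred).
    """
    prefix = Path(path_prefix)
    if dialect is None:
        dialect = "bed" if Path(f"{prefix}.bed").exists() else "ped"
    if dialect == "ped":
        for ext in (".ped", ".map"):
            if not Path(f"{prefix}{ext}").exists():
                raise FileNotFoundError(f"{prefix}{ext}")
        return _read_ped_map(prefix, population_file)
    if dialect == "bed":
        for ext in (".bed", ".bim", ".fam"):
            if not Path(f"{prefix}{ext}").exists():
                raise FileNotFoundError(f"{prefix}{ext}")
        return _read_bed(prefix, population_file)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_plink(ds: GenotypeDataset, path_prefix, dialect: str = "ped") -> None:
    """Write ``ds`` as a PLINK fileset (text ``ped`` or binary ``bed``)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    m = ds.snp_map
    fam_cols = ["fid", "sample", "father", "mother", "sex", "phenotype"]
    if dialect == "ped":
        with open(f"{prefix}.map", "w") as fh:
            for _, r in m.iterrows():
                fh.write(f"{r['chrom']}\t{r['snp']}\t{r['cm']:g}\t{r['pos']}\n")
        a1 = m["a1"].to_numpy(dtype="U8")
        a2 = m["a2"].to_numpy(dtype="U8")
        with open(f"{prefix}.ped", "w") as fh:
            for i, (_, s) in enumerate(ds.samples.iterrows()):
                g = ds.genotypes[i]
                first = np.choose(g, [a1, a1, a2, np.full_like(a1, "0")])
                second = np.choose(g, [a1, a2, a2, np.full_like(a1, "0")])
                pair = np.empty(2 * len(a1), dtype="U8")
                pair[0::2] = first
                pair[1::2] = second
                fh.write(" ".join(str(s[c]) for c in fam_cols) + " " + " ".join(pair) + "\n")
    elif dialect == "bed":
        with open(f"{prefix}.bim", "w") as fh:
            for _, r in m.iterrows():
                fh.write(f"{r['chrom']}\t{r['snp']}\t{r['cm']:g}\t{r['pos']}\t{r['a1']}\t{r['a2']}\n")
        with open(f"{prefix}.fam", "w") as fh:
            for _, s in ds.samples.iterrows():
                fh.write(" ".join(str(s[c]) for c in fam_cols) + "\n")
        n = ds.n_samples
        nb = (n + 3) // 4
        bed_vals = _CODE_TO_BED[ds.genotypes.T]  # (m, n)
        padded = np.zeros((ds.n_markers, nb * 4), dtype=np.uint8)
        padded[:, :n] = bed_vals
        body = np.zeros((ds.n_markers, nb), dtype=np.uint8)
        for k in range(4):
            body |= padded[:, k::4] << (2 * k)
        with open(f"{prefix}.bed", "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(body.tobytes())
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_population_sidecar(ds: GenotypeDataset, path) -> None:
    ds.samples[["sample", "population"]].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def genotyping_rate(ds: GenotypeDataset) -> float:
    """Fraction of non-missing cells in the genotype matrix."""
    if ds.genotypes.size == 0:
        raise ValueError("empty dataset")
    return float(1.0 - (ds.genotypes == MISSING).mean())


def apply_qc(ds: GenotypeDataset, max_marker_missing: float = 0.1,
             max_sample_missing: float = 0.1) -> tuple[GenotypeDataset, QcReport]:
    """Missingness QC: drop markers with missing fraction > ``max_marker_missing``,
    then samples with missing fraction (over surviving markers) >
    ``max_sample_missing``.

    Mirrors the behaviour of PLINK's ``--geno``/``--mind`` pair: the marker
    filter runs first, and strict inequality is used.  No minor-allele-
    frequency filter is ever applied — rare alleles are informative for runs
    of homozygosity.
    """
    for t in (max_marker_missing, max_sample_missing):
        if not 0.0 <= t <= 1.0:
            raise ValueError("missingness thresholds must be in [0, 1]")
    miss = ds.genotypes == MISSING
    marker_frac = pd.Series(miss.mean(axis=0), index=ds.snp_map["snp"].to_numpy(),
                            name="missing_fraction")
    keep_markers = marker_frac.to_numpy() <= max_marker_missing
    if not keep_markers.any():
        raise QcError("all markers removed by the marker-missingness filter")
    sample_frac_surv = miss[:, keep_markers].mean(axis=1)
    sample_frac = pd.Series(sample_frac_surv, index=ds.samples["sample"].to_numpy(),
                            name="missing_fraction")
    keep_samples = sample_frac_surv <= max_sample_missing
    if not keep_samples.any():
        raise QcError("all samples removed by the sample-missingness filter")
    out = ds.subset(keep_samples, keep_markers)
    report = QcReport(
        markers_before=ds.n_markers,
        markers_after=out.n_markers,
        samples_before=ds.n_samples,
        samples_after=out.n_samples,
        marker_missing_fraction=marker_frac,
        sample_missing_fraction=sample_frac,
        genotyping_rate=genotyping_rate(out),
    )
    return out, report


def apply_qc_per_population(ds: GenotypeDataset, max_marker_missing: float = 0.1,
                            max_sample_missing: float = 0.1) -> tuple[GenotypeDataset, QcReport]:
    """Per-population variant of :func:`apply_qc`: a marker is dropped when it
    fails the missingness threshold within any single population, then samples
    are filtered on the surviving markers (pooled)."""
    miss = ds.genotypes == MISSING
    keep_markers = np.ones(ds.n_markers, bool)
    for pop in ds.populations():
        rows = (ds.samples["population"] == pop).to_numpy()
        keep_markers &= miss[rows].mean(axis=0) <= max_marker_missing
    if not keep_markers.any():
        raise QcError("all markers removed by the per-population marker filter")
    trimmed = ds.subset(marker_mask=keep_markers)
    out, rep = apply_qc(trimmed, max_marker_missing=1.0, max_sample_missing=max_sample_missing)
    report = QcReport(
        markers_before=ds.n_markers,
        markers_after=out.n_markers,
        samples_before=ds.n_samples,
        samples_after=out.n_samples,
        marker_missing_fraction=pd.Series(miss.mean(axis=0), index=ds.snp_map["snp"].to_numpy()),
        sample_missing_fraction=rep.sample_missing_fraction,
        genotyping_rate=genotyping_rate(out),
    )
    return out, report
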