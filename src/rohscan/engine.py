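"""Consecutive-runs detection of runs of homozygosity (ROH).

The detector scans markers in chromosomal order and extends a run until an
allowance is violated, in the spirit of the consecutive-runs method of Marras
et al. as implemented by detectRUNS' ``consecutiveRUNS`` — no sliding windows.
A run is a maximal stretch of consecutive markers that

* contains at most ``max_het`` heterozygous and ``max_missing`` missing calls,
* never has two adjacent markers more than ``max_gap_bp`` apart,
* starts and ends on a homozygous, non-missing call (boundary calls that
  consume allowances are trimmed off).

A heterozygous (or missing) call that would exceed its allowance terminates
the run before that call; scanning resumes after it.  Runs with fewer than
``min_snp`` markers or spanning less than ``min_len_bp`` are discarded after
detection.

Detection is calibrated in two passes.  Pass 1 finds all candidate runs with
permissive allowances and groups them into five length classes (1–2, 2–4,
4–8, 8–16, >16 Mb).  From each class's mean SNP count, per-class allowances
are derived as ``round(mean_snp_count * rate)`` using an assumed genotyping
error rate (default 0.25%, producing spurious heterozygotes inside autozygous
tracts) and the dataset's missing-call rate (default 0.14%).  Pass 2 re-scans
once per class with that class's allowances and minimum length, keeps the
runs whose realized length falls inside the class that was scanned for, and
reconciles overlaps so each genomic stretch yields one segment.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenotypeDataset, HET, HOM_A1, HOM_A2, MISSING

MB = 1_000_000


class CalibrationError(ValueError):
    """Raised when no length class holds any pass-1 run."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RohCallConfig:
    """Tunable parameters of the two-pass consecutive-runs detector.

    ``class_bounds_mb`` are the lower edges of the length classes in Mb; the
    last class is open-ended.  ``rounding`` controls how fractional allowance
    values are turned into integers during calibration (``nearest`` uses
    round-half-up).  ``min_allowance`` floors calibrated allowances for
    populated classes (the conventional minimum of one).  Pass 1 uses the
    permissive ``pass1_max_het``/``pass1_max_missing`` so that it never
    under-segments relative to pass 2.  ``calibration_basis`` selects whether
    allowances derive from mean SNP counts (default) or mean bp lengths (a
    sensitivity-analysis option; bp-based allowances are orders of magnitude
    larger and not recommended).
    """

    min_snp: int = 15
    max_gap_bp: int = 100_000
    genotype_error_rate: float = 0.0025
    missing_rate: float = 0.0014
    class_bounds_mb: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    rounding: str = "nearest"
    min_allowance: int = 1
    pass1_max_het: int = 12
    pass1_max_missing: int = 8
    calibration_basis: str = "snp"

    def __post_init__(self) -> None:
        if self.min_snp < 2:
            raise ValueError("min_snp must be >= 2")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be positive")
        for r in (self.genotype_error_rate, self.missing_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")
        b = self.class_bounds_mb
        if len(b) < 1 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("class bounds must be strictly increasing")
        if self.rounding not in ("nearest", "floor", "ceiling"):
            raise ValueError("rounding must be nearest/floor/ceiling")
        if self.calibration_basis not in ("snp", "bp"):
            raise ValueError("calibration_basis must be 'snp' or 'bp'")
        if self.min_allowance < 0:
            raise ValueError("min_allowance must be >= 0")

    @property
    def class_labels(self) -> list[str]:
        b = self.class_bounds_mb
        labels = [f"{_fmt_mb(b[i])}-{_fmt_mb(b[i + 1])}Mb" for i in range(len(b) - 1)]
        labels.append(f">{_fmt_mb(b[-1])}Mb")
        return labels

    @property
    def min_length_bp(self) -> int:
        return int(self.class_bounds_mb[0] * MB)


def _fmt_mb(x: float) -> str:
    return f"{x:g}"


def classify_roh(length_bp: int, class_bounds_mb=( 1.0, 2.0, 4.0, 8.0, 16.0)) -> str:
    """Assign a run length to its half-open length class ``[lower, upper)``."""
    b = class_bounds_mb
    if length_bp < b[0] * MB:
        raise ValueError(f"length {length_bp} bp is below the smallest class bound")
    for i in range(len(b) - 1):
        if length_bp < b[i + 1] * MB:
            return f"{_fmt_mb(b[i])}-{_fmt_mb(b[i + 1])}Mb"
    return f">{_fmt_mb(b[-1])}Mb"


# ---------------------------------------------------------------------------
# the scanner
# ---------------------------------------------------------------------------

def scan_consecutive(genotypes: np.ndarray, positions: np.ndarray, *,
                     max_het: int, max_missing: int, min_snp: int,
                     min_len_bp: int, max_gap_bp: int) -> list[tuple]:
    """Detect maximal runs on one chromosome of one individual.

    Returns a list of ``(start_idx, end_idx, n_snp, n_het, n_missing,
    length_bp)`` tuples with inclusive marker indices, ordered and disjoint.
    """
    geno = np.asarray(genotypes)
    pos = np.asarray(positions, dtype=np.int64)
    if geno.shape != pos.shape:
        raise ValueError("genotypes and positions must have equal length")
    if pos.size == 0:
        return []
    if pos.size > 1 and not (np.diff(pos) > 0).all():
        raise ValueError("positions must be sorted strictly ascending")

    is_hom = (geno == HOM_A1) | (geno == HOM_A2)
    hom_idx = np.flatnonzero(is_hom)
    if hom_idx.size == 0:
        return []
    het_idx = np.flatnonzero(geno == HET)
    mis_idx = np.flatnonzero(geno == MISSING)
    ev_idx = np.flatnonzero(~is_hom)
    ev_is_het = geno[ev_idx] == HET
    cum_het = np.cumsum(ev_is_het)
    cum_mis = np.cumsum(~ev_is_het)

    # blocks delimited by gaps larger than max_gap_bp
    breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
    block_edges = np.concatenate(([0], breaks + 1, [pos.size]))

    runs: list[tuple] = []
    for bi in range(len(block_edges) - 1):
        lo, hi = int(block_edges[bi]), int(block_edges[bi + 1]) - 1  # inclusive
        # first homozygous marker in block
        h = np.searchsorted(hom_idx, lo)
        if h == hom_idx.size or hom_idx[h] > hi:
            continue
        start = int(hom_idx[h])
        while start is not None and start <= hi:
            k0 = int(np.searchsorted(ev_idx, start))
            base_h = cum_het[k0 - 1] if k0 > 0 else 0
            base_m = cum_mis[k0 - 1] if k0 > 0 else 0
            k_h = int(np.searchsorted(cum_het, base_h + max_het, side="right"))
            k_m = int(np.searchsorted(cum_mis, base_m + max_missing, side="right"))
            k_break = min(k_h, k_m)
            if k_break < ev_idx.size and ev_idx[k_break] <= hi:
                e = int(ev_idx[k_break])
                # end = last homozygous marker before the violating call
                p = int(np.searchsorted(hom_idx, e)) - 1
                end = int(hom_idx[p])
                _emit(runs, start, end, pos, het_idx, mis_idx, min_snp, min_len_bp)
                nh = int(np.searchsorted(hom_idx, e + 1))
                if nh == hom_idx.size or hom_idx[nh] > hi:
                    break
                start = int(hom_idx[nh])
            else:
                # run reaches the end of the block
                p = int(np.searchsorted(hom_idx, hi, side="right")) - 1
                end = int(hom_idx[p])
                _emit(runs, start, end, pos, het_idx, mis_idx, min_snp, min_len_bp)
                break
    return runs


def _emit(runs, start, end, pos, het_idx, mis_idx, min_snp, min_len_bp):
    n_snp = end - start + 1
    length = int(pos[end] - pos[start])
    if n_snp < min_snp or length < min_len_bp:
        return
    n_het = int(np.searchsorted(het_idx, end, side="right") - np.searchsorted(het_idx, start))
    n_mis = int(np.searchsorted(mis_idx, end, side="right") - np.searchsorted(mis_idx, start))
    runs.append((start, end, n_snp, n_het, n_mis, length))


# ---------------------------------------------------------------------------
# run collections
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["sample", "population", "chrom", "start_bp", "end_bp",
                   "start_idx", "end_idx", "n_snp", "n_het", "n_missing",
                   "length_bp", "class"]


@dataclass
class RohSet:
    """A collection of detected ROH segments plus provenance.

    ``segments`` has one row per run with the columns in
    :data:`SEGMENT_COLUMNS`; ``start_idx``/``end_idx`` are inclusive marker
    indices within the chromosome's marker array of the scanned dataset.
    """

    segments: pd.DataFrame
    config: RohCallConfig
    pass_number: int
    dataset_fingerprint: str = ""

    def __post_init__(self) -> None:
        if list(self.segments.columns) != SEGMENT_COLUMNS:
            self.segments = self.segments.reindex(columns=SEGMENT_COLUMNS)

    def __len__(self) -> int:
        return len(self.segments)

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.segments[self.segments["sample"] == sample]

    def for_population(self, population: str) -> pd.DataFrame:
        return self.segments[self.segments["population"] == population]

    def for_chromosome(self, chrom: str) -> pd.DataFrame:
        return self.segments[self.segments["chrom"] == chrom]

    def for_class(self, label: str) -> pd.DataFrame:
        return self.segments[self.segments["class"] == label]

    def write_tsv(self, path) -> None:
        self.segments.to_csv(path, sep="\t", index=False)


def dataset_fingerprint(ds: GenotypeDataset) -> str:
    h = hashlib.sha256()
    h.update(ds.genotypes.tobytes())
    h.update(",".join(ds.snp_map["snp"]).encode())
    h.update(",".join(ds.samples["sample"]).encode())
    return h.hexdigest()[:16]


def _sorted_samples(ds: GenotypeDataset) -> pd.DataFrame:
    # deterministic order regardless of input sample order
    return ds.samples.sort_values("sample", kind="stable")


def _collect(ds: GenotypeDataset, rows: list[dict], cfg: RohCallConfig,
             pass_number: int) -> RohSet:
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    seg = seg.sort_values(["sample", "chrom", "start_idx"], kind="stable").reset_index(drop=True)
    return RohSet(seg, cfg, pass_number, dataset_fingerprint(ds))


def first_pass_roh(ds: GenotypeDataset, cfg: RohCallConfig = RohCallConfig()) -> RohSet:
    """Pass 1: detect all candidate runs with permissive allowances.

    Runs at least 1 Mb long (the smallest class bound) with at least
    ``cfg.min_snp`` markers are kept and labelled with their length class;
    their per-class mean sizes feed :func:`calibrate_class_params`.
    """
    rows: list[dict] = []
    for chrom in ds.autosomes():
        sl = ds.marker_slice(chrom)
        pos = ds.snp_map["pos"].to_numpy()[sl]
        for _, srow in _sorted_samples(ds).iterrows():
            i = int(srow.name)
            geno = ds.genotypes[i, sl]
            for (s, e, n, nh, nm, ln) in scan_consecutive(
                    geno, pos, max_het=cfg.pass1_max_het,
                    max_missing=cfg.pass1_max_missing, min_snp=cfg.min_snp,
                    min_len_bp=cfg.min_length_bp, max_gap_bp=cfg.max_gap_bp):
                rows.append(dict(sample=srow["sample"], population=srow["population"],
                                 chrom=chrom, start_bp=int(pos[s]), end_bp=int(pos[e]),
                                 start_idx=s, end_idx=e, n_snp=n, n_het=nh,
                                 n_missing=nm, length_bp=ln,
                                 **{"class": classify_roh(ln, cfg.class_bounds_mb)}))
    return _collect(ds, rows, cfg, pass_number=1)


@dataclass
class RohClassParams:
    """Per-length-class allowances calibrated from pass 1.

    ``table`` has one row per class with columns ``class``, ``min_length_bp``,
    ``mean_snp_count``, ``mean_length_bp``, ``n_runs``, ``max_het``,
    ``max_missing``, ``inherited`` (True where an empty class borrowed its
    neighbour's allowances).
    """

    table: pd.DataFrame

    def row(self, label: str) -> pd.Series:
        m = self.table[self.table["class"] == label]
        if m.empty:
            raise KeyError(label)
        return m.iloc[0]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _round(x: float, rule: str) -> int:
    if rule == "nearest":
        return int(math.floor(x + 0.5))
    if rule == "floor":
        return int(math.floor(x))
    return int(math.ceil(x))


def calibrate_class_params(pass1: RohSet | pd.DataFrame,
                           cfg: RohCallConfig = RohCallConfig()) -> RohClassParams:
    """Derive per-class heterozygote/missing allowances from pass-1 run sizes.

    For each populated class: ``max_het = round(mean_snp_count *
    genotype_error_rate)`` and ``max_missing = round(mean_snp_count *
    missing_rate)``, floored at ``cfg.min_allowance``.  Classes without any
    pass-1 run inherit the nearest populated class's allowances (a warning is
    emitted).  With ``calibration_basis='bp'`` the mean bp length replaces
    the mean SNP count.
    """
    seg = pass1.segments if isinstance(pass1, RohSet) else pass1
    labels = cfg.class_labels
    bounds = cfg.class_bounds_mb
    rows = []
    for i, lab in enumerate(labels):
        grp = seg[seg["class"] == lab]
        rows.append(dict(
            **{"class": lab},
            min_length_bp=int(bounds[i] * MB),
            mean_snp_count=float(grp["n_snp"].mean()) if len(grp) else np.nan,
            mean_length_bp=float(grp["length_bp"].mean()) if len(grp) else np.nan,
            n_runs=len(grp),
        ))
    tbl = pd.DataFrame(rows)
    if (tbl["n_runs"] == 0).all():
        raise CalibrationError("no pass-1 runs in any length class")

    basis = "mean_snp_count" if cfg.calibration_basis == "snp" else "mean_length_bp"
    het, mis, inherited = [], [], []
    populated = tbl.index[tbl["n_runs"] > 0].to_numpy()
    for i in range(len(tbl)):
        if tbl.loc[i, "n_runs"] > 0:
            m = tbl.loc[i, basis]
            het.append(max(_round(m * cfg.genotype_error_rate, cfg.rounding), cfg.min_allowance))
            mis.append(max(_round(m * cfg.missing_rate, cfg.rounding), cfg.min_allowance))
            inherited.append(False)
        else:
            het.append(-1)
            mis.append(-1)
            inherited.append(True)
    for i in range(len(tbl)):
        if inherited[i]:
            j = populated[np.argmin(np.abs(populated - i))]
            het[i], mis[i] = het[j], mis[j]
            warnings.warn(f"class {tbl.loc[i, 'class']} empty in pass 1; "
                          f"inheriting allowances from {tbl.loc[j, 'class']}")
    tbl["max_het"] = het
    tbl["max_missing"] = mis
    tbl["inherited"] = inherited
    return RohClassParams(tbl)


def second_pass_roh(ds: GenotypeDataset, params: RohClassParams,
                    cfg: RohCallConfig = RohCallConfig()) -> RohSet:
    """Pass 2: per-class scans with calibrated allowances, reconciled.

    For each class the chromosome is re-scanned with that class's
    ``(max_het, max_missing, min_length_bp)``.  Every candidate is assigned
    to the class matching its realized length; identical candidates from
    several scans are deduplicated.  Overlapping candidates for one
    individual are reconciled so each genomic stretch yields one segment:
    a candidate whose realized length falls inside the class bounds it was
    scanned for wins over overlapping candidates that do not, ties broken by
    the longer segment, then fewer heterozygotes, then the leftmost.  Each
    segment honours the allowances of the scan that produced it.
    """
    labels = cfg.class_labels
    bounds = cfg.class_bounds_mb
    upper = [bounds[i + 1] * MB for i in range(len(bounds) - 1)] + [np.inf]
    rows: list[dict] = []
    for chrom in ds.autosomes():
        sl = ds.marker_slice(chrom)
        pos = ds.snp_map["pos"].to_numpy()[sl]
        for _, srow in _sorted_samples(ds).iterrows():
            i = int(srow.name)
            geno = ds.genotypes[i, sl]
            cands: dict[tuple[int, int], list] = {}
            for ci, lab in enumerate(labels):
                p = params.row(lab)
                lo_bp = int(p["min_length_bp"])
                for (s, e, n, nh, nm, ln) in scan_consecutive(
                        geno, pos, max_het=int(p["max_het"]),
                        max_missing=int(p["max_missing"]), min_snp=cfg.min_snp,
                        min_len_bp=lo_bp, max_gap_bp=cfg.max_gap_bp):
                    matched = lo_bp <= ln < upper[ci]
                    realized = classify_roh(ln, bounds)
                    prev = cands.get((s, e))
                    if prev is None or (matched and not prev[6]):
                        cands[(s, e)] = [s, e, n, nh, nm, ln, matched, realized]
            # matched candidates win; then longer, fewer het, leftmost
            chosen: list[list] = []
            for c in sorted(cands.values(), key=lambda c: (not c[6], -c[5], c[3], c[0])):
                if all(c[1] < t[0] or c[0] > t[1] for t in chosen):
                    chosen.append(c)
            for (s, e, n, nh, nm, ln, matched, lab) in sorted(chosen, key=lambda c: c[0]):
                rows.append(dict(sample=srow["sample"], population=srow["population"],
                                 chrom=chrom, start_bp=int(pos[s]), end_bp=int(pos[e]),
                                 start_idx=s, end_idx=e, n_snp=n, n_het=nh,
                                 n_missing=nm, length_bp=ln, **{"class": lab}))
    return _collect(ds, rows, cfg, pass_number=2)


def detect_roh(ds: GenotypeDataset, cfg: RohCallConfig = RohCallConfig()
               ) -> tuple[RohSet, RohClassParams, RohSet]:
    """Convenience wrapper: pass 1, calibration, pass 2.

    Returns ``(pass2, params, pass1)``.
    """
    p1 = first_pass_roh(ds, cfg)
    params = calibrate_class_params(p1, cfg)
    p2 = second_pass_roh(ds, params, cfg)
    return p2, params, p1
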